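"""Genome model, fixed-width genomic binning and interval arithmetic.

All coordinates are 0-based half-open throughout the package.  Annotation
interval sets (promoter, CpG island/shore/shelf, open sea, repeats, ...) are
stored per chromosome as sorted, merged ``(start, end)`` arrays so that
bin-vs-annotation overlap reduces to a single ``searchsorted`` pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeModel",
    "BinSet",
    "bin_genome",
    "merge_intervals",
    "overlaps_any",
]


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Sort and merge possibly overlapping half-open intervals (N x 2)."""
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if len(iv) == 0:
        return iv
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def overlaps_any(starts, ends, intervals: np.ndarray) -> np.ndarray:
    """Boolean mask: does [starts[i], ends[i]) intersect any merged interval?

    ``intervals`` must be sorted and non-overlapping (see merge_intervals);
    an overlap is >= 1 bp of shared sequence.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if len(intervals) == 0:
        return np.zeros(len(starts), dtype=bool)
    idx = np.searchsorted(intervals[:, 0], ends, side="left") - 1
    ok = idx >= 0
    hit = np.zeros(len(starts), dtype=bool)
    hit[ok] = intervals[idx[ok], 1] > starts[ok]
    return hit


@dataclass
class GenomeModel:
    """A (possibly toy) genome: chromosome sizes, CpG positions, annotations.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    cpg_positions
        Per chromosome, sorted positions of CpG dinucleotides (position of
        the C), 0-based.
    annotations
        ``{category: {chrom: merged interval array}}``; categories typically
        include promoter, cpg_island, cpg_shore, cpg_shelf, open_sea,
        intergenic and repeat.
    centromere_gaps
        One ``(start, end)`` assembly-gap interval per chromosome.
    """

    chromosomes: list[tuple[str, int]]
    cpg_positions: dict[str, np.ndarray] = field(default_factory=dict)
    annotations: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    centromere_gaps: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("GenomeModel requires at least one chromosome")
        lengths = dict(self.chromosomes)
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for chrom, pos in self.cpg_positions.items():
            pos = np.asarray(pos)
            if len(pos) and (pos.min() < 0 or pos.max() >= lengths[chrom]):
                raise ValueError(f"CpG positions out of bounds on {chrom}")
        for cat, per_chrom in self.annotations.items():
            for chrom, iv in per_chrom.items():
                iv = np.asarray(iv).reshape(-1, 2)
                if len(iv) and (np.any(iv[:, 0] >= iv[:, 1]) or iv[-1, 1] > lengths[chrom]):
                    raise ValueError(f"annotation {cat} out of bounds on {chrom}")

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def chrom_length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def cpg_density(self) -> float:
        """Genome-wide CpG dinucleotides per base."""
        n = sum(len(self.cpg_positions.get(c, ())) for c in self.chrom_names)
        return n / self.total_length

    def annotation_intervals(self, category: str, chrom: str) -> np.ndarray:
        return np.asarray(
            self.annotations.get(category, {}).get(chrom, np.empty((0, 2), dtype=np.int64))
        ).reshape(-1, 2)


@dataclass
class BinSet:
    """Fixed-width, non-overlapping tiling of a genome.

    Bins are sorted by (chromosome order, start); the last bin of a
    chromosome may be shorter than ``width``.
    """

    chroms: np.ndarray          # str per bin
    starts: np.ndarray
    ends: np.ndarray
    cpg_counts: np.ndarray
    width: int
    chrom_offsets: dict[str, int]   # chrom -> index of its first bin
    chrom_nbins: dict[str, int]

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def bin_ids(self) -> np.ndarray:
        return np.array(
            [f"{c}:{s}-{e}" for c, s, e in zip(self.chroms, self.starts, self.ends)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "cpg_count": self.cpg_counts,
            },
            index=self.bin_ids,
        )

    def assign(self, chroms, positions) -> np.ndarray:
        """Map genomic positions to global bin indices.

        Raises KeyError listing unknown chromosomes.
        """
        chroms = np.asarray(chroms)
        positions = np.asarray(positions, dtype=np.int64)
        out = np.empty(len(positions), dtype=np.int64)
        unknown = set()
        for chrom in pd.unique(chroms):
            mask = chroms == chrom
            if chrom not in self.chrom_offsets:
                unknown.add(str(chrom))
                continue
            local = positions[mask] // self.width
            local = np.minimum(local, self.chrom_nbins[chrom] - 1)
            out[mask] = self.chrom_offsets[chrom] + local
        if unknown:
            raise KeyError(f"fragments on unknown chromosome(s): {sorted(unknown)}")
        return out


def bin_genome(genome: GenomeModel, width: int = 300) -> BinSet:
    """Tile every chromosome into non-overlapping windows of ``width`` bp.

    Per-bin CpG counts are computed from the genome's CpG positions.
    """
    if width <= 0:
        raise ValueError("bin width must be >= 1")
    chroms, starts, ends, cpgs = [], [], [], []
    offsets: dict[str, int] = {}
    nbins: dict[str, int] = {}
    for name, length in genome.chromosomes:
        edges = np.arange(0, length + width, width)
        edges[-1] = min(edges[-1], length)
        if edges[-1] == edges[-2]:
            edges = edges[:-1]
        s, e = edges[:-1], edges[1:]
        chroms.append(np.repeat(name, len(s)))
        starts.append(s)
        ends.append(e)
        pos = np.asarray(genome.cpg_positions.get(name, np.empty(0, dtype=np.int64)))
        cpgs.append(np.searchsorted(pos, e) - np.searchsorted(pos, s))
        nbins[name] = len(s)
    off = 0
    for name, _ in genome.chromosomes:
        offsets[name] = off
        off += nbins[name]
    return BinSet(
        chroms=np.concatenate(chroms),
        starts=np.concatenate(starts).astype(np.int64),
        ends=np.concatenate(ends).astype(np.int64),
        cpg_counts=np.concatenate(cpgs).astype(np.int64),
        width=width,
        chrom_offsets=offsets,
        chrom_nbins=nbins,
    )
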
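"""Bin-level quantification of cfMeDIP fragments.

Fragments are assigned to the single bin containing their midpoint, counts
are normalized to RPKM using the total fragment count as library size, and
the analysis universe is restricted to "non-low" bins — bins exceeding
5 RPKM in at least one sample of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BinCountMatrix, FragmentTable
from .genome import BinSet, GenomeModel

__all__ = [
    "count_fragments", "count_matrix", "rpkm", "filter_nonlow",
    "cpg_enrichment", "QCReport", "qc_report",
]


def count_fragments(fragments: FragmentTable, bins: BinSet) -> tuple[np.ndarray, int]:
    """Count fragments per bin by the midpoint rule.

    Each fragment increments exactly one bin: the one containing
    ``floor((start + end) / 2)``.  Returns the count vector and the library
    size (total fragments).  Fragments on chromosomes absent from the bin
    set raise a KeyError listing the offenders.
    """
    counts = np.zeros(len(bins), dtype=np.int64)
    if len(fragments) == 0:
        return counts, 0
    idx = bins.assign(fragments.df["chrom"].to_numpy(), fragments.midpoints)
    np.add.at(counts, idx, 1)
    return counts, len(fragments)


def count_matrix(fragments: FragmentTable, bins: BinSet) -> BinCountMatrix:
    """Build a bins x samples count matrix from a pooled fragment table."""
    cols, libs = {}, {}
    for sample_id, grp in fragments.df.groupby("sample_id", sort=True):
        col, lib = count_fragments(FragmentTable(grp), bins)
        cols[sample_id] = col
        libs[sample_id] = lib
    counts = pd.DataFrame(cols, index=bins.bin_ids)
    return BinCountMatrix(counts, pd.Series(libs))


def rpkm(mat: BinCountMatrix) -> BinCountMatrix:
    """Attach the RPKM layer: count / (bin length in kb x library size in millions)."""
    libs = mat.lib_sizes.to_numpy(dtype=float)
    if (libs <= 0).any():
        bad = list(mat.lib_sizes.index[mat.lib_sizes <= 0])
        raise ValueError(f"library size is zero for sample(s) {bad}")
    kb = mat.bin_lengths / 1_000.0
    vals = mat.counts.to_numpy(dtype=float) / (kb[:, None] * (libs[None, :] / 1e6))
    mat.rpkm = pd.DataFrame(vals, index=mat.counts.index, columns=mat.counts.columns)
    return mat


def filter_nonlow(mat: BinCountMatrix, threshold: float = 5.0) -> BinCountMatrix:
    """Keep bins whose RPKM strictly exceeds ``threshold`` in >= 1 sample.

    The cohort passed in defines the universe; callers doing train/test
    splits must pass the training samples only.
    """
    if mat.rpkm is None:
        mat = rpkm(mat)
    keep = (mat.rpkm.to_numpy() > threshold).any(axis=1)
    return mat.subset_bins(mat.counts.index[keep])


def cpg_enrichment(fragments: FragmentTable, genome: GenomeModel) -> float:
    """CpG enrichment fold of the sequenced fragments (relH-style).

    Observed CpG dinucleotides per base across all fragment intervals,
    divided by the genome-wide CpG density.  Returns NaN for an empty
    fragment table.
    """
    dens_genome = genome.cpg_density()
    if dens_genome <= 0:
        raise ValueError("genome has zero CpG density")
    if len(fragments) == 0:
        return float("nan")
    total_cpg = 0
    total_bp = 0
    for chrom, grp in fragments.df.groupby("chrom", sort=False):
        pos = np.asarray(genome.cpg_positions.get(str(chrom), np.empty(0, dtype=np.int64)))
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        total_cpg += int(np.sum(np.searchsorted(pos, e) - np.searchsorted(pos, s)))
        total_bp += int(np.sum(e - s))
    return (total_cpg / total_bp) / dens_genome


@dataclass
class QCReport:
    """Per-sample sequencing QC: depth, breadth of coverage, CpG enrichment."""

    table: pd.DataFrame  # index sample_id; total_fragments, genome_covered, cpg_fold

    def __post_init__(self) -> None:
        cov = self.table["genome_covered"].dropna()
        if ((cov < 0) | (cov > 1)).any():
            raise ValueError("covered fraction outside [0, 1]")


def qc_report(fragments: FragmentTable, bins: BinSet, genome: GenomeModel) -> QCReport:
    rows = {}
    for sample_id, grp in fragments.df.groupby("sample_id", sort=True):
        ft = FragmentTable(grp)
        col, lib = count_fragments(ft, bins)
        rows[sample_id] = {
            "total_fragments": lib,
            "genome_covered": float((col > 0).mean()),
            "cpg_fold": cpg_enrichment(ft, genome),
        }
    return QCReport(pd.DataFrame(rows).T)
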
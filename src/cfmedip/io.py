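"""Readers and writers for the package's plain-text formats.

Everything round-trips exactly: integer columns bitwise, floats to full
``repr`` precision (pandas ``float_format=None``).  All files are TSV; BED
is written 0-based half-open, which is also the internal convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BinCountMatrix, FragmentTable, SampleSheet

__all__ = [
    "load_sample_sheet", "save_sample_sheet",
    "load_count_matrix", "save_count_matrix",
    "load_fragments", "save_fragments",
    "load_bed", "save_bed",
]


def load_sample_sheet(path) -> SampleSheet:
    """Read a TSV sample sheet; validation errors name the offending row."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str, "batch": str})
    return SampleSheet(df)


def save_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.df.to_csv(path, sep="\t", index=False)


def save_count_matrix(mat: BinCountMatrix, prefix) -> None:
    """Write ``<prefix>.counts.tsv`` and ``<prefix>.libsizes.tsv``.

    The counts file has a ``bin_id`` first column and sample-id headers; the
    optional RPKM layer goes to ``<prefix>.rpkm.tsv``.
    """
    prefix = Path(prefix)
    out = mat.counts.copy()
    out.insert(0, "bin_id", out.index)
    out.to_csv(prefix.with_suffix(".counts.tsv"), sep="\t", index=False)
    mat.lib_sizes.rename("lib_size").rename_axis("sample_id").to_csv(
        prefix.with_suffix(".libsizes.tsv"), sep="\t"
    )
    if mat.rpkm is not None:
        rp = mat.rpkm.copy()
        rp.insert(0, "bin_id", rp.index)
        rp.to_csv(prefix.with_suffix(".rpkm.tsv"), sep="\t", index=False)


def load_count_matrix(prefix) -> BinCountMatrix:
    prefix = Path(prefix)
    counts = pd.read_csv(prefix.with_suffix(".counts.tsv"), sep="\t", index_col="bin_id")
    counts = counts.astype(np.int64)
    libs = pd.read_csv(
        prefix.with_suffix(".libsizes.tsv"), sep="\t", index_col="sample_id"
    )["lib_size"]
    libs.index = libs.index.astype(str)
    rpkm_path = prefix.with_suffix(".rpkm.tsv")
    rpkm = None
    if rpkm_path.exists():
        rpkm = pd.read_csv(rpkm_path, sep="\t", index_col="bin_id")
    return BinCountMatrix(counts, libs, rpkm=rpkm)


def save_fragments(frags: FragmentTable, path) -> None:
    frags.df[["sample_id", "chrom", "start", "end"]].to_csv(path, sep="\t", index=False)


def load_fragments(path) -> FragmentTable:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"sample_id": str, "chrom": str, "start": np.int64, "end": np.int64},
    )
    return FragmentTable(df)


def save_bed(intervals: dict[str, np.ndarray], path, name: str | None = None) -> None:
    """Write ``{chrom: (N, 2) interval array}`` as BED3(+name)."""
    rows = []
    for chrom in sorted(intervals):
        for s, e in np.asarray(intervals[chrom]).reshape(-1, 2):
            rows.append((chrom, int(s), int(e)) + ((name,) if name else ()))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def load_bed(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"], dtype={0: str})
    out: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        out[str(chrom)] = grp[["start", "end"]].to_numpy(dtype=np.int64)
    return out
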
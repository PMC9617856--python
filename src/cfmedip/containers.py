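"""In-memory containers: sample sheet, bin-by-sample count matrix, fragments."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SampleSheet", "BinCountMatrix", "FragmentTable", "parse_bin_ids"]

SHEET_REQUIRED = ["sample_id", "patient_id", "cohort", "class", "batch"]
SHEET_NUMERIC = [
    "pct_ctdna", "age", "ldh", "alp",
    "os_time", "os_event", "pfs_time", "pfs_event",
]
CLASSES = {"localized", "metastatic", "control"}


@dataclass
class SampleSheet:
    """Per-sample clinical metadata.

    One row per sample; a patient may contribute several samples
    (e.g. baseline and progression draws).  Missing covariates stay
    missing (NaN) and are dropped per-analysis, never imputed as zero.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in SHEET_REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"sample sheet missing required columns: {missing}")
        dup = df["sample_id"][df["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample_id: {sorted(set(dup))}")
        bad_cls = set(df["class"]) - CLASSES
        if bad_cls:
            raise ValueError(f"unknown class labels: {sorted(bad_cls)}")
        for col in SHEET_NUMERIC:
            if col in df.columns and not pd.api.types.is_numeric_dtype(df[col]):
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = df[col].notna() & coerced.isna()
                if bad.any():
                    row = df.index[bad][0]
                    raise ValueError(
                        f"non-numeric value in column {col!r}, row {row} "
                        f"(sample {df.loc[row, 'sample_id']!r})"
                    )
                self.df[col] = coerced
        if "pct_ctdna" in df.columns:
            v = df["pct_ctdna"].dropna()
            if ((v < 0) | (v > 1)).any():
                bad_id = df.loc[df["pct_ctdna"].notna() & ((df.pct_ctdna < 0) | (df.pct_ctdna > 1)), "sample_id"].iloc[0]
                raise ValueError(f"pct_ctdna outside [0, 1] for sample {bad_id!r}")
        for col in ("os_event", "pfs_event"):
            if col in df.columns:
                v = df[col].dropna()
                if not v.isin([0, 1]).all():
                    raise ValueError(f"{col} must be 0/1")
        multi = df.groupby("sample_id")["patient_id"].nunique()
        if (multi > 1).any():
            raise ValueError("a sample_id maps to more than one patient_id")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def subset(self, sample_ids) -> "SampleSheet":
        keep = self.df[self.df["sample_id"].isin(list(sample_ids))].copy()
        return SampleSheet(keep)

    def column(self, name: str) -> pd.Series:
        """Series of a per-sample column indexed by sample_id."""
        return self.df.set_index("sample_id")[name]


def parse_bin_ids(bin_ids) -> pd.DataFrame:
    """Decode 'chrom:start-end' identifiers into a coordinate frame."""
    chroms, starts, ends = [], [], []
    for b in bin_ids:
        chrom, rng = b.rsplit(":", 1)
        s, e = rng.split("-")
        chroms.append(chrom)
        starts.append(int(s))
        ends.append(int(e))
    return pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends}, index=list(bin_ids)
    )


@dataclass
class BinCountMatrix:
    """Bins x samples fragment counts with per-sample library sizes.

    ``counts`` is indexed by bin ids of the form ``chrom:start-end``.
    ``lib_sizes`` is the total number of mapped fragments per sample; it is
    at least the column sum of counts (equal when every fragment falls in a
    bin).  The optional ``rpkm`` layer is derived, never stored out of sync:
    recompute it with :func:`cfmedip.quantify.rpkm` after any subsetting.
    """

    counts: pd.DataFrame
    lib_sizes: pd.Series
    rpkm: pd.DataFrame | None = None
    _coords: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.counts = self.counts.rename_axis("bin_id")
        if self.rpkm is not None:
            self.rpkm = self.rpkm.rename_axis("bin_id")
        self.lib_sizes = self.lib_sizes.rename_axis("sample_id")
        self.lib_sizes = self.lib_sizes.reindex(self.counts.columns)
        if self.lib_sizes.isna().any():
            raise ValueError("library size missing for some samples")
        short = self.counts.sum(axis=0) > self.lib_sizes
        if short.any():
            raise ValueError(
                f"library size smaller than column sum for {list(short[short].index)}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def bin_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def coords(self) -> pd.DataFrame:
        if self._coords is None or not self._coords.index.equals(self.counts.index):
            self._coords = parse_bin_ids(self.counts.index)
        return self._coords

    @property
    def bin_lengths(self) -> np.ndarray:
        c = self.coords
        return (c["end"] - c["start"]).to_numpy()

    def subset_bins(self, bin_ids) -> "BinCountMatrix":
        sub = self.counts.loc[bin_ids]
        rp = self.rpkm.loc[bin_ids] if self.rpkm is not None else None
        return BinCountMatrix(sub, self.lib_sizes.copy(), rpkm=rp)

    def subset_samples(self, sample_ids) -> "BinCountMatrix":
        sample_ids = list(sample_ids)
        rp = self.rpkm[sample_ids] if self.rpkm is not None else None
        return BinCountMatrix(
            self.counts[sample_ids], self.lib_sizes[sample_ids], rpkm=rp
        )


@dataclass
class FragmentTable:
    """Sequenced cfDNA fragments: sample_id, chrom, start, end (half-open)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        need = ["sample_id", "chrom", "start", "end"]
        missing = [c for c in need if c not in self.df.columns]
        if missing:
            raise ValueError(f"fragment table missing columns: {missing}")
        if (self.df["end"] <= self.df["start"]).any():
            raise ValueError("fragment with end <= start")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        # midpoint of [s, e) is floor((s + e) / 2)
        return ((self.df["start"] + self.df["end"]) // 2).to_numpy()

    def for_sample(self, sample_id: str) -> "FragmentTable":
        return FragmentTable(self.df[self.df["sample_id"] == sample_id].copy())
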
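"""cfDNA fragment-size statistics.

Two summaries drive the biology here: the longer-fragment ratio (fragments
of 170-210 bp over fragments of 100-210 bp, both ranges inclusive — lower
values mean shorter, more tumor-like cfDNA) and the DELFI-style
fragmentation profile (short/long count ratio in 5-Mb windows, whose
standard deviation across the genome rises with tumor burden).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FragmentTable
from .genome import GenomeModel, bin_genome

__all__ = [
    "longer_fragment_ratio", "fragmentation_profile", "cohort_fragment_stats",
    "associate", "FragmentStats",
]

RATIO_NUM = (170, 210)   # inclusive bounds
RATIO_DEN = (100, 210)
SHORT_BAND = (100, 150)  # DELFI short fragments, inclusive
LONG_BAND = (151, 220)


def longer_fragment_ratio(lengths) -> float:
    """#fragments in [170, 210] / #fragments in [100, 210], NaN if the
    denominator is empty."""
    ln = np.asarray(lengths)
    den = np.count_nonzero((ln >= RATIO_DEN[0]) & (ln <= RATIO_DEN[1]))
    if den == 0:
        return float("nan")
    num = np.count_nonzero((ln >= RATIO_NUM[0]) & (ln <= RATIO_NUM[1]))
    return num / den


@dataclass
class FragmentStats:
    """Per-sample fragmentomics: ratio, per-window profile, profile SD."""

    table: pd.DataFrame            # index sample_id; longer_fragment_ratio, profile_sd
    profiles: pd.DataFrame         # windows x samples short/long ratios (NaN where undefined)


def fragmentation_profile(
    fragments: FragmentTable,
    genome: GenomeModel,
    window: int = 5_000_000,
    short_band: tuple[int, int] = SHORT_BAND,
    long_band: tuple[int, int] = LONG_BAND,
) -> tuple[pd.Series, float]:
    """Short/long fragment-count ratio per genomic window, plus its SD.

    Fragments are assigned to windows by midpoint.  Windows with zero long
    fragments get NaN; the SD (ddof=1) is over non-missing windows and is
    NaN when fewer than two windows are defined.
    """
    if window <= 0:
        raise ValueError("window width must be positive")
    wins = bin_genome(genome, width=window)
    idx = wins.assign(fragments.df["chrom"].to_numpy(), fragments.midpoints)
    ln = fragments.lengths
    is_short = (ln >= short_band[0]) & (ln <= short_band[1])
    is_long = (ln >= long_band[0]) & (ln <= long_band[1])
    n_short = np.bincount(idx[is_short], minlength=len(wins)).astype(float)
    n_long = np.bincount(idx[is_long], minlength=len(wins)).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n_long > 0, n_short / n_long, np.nan)
    series = pd.Series(ratio, index=wins.bin_ids)
    valid = series.dropna()
    sd = float(valid.std(ddof=1)) if len(valid) >= 2 else float("nan")
    return series, sd


def cohort_fragment_stats(
    fragments: FragmentTable, genome: GenomeModel, window: int = 5_000_000
) -> FragmentStats:
    rows, profs = {}, {}
    for sample_id, grp in fragments.df.groupby("sample_id", sort=True):
        ft = FragmentTable(grp)
        prof, sd = fragmentation_profile(ft, genome, window=window)
        rows[sample_id] = {
            "longer_fragment_ratio": longer_fragment_ratio(ft.lengths),
            "profile_sd": sd,
        }
        profs[sample_id] = prof
    return FragmentStats(pd.DataFrame(rows).T, pd.DataFrame(profs))


def associate(values: pd.Series, covariate: pd.Series, mode: str, alternative: str = "two-sided"):
    """Associate a per-sample statistic with a grouping or numeric covariate.

    mode='group_test': Mann-Whitney U between the two groups named by
    ``covariate`` (statistic, p).  mode='pearson': Pearson r with its
    t-test p (df = n - 2).  Samples missing either value are dropped.
    """
    joined = pd.concat([values.rename("v"), covariate.rename("c")], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 complete pairs")
    if mode == "group_test":
        groups = joined.groupby("c")["v"]
        if groups.ngroups != 2:
            raise ValueError("group_test requires exactly two groups")
        (g1, x), (g2, y) = list(groups)
        res = stats.mannwhitneyu(x, y, alternative=alternative)
        return float(res.statistic), float(res.pvalue)
    if mode == "pearson":
        if joined["c"].nunique() == 1 or joined["v"].nunique() == 1:
            raise ValueError("constant vector: Pearson r undefined")
        res = stats.pearsonr(joined["v"], joined["c"], alternative=alternative)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown mode {mode!r}")
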
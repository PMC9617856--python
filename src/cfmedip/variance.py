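"""Per-bin variance decomposition over clinical covariates.

For each bin, the methylation signal (RPKM across samples) is regressed on
a covariate; the adjusted R-squared measures the fraction of variance that
covariate explains.  "Explained by LDH independent of %ctDNA" is the
adjusted-R-squared increment of adding LDH to a ctDNA-only model.  Bins are
categorized by the fixed 0.2 / 0.5 cutoffs (strict inequalities), and
selected bins are tested for annotation enrichment by Fisher's exact test
and by permutation against the non-low background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeModel, merge_intervals, overlaps_any

__all__ = [
    "fit_bin_covariate", "fit_bins_covariate", "delta_r2", "classify_bins",
    "annotation_enrichment_fisher", "annotation_enrichment_permutation",
    "VarianceResult", "bin_annotation_mask",
]

CUTOFFS = (0.2, 0.5)
CATEGORIES = ("unexplained", "weak_to_moderate", "moderate_to_high")


def _adjusted_r2(r2: np.ndarray, n: int, p: int) -> np.ndarray:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - p)


def _ols_r2(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """R^2 of each row of Y regressed on design X (with intercept)."""
    n = X.shape[0]
    X1 = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(X1, Y.T, rcond=None)
    resid = Y.T - X1 @ beta
    sse = np.sum(resid**2, axis=0)
    sst = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sst > 0, 1.0 - sse / sst, np.nan)


def fit_bins_covariate(signal: pd.DataFrame, covariate: pd.Series) -> pd.Series:
    """Adjusted R^2 of each bin's signal on one covariate (vectorized OLS).

    ``signal`` is bins x samples; samples with a missing covariate are
    dropped (complete-case).
    """
    cov = covariate.reindex(signal.columns).astype(float)
    keep = cov.notna()
    if keep.sum() < 3:
        raise ValueError("need >= 3 samples with the covariate observed")
    x = cov[keep].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    Y = signal.loc[:, keep.to_numpy()].to_numpy(dtype=float)
    r2 = _ols_r2(Y, x[:, None])
    return pd.Series(_adjusted_r2(r2, len(x), 1), index=signal.index)


def fit_bin_covariate(signal, covariate) -> float:
    """Adjusted R^2 for a single bin: 1 - (1 - R^2)(n - 1)/(n - 2)."""
    s = pd.Series(np.asarray(signal, dtype=float))
    frame = pd.DataFrame({"y": s.to_numpy(), "x": np.asarray(covariate, dtype=float)}).dropna()
    return float(
        fit_bins_covariate(
            pd.DataFrame([frame["y"].to_numpy()]), pd.Series(frame["x"].to_numpy())
        ).iloc[0]
    )


def delta_r2(signal: pd.DataFrame, primary: pd.Series, secondary: pd.Series) -> pd.Series:
    """Adjusted-R^2 gain of the two-covariate model over primary alone.

    delta = adjR2(signal ~ primary + secondary) - adjR2(signal ~ primary).
    Collinear covariates (|r| > 0.999) are rejected.
    """
    cov = pd.concat(
        [primary.reindex(signal.columns).rename("p"),
         secondary.reindex(signal.columns).rename("s")], axis=1
    ).astype(float)
    keep = cov.notna().all(axis=1)
    if keep.sum() < 4:
        raise ValueError("need >= 4 samples with both covariates observed")
    x = cov[keep].to_numpy()
    if np.ptp(x[:, 0]) == 0 or np.ptp(x[:, 1]) == 0:
        raise ValueError("constant covariate")
    r = np.corrcoef(x[:, 0], x[:, 1])[0, 1]
    if abs(r) > 0.999:
        raise ValueError(f"covariates are collinear (|r| = {abs(r):.4f})")
    Y = signal.loc[:, keep.to_numpy()].to_numpy(dtype=float)
    n = x.shape[0]
    adj_both = _adjusted_r2(_ols_r2(Y, x), n, 2)
    adj_primary = _adjusted_r2(_ols_r2(Y, x[:, :1]), n, 1)
    return pd.Series(adj_both - adj_primary, index=signal.index)


@dataclass
class VarianceResult:
    """Adjusted R^2 per bin per covariate, with threshold categories."""

    adj_r2: pd.DataFrame        # bins x covariates
    categories: pd.DataFrame | None = None
    fractions: pd.DataFrame | None = None


def classify_bins(adj_r2: pd.DataFrame, cutoffs: tuple[float, float] = CUTOFFS) -> VarianceResult:
    """Assign each bin x covariate cell to unexplained / weak_to_moderate /
    moderate_to_high using strict > comparisons, and report cohort fractions."""
    lo, hi = cutoffs
    vals = adj_r2.to_numpy(dtype=float)
    cat = np.full(vals.shape, CATEGORIES[0], dtype=object)
    cat[vals > lo] = CATEGORIES[1]
    cat[vals > hi] = CATEGORIES[2]
    categories = pd.DataFrame(cat, index=adj_r2.index, columns=adj_r2.columns)
    fractions = pd.DataFrame(
        {c: categories[c].value_counts(normalize=True) for c in categories},
    ).reindex(list(CATEGORIES)).fillna(0.0)
    return VarianceResult(adj_r2=adj_r2, categories=categories, fractions=fractions)


def bin_annotation_mask(
    coords: pd.DataFrame, genome: GenomeModel, category: str
) -> np.ndarray:
    """True where a bin overlaps (>= 1 bp) the named annotation category."""
    mask = np.zeros(len(coords), dtype=bool)
    for chrom, grp in coords.groupby("chrom", sort=False):
        iv = merge_intervals(genome.annotation_intervals(category, str(chrom)))
        sel = coords["chrom"] == chrom
        mask[sel.to_numpy()] = overlaps_any(
            grp["start"].to_numpy(), grp["end"].to_numpy(), iv
        )
    return mask


def annotation_enrichment_fisher(selected: np.ndarray, annotated: np.ndarray):
    """Fisher's exact test of selected bins vs annotation overlap.

    ``selected`` and ``annotated`` are boolean masks over the same background
    universe.  Returns (odds_ratio, p, table, corrected_flag); a zero cell
    makes the sample OR undefined, in which case the Haldane-Anscombe 0.5
    correction is applied and flagged.
    """
    selected = np.asarray(selected, dtype=bool)
    annotated = np.asarray(annotated, dtype=bool)
    if selected.sum() == 0 or len(selected) == 0:
        raise ValueError("empty selected set or background")
    a = int(np.sum(selected & annotated))
    b = int(np.sum(selected & ~annotated))
    c = int(np.sum(~selected & annotated))
    d = int(np.sum(~selected & ~annotated))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = 0 in (a, b, c, d)
    if corrected:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return float(orr), float(p), np.array([[a, b], [c, d]]), corrected


def annotation_enrichment_permutation(
    selected: np.ndarray,
    annotated: np.ndarray,
    iterations: int = 1000,
    seed: int | np.random.Generator = 0,
):
    """Permutation enrichment of selected bins in an annotation.

    The null redraws |selected| bins uniformly without replacement from the
    background; the overlap count of such a draw is exactly hypergeometric,
    which is what we sample.  Returns (z, empirical p, observed); p uses the
    add-one rule (1 + #null >= obs)/(iterations + 1), mirrored for depletion.
    """
    if iterations <= 0:
        raise ValueError("iterations must be positive")
    import warnings

    if iterations < 100:
        warnings.warn("fewer than 100 permutation iterations", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    selected = np.asarray(selected, dtype=bool)
    annotated = np.asarray(annotated, dtype=bool)
    n_sel = int(selected.sum())
    n_ann = int(annotated.sum())
    n_bg = len(selected)
    if n_sel == 0 or n_bg == 0:
        raise ValueError("empty selected set or background")
    obs = int(np.sum(selected & annotated))
    null = rng.hypergeometric(n_ann, n_bg - n_ann, n_sel, size=iterations)
    mu, sd = null.mean(), null.std(ddof=0)
    z = (obs - mu) / sd if sd > 0 else 0.0
    if obs >= mu:
        p = (1 + int(np.sum(null >= obs))) / (iterations + 1)
    else:
        p = (1 + int(np.sum(null <= obs))) / (iterations + 1)
    return float(z), float(p), obs
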
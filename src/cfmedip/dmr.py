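"""Differential methylation between sample classes, with covariate control.

Counts are modeled per bin as negative binomial,

    K_ij ~ NB(mu_ij, alpha_i),   log mu_ij = log s_j + x_j' beta_i,

with median-of-ratios size factors s_j, a per-bin method-of-moments
dispersion alpha_i (floored), and a design holding the class contrast
(metastatic vs localized) plus optional age and batch covariates.  The fit
is an iteratively reweighted least squares (IRLS) run vectorized across all
bins; inference is a Wald z on the class coefficient with Benjamini-
Hochberg correction across tested bins.  A bin is a DMR when q < 0.05 and
|log2 fold change| > 1 (i.e. fold change > 2), hyper- or hypomethylated by
the sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import BinCountMatrix, SampleSheet, parse_bin_ids
from .genome import GenomeModel, overlaps_any

__all__ = [
    "size_factors", "build_design", "nb_wald_test", "call_dmrs",
    "hyper_hypo_ratio", "pericentromeric_summary", "region_score",
    "DMRTable", "DISPERSION_FLOOR",
]

DISPERSION_FLOOR = 1e-8


def size_factors(mat: BinCountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-bin geometric mean over samples, using only
    bins with a nonzero count in every sample.
    """
    K = mat.counts.to_numpy(dtype=float)
    all_pos = (K > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no bin has nonzero counts in every sample")
    Kp = K[all_pos]
    ref = np.exp(np.mean(np.log(Kp), axis=1))
    s = np.median(Kp / ref[:, None], axis=0)
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=mat.counts.columns, name="size_factor")


def build_design(
    sheet: SampleSheet,
    samples: list[str],
    covariates: tuple[str, ...] = ("age",),
    contrast: tuple[str, str] = ("metastatic", "localized"),
) -> tuple[np.ndarray, list[str]]:
    """Design matrix [intercept, class, covariates..., batch dummies].

    The class column is 1 for ``contrast[0]`` and 0 for ``contrast[1]``;
    numeric covariates are mean-centered.  Batch (if requested and with
    > 1 level among these samples) enters as treatment-coded dummies.
    """
    sub = sheet.df.set_index("sample_id").loc[samples]
    cls = sub["class"]
    bad = set(cls) - set(contrast)
    if bad:
        raise ValueError(f"samples outside the contrast classes: {sorted(bad)}")
    cols = [np.ones(len(sub)), (cls == contrast[0]).to_numpy(dtype=float)]
    names = ["intercept", "class"]
    for cov in covariates:
        if cov == "batch":
            levels = sorted(sub["batch"].unique())
            for lev in levels[1:]:
                cols.append((sub["batch"] == lev).to_numpy(dtype=float))
                names.append(f"batch[{lev}]")
            continue
        v = sub[cov].astype(float)
        if v.isna().any():
            raise ValueError(
                f"covariate {cov!r} missing for {list(sub.index[v.isna()])}; "
                "drop those samples first (complete-case)"
            )
        cols.append((v - v.mean()).to_numpy())
        names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names


def _mom_dispersion(q: np.ndarray, groups: np.ndarray, inv_s_mean: float) -> np.ndarray:
    """Per-bin method-of-moments dispersion from size-factor-normalized counts.

    Pools within-group variances so planted class effects do not inflate
    alpha; Var(K/s) ~= mu * mean(1/s) + alpha * mu^2.
    """
    n = q.shape[1]
    uniq = np.unique(groups)
    sse = np.zeros(q.shape[0])
    for g in uniq:
        sel = groups == g
        qg = q[:, sel]
        sse += np.sum((qg - qg.mean(axis=1, keepdims=True)) ** 2, axis=1)
    v = sse / max(n - len(uniq), 1)
    m = q.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m * inv_s_mean) / m**2
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    return np.maximum(alpha, DISPERSION_FLOOR)


@dataclass
class DMRTable:
    """Per-bin differential statistics plus the called direction."""

    table: pd.DataFrame  # baseMean, log2fc, wald, p, q, direction
    n_nonconverged: int = 0
    design_names: list[str] = field(default_factory=list)

    @property
    def hyper(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "hyper"]

    @property
    def hypo(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "hypo"]

    @property
    def count_ratio(self) -> float:
        """Hyper:hypo DMR count ratio, rounded to one decimal; NaN if no hypo."""
        n_hypo = len(self.hypo)
        if n_hypo == 0:
            return float("nan")
        return round(len(self.hyper) / n_hypo, 1)


def nb_wald_test(
    mat: BinCountMatrix,
    sheet: SampleSheet,
    covariates: tuple[str, ...] = ("age",),
    contrast: tuple[str, str] = ("metastatic", "localized"),
    floor_dispersion: float = DISPERSION_FLOOR,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Per-bin NB GLM Wald test of the class contrast, vectorized IRLS.

    Returns a frame with baseMean, log2fc, wald, p and BH q.  Bins whose
    IRLS did not converge are flagged (``converged`` column) and assigned
    p = 1 rather than dropped.
    """
    samples = [
        s for s in mat.samples
        if sheet.column("class").get(s) in contrast
    ]
    for cls in contrast:
        if sum(sheet.column("class").get(s) == cls for s in samples) < 3:
            raise ValueError(f"need >= 3 samples in class {cls!r}")
    mat = mat.subset_samples(samples)
    X, names = build_design(sheet, samples, covariates=covariates, contrast=contrast)
    s = size_factors(mat).to_numpy()
    K = mat.counts.to_numpy(dtype=float)
    q = K / s[None, :]
    groups = X[:, 1]  # class column defines the pooling for dispersion
    alpha = _mom_dispersion(q, groups, float(np.mean(1.0 / s)))
    alpha = np.maximum(alpha, floor_dispersion)

    n_bins, n = K.shape
    p_dim = X.shape[1]
    offset = np.log(s)[None, :]
    beta = np.zeros((n_bins, p_dim))
    beta[:, 0] = np.log(np.maximum(q.mean(axis=1), 1e-8))
    active = np.ones(n_bins, dtype=bool)
    A = np.zeros((n_bins, p_dim, p_dim))
    for _ in range(max_iter):
        eta = offset + beta @ X.T
        mu = np.clip(np.exp(eta), 1e-10, 1e12)
        W = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset) + (K - mu) / mu
        A = np.einsum("jp,bj,jq->bpq", X, W, X)
        b = np.einsum("jp,bj->bp", X, W * z)
        # ridge epsilon guards all-zero bins without touching informative ones
        A += 1e-10 * np.eye(p_dim)[None, :, :]
        new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.max(np.abs(new_beta - beta), axis=1)
        beta = new_beta
        active = delta > tol
        if not active.any():
            break
    converged = ~active
    cov = np.linalg.inv(A)
    se = np.sqrt(np.maximum(cov[:, 1, 1], 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, beta[:, 1] / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(wald))
    pvals = np.where(converged, pvals, 1.0)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "baseMean": q.mean(axis=1),
            "log2fc": beta[:, 1] / np.log(2),
            "wald": wald,
            "p": pvals,
            "q": qvals,
            "converged": converged,
        },
        index=mat.counts.index,
    )


def call_dmrs(stats_df: pd.DataFrame, q_max: float = 0.05, min_abs_l2fc: float = 1.0) -> DMRTable:
    """Nominate DMRs: q < q_max and |log2FC| > min_abs_l2fc; sign gives direction."""
    t = stats_df.copy()
    direction = np.full(len(t), "ns", dtype=object)
    sig = (t["q"].to_numpy() < q_max) & (np.abs(t["log2fc"].to_numpy()) > min_abs_l2fc)
    direction[sig & (t["log2fc"].to_numpy() > 0)] = "hyper"
    direction[sig & (t["log2fc"].to_numpy() < 0)] = "hypo"
    t["direction"] = direction
    n_nc = int((~t["converged"]).sum()) if "converged" in t else 0
    return DMRTable(t, n_nonconverged=n_nc)


def hyper_hypo_ratio(rpkm: pd.DataFrame, dmrs: DMRTable) -> pd.DataFrame:
    """Per-sample risk score: mean RPKM over hyper-DMRs / mean over hypo-DMRs.

    The cohort is split at the median score into high/low; scores exactly at
    the median go to "low".  Samples with a zero hypo mean get a missing
    score and no group.
    """
    hyper, hypo = dmrs.hyper, dmrs.hypo
    if len(hyper) == 0 or len(hypo) == 0:
        raise ValueError("both hyper- and hypo-DMR sets must be non-empty")
    hyper_mean = rpkm.loc[hyper].mean(axis=0)
    hypo_mean = rpkm.loc[hypo].mean(axis=0)
    score = hyper_mean / hypo_mean.where(hypo_mean > 0)
    med = score.median()
    group = pd.Series(
        np.where(score > med, "high", "low"), index=score.index, dtype=object
    )
    group[score.isna()] = None
    return pd.DataFrame({"score": score, "group": group})


def pericentromeric_summary(
    dmrs: DMRTable,
    rpkm: pd.DataFrame,
    sheet: SampleSheet,
    genome: GenomeModel,
    flank: int = 1_000_000,
    direction: str | None = None,
) -> pd.DataFrame:
    """Mean normalized signal per class over differential bins within
    centromere gap +/- flank (closed boundaries at the flank edges)."""
    if not genome.centromere_gaps:
        raise ValueError("genome has no centromere gap annotation")
    diff = dmrs.table[dmrs.table["direction"] != "ns"]
    if direction is not None:
        diff = diff[diff["direction"] == direction]
    coords = parse_bin_ids(diff.index)
    keep = np.zeros(len(coords), dtype=bool)
    for chrom, (gs, ge) in genome.centromere_gaps.items():
        region = np.array([[max(gs - flank, 0), ge + flank]])
        sel = (coords["chrom"] == chrom).to_numpy()
        if sel.any():
            keep[sel] = overlaps_any(
                coords.loc[sel, "start"].to_numpy(),
                coords.loc[sel, "end"].to_numpy(),
                region,
            )
    bins = diff.index[keep]
    cls = sheet.column("class").reindex(rpkm.columns)
    if len(bins) == 0:
        return pd.DataFrame({"mean_signal": pd.Series(dtype=float)})
    per_sample = rpkm.loc[bins].mean(axis=0)
    out = per_sample.groupby(cls).mean().rename("mean_signal").to_frame()
    out["n_bins"] = len(bins)
    return out


def region_score(
    rpkm: pd.DataFrame,
    region: tuple[str, int, int],
    k: int | None = None,
) -> pd.DataFrame:
    """Per-sample mean signal over bins overlapping one genomic region.

    Returns a frame with the score, a median-split group (ties -> "low"),
    and, when ``k`` is given, top-k / bottom-k flags.  Rank ties at the k-th
    position break deterministically by sample_id order.
    """
    chrom, start, end = region
    coords = parse_bin_ids(rpkm.index)
    sel = (
        (coords["chrom"] == chrom)
        & (coords["start"] < end)
        & (coords["end"] > start)
    ).to_numpy()
    if not sel.any():
        raise ValueError(f"region {chrom}:{start}-{end} overlaps no bin")
    score = rpkm.loc[rpkm.index[sel]].mean(axis=0).sort_index().rename("score")
    med = score.median()
    out = pd.DataFrame(
        {"score": score, "group": np.where(score > med, "high", "low")}
    )
    if k is not None:
        if 2 * k > len(score):
            raise ValueError("k too large for cohort size")
        frame = score.rename_axis("sample_id").reset_index()
        order = frame.sort_values(["score", "sample_id"], ascending=[False, True])
        out["top_k"] = out.index.isin(order["sample_id"].head(k))
        order_low = frame.sort_values(["score", "sample_id"], ascending=[True, True])
        out["bottom_k"] = out.index.isin(order_low["sample_id"].head(k))
    return out
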
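"""Copy-number inference from enrichment coverage, multiscale HMM style.

Bin-level normalized signal is aggregated into large windows (default
250 kb), expressed as a log2 ratio against the median of a reference cohort
(localized samples), median-smoothed at three length scales, and decoded
per scale by a 3-state HMM (loss / neutral / gain) with symmetric Gaussian
emissions.  A window's allelic-shift evidence (mean |BAF - 0.5| from
heterozygous SNPs, smoothed at the same three scales and split by a
two-component Gaussian mixture) corrects calls with weak methylation
evidence.  The 3 x 3 scale combinations each cast one vote per window; a
final non-neutral state needs at least six of the nine votes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .containers import BinCountMatrix
from .fragmentomics import associate
from .genome import GenomeModel, bin_genome

__all__ = [
    "aggregate_windows", "log_ratio_track", "multiscale_smooth", "hmm_call",
    "baf_shift", "consensus_call", "cna_coverage", "compare_to_truth",
    "CNACallSet", "viterbi", "STATES",
]

STATES = ("loss", "neutral", "gain")
SCALES = (3, 15, 51)
STRONG_EVIDENCE = 0.4  # |log2 ratio| treated as self-sufficient
MIN_VOTES = 6
# 250 kb keeps ~5 heterozygous SNPs per window at typical density while
# giving chromosome tracks long enough for the coarsest smoothing scale
DEFAULT_WINDOW = 250_000


def aggregate_windows(
    mat: BinCountMatrix, genome: GenomeModel, window: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Sum per-sample normalized signal (counts per million mapped
    fragments) of all bins inside each genomic window."""
    wins = bin_genome(genome, width=window)
    coords = mat.coords
    mids = ((coords["start"] + coords["end"]) // 2).to_numpy()
    idx = wins.assign(coords["chrom"].to_numpy(), mids)
    cpm = mat.counts.to_numpy(dtype=float) / (mat.lib_sizes.to_numpy(dtype=float)[None, :] / 1e6)
    out = np.zeros((len(wins), cpm.shape[1]))
    np.add.at(out, idx, cpm)
    return pd.DataFrame(out, index=wins.bin_ids, columns=mat.counts.columns)


def log_ratio_track(
    windows: pd.DataFrame, sample: str, reference_samples: list[str], pseudocount: float = 1.0
) -> pd.Series:
    """Median-centered log2 ratio of one sample to the reference median."""
    if len(reference_samples) < 3:
        raise ValueError("need >= 3 reference samples")
    if pseudocount <= 0:
        ref_med = windows[reference_samples].median(axis=1)
        if (ref_med == 0).any():
            raise ValueError("zero reference median requires pseudocount > 0")
    x = windows[sample].to_numpy(dtype=float)
    ref = windows[reference_samples].median(axis=1).to_numpy(dtype=float)
    lr = np.log2((x + pseudocount) / (ref + pseudocount))
    lr = lr - np.median(lr)
    return pd.Series(lr, index=windows.index)


def _shrink_median(x: np.ndarray, width: int) -> np.ndarray:
    """One pass of a centered median filter; edge windows shrink."""
    h = width // 2
    out = np.empty_like(x, dtype=float)
    for i in range(len(x)):
        out[i] = np.median(x[max(0, i - h): i + h + 1])
    return out


def multiscale_smooth(
    track: pd.Series, scales: tuple[int, ...] = SCALES, max_passes: int = 30
) -> dict[int, pd.Series]:
    """Iterated median filtering at each scale until a fixed point.

    Scale widths must be odd; filtering repeats up to ``max_passes`` times
    or until the track stops changing (median filters reach root signals).
    Chromosomes are smoothed independently when the index carries
    ``chrom:start-end`` window ids; edge windows shrink.
    """
    out: dict[int, pd.Series] = {}
    x0 = track.to_numpy(dtype=float)
    try:
        chrom_labels = np.array([str(i).rsplit(":", 1)[0] for i in track.index])
    except Exception:
        chrom_labels = np.repeat("all", len(track))
    blocks = [np.flatnonzero(chrom_labels == c) for c in pd.unique(chrom_labels)]
    for width in scales:
        if width % 2 == 0:
            raise ValueError(f"scale width {width} must be odd")
        x = x0.copy()
        for idx in blocks:
            seg = x[idx]
            for _ in range(max_passes):
                new = _shrink_median(seg, width)
                if np.array_equal(new, seg):
                    break
                seg = new
            x[idx] = seg
        out[width] = pd.Series(x, index=track.index)
    return out


def viterbi(obs_loglik: np.ndarray, log_trans: np.ndarray, log_start: np.ndarray) -> np.ndarray:
    """Most probable state path; obs_loglik is (T, S)."""
    T, S = obs_loglik.shape
    delta = log_start + obs_loglik[0]
    back = np.zeros((T, S), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + log_trans
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(S)] + obs_loglik[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def hmm_call(
    smoothed: pd.Series,
    mu0: float = 0.3,
    self_transition: float = 0.99,
    max_iter: int = 100,
    tol: float = 1e-6,
    min_amplitude: float = 0.1,
) -> tuple[pd.Series, dict]:
    """3-state HMM decoding of a smoothed log-ratio track.

    Emissions are Gaussian with means (-mu, 0, +mu) and a common sigma;
    mu and sigma are re-estimated by EM from mu0 and the track's robust
    MAD, transitions stay fixed at a 0.99 self-transition prior, and the
    state path is decoded by Viterbi.  EM failure falls back to the
    initialization values with a flag.  A fitted amplitude below
    ``min_amplitude`` (log2 units; a one-copy event at roughly 15%% tumor
    fraction) means the track carries no interpretable copy-number signal
    and every window is reported neutral, flagged in the metadata.
    """
    x = smoothed.to_numpy(dtype=float)
    if len(x) < 10:
        raise ValueError("need >= 10 windows for HMM decoding")
    off = (1.0 - self_transition) / 2
    trans = np.full((3, 3), off)
    np.fill_diagonal(trans, self_transition)
    log_trans = np.log(trans)
    log_start = np.log(np.array([off, self_transition, off]))

    mad = stats.median_abs_deviation(x, scale="normal")
    sigma0 = float(max(mad, 1e-3))
    mu, sigma = mu0, sigma0
    converged = False
    for _ in range(max_iter):
        means = np.array([-mu, 0.0, mu])
        ll = stats.norm.logpdf(x[:, None], loc=means[None, :], scale=sigma)
        # forward-backward in log space
        T = len(x)
        la = np.zeros((T, 3))
        la[0] = log_start + ll[0]
        for t in range(1, T):
            la[t] = ll[t] + np.logaddexp.reduce(la[t - 1][:, None] + log_trans, axis=0)
        lb = np.zeros((T, 3))
        for t in range(T - 2, -1, -1):
            lb[t] = np.logaddexp.reduce(log_trans + (ll[t + 1] + lb[t + 1])[None, :], axis=1)
        lg = la + lb
        lg -= np.logaddexp.reduce(lg, axis=1)[:, None]
        g = np.exp(lg)
        w_alt = g[:, 0] + g[:, 2]
        denom = float(w_alt.sum())
        alt_mass = denom > 1e-6
        new_mu = float((g[:, 2] @ x - g[:, 0] @ x) / denom) if alt_mass else mu
        new_mu = max(new_mu, 1e-3)
        var = float((g * (x[:, None] - np.array([-new_mu, 0.0, new_mu])[None, :]) ** 2).sum() / T)
        new_sigma = max(np.sqrt(var), 1e-4)
        if abs(new_mu - mu) < tol and abs(new_sigma - sigma) < tol:
            mu, sigma = new_mu, new_sigma
            converged = True
            break
        mu, sigma = new_mu, new_sigma
    # the data-driven amplitude; no posterior mass on the altered states
    # means no interpretable copy-number signal at all
    mu_est = mu if alt_mass else 0.0
    if not converged:
        mu, sigma = mu0, sigma0  # decode with the initialization values
    info = {"mu": mu, "sigma": sigma, "em_converged": converged,
            "below_min_amplitude": mu_est < min_amplitude}
    if mu_est < min_amplitude:
        return pd.Series("neutral", index=smoothed.index, dtype=object), info
    means = np.array([-mu, 0.0, mu])
    ll = stats.norm.logpdf(x[:, None], loc=means[None, :], scale=sigma)
    path = viterbi(ll, log_trans, log_start)
    states = pd.Series(np.array(STATES)[path], index=smoothed.index)
    return states, info


def baf_shift(
    baf_windows: pd.Series,
    scales: tuple[int, ...] = SCALES,
    seed: int = 0,
    min_windows: int = 50,
) -> dict[int, pd.Series]:
    """Allelic-shift flags per window at each smoothing scale.

    ``baf_windows`` holds the per-window mean |BAF - 0.5| (NaN where a
    window has no informative SNP).  Each scale's smoothed profile is split
    genome-wide by a 2-component Gaussian mixture; a window is "shifted"
    when the posterior of the higher-mean component exceeds 0.5.  With
    fewer than ``min_windows`` informative windows every call is no-call
    (None).
    """
    valid = baf_windows.dropna()
    out: dict[int, pd.Series] = {}
    if len(valid) < min_windows:
        for sc in scales:
            out[sc] = pd.Series([None] * len(baf_windows), index=baf_windows.index, dtype=object)
        return out
    filled = baf_windows.ffill().bfill()
    smoothed = multiscale_smooth(filled, scales=scales)
    for sc in scales:
        # log scale: allelic shifts act multiplicatively on the deviation,
        # so baseline vs shifted separates at every tumor fraction
        x = np.log(smoothed[sc].to_numpy(dtype=float) + 1e-3)[:, None]
        if np.ptp(x) < 1e-12:
            flags = pd.Series(False, index=baf_windows.index)
        else:
            gm = GaussianMixture(n_components=2, random_state=int(seed) % (2**31), n_init=3)
            gm.fit(x)
            means = gm.means_.ravel()
            sds = np.sqrt(gm.covariances_.ravel())
            lo, hi = int(np.argmin(means)), int(np.argmax(means))
            post = gm.predict_proba(x)[:, hi]
            # shifted windows must also clear the neutral (lower) component's
            # own deviation range, not just win the posterior
            floor = means[lo] + 2.0 * sds[lo]
            flags = pd.Series((post > 0.5) & (x.ravel() > floor), index=baf_windows.index)
        flags[baf_windows.isna()] = None
        out[sc] = flags.astype(object)
    return out


@dataclass
class CNACallSet:
    """Consensus copy-number calls for one sample."""

    states: pd.Series                 # per window: loss / neutral / gain
    votes: pd.DataFrame               # per window x state, 0..9
    provenance: dict = field(default_factory=dict)

    @property
    def coverage(self) -> float:
        """Fraction of windows with a non-neutral final state."""
        return float((self.states != "neutral").mean())


def consensus_call(
    scale_states: dict[int, pd.Series],
    smoothed: dict[int, pd.Series],
    baf_calls: dict[int, pd.Series] | None = None,
    min_votes: int = MIN_VOTES,
    strong_evidence: float = STRONG_EVIDENCE,
) -> CNACallSet:
    """Vote over all (methylation scale x BAF scale) combinations.

    A combination votes a window's HMM state when the state is non-neutral
    and either the BAF scale flags the window as allele-shifted or the
    smoothed |log2 ratio| exceeds ``strong_evidence``.  Without BAF, each
    methylation scale contributes three identical votes, so >= 6 votes
    means >= 2 of 3 scales agree.  The final state needs >= ``min_votes``;
    if both non-neutral states qualify the majority wins and an exact tie
    is neutral.
    """
    meth_scales = sorted(scale_states)
    index = scale_states[meth_scales[0]].index
    baf_scales = sorted(baf_calls) if baf_calls else [None, None, None]
    votes = pd.DataFrame(0, index=index, columns=["loss", "gain"])
    for ms in meth_scales:
        st = scale_states[ms].to_numpy()
        strong = np.abs(smoothed[ms].to_numpy(dtype=float)) > strong_evidence
        for bs in baf_scales:
            if baf_calls is None or bs is None:
                support = np.ones(len(index), dtype=bool)
            else:
                flags = baf_calls[bs].to_numpy(dtype=object)
                shifted = np.array([bool(f) if f is not None else False for f in flags])
                support = shifted | strong
            for state in ("loss", "gain"):
                votes[state] += ((st == state) & support).astype(int)
    final = np.full(len(index), "neutral", dtype=object)
    loss_v = votes["loss"].to_numpy()
    gain_v = votes["gain"].to_numpy()
    call_loss = (loss_v >= min_votes) & (loss_v > gain_v)
    call_gain = (gain_v >= min_votes) & (gain_v > loss_v)
    final[call_loss] = "loss"
    final[call_gain] = "gain"
    n_combos = len(meth_scales) * len(baf_scales)
    vote_frame = votes.copy()
    vote_frame["neutral"] = n_combos - votes.sum(axis=1)
    return CNACallSet(
        states=pd.Series(final, index=index),
        votes=vote_frame[["loss", "neutral", "gain"]],
        provenance={"min_votes": min_votes, "strong_evidence": strong_evidence,
                    "baf_used": baf_calls is not None},
    )


def call_sample(
    windows: pd.DataFrame,
    sample: str,
    reference_samples: list[str],
    baf_windows: pd.Series | None = None,
    scales: tuple[int, ...] = SCALES,
    seed: int = 0,
) -> CNACallSet:
    """End-to-end per-sample pipeline: log ratio -> smooth -> HMM -> vote."""
    track = log_ratio_track(windows, sample, reference_samples)
    smoothed = multiscale_smooth(track, scales=scales)
    states = {sc: hmm_call(smoothed[sc])[0] for sc in scales}
    baf_calls = baf_shift(baf_windows, scales=scales, seed=seed) if baf_windows is not None else None
    return consensus_call(states, smoothed, baf_calls)


def cna_coverage(calls: dict[str, CNACallSet]) -> pd.Series:
    """Per-sample fraction of windows with a non-neutral state."""
    return pd.Series({s: c.coverage for s, c in calls.items()}, name="cna_coverage")


def coverage_vs_ctdna(coverage: pd.Series, pct_ctdna: pd.Series, mode: str = "pearson"):
    return associate(coverage, pct_ctdna, mode=mode)


def compare_to_truth(
    calls: dict[str, CNACallSet],
    truth_states: dict[str, pd.Series],
    gene_windows: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """3 x 3 confusion matrix (truth x predicted) over genes (or windows)
    x samples.

    ``gene_windows`` maps gene -> overlapping window ids; the predicted
    per-gene state is the majority window state (ties -> neutral).  Genes
    with no overlapping window are excluded.  Without a gene map the
    comparison runs window-by-window.
    """
    from .metrics import confusion_matrix

    rows_t, rows_p = [], []
    for sample, call in calls.items():
        truth = truth_states[sample]
        if gene_windows is None:
            common = call.states.index.intersection(truth.index)
            rows_t += list(truth.loc[common])
            rows_p += list(call.states.loc[common])
        else:
            for gene, wins in gene_windows.items():
                wins = [w for w in wins if w in call.states.index]
                if not wins:
                    continue
                counts = call.states.loc[wins].value_counts()
                top = counts[counts == counts.max()].index
                rows_p.append(top[0] if len(top) == 1 else "neutral")
                rows_t.append(truth[gene])
    return confusion_matrix(rows_t, rows_p, labels=list(STATES))
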
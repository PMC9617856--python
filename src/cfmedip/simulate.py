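"""Synthetic cfMeDIP cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes
rather than raw sequence: per-bin counts are negative-binomial draws around
a per-sample expected signal

    mu_bin = depth * [(1 - f) * m_bin + f * t_bin] * c_bin * cov_bin,

where ``f`` is the sample's ctDNA fraction, ``m`` the normal cfDNA
methylation profile, ``t`` the tumor profile (``m`` plus hypermethylation
effects at planted DMR bins), ``c`` the copy-number scaling
``(2 + f * delta) / 2`` over planted CNA segments, and ``cov`` the effect
of tumor-fraction-independent covariates (LDH/ALP-linked bins, and the
hypomethylation of repeat/pericentromeric bins in metastatic samples,
modeling a tumor-microenvironment rather than tumor-burden source).
Fragment lengths mix a normal component with a shorter tumor component
weighted by ``f``; SNP B-allele fractions shift inside CNA segments in
proportion to ``f``; survival times follow an exponential hazard tied to a
planted risk score.  All randomness flows from one master seed through
named ``SeedSequence`` substreams, so equal seeds give identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BinCountMatrix, FragmentTable, SampleSheet
from .genome import BinSet, GenomeModel, bin_genome, merge_intervals, overlaps_any

__all__ = [
    "SimulationParams", "SyntheticTruth", "SimulatedCohort",
    "build_genome_model", "simulate_cohort", "simulate_survival",
    "baf_window_track",
]


@dataclass
class SimulationParams:
    """All knobs of the synthetic cohort; defaults define the study-scale
    regime the pipeline is designed for (see docs/methods.md)."""

    # cohort
    n_localized: int = 30
    n_metastatic: int = 60
    n_control: int = 0
    # toy genome
    n_chromosomes: int = 3
    chrom_length: int = 30_000_000
    bin_width: int = 300
    island_spacing: int = 100_000
    island_length: int = 1_000
    shore_width: int = 2_000
    shelf_width: int = 2_000
    promoter_pad: int = 500
    repeat_fraction: float = 0.3
    repeat_mean_length: int = 5_000
    centromere_gap: int = 2_000_000
    cpg_island_density: float = 0.08
    cpg_background_density: float = 0.008
    # sequencing depth / count noise
    libsize_log_mean: float = math.log(5e6)
    libsize_log_sd: float = 0.2
    dispersion: float = 0.1
    low_bin_fraction: float = 0.2
    low_bin_factor: float = 0.02
    # ctDNA fraction per class
    localized_f_beta: tuple[float, float] = (1.5, 30.0)
    metastatic_f_beta: tuple[float, float] = (2.0, 3.0)
    metastatic_f_max: float = 0.9
    metastatic_f: tuple[float, ...] | None = None  # explicit override (cycled)
    # planted DMRs
    n_hyper: int = 200
    n_hypo: int = 200
    hyper_log2fc: float = 3.0     # on the tumor profile, diluted by f
    hypo_log2fc: float = 2.5      # class effect scaled by per-sample TME intensity
    tme_beta: tuple[float, float] = (2.0, 1.2)  # TME intensity ~ Beta, independent of f
    placement_bias: float = 0.8
    # covariate-linked bins (tumor-fraction independent)
    n_ldh_bins: int = 100
    n_alp_bins: int = 100
    covariate_slope: float = 0.5  # per SD of the covariate, natural-log scale
    # fragment model (synthetic; lengths in bp)
    n_fragments: int = 20_000
    frag_normal: tuple[float, float] = (187.0, 25.0)
    frag_tumor: tuple[float, float] = (155.0, 22.0)
    frag_range: tuple[int, int] = (60, 400)
    frag_window: int = 5_000_000
    frag_window_sd: float = 10.0  # regional jitter of the tumor length mean
    # CNAs (metastatic samples only; localized serve as reference)
    cna_segments_per_sample: int = 3
    cna_min_length: int = 9_000_000     # arm-scale events, as seen in mCRPC
    cna_max_length: int = 15_000_000
    shared_cna_segments: bool = False   # titration design: one tumor genome, varying f
    cna_clonality: tuple[float, ...] = (1.0,)  # cell fraction carrying each segment (cycled)
    coverage_bias_window: int = 1_000_000
    coverage_bias_sd: float = 0.035       # ln-scale regional coverage waviness
    coverage_bias_corr: float = 4.0       # Gaussian correlation length, in windows
    snp_spacing: int = 50_000
    baf_concentration: float = 100.0
    # survival
    baseline_hazard: float = 1.0 / 30.0   # per month
    hazard_beta: float = 1.5
    censoring_rate: float = 0.3

    def validate(self) -> None:
        if self.n_chromosomes <= 0:
            raise ValueError("need at least one chromosome")
        if min(self.n_localized, self.n_metastatic, self.n_control) < 0:
            raise ValueError("cohort sizes must be >= 0")
        for a, b in (self.localized_f_beta, self.metastatic_f_beta):
            if a <= 0 or b <= 0:
                raise ValueError("Beta parameters must be positive")
        if self.libsize_log_sd < 0 or self.dispersion < 0:
            raise ValueError("invalid depth parameters")
        if self.centromere_gap >= self.chrom_length:
            raise ValueError("centromere gap must be smaller than the chromosome")
        for v in (self.hyper_log2fc, self.hypo_log2fc, self.covariate_slope):
            if not np.isfinite(v):
                raise ValueError("effect sizes must be finite")


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for downstream parameter recovery."""

    hyper_bins: list[str]
    hypo_bins: list[str]
    ldh_bins: list[str]
    alp_bins: list[str]
    f: pd.Series                       # per-sample true ctDNA fraction
    tme: pd.Series                     # per-sample TME intensity (hypo effect scale)
    risk_score: pd.Series              # per-sample planted risk (z of f)
    # sample -> (chrom, start, end, delta, clonality)
    cna_segments: dict[str, list[tuple[str, int, int, int, float]]]

    def window_states(self, sample: str, genome: GenomeModel, window: int = 250_000) -> pd.Series:
        """Truth copy-number state per genomic window (majority overlap)."""
        wins = bin_genome(genome, width=window)
        states = np.full(len(wins), "neutral", dtype=object)
        for chrom, start, end, delta, _clon in self.cna_segments.get(sample, []):
            sel = wins.chroms == chrom
            ov_start = np.maximum(wins.starts[sel], start)
            ov_end = np.minimum(wins.ends[sel], end)
            ov = np.maximum(ov_end - ov_start, 0)
            length = wins.ends[sel] - wins.starts[sel]
            majority = ov > length // 2
            idx = np.flatnonzero(sel)[majority]
            states[idx] = "gain" if delta > 0 else "loss"
        return pd.Series(states, index=wins.bin_ids)

    def window_copy_delta(self, sample: str, genome: GenomeModel, window: int = 250_000) -> pd.Series:
        wins = bin_genome(genome, width=window)
        delta = np.zeros(len(wins))
        for chrom, start, end, d, clon in self.cna_segments.get(sample, []):
            sel = wins.chroms == chrom
            ov_start = np.maximum(wins.starts[sel], start)
            ov_end = np.minimum(wins.ends[sel], end)
            ov = np.maximum(ov_end - ov_start, 0)
            length = wins.ends[sel] - wins.starts[sel]
            majority = ov > length // 2
            delta[np.flatnonzero(sel)[majority]] = d * clon
        return pd.Series(delta, index=wins.bin_ids)


@dataclass
class SimulatedCohort:
    genome: GenomeModel
    bins: BinSet
    sheet: SampleSheet
    matrix: BinCountMatrix
    fragments: FragmentTable
    baf: dict[str, pd.DataFrame]       # sample -> chrom, pos, baf
    truth: SyntheticTruth


def build_genome_model(params: SimulationParams, seed: int = 0) -> GenomeModel:
    """Construct the toy genome: CpG islands at promoter sites with shore
    and shelf flanks, repeat intervals (pericentromere-enriched), one
    centromere gap per chromosome."""
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6E]))
    chroms = [(f"chr{i + 1}", params.chrom_length) for i in range(params.n_chromosomes)]
    annotations: dict[str, dict[str, np.ndarray]] = {
        k: {} for k in ("promoter", "cpg_island", "cpg_shore", "cpg_shelf",
                        "open_sea", "intergenic", "repeat")
    }
    cpg_positions: dict[str, np.ndarray] = {}
    gaps: dict[str, tuple[int, int]] = {}
    L = params.chrom_length
    for name, _ in chroms:
        gap = (L // 2 - params.centromere_gap // 2, L // 2 + params.centromere_gap // 2)
        gaps[name] = gap
        # islands on a jittered grid, kept clear of the gap and the edges
        islands = []
        pos = params.island_spacing
        while pos + params.island_length < L - params.shelf_width - 1:
            start = pos + int(rng.integers(0, params.island_spacing // 4 + 1))
            end = start + params.island_length
            if end < gap[0] - params.shelf_width or start > gap[1] + params.shelf_width:
                islands.append((start, end))
            pos += params.island_spacing
        islands_arr = np.array(islands, dtype=np.int64).reshape(-1, 2)
        annotations["cpg_island"][name] = islands_arr
        pad = params.promoter_pad
        annotations["promoter"][name] = np.clip(islands_arr + [-pad, pad], 0, L)
        shores, shelves = [], []
        for s, e in islands_arr:
            shores += [(max(s - params.shore_width, 0), s), (e, min(e + params.shore_width, L))]
            shelves += [
                (max(s - params.shore_width - params.shelf_width, 0), max(s - params.shore_width, 0)),
                (min(e + params.shore_width, L), min(e + params.shore_width + params.shelf_width, L)),
            ]
        annotations["cpg_shore"][name] = merge_intervals(np.array(shores).reshape(-1, 2)) if shores else np.empty((0, 2), np.int64)
        annotations["cpg_shelf"][name] = merge_intervals(np.array(shelves).reshape(-1, 2)) if shelves else np.empty((0, 2), np.int64)
        # repeats: exponential gaps and lengths; extra density in the pericentromere
        reps = []
        frac = params.repeat_fraction
        mean_gap = params.repeat_mean_length * (1 - frac) / max(frac, 1e-6)
        cursor = 0
        while cursor < L:
            cursor += int(rng.exponential(mean_gap)) + 1
            length = int(rng.exponential(params.repeat_mean_length)) + 200
            if cursor + length >= L:
                break
            reps.append((cursor, cursor + length))
            cursor += length
        peri = (max(gap[0] - 1_000_000, 0), min(gap[1] + 1_000_000, L))
        step = 20_000
        for s in range(peri[0], peri[1], step):
            if rng.random() < 0.5:
                reps.append((s, min(s + step // 2, L)))
        annotations["repeat"][name] = merge_intervals(np.array(reps).reshape(-1, 2))
        # intergenic: complement of promoters; open sea: beyond the shelves
        prom = annotations["promoter"][name]
        inter, prev = [], 0
        for s, e in prom:
            if s > prev:
                inter.append((prev, s))
            prev = e
        if prev < L:
            inter.append((prev, L))
        annotations["intergenic"][name] = np.array(inter, dtype=np.int64).reshape(-1, 2)
        cpg_zone = merge_intervals(np.vstack([
            islands_arr,
            annotations["cpg_shore"][name].reshape(-1, 2),
            annotations["cpg_shelf"][name].reshape(-1, 2),
        ])) if len(islands_arr) else np.empty((0, 2), np.int64)
        sea, prev = [], 0
        for s, e in cpg_zone:
            if s > prev:
                sea.append((prev, s))
            prev = e
        if prev < L:
            sea.append((prev, L))
        annotations["open_sea"][name] = np.array(sea, dtype=np.int64).reshape(-1, 2)
        # CpG positions: dense inside islands, sparse elsewhere
        n_bg = rng.poisson(params.cpg_background_density * L)
        pos_bg = rng.integers(0, L - 1, size=n_bg)
        pos_isl = []
        for s, e in islands_arr:
            n = rng.poisson(params.cpg_island_density * (e - s))
            pos_isl.append(rng.integers(s, e, size=n))
        allpos = np.concatenate([pos_bg] + pos_isl) if pos_isl else pos_bg
        cpg_positions[name] = np.unique(allpos).astype(np.int64)
    return GenomeModel(chroms, cpg_positions, annotations, gaps)


def _truncated_beta(rng: np.random.Generator, a: float, b: float, upper: float, size: int) -> np.ndarray:
    out = rng.beta(a, b, size=size)
    for _ in range(100):
        bad = out > upper
        if not bad.any():
            break
        out[bad] = rng.beta(a, b, size=int(bad.sum()))
    return np.minimum(out, upper)


def simulate_survival(
    risk_scores: pd.Series,
    baseline_hazard: float = 1.0 / 30.0,
    beta: float = 1.5,
    censoring_rate: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival with hazard h0 * exp(beta * z(score)).

    Censoring is an independent exponential clock whose rate is set so that
    a null subject is censored with probability ``censoring_rate``;
    ``censoring_rate >= 1`` censors everyone.
    """
    scores = pd.Series(risk_scores, dtype=float)
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("non-finite risk score")
    rng = np.random.default_rng(seed)
    z = scores.to_numpy()
    if np.std(z) > 0:
        z = (z - z.mean()) / z.std()
    hazard = baseline_hazard * np.exp(beta * z)
    t_event = rng.exponential(1.0 / hazard)
    if censoring_rate >= 1.0:
        return pd.DataFrame(
            {"os_time": rng.exponential(1.0 / baseline_hazard, size=len(scores)),
             "os_event": 0}, index=scores.index,
        )
    if censoring_rate <= 0:
        return pd.DataFrame({"os_time": t_event, "os_event": 1}, index=scores.index)
    lam_c = baseline_hazard * censoring_rate / (1.0 - censoring_rate)
    t_cens = rng.exponential(1.0 / lam_c, size=len(scores))
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"os_time": time, "os_event": event}, index=scores.index)


def _place_segments(rng, genome: GenomeModel, params: SimulationParams):
    """Non-overlapping CNA segments for one sample."""
    segs = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}
    for k in range(params.cna_segments_per_sample):
        clon = params.cna_clonality[k % len(params.cna_clonality)]
        for _attempt in range(50):
            chrom = genome.chrom_names[int(rng.integers(len(genome.chrom_names)))]
            L = genome.chrom_length(chrom)
            length = int(rng.integers(params.cna_min_length, params.cna_max_length + 1))
            start = int(rng.integers(0, max(L - length, 1)))
            end = start + length
            if any(s < end and start < e for s, e in occupied[chrom]):
                continue
            delta = int(rng.choice([-1, 1]))
            occupied[chrom].append((start, end))
            segs.append((chrom, start, end, delta, clon))
            break
    return segs


def simulate_cohort(
    genome: GenomeModel, params: SimulationParams, seed: int = 0
) -> SimulatedCohort:
    """Generate the full synthetic cohort with ground truth.

    Returns the sample sheet (with survival columns), the bin count matrix,
    per-sample fragment tables (pooled), SNP B-allele-fraction tracks, and
    the :class:`SyntheticTruth` object every recovery test runs against.
    """
    params.validate()
    ss = np.random.SeedSequence([seed, 0xC0])
    rng_plan, rng_sheet, rng_surv, *_ = [np.random.default_rng(s) for s in ss.spawn(4)]
    bins = bin_genome(genome, width=params.bin_width)
    n_bins = len(bins)
    bin_ids = bins.bin_ids

    # --- baseline (normal cfDNA) profile: CpG-driven with noise, some low bins
    m = (bins.cpg_counts + 0.5) ** 0.7 * rng_plan.lognormal(0.0, 0.3, size=n_bins)
    low = rng_plan.random(n_bins) < params.low_bin_fraction
    m[low] *= params.low_bin_factor

    # --- planted bin sets
    island_mask = np.zeros(n_bins, dtype=bool)
    repeat_mask = np.zeros(n_bins, dtype=bool)
    peri_mask = np.zeros(n_bins, dtype=bool)
    for chrom in genome.chrom_names:
        sel = bins.chroms == chrom
        s_, e_ = bins.starts[sel], bins.ends[sel]
        island_mask[sel] = overlaps_any(s_, e_, merge_intervals(genome.annotation_intervals("cpg_island", chrom)))
        repeat_mask[sel] = overlaps_any(s_, e_, merge_intervals(genome.annotation_intervals("repeat", chrom)))
        gs, ge = genome.centromere_gaps[chrom]
        peri_mask[sel] = overlaps_any(s_, e_, np.array([[max(gs - 1_000_000, 0), ge + 1_000_000]]))
        # no signal inside the assembly gap itself
        in_gap = (s_ < ge) & (e_ > gs)
        m[np.flatnonzero(sel)[in_gap]] *= 0.0

    usable = (~low) & (m > 0)  # keep planted effects out of zero-signal gap bins

    def _biased_choice(preferred: np.ndarray, n: int, taken: set[int]) -> np.ndarray:
        pref = np.flatnonzero(preferred & usable & ~np.isin(np.arange(n_bins), list(taken)))
        rest = np.flatnonzero(usable & ~preferred & ~np.isin(np.arange(n_bins), list(taken)))
        n_pref = min(int(round(params.placement_bias * n)), len(pref))
        chosen = list(rng_plan.choice(pref, size=n_pref, replace=False)) if n_pref else []
        n_rest = min(n - n_pref, len(rest))
        chosen += list(rng_plan.choice(rest, size=n_rest, replace=False))
        return np.array(sorted(chosen), dtype=int)

    taken: set[int] = set()
    hyper_idx = _biased_choice(island_mask, params.n_hyper, taken)
    taken |= set(hyper_idx)
    hypo_idx = _biased_choice(repeat_mask | peri_mask, params.n_hypo, taken)
    taken |= set(hypo_idx)
    free = np.flatnonzero(usable & ~np.isin(np.arange(n_bins), list(taken)))
    ldh_idx = rng_plan.choice(free, size=min(params.n_ldh_bins, len(free)), replace=False)
    taken |= set(ldh_idx)
    free = np.flatnonzero(usable & ~np.isin(np.arange(n_bins), list(taken)))
    alp_idx = rng_plan.choice(free, size=min(params.n_alp_bins, len(free)), replace=False)

    # --- sample sheet
    rows = []
    classes = (
        [("localized", i) for i in range(params.n_localized)]
        + [("metastatic", i) for i in range(params.n_metastatic)]
        + [("control", i) for i in range(params.n_control)]
    )
    f_loc = rng_sheet.beta(*params.localized_f_beta, size=params.n_localized)
    if params.metastatic_f is not None:
        reps = int(np.ceil(params.n_metastatic / len(params.metastatic_f)))
        f_met = np.tile(np.asarray(params.metastatic_f, dtype=float), reps)[: params.n_metastatic]
    else:
        f_met = _truncated_beta(
            rng_sheet, *params.metastatic_f_beta, params.metastatic_f_max, params.n_metastatic
        )
    f_by_class = {"localized": f_loc, "metastatic": f_met,
                  "control": np.zeros(params.n_control)}
    for cls, i in classes:
        sid = f"{cls[:3].upper()}{i + 1:03d}"
        rows.append({
            "sample_id": sid,
            "patient_id": f"P_{sid}",
            "cohort": "synthetic",
            "class": cls,
            "batch": f"b{(i % 2) + 1}",
            "pct_ctdna": float(f_by_class[cls][i]),
            "age": float(np.round(rng_sheet.normal(68 if cls == "metastatic" else 65, 8), 1)),
            "ldh": float(np.round(rng_sheet.lognormal(math.log(200), 0.4), 2)),
            "alp": float(np.round(rng_sheet.lognormal(math.log(100), 0.4), 2)),
        })
    sheet_df = pd.DataFrame(rows)
    f = sheet_df.set_index("sample_id")["pct_ctdna"]
    risk = (f - f.mean()) / (f.std() if f.std() > 0 else 1.0)
    surv = simulate_survival(
        risk, params.baseline_hazard, params.hazard_beta, params.censoring_rate,
        seed=int(rng_surv.integers(2**31)),
    )
    sheet_df["os_time"] = surv["os_time"].to_numpy()
    sheet_df["os_event"] = surv["os_event"].to_numpy()

    # --- per-sample CNA segments (metastatic only; localized are the CNA
    # reference cohort and stay copy-neutral)
    cna_segments: dict[str, list] = {}
    met_ids = sheet_df.loc[sheet_df["class"] == "metastatic", "sample_id"]
    if params.shared_cna_segments:
        shared = _place_segments(rng_plan, genome, params)
        for sid in met_ids:
            cna_segments[sid] = list(shared)
    else:
        for sid in met_ids:
            cna_segments[sid] = _place_segments(rng_plan, genome, params)

    # --- covariate z-scores (LDH/ALP drawn independently of f)
    def _log_z(col: str) -> pd.Series:
        lv = np.log(sheet_df.set_index("sample_id")[col])
        sd = lv.std(ddof=0)
        return (lv - lv.mean()) / (sd if sd > 0 else 1.0)

    ldh_z = _log_z("ldh")
    alp_z = _log_z("alp")

    # per-window tumor fragment-length offsets (regional fragmentation)
    frag_wins = bin_genome(genome, width=params.frag_window)
    win_offsets = rng_plan.normal(0.0, params.frag_window_sd, size=len(frag_wins))

    # map bins to coverage-bias windows (spatially correlated noise below)
    bias_wins = bin_genome(genome, width=params.coverage_bias_window)
    bin_mids = (bins.starts + bins.ends) // 2
    bias_idx = bias_wins.assign(bins.chroms, bin_mids)
    kernel_half = int(4 * params.coverage_bias_corr)
    kx = np.arange(-kernel_half, kernel_half + 1)
    kernel = np.exp(-0.5 * (kx / params.coverage_bias_corr) ** 2)
    kernel /= np.sqrt(np.sum(kernel**2))  # unit-variance output for white input

    hyper_mult = np.ones(n_bins)
    hyper_mult[hyper_idx] = 2.0 ** params.hyper_log2fc
    # per-sample TME intensity: scales the hypomethylation of repeat /
    # pericentromeric bins in metastatic samples, independent of f
    tme = pd.Series(
        rng_sheet.beta(*params.tme_beta, size=len(sheet_df)),
        index=sheet_df["sample_id"],
    )

    counts_cols, libs = {}, {}
    frag_frames = []
    baf_tracks: dict[str, pd.DataFrame] = {}
    sample_streams = ss.spawn(len(sheet_df))
    for row, sstream in zip(sheet_df.to_dict("records"), sample_streams):
        rng = np.random.default_rng(sstream)
        sid = row["sample_id"]
        fi = row["pct_ctdna"]
        t = m * hyper_mult                       # tumor methylation profile
        w = (1.0 - fi) * m + fi * t              # ctDNA mixture
        if row["class"] == "metastatic":
            hypo_mult = np.ones(n_bins)
            hypo_mult[hypo_idx] = 2.0 ** (-params.hypo_log2fc * tme[sid])
            w = w * hypo_mult                    # TME-linked, f-independent
        # CNA scaling
        c = np.ones(n_bins)
        for chrom, s_, e_, delta, clon in cna_segments.get(sid, []):
            sel = (bins.chroms == chrom)
            inside = (bins.starts >= s_) & (bins.ends <= e_) & sel
            c[inside] = (2.0 + fi * clon * delta) / 2.0
        w = w * c
        cov = np.ones(n_bins)
        cov[ldh_idx] = np.exp(params.covariate_slope * ldh_z[sid])
        cov[alp_idx] = np.exp(params.covariate_slope * alp_z[sid])
        w = w * cov
        if params.coverage_bias_sd > 0:
            white = rng.normal(0.0, 1.0, size=len(bias_wins) + 2 * kernel_half)
            smooth = np.convolve(white, kernel, mode="valid")
            w = w * np.exp(params.coverage_bias_sd * smooth[bias_idx])
        depth = rng.lognormal(params.libsize_log_mean, params.libsize_log_sd)
        mu = depth * w / w.sum()
        if params.dispersion > 0:
            shape = 1.0 / params.dispersion
            lam = rng.gamma(shape, mu / shape)
            counts = rng.poisson(lam)
        else:
            counts = rng.poisson(mu)
        counts_cols[sid] = counts.astype(np.int64)
        libs[sid] = int(counts.sum())

        # fragments: positions follow the signal, lengths follow the mixture
        nf = params.n_fragments
        p = w / w.sum()
        frag_bins = rng.choice(n_bins, size=nf, p=p)
        offset = rng.integers(0, params.bin_width, size=nf)
        mids = bins.starts[frag_bins] + np.minimum(offset, bins.ends[frag_bins] - bins.starts[frag_bins] - 1)
        is_tumor = rng.random(nf) < fi
        mean_n, sd_n = params.frag_normal
        mean_t, sd_t = params.frag_tumor
        widx = frag_wins.assign(bins.chroms[frag_bins], mids)
        len_tumor = rng.normal(mean_t + win_offsets[widx], sd_t)
        len_normal = rng.normal(mean_n, sd_n, size=nf)
        lengths = np.where(is_tumor, len_tumor, len_normal)
        lengths = np.clip(np.round(lengths), params.frag_range[0], params.frag_range[1]).astype(np.int64)
        starts = np.maximum(mids - lengths // 2, 0)
        frag_frames.append(pd.DataFrame({
            "sample_id": sid,
            "chrom": bins.chroms[frag_bins],
            "start": starts,
            "end": starts + lengths,
        }))

        # SNP BAF track
        snp_rows = []
        for chrom in genome.chrom_names:
            L = genome.chrom_length(chrom)
            pos = np.arange(params.snp_spacing // 2, L, params.snp_spacing)
            mean_baf = np.full(len(pos), 0.5)
            for c_, s_, e_, delta, clon in cna_segments.get(sid, []):
                if c_ != chrom:
                    continue
                inside = (pos >= s_) & (pos < e_)
                fe = fi * clon
                shifted = (1.0 + fe * delta) / (2.0 + fe * delta)
                flip = rng.random(int(inside.sum())) < 0.5
                vals = np.where(flip, shifted, 1.0 - shifted)
                mean_baf[inside] = vals
            kappa = params.baf_concentration
            baf = rng.beta(mean_baf * kappa, (1.0 - mean_baf) * kappa)
            snp_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "baf": baf}))
        baf_tracks[sid] = pd.concat(snp_rows, ignore_index=True)

    counts = pd.DataFrame(counts_cols, index=bin_ids)
    matrix = BinCountMatrix(counts, pd.Series(libs))
    fragments = FragmentTable(pd.concat(frag_frames, ignore_index=True))
    truth = SyntheticTruth(
        hyper_bins=list(bin_ids[hyper_idx]),
        hypo_bins=list(bin_ids[hypo_idx]),
        ldh_bins=list(bin_ids[ldh_idx]),
        alp_bins=list(bin_ids[alp_idx]),
        f=f,
        tme=tme,
        risk_score=risk,
        cna_segments=cna_segments,
    )
    return SimulatedCohort(
        genome=genome, bins=bins, sheet=SampleSheet(sheet_df), matrix=matrix,
        fragments=fragments, baf=baf_tracks, truth=truth,
    )


def baf_window_track(
    baf: pd.DataFrame, genome: GenomeModel, window: int = 250_000
) -> pd.Series:
    """Per-window mean |BAF - 0.5| from a sample's SNP table (NaN where a
    window has no SNP)."""
    wins = bin_genome(genome, width=window)
    idx = wins.assign(baf["chrom"].to_numpy(), baf["pos"].to_numpy())
    dev = np.abs(baf["baf"].to_numpy() - 0.5)
    tot = np.bincount(idx, weights=dev, minlength=len(wins))
    n = np.bincount(idx, minlength=len(wins))
    with np.errstate(invalid="ignore"):
        out = np.where(n > 0, tot / np.maximum(n, 1), np.nan)
    return pd.Series(out, index=wins.bin_ids)
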
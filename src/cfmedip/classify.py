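"""Repeated balanced-resampling diagnostic classifier.

Each repeat draws an equal number of localized and metastatic patients
(default 21 per class) for training, discovers DMRs *inside the training
fold only*, ranks hyper- and hypo-DMR candidates by information gain, takes
the top 150 of each, and fits a random forest evaluated on one sample per
held-out patient.  Fifty repeats are summarized by median accuracy and
AUROC and by per-sample misclassification frequency, which is compared to
tumor fraction (misclassified metastatic samples tend to carry less ctDNA).

Every statistic that could leak — non-low bin filtering, size factors, DMR
discovery, feature ranking — is recomputed from the training fold of each
repeat.  Test samples are normalized by projecting onto the training
reference (median ratio to the training per-bin geometric mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .containers import BinCountMatrix, SampleSheet
from .dmr import call_dmrs, nb_wald_test, size_factors
from .metrics import auroc
from .quantify import filter_nonlow, rpkm

__all__ = [
    "SplitPlan", "FeatureSet", "ClassifierReport",
    "split_balanced", "information_gain", "ig_scores",
    "select_features", "train_eval_once", "repeat_harness",
]

CONTRAST = ("metastatic", "localized")


@dataclass
class SplitPlan:
    repeat: int
    train_ids: list[str]
    test_ids: list[str]
    seed: int


@dataclass
class FeatureSet:
    hyper: list[str]
    hypo: list[str]
    ig: pd.Series
    nonlow_bins: pd.Index
    ref_bins: pd.Index           # training bins positive in all training samples
    log_ref: np.ndarray          # their per-bin log geometric mean (training)
    train_size_factors: pd.Series

    @property
    def bins(self) -> list[str]:
        return list(self.hyper) + list(self.hypo)


def _one_per_patient(df: pd.DataFrame) -> pd.DataFrame:
    """Earliest sample per patient: by 'timepoint' when present, else by
    sample_id — a deterministic stand-in for draw order."""
    sort_cols = ["patient_id"] + (["timepoint"] if "timepoint" in df.columns else []) + ["sample_id"]
    return df.sort_values(sort_cols).groupby("patient_id", sort=True).head(1)


def split_balanced(
    sheet: SampleSheet, n_per_class: int = 21, seed: int = 0, repeat: int = 0
) -> SplitPlan:
    """Patient-level balanced split: ``n_per_class`` training patients per
    class (one sample each), test = one sample per remaining patient."""
    rng = np.random.default_rng(seed)
    df = sheet.df[sheet.df["class"].isin(CONTRAST)]
    train_ids: list[str] = []
    train_patients: set[str] = set()
    for cls in CONTRAST:
        sub = df[df["class"] == cls]
        patients = np.array(sorted(sub["patient_id"].unique()))
        if len(patients) <= n_per_class:
            raise ValueError(
                f"class {cls!r} has {len(patients)} unique patients; "
                f"need more than n_per_class = {n_per_class}"
            )
        chosen = rng.choice(patients, size=n_per_class, replace=False)
        chosen_rows = _one_per_patient(sub[sub["patient_id"].isin(chosen)])
        train_ids += list(chosen_rows["sample_id"])
        train_patients |= set(chosen)
    held = df[~df["patient_id"].isin(train_patients)]
    test_ids = list(_one_per_patient(held)["sample_id"])
    return SplitPlan(repeat=repeat, train_ids=sorted(train_ids), test_ids=sorted(test_ids), seed=seed)


def information_gain(feature, labels) -> tuple[float, float]:
    """Information gain (bits) of the best binary split of one feature.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values; ties in IG break toward the smaller threshold.  A constant
    feature has IG 0.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(labels)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], (y[order] == np.unique(y)[-1])

    def _h(p):
        p = p[(p > 0)]
        return float(-(p * np.log2(p)).sum())

    n = len(xs)
    total_pos = ys.sum()
    h_full = _h(np.array([total_pos / n, 1 - total_pos / n]))
    distinct = np.nonzero(np.diff(xs))[0]  # split after these indices
    if len(distinct) == 0:
        return 0.0, float("nan")
    cum_pos = np.cumsum(ys)
    best_ig, best_thr = -1.0, float("nan")
    for i in distinct:
        n_left = i + 1
        p_left = cum_pos[i] / n_left
        n_right = n - n_left
        p_right = (total_pos - cum_pos[i]) / n_right
        h_cond = (
            n_left / n * _h(np.array([p_left, 1 - p_left]))
            + n_right / n * _h(np.array([p_right, 1 - p_right]))
        )
        ig = h_full - h_cond
        if ig > best_ig + 1e-12:
            best_ig = ig
            best_thr = (xs[i] + xs[i + 1]) / 2
    return max(best_ig, 0.0), best_thr


def ig_scores(signal: pd.DataFrame, labels: pd.Series) -> pd.Series:
    y = labels.reindex(signal.columns).to_numpy()
    return pd.Series(
        [information_gain(signal.loc[b].to_numpy(), y)[0] for b in signal.index],
        index=signal.index,
    )


def _normalized_signal(counts: pd.DataFrame, s: pd.Series) -> pd.DataFrame:
    return np.log2(counts / s.reindex(counts.columns) + 1.0)


def select_features(
    mat: BinCountMatrix,
    sheet: SampleSheet,
    train_ids: list[str],
    k: int = 150,
    covariates: tuple[str, ...] | None = None,
    require_dmrs: bool = True,
) -> FeatureSet:
    """Fold-internal feature discovery on the training samples only.

    Runs non-low filtering, the NB Wald test (age + batch control when the
    fold has the variation to support it) and DMR calling inside the fold,
    then ranks hyper and hypo candidates separately by information gain on
    fold-normalized signal.
    """
    train = mat.subset_samples(train_ids)
    train = filter_nonlow(rpkm(train))
    sub_sheet = sheet.subset(train_ids)
    if covariates is None:
        covariates = ()
        if sub_sheet.df["age"].notna().all():
            covariates += ("age",)
        if sub_sheet.df["batch"].nunique() > 1:
            covariates += ("batch",)
    stats_df = nb_wald_test(train, sheet, covariates=covariates, contrast=CONTRAST)
    dmrs = call_dmrs(stats_df)
    hyper_cand, hypo_cand = list(dmrs.hyper), list(dmrs.hypo)
    if not hyper_cand and not hypo_cand:
        if require_dmrs:
            raise ValueError(
                "no DMRs found in the training fold; check effect sizes or cohort simulation"
            )
        # fallback (null harness): rank every non-low bin, split by FC sign
        l2fc = stats_df["log2fc"]
        hyper_cand = list(stats_df.index[l2fc.to_numpy() > 0])
        hypo_cand = list(stats_df.index[l2fc.to_numpy() <= 0])
        warnings.warn("no DMRs in fold; ranking all bins by information gain", stacklevel=2)
    s = size_factors(train)
    signal = _normalized_signal(train.counts, s)
    labels = sub_sheet.column("class")
    ig = ig_scores(signal.loc[hyper_cand + hypo_cand], labels)

    def _top(idx) -> list[str]:
        if len(idx) == 0:
            return []
        ranked = ig.loc[list(idx)].sort_values(ascending=False, kind="stable")
        if len(ranked) < k and require_dmrs:
            warnings.warn(f"only {len(ranked)} DMRs available for k = {k}", stacklevel=2)
        return list(ranked.head(k).index)

    all_pos = (train.counts > 0).all(axis=1)
    ref_bins = train.counts.index[all_pos]
    log_ref = np.log(train.counts.loc[ref_bins].to_numpy(dtype=float)).mean(axis=1)
    return FeatureSet(
        hyper=_top(hyper_cand),
        hypo=_top(hypo_cand),
        ig=ig,
        nonlow_bins=train.counts.index,
        ref_bins=ref_bins,
        log_ref=log_ref,
        train_size_factors=s,
    )


def _project_size_factors(counts: pd.DataFrame, features: FeatureSet) -> pd.Series:
    """Size factors for new samples against the training reference."""
    K = counts.loc[features.ref_bins].to_numpy(dtype=float)
    out = {}
    for j, sample in enumerate(counts.columns):
        col = K[:, j]
        pos = col > 0
        if not pos.any():
            raise ValueError(f"sample {sample} has no counts on reference bins")
        out[sample] = float(np.exp(np.median(np.log(col[pos]) - features.log_ref[pos])))
    return pd.Series(out)


def train_eval_once(
    mat: BinCountMatrix,
    sheet: SampleSheet,
    plan: SplitPlan,
    features: FeatureSet,
    seed: int = 0,
    n_trees: int = 500,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Fit the forest on the training fold and evaluate on the test fold.

    Returns (metrics, per-sample predictions).  Class probabilities are for
    the metastatic class; AUROC uses the rank statistic.
    """
    bins = features.bins
    cls = sheet.column("class")
    strain = features.train_size_factors
    X_train = _normalized_signal(mat.counts[plan.train_ids].loc[bins], strain).T
    if X_train.isna().any().any():
        raise ValueError("missing values in the training feature matrix")
    y_train = (cls.reindex(plan.train_ids) == "metastatic").astype(int)
    stest = _project_size_factors(mat.counts[plan.test_ids], features)
    X_test = _normalized_signal(mat.counts[plan.test_ids].loc[bins], stest).T
    y_test = (cls.reindex(plan.test_ids) == "metastatic").astype(int)
    rf = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(seed) % (2**31), n_jobs=1
    )
    rf.fit(X_train.to_numpy(), y_train.to_numpy())
    prob = rf.predict_proba(X_test.to_numpy())[:, list(rf.classes_).index(1)]
    pred = (prob >= 0.5).astype(int)
    acc = float((pred == y_test.to_numpy()).mean())
    auc = auroc(prob, y_test.to_numpy())
    preds = pd.DataFrame(
        {
            "sample_id": plan.test_ids,
            "true": y_test.to_numpy(),
            "pred": pred,
            "prob_metastatic": prob,
            "correct": pred == y_test.to_numpy(),
        }
    )
    return {"accuracy": acc, "auroc": auc}, preds


@dataclass
class ClassifierReport:
    per_repeat: pd.DataFrame             # repeat, accuracy, auroc
    predictions: pd.DataFrame            # pooled per-repeat test predictions
    misclassification: pd.DataFrame      # per sample: times_tested, times_wrong, freq
    median_accuracy: float = field(init=False)
    median_auroc: float = field(init=False)

    def __post_init__(self) -> None:
        self.median_accuracy = float(self.per_repeat["accuracy"].median())
        self.median_auroc = float(self.per_repeat["auroc"].median())

    def misclassified_vs_ctdna(self, sheet: SampleSheet):
        """Fig. 4C-style readout: true tumor fraction of misclassified vs
        correctly classified metastatic test results, pooled over repeats
        (one-sided Mann-Whitney: misclassified lower)."""
        cls = sheet.column("class")
        f = sheet.column("pct_ctdna")
        met = self.predictions[self.predictions["sample_id"].map(cls) == "metastatic"]
        vals = met["sample_id"].map(f)
        ok = met["correct"].to_numpy()
        x, y = vals[~ok].dropna(), vals[ok].dropna()
        if len(x) == 0 or len(y) == 0:
            return float("nan"), float("nan")
        from scipy import stats as sps

        res = sps.mannwhitneyu(x, y, alternative="less")
        return float(res.statistic), float(res.pvalue)


def repeat_harness(
    mat: BinCountMatrix,
    sheet: SampleSheet,
    repeats: int = 50,
    n_per_class: int = 21,
    k: int = 150,
    master_seed: int = 0,
    n_trees: int = 500,
    permute_labels: bool = False,
) -> ClassifierReport:
    """Run the full resampling protocol and summarize across repeats.

    One sub-seed per repeat is derived from ``master_seed`` via
    ``numpy.random.SeedSequence.spawn``; ``permute_labels`` shuffles class
    labels at the patient level first (the null harness).
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    if permute_labels:
        rng = np.random.default_rng(ss.spawn(1)[0])
        df = sheet.df.copy()
        pat = df.drop_duplicates("patient_id")[["patient_id", "class"]]
        shuffled = rng.permutation(pat["class"].to_numpy())
        lut = dict(zip(pat["patient_id"], shuffled))
        df["class"] = df["patient_id"].map(lut)
        sheet = SampleSheet(df)
    child_seeds = ss.spawn(repeats)
    rows, preds = [], []
    for r in range(repeats):
        states = child_seeds[r].generate_state(2)
        plan = split_balanced(
            sheet, n_per_class=n_per_class, seed=int(states[0] % (2**31)), repeat=r
        )
        features = select_features(
            mat, sheet, plan.train_ids, k=k, require_dmrs=not permute_labels
        )
        m, p = train_eval_once(
            mat, sheet, plan, features, seed=int(states[1] % (2**31)), n_trees=n_trees
        )
        rows.append({"repeat": r, **m})
        p.insert(0, "repeat", r)
        preds.append(p)
    per_repeat = pd.DataFrame(rows)
    predictions = pd.concat(preds, ignore_index=True)
    mis = predictions.groupby("sample_id").agg(
        times_tested=("correct", "size"), times_wrong=("correct", lambda c: int((~c).sum()))
    )
    mis["freq"] = mis["times_wrong"] / mis["times_tested"]
    return ClassifierReport(per_repeat, predictions, mis)
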
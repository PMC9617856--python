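"""Differential methylation: normalization, NB Wald test, DMR calling,
risk score, survival and region summaries."""

import numpy as np
import pandas as pd
import pytest

from cfmedip.containers import BinCountMatrix, SampleSheet
from cfmedip.dmr import (
    DMRTable,
    call_dmrs,
    hyper_hypo_ratio,
    nb_wald_test,
    pericentromeric_summary,
    region_score,
    size_factors,
)
from cfmedip.survival import km_logrank


def _matrix(counts_dict, bins=None):
    n = len(next(iter(counts_dict.values())))
    bins = bins or [f"chr1:{i * 300}-{(i + 1) * 300}" for i in range(n)]
    counts = pd.DataFrame(counts_dict, index=bins)
    return BinCountMatrix(counts, counts.sum(axis=0))


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        mat = _matrix({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(size_factors(mat), [1.0, 1.0])

    def test_scaling_equivariance(self):
        mat = _matrix({"a": [10, 20, 30], "b": [20, 40, 60]})
        s = size_factors(mat)
        assert s["b"] / s["a"] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(s))) == pytest.approx(1.0)

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(17)
        counts = rng.negative_binomial(10, 0.3, size=(50, 4)) + 1
        mat = _matrix({f"s{j}": counts[:, j] for j in range(4)})
        s = size_factors(mat)
        # independent arithmetic: per-bin geometric mean, median ratio per sample
        ref = np.exp(np.mean(np.log(counts), axis=1))
        expected = np.array([np.median(counts[:, j] / ref) for j in range(4)])
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(s.to_numpy(), expected)

    def test_no_common_nonzero_bin_rejected(self):
        mat = _matrix({"a": [5, 0], "b": [0, 5]})
        with pytest.raises(ValueError):
            size_factors(mat)


def _two_class_sheet(n_per_class, age_by_class=None):
    rows = []
    for cls, n in (("localized", n_per_class), ("metastatic", n_per_class)):
        for i in range(n):
            age = 65.0
            if age_by_class:
                age = age_by_class[cls][i]
            rows.append({
                "sample_id": f"{cls[:3]}{i}", "patient_id": f"p_{cls[:3]}{i}",
                "cohort": "t", "class": cls, "batch": "b1", "age": age,
            })
    return SampleSheet(pd.DataFrame(rows))


def _nb_counts(rng, mu, phi):
    shape = 1.0 / phi
    return rng.poisson(rng.gamma(shape, mu / shape))


class TestNBWaldTest:
    def test_label_swap_negates_log2fc(self, dmr_cohort):
        from cfmedip.quantify import filter_nonlow, rpkm

        mat = filter_nonlow(rpkm(dmr_cohort.matrix)).subset_bins(
            filter_nonlow(rpkm(dmr_cohort.matrix)).counts.index[:300]
        )
        fwd = nb_wald_test(mat, dmr_cohort.sheet, covariates=())
        rev = nb_wald_test(
            mat, dmr_cohort.sheet, covariates=(),
            contrast=("localized", "metastatic"),
        )
        assert np.allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-4)
        assert np.allclose(np.abs(fwd["wald"]), np.abs(rev["wald"]), atol=1e-3)

    def test_age_confounded_bins_controlled_by_design(self):
        rng = np.random.default_rng(23)
        n = 15
        ages = {"localized": 55 + rng.normal(0, 3, n), "metastatic": 75 + rng.normal(0, 3, n)}
        sheet = _two_class_sheet(n, age_by_class=ages)
        all_ages = np.concatenate([ages["localized"], ages["metastatic"]])
        mu = np.full((60, 2 * n), 200.0)
        mu[:10] *= np.exp(0.06 * (all_ages - 65))[None, :]  # age-driven bins
        counts = _nb_counts(rng, mu, 0.05)
        mat = _matrix({s: counts[:, j] for j, s in enumerate(sheet.sample_ids)})
        with_age = call_dmrs(nb_wald_test(mat, sheet, covariates=("age",)))
        without_age = call_dmrs(nb_wald_test(mat, sheet, covariates=()))
        age_bins = set(mat.counts.index[:10])
        assert len(set(without_age.hyper) & age_bins) >= 8   # confounded when omitted
        controlled = set(with_age.hyper) | set(with_age.hypo)
        assert len(controlled & age_bins) <= 1

    def test_needs_three_samples_per_class(self):
        sheet = _two_class_sheet(2)
        mat = _matrix({s: [10, 20] for s in sheet.sample_ids})
        with pytest.raises(ValueError, match=">= 3"):
            nb_wald_test(mat, sheet, covariates=())


class TestBenjaminiHochberg:
    def test_matches_brute_force_step_up(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(31)
        for size in (10, 100, 5000):
            p = rng.uniform(size=size) ** 2
            q = multipletests(p, method="fdr_bh")[1]
            # brute force: sort, step-up, enforce monotonicity, unsort
            order = np.argsort(p)
            ranked = p[order] * size / (np.arange(size) + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            expected = np.empty(size)
            expected[order] = np.minimum(ranked, 1.0)
            assert np.allclose(q, expected)


class TestCallDmrs:
    def _stats(self, rows):
        return pd.DataFrame(rows, columns=["log2fc", "q"]).assign(
            baseMean=10.0, wald=0.0, p=lambda d: d["q"], converged=True
        )

    def test_fold_change_gate(self):
        t = self._stats([(0.9, 0.04), (1.2, 0.04), (-1.5, 0.2), (-1.5, 0.01)])
        called = call_dmrs(t)
        assert list(called.table["direction"]) == ["ns", "hyper", "ns", "hypo"]

    def test_count_ratio_rounding(self):
        rows = [(2.0, 0.01)] * 19048 + [(-2.0, 0.01)] * 2493
        called = call_dmrs(self._stats(rows))
        assert called.count_ratio == 7.6

    def test_empty_stats_undefined_ratio(self):
        called = call_dmrs(self._stats([]))
        assert len(called.table) == 0 and np.isnan(called.count_ratio)


class TestRiskScore:
    def _rpkm(self):
        return pd.DataFrame(
            {"s1": [2.0, 2.0, 1.0], "s2": [4.0, 4.0, 1.0], "s3": [1.0, 1.0, 1.0]},
            index=["b1", "b2", "b3"],
        )

    def _dmrs(self):
        t = pd.DataFrame(
            {"direction": ["hyper", "hyper", "hypo"]}, index=["b1", "b2", "b3"]
        )
        return DMRTable(t.assign(log2fc=[2, 2, -2], q=0.01))

    def test_ratio_of_means(self):
        scores = hyper_hypo_ratio(self._rpkm(), self._dmrs())
        assert scores.loc["s1", "score"] == pytest.approx(2.0)
        assert scores.loc["s2", "score"] == pytest.approx(4.0)

    def test_ties_assigned_low(self):
        rp = pd.DataFrame({"s1": [2.0, 1.0], "s2": [2.0, 1.0]}, index=["b1", "b3"])
        dmrs = DMRTable(pd.DataFrame(
            {"direction": ["hyper", "hypo"], "log2fc": [2, -2], "q": [0.01, 0.01]},
            index=["b1", "b3"],
        ))
        scores = hyper_hypo_ratio(rp, dmrs)
        assert (scores["group"] == "low").all()

    def test_zero_hypo_mean_gives_missing(self):
        rp = pd.DataFrame({"s1": [2.0, 0.0]}, index=["b1", "b3"])
        dmrs = DMRTable(pd.DataFrame(
            {"direction": ["hyper", "hypo"], "log2fc": [2, -2], "q": [0.01, 0.01]},
            index=["b1", "b3"],
        ))
        scores = hyper_hypo_ratio(rp, dmrs)
        assert np.isnan(scores.loc["s1", "score"])

    def test_score_tracks_tumor_fraction(self, dmr_cohort):
        from cfmedip.quantify import filter_nonlow, rpkm
        from scipy.stats import spearmanr

        mat = filter_nonlow(rpkm(dmr_cohort.matrix))
        dmrs = call_dmrs(nb_wald_test(mat, dmr_cohort.sheet))
        scores = hyper_hypo_ratio(mat.rpkm, dmrs)
        cls = dmr_cohort.sheet.column("class")
        met = cls[cls == "metastatic"].index
        rho = spearmanr(scores.loc[met, "score"], dmr_cohort.truth.f[met]).statistic
        assert rho > 0.5


class TestKMLogrank:
    def test_identical_groups_give_null_statistic(self):
        time = pd.Series([5.0, 8, 12, 5, 8, 12], index=list("abcdef"))
        event = pd.Series([1, 1, 0, 1, 1, 0], index=list("abcdef"))
        groups = pd.Series(["x", "x", "x", "y", "y", "y"], index=list("abcdef"))
        res = km_logrank(groups, time, event)
        assert res.estimable
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_six_subject_hand_computed_table(self):
        # A: events at 1, 3, censored 5.  B: events at 2, 4, 6.
        # O_A = 2; E_A = 1/2 + 2/5 + 1/2 + 1/3 = 26/15; V = 0.25+0.24+0.25+2/9
        groups = pd.Series(["A", "A", "A", "B", "B", "B"], index=range(6))
        time = pd.Series([1.0, 3, 5, 2, 4, 6], index=range(6))
        event = pd.Series([1, 1, 0, 1, 1, 1], index=range(6))
        o_minus_e = 2 - (0.5 + 0.4 + 0.5 + 1 / 3)
        v = 0.25 + 0.24 + 0.25 + 2 / 9
        res = km_logrank(groups, time, event)
        assert res.chi2 == pytest.approx(o_minus_e**2 / v, rel=1e-6)

    def test_group_without_events_non_estimable(self):
        groups = pd.Series(["x", "x", "y", "y"], index=range(4))
        time = pd.Series([5.0, 8, 4, 9], index=range(4))
        event = pd.Series([1, 1, 0, 0], index=range(4))
        res = km_logrank(groups, time, event)
        assert not res.estimable and np.isnan(res.p)

    def test_requires_exactly_two_groups(self):
        groups = pd.Series(["x", "y", "z"], index=range(3))
        with pytest.raises(ValueError):
            km_logrank(groups, pd.Series([1.0, 2, 3]), pd.Series([1, 1, 1]))


class TestPericentromericSummary:
    def test_boundary_bin_included_and_direction(self, dmr_cohort):
        from cfmedip.quantify import filter_nonlow, rpkm

        mat = filter_nonlow(rpkm(dmr_cohort.matrix))
        dmrs = call_dmrs(nb_wald_test(mat, dmr_cohort.sheet))
        out = pericentromeric_summary(
            dmrs, mat.rpkm, dmr_cohort.sheet, dmr_cohort.genome,
            flank=50_000, direction="hypo",
        )
        if len(out):
            assert out.loc["metastatic", "mean_signal"] < out.loc["localized", "mean_signal"]

    def test_no_centromere_annotation_rejected(self):
        from cfmedip.genome import GenomeModel

        genome = GenomeModel([("chr1", 1000)])
        dmrs = DMRTable(pd.DataFrame(
            {"direction": ["hyper"], "log2fc": [2.0], "q": [0.01]}, index=["chr1:0-300"]
        ))
        rp = pd.DataFrame({"s": [1.0]}, index=["chr1:0-300"])
        sheet = _two_class_sheet(3)
        with pytest.raises(ValueError, match="centromere"):
            pericentromeric_summary(dmrs, rp, sheet, genome)

    def test_no_differential_bins_is_empty_not_error(self, toy_genome):
        dmrs = DMRTable(pd.DataFrame(
            {"direction": ["ns"], "log2fc": [0.1], "q": [0.9]}, index=["chr1:0-300"]
        ))
        rp = pd.DataFrame({"s": [1.0]}, index=["chr1:0-300"])
        sheet = _two_class_sheet(3)
        out = pericentromeric_summary(dmrs, rp, sheet, toy_genome)
        assert len(out) == 0


class TestRegionScore:
    rp = pd.DataFrame(
        {"s1": [1.0, 5.0], "s2": [2.0, 6.0], "s3": [3.0, 7.0], "s4": [3.0, 8.0]},
        index=["chr1:0-300", "chr1:300-600"],
    )

    def test_single_bin_region_equals_bin_rpkm(self):
        out = region_score(self.rp, ("chr1", 0, 300))
        assert out.loc["s1", "score"] == 1.0

    def test_topk_bottomk_disjoint(self):
        out = region_score(self.rp, ("chr1", 0, 600), k=2)
        assert not (out["top_k"] & out["bottom_k"]).any()
        assert out["top_k"].sum() == 2 and out["bottom_k"].sum() == 2

    def test_tie_breaks_by_sample_id(self):
        out = region_score(self.rp, ("chr1", 0, 300), k=2)
        # s3 and s4 tie at 3.0; the top-2 must resolve deterministically: s3 first
        assert out.loc["s3", "top_k"] and out.loc["s4", "top_k"]
        out2 = region_score(self.rp, ("chr1", 0, 300), k=1)
        assert out2.loc["s3", "top_k"] and not out2.loc["s4", "top_k"]

    def test_off_genome_region_rejected(self):
        with pytest.raises(ValueError):
            region_score(self.rp, ("chr9", 0, 300))
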
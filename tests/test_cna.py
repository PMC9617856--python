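"""Copy-number inference: log ratios, smoothing, HMM, BAF, consensus."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cfmedip.cna import (
    CNACallSet,
    baf_shift,
    cna_coverage,
    compare_to_truth,
    consensus_call,
    hmm_call,
    log_ratio_track,
    multiscale_smooth,
    viterbi,
)


def _wins(n, chrom="chr1", width=1000):
    return [f"{chrom}:{i * width}-{(i + 1) * width}" for i in range(n)]


class TestLogRatio:
    def _windows(self, sample_vals, ref_vals, n_ref=3):
        idx = _wins(len(sample_vals))
        data = {"s": sample_vals}
        for j in range(n_ref):
            data[f"r{j}"] = ref_vals
        return pd.DataFrame(data, index=idx)

    def test_sample_equal_to_reference_gives_zero_track(self):
        w = self._windows([10.0] * 20, [10.0] * 20)
        track = log_ratio_track(w, "s", ["r0", "r1", "r2"])
        assert np.allclose(track, 0.0)

    def test_doubled_window_near_one(self):
        vals = [1000.0] * 20
        vals[10] = 2000.0
        w = self._windows(vals, [1000.0] * 20)
        track = log_ratio_track(w, "s", ["r0", "r1", "r2"], pseudocount=1e-3)
        assert track.iloc[10] == pytest.approx(1.0, abs=0.01)

    def test_reference_minimum_enforced(self):
        w = self._windows([1.0] * 20, [1.0] * 20, n_ref=2)
        with pytest.raises(ValueError, match="reference"):
            log_ratio_track(w, "s", ["r0", "r1"])

    def test_zero_reference_needs_pseudocount(self):
        w = self._windows([1.0] * 20, [0.0] * 20)
        with pytest.raises(ValueError, match="pseudocount"):
            log_ratio_track(w, "s", ["r0", "r1", "r2"], pseudocount=0.0)


def _brute_force_iterated_median(x, width, max_passes=30):
    x = np.asarray(x, dtype=float)
    h = width // 2
    for _ in range(max_passes):
        new = np.array([np.median(x[max(0, i - h): i + h + 1]) for i in range(len(x))])
        if np.array_equal(new, x):
            break
        x = new
    return x


class TestMultiscaleSmooth:
    def test_constant_track_is_fixed_point(self):
        track = pd.Series(0.7, index=_wins(60))
        out = multiscale_smooth(track)
        for sc in (3, 15, 51):
            assert np.allclose(out[sc], 0.7)

    def test_single_spike_removed(self):
        x = np.zeros(60)
        x[30] = 5.0
        out = multiscale_smooth(pd.Series(x, index=_wins(60)), scales=(3,))
        assert np.allclose(out[3], 0.0)

    def test_step_location_preserved_at_fine_scale(self):
        x = np.where(np.arange(30) < 15, 0.0, 1.0) + 0.01 * np.sin(np.arange(30))
        track = pd.Series(x, index=_wins(30))
        mine = multiscale_smooth(track, scales=(3,))[3]
        oracle = _brute_force_iterated_median(x, 3)
        assert np.allclose(mine, oracle)
        assert mine.iloc[14] < 0.5 < mine.iloc[15]

    def test_even_width_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            multiscale_smooth(pd.Series(np.zeros(60), index=_wins(60)), scales=(4,))

    def test_chromosomes_smoothed_independently(self):
        idx = _wins(30, "chr1") + _wins(30, "chr2")
        x = np.concatenate([np.zeros(30), np.ones(30)])
        out = multiscale_smooth(pd.Series(x, index=idx), scales=(15,))[15]
        # a cross-chromosome filter would blur the boundary; per-chromosome keeps it sharp
        assert np.allclose(out.iloc[:30], 0.0) and np.allclose(out.iloc[30:], 1.0)


class TestHmm:
    def test_all_zero_track_all_neutral(self):
        states, info = hmm_call(pd.Series(np.zeros(40), index=_wins(40)))
        assert (states == "neutral").all()

    def test_block_gain_recovered(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([np.zeros(10), np.full(10, 0.8), np.zeros(10)])
        x += rng.normal(0, 0.05, size=30)
        states, info = hmm_call(pd.Series(x, index=_wins(30)))
        assert (states.iloc[10:20] == "gain").all()
        assert (states.iloc[:10] == "neutral").all()
        assert (states.iloc[20:] == "neutral").all()

    def test_sign_flip_swaps_gain_and_loss(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([np.zeros(12), np.full(10, 0.6), np.zeros(12)])
        x += rng.normal(0, 0.04, size=34)
        track = pd.Series(x, index=_wins(34))
        fwd, _ = hmm_call(track)
        rev, _ = hmm_call(-track)
        swap = {"gain": "loss", "loss": "gain", "neutral": "neutral"}
        assert list(rev) == [swap[s] for s in fwd]

    def test_minimum_track_length(self):
        with pytest.raises(ValueError):
            hmm_call(pd.Series(np.zeros(5), index=_wins(5)))

    def test_sub_amplitude_track_flagged_neutral(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([np.zeros(15), np.full(10, 0.05), np.zeros(15)])
        x += rng.normal(0, 0.01, size=40)
        states, info = hmm_call(pd.Series(x, index=_wins(40)))
        assert info["below_min_amplitude"]
        assert (states == "neutral").all()


class TestViterbiOracle:
    def test_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            T = int(rng.integers(3, 9))
            ll = rng.normal(size=(T, 3))
            trans = rng.dirichlet(np.ones(3), size=3)
            start = rng.dirichlet(np.ones(3))
            path = viterbi(ll, np.log(trans), np.log(start))
            best_score, best_path = -np.inf, None
            for cand in itertools.product(range(3), repeat=T):
                score = np.log(start[cand[0]]) + ll[0, cand[0]]
                for t in range(1, T):
                    score += np.log(trans[cand[t - 1], cand[t]]) + ll[t, cand[t]]
                if score > best_score:
                    best_score, best_path = score, cand
            assert tuple(path) == best_path


class TestBafShift:
    def test_all_half_baf_gives_no_calls(self):
        dev = pd.Series(np.zeros(200), index=_wins(200))
        calls = baf_shift(dev, seed=0)
        for sc, flags in calls.items():
            assert not any(bool(f) for f in flags if f is not None)

    def test_too_few_windows_all_no_call(self):
        dev = pd.Series(np.full(30, 0.1), index=_wins(30))
        calls = baf_shift(dev, min_windows=50, seed=0)
        for flags in calls.values():
            assert all(f is None for f in flags)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        dev = np.where(np.arange(200) % 7 < 2, 0.15, 0.04) + rng.normal(0, 0.005, 200)
        track = pd.Series(dev, index=_wins(200))
        a = baf_shift(track, seed=9)
        b = baf_shift(track, seed=9)
        for sc in a:
            assert list(a[sc]) == list(b[sc])

    def test_planted_shift_blocks_flagged(self):
        rng = np.random.default_rng(6)
        dev = np.full(240, 0.04) + rng.normal(0, 0.004, 240)
        dev[60:120] = 0.13 + rng.normal(0, 0.006, 60)
        flags = baf_shift(pd.Series(dev, index=_wins(240)), seed=1)
        fine = np.array([bool(f) for f in flags[3]])
        jaccard = (fine[60:120].sum()) / (fine.sum() + 60 - fine[60:120].sum())
        assert jaccard >= 0.7


class TestConsensus:
    def _inputs(self, n=30, strong=(0.5, 0.2, 0.2), states=("gain", "gain", "neutral"),
                baf=(True, True, True), window=5):
        idx = _wins(n)
        scale_states, smoothed, baf_calls = {}, {}, {}
        for sc, st, ev in zip((3, 15, 51), states, strong):
            s = pd.Series("neutral", index=idx, dtype=object)
            vals = pd.Series(0.0, index=idx)
            if st != "neutral":
                s.iloc[window] = st
                vals.iloc[window] = ev if st == "gain" else -ev
            scale_states[sc] = s
            smoothed[sc] = vals
        for sc, flag in zip((3, 15, 51), baf):
            f = pd.Series(False, index=idx, dtype=object)
            f.iloc[window] = flag
            baf_calls[sc] = f
        return scale_states, smoothed, baf_calls

    def test_six_of_nine_votes_calls(self):
        # two scales gain, no strong evidence, BAF support at all three scales
        ss, sm, bc = self._inputs(strong=(0.2, 0.2, 0.2))
        calls = consensus_call(ss, sm, bc)
        assert calls.states.iloc[5] == "gain"
        assert calls.votes.iloc[5]["gain"] == 6

    def test_five_of_nine_votes_stays_neutral(self):
        # one scale carries strong evidence (3 votes), the other needs BAF
        # support but only two BAF scales provide it -> 3 + 2 = 5
        ss, sm, bc = self._inputs(strong=(0.5, 0.2, 0.2), baf=(True, True, False))
        calls = consensus_call(ss, sm, bc)
        assert calls.votes.iloc[5]["gain"] == 5
        assert calls.states.iloc[5] == "neutral"

    def test_all_scales_neutral_zero_votes(self):
        ss, sm, bc = self._inputs(states=("neutral", "neutral", "neutral"))
        calls = consensus_call(ss, sm, bc)
        assert calls.states.iloc[5] == "neutral"
        assert calls.votes.iloc[5][["loss", "gain"]].sum() == 0

    def test_without_baf_two_of_three_scales_suffice(self):
        ss, sm, _ = self._inputs(strong=(0.5, 0.5, 0.2))
        calls = consensus_call(ss, sm, baf_calls=None)
        assert calls.states.iloc[5] == "gain"
        assert calls.votes.iloc[5]["gain"] == 6


class TestCoverageAndTruth:
    def _calls(self, states):
        idx = _wins(len(states))
        s = pd.Series(states, index=idx, dtype=object)
        votes = pd.DataFrame(0, index=idx, columns=["loss", "neutral", "gain"])
        return CNACallSet(states=s, votes=votes)

    def test_all_neutral_coverage_zero(self):
        calls = {"s": self._calls(["neutral"] * 20)}
        assert cna_coverage(calls)["s"] == 0.0

    def test_ten_percent_gain(self):
        calls = {"s": self._calls(["gain"] * 2 + ["neutral"] * 18)}
        assert cna_coverage(calls)["s"] == pytest.approx(0.10)

    def test_identical_predictions_perfect_confusion(self):
        states = ["gain"] * 3 + ["loss"] * 3 + ["neutral"] * 14
        calls = {"s": self._calls(states)}
        truth = {"s": pd.Series(states, index=_wins(20))}
        conf = compare_to_truth(calls, truth)
        assert np.trace(conf.to_numpy()) == 20
        assert conf.to_numpy().sum() == 20

    def test_all_neutral_predictions_vs_20pct_altered(self):
        truth_states = ["gain"] * 2 + ["loss"] * 2 + ["neutral"] * 16
        calls = {"s": self._calls(["neutral"] * 20)}
        truth = {"s": pd.Series(truth_states, index=_wins(20))}
        conf = compare_to_truth(calls, truth)
        from cfmedip.metrics import macro_average, per_class_metrics

        per = per_class_metrics(conf)
        _, overall, _ = macro_average(per, conf)
        assert overall == pytest.approx(0.8)
        assert per.loc["gain", "sensitivity"] == 0.0

    def test_gene_majority_state(self):
        states = ["gain", "gain", "neutral", "loss"] + ["neutral"] * 16
        calls = {"s": self._calls(states)}
        gene_map = {"G1": _wins(20)[0:3], "G2": [_wins(20)[3]], "G3": ["chrX:0-1000"]}
        truth = {"s": pd.Series({"G1": "gain", "G2": "loss", "G3": "gain"})}
        conf = compare_to_truth(calls, truth, gene_windows=gene_map)
        # G3 has no overlapping window and is excluded
        assert conf.to_numpy().sum() == 2
        assert conf.loc["gain", "gain"] == 1 and conf.loc["loss", "loss"] == 1
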
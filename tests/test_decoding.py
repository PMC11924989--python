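"""Time-resolved LDA: separability, nulls, generalization, condition mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from saccdecode.decoding import (
    DecodeSeries,
    aggregate,
    bin_by_saccade_latency,
    cross_test,
    crossval_same,
    fit_lda_timecourse,
    map_condition,
    predict_timecourse,
    train_stack,
)
from saccdecode.epochs import EpochSet, epoch_times


def _gaussian_epochs(n, p=64, T=8, d=0.0, seed=0, subject="s"):
    """Two-class Gaussian toy epochs with separation d along a fixed axis."""
    rng = np.random.default_rng(seed)
    y = np.tile([0, 1], n // 2)
    u = np.zeros(p)
    u[0] = 1.0
    X = rng.standard_normal((n, p, T))
    X += np.where(y[:, None, None] == 1, d / 2, -d / 2) * u[:, None]
    times = epoch_times()[:T]
    meta = pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "trial_type": "fixation",
            "location_id": 1,
            "fixation_side": "left",
            "sf_class": np.where(y == 1, "high", "low"),
            "stim_to_saccade_ms": np.nan,
            "is_catch": False,
        }
    )
    return EpochSet(data=X, times=times, meta=meta, subject_id=subject)


class TestLDA:
    def test_separable_classes_perfect_training_accuracy(self):
        ep = _gaussian_epochs(40, d=20.0, seed=1)
        y = (ep.meta.sf_class == "high").to_numpy().astype(int)
        w, b = fit_lda_timecourse(ep.data, y)
        pred = predict_timecourse(w, b, ep.data)
        assert (pred == y[:, None]).all()

    def test_shuffled_labels_decode_at_chance(self):
        rng = np.random.default_rng(2)
        ep = _gaussian_epochs(120, d=8.0, seed=2)
        y = (ep.meta.sf_class == "high").to_numpy().astype(int)
        y_shuf = rng.permutation(y)
        w, b = fit_lda_timecourse(ep.data[:80], y_shuf[:80])
        acc = (predict_timecourse(w, b, ep.data[80:]) == y_shuf[80:, None]).mean()
        lo, hi = stats.binom.interval(0.9999, 40 * ep.times.size, 0.5)
        assert lo <= acc * 40 * ep.times.size <= hi

    def test_single_class_errors(self):
        ep = _gaussian_epochs(10, d=1.0)
        with pytest.raises(ValueError):
            fit_lda_timecourse(ep.data, np.zeros(10, int))

    def test_shrinkage_matches_ledoit_wolf_oracle(self):
        """Per-timepoint shrinkage intensity agrees with the standard
        analytic estimator on class-centered data."""
        from sklearn.covariance import LedoitWolf

        from saccdecode.decoding import _ledoit_wolf_shrinkage

        rng = np.random.default_rng(3)
        xc = rng.standard_normal((30, 4, 16))  # (n, T, p)
        S = np.einsum("itp,itq->tpq", xc, xc) / 30
        gamma = _ledoit_wolf_shrinkage(xc, S)
        for t in range(4):
            lw = LedoitWolf(assume_centered=True).fit(xc[:, t, :])
            assert gamma[t] == pytest.approx(lw.shrinkage_, rel=1e-9)

    def test_discriminant_aligns_with_embedded_topography(
        self, demo_epochs, subject_truth
    ):
        stack = train_stack(demo_epochs, 1, "left", seed=0)
        times = demo_epochs.times * 1000
        # window where only the location-specific pattern is active in training
        early = (times > 95) & (times < 140)
        w = stack.weights[early]
        w = w / np.linalg.norm(w, axis=1, keepdims=True)
        assert np.abs(w @ subject_truth.loc_topo[1]).mean() > 0.5
        # later the discriminant spreads over the invariant pattern too
        late = (times > 160) & (times < 400)
        wl = stack.weights[late]
        wl = wl / np.linalg.norm(wl, axis=1, keepdims=True)
        span = np.hypot(
            wl @ subject_truth.loc_topo[1], wl @ subject_truth.inv_topo
        )
        assert span.mean() > 0.5


class TestCrossVal:
    def test_separable_data_reaches_ceiling(self):
        ep = _gaussian_epochs(60, d=20.0, seed=4)
        series = crossval_same(ep, 1, "left", k=5, seed=0)
        assert series.condition == "same"
        assert series.accuracy.min() > 0.95

    def test_pure_noise_stays_at_chance_everywhere(self):
        ep = _gaussian_epochs(200, d=0.0, seed=5)
        series = crossval_same(ep, 1, "left", k=5, seed=0)
        # multiplicity-aware: every timepoint within a Bonferroni binomial band
        n = series.n_test_trials
        alpha = 0.001 / series.times.size
        lo, hi = stats.binom.interval(1 - alpha, n, 0.5)
        assert (series.accuracy * n >= lo).all() and (series.accuracy * n <= hi).all()

    def test_k_exceeding_minority_count_errors(self):
        ep = _gaussian_epochs(8, d=1.0)
        with pytest.raises(ValueError):
            crossval_same(ep, 1, "left", k=5)

    def test_recovery_begins_at_embedded_onset(self, demo_epochs, subject_truth):
        series = crossval_same(demo_epochs, 3, "left", k=5, seed=1)
        times = demo_epochs.times * 1000
        onset = subject_truth.onsets_ms["same"]
        pre = series.accuracy[(times > -150) & (times < onset - 8)]
        post = series.accuracy[(times > onset + 30) & (times < 450)]
        assert pre.mean() < 0.58
        assert post.mean() > 0.7


class TestCrossTest:
    def test_training_set_accuracy_upper_bounds_heldout(self):
        ep = _gaussian_epochs(80, d=2.0, seed=6)
        held = _gaussian_epochs(400, d=2.0, seed=7)
        stack = train_stack(ep, 1, "left", seed=0)
        on_train = cross_test(stack, ep, np.ones(80, bool), "train")
        on_held = cross_test(stack, held, np.ones(400, bool), "held")
        assert on_train.accuracy.mean() >= on_held.accuracy.mean() - 0.02

    def test_sign_flipped_test_patterns_decode_below_chance(self):
        ep = _gaussian_epochs(80, d=3.0, seed=8)
        flipped = _gaussian_epochs(400, d=-3.0, seed=9)
        stack = train_stack(ep, 1, "left", seed=0)
        series = cross_test(stack, flipped, np.ones(400, bool), "flip")
        assert series.accuracy.mean() < 0.4

    def test_empty_selection_errors_with_condition_name(self):
        ep = _gaussian_epochs(20, d=1.0)
        stack = train_stack(ep, 1, "left", seed=0)
        with pytest.raises(ValueError, match="mycond"):
            cross_test(stack, ep, np.zeros(20, bool), "mycond")


class TestConditionMapping:
    def test_congruency_pairs(self, geometry):
        assert map_condition(1, 5, "saccade_peripheral", geometry) == "congruent"
        assert map_condition(1, 6, "saccade_peripheral", geometry) == "incongruent"
        assert map_condition(2, 6, "saccade_peripheral", geometry) == "congruent"
        assert map_condition(3, 7, "saccade_peripheral", geometry) == "congruent"
        assert map_condition(4, 8, "saccade_peripheral", geometry) == "congruent"
        # symmetric when training on the right-side cluster
        assert map_condition(5, 1, "saccade_peripheral", geometry) == "congruent"
        assert map_condition(5, 2, "saccade_peripheral", geometry) == "incongruent"

    def test_fixation_eccentricity_labels(self, geometry):
        assert map_condition(1, 1, "fixation", geometry) == "same"
        assert map_condition(1, 2, "fixation", geometry) == "near"
        assert map_condition(1, 7, "control", geometry) == "mid"
        assert map_condition(1, 5, "control", geometry) == "far"

    def test_unknown_location_errors(self, geometry):
        with pytest.raises(KeyError):
            map_condition(1, 99, "fixation", geometry)


class TestAggregate:
    def _series(self, cond, acc, sid="s0"):
        t = epoch_times()[:4]
        return DecodeSeries(sid, cond, t, np.full(4, acc), 10)

    def test_identity_mean_and_permutation_invariance(self):
        a, b = self._series("x", 0.4), self._series("x", 0.6)
        only = aggregate([a])
        assert np.allclose(only[0].accuracy, 0.4)
        m1 = aggregate([a, b])[0].accuracy
        m2 = aggregate([b, a])[0].accuracy
        assert np.allclose(m1, 0.5) and np.allclose(m1, m2)

    def test_mixed_time_grids_error(self):
        a = self._series("x", 0.5)
        b = DecodeSeries("s0", "x", epoch_times()[2:6], np.full(4, 0.5), 10)
        with pytest.raises(ValueError):
            aggregate([a, b])


class TestLatencyBins:
    def _saccade_epochs(self, latencies, seed=0):
        ep = _gaussian_epochs(len(latencies), d=2.0, seed=seed)
        ep.meta["trial_type"] = "saccade_peripheral"
        ep.meta["stim_to_saccade_ms"] = latencies
        return ep

    def test_single_latency_lands_in_one_bin(self):
        train = _gaussian_epochs(40, d=2.0, seed=10)
        stack = train_stack(train, 1, "left", seed=0)
        ep = self._saccade_epochs(np.full(30, 200.0), seed=11)
        out = bin_by_saccade_latency(stack, ep, np.ones(30, bool))
        assert [s.condition for s in out] == ["latbin_200_300"]
        assert out[0].n_test_trials == 30

    def test_uniform_latencies_fill_bins_evenly(self):
        rng = np.random.default_rng(12)
        lat = rng.uniform(100, 400, 300)
        train = _gaussian_epochs(40, d=2.0, seed=13)
        stack = train_stack(train, 1, "left", seed=0)
        out = bin_by_saccade_latency(stack, self._saccade_epochs(lat, 14), np.ones(300, bool))
        counts = np.array([s.n_test_trials for s in out])
        assert counts.sum() == 300 and len(counts) == 3
        assert stats.chisquare(counts).pvalue > 1e-4
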
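"""Velocity estimation, saccade detection, merge rules, trial exclusion."""

import numpy as np
import pandas as pd
import pytest

from saccdecode.config import desk_scale_config
from saccdecode.eye_events import (
    SaccadeParams,
    compute_velocity,
    detect_saccades,
    exclude_trials,
    merge_events,
)
from saccdecode.gaze import GazeParams, GazeTrace, generate_gaze
from saccdecode.schedule import build_session_schedule


def _trace(x, y=None, rate=1000.0, blink=None):
    x = np.asarray(x, float)
    y = np.zeros_like(x) if y is None else np.asarray(y, float)
    blink = np.zeros(x.size, bool) if blink is None else blink
    return GazeTrace(rate_hz=rate, x=x, y=y, blink=blink)


def _raised_cosine_saccade(n_pre, amp=20.0, dur_s=0.05, rate=1000.0, n_post=300):
    n_sac = int(dur_s * rate)
    prof = amp * 0.5 * (1 - np.cos(np.pi * np.arange(1, n_sac + 1) / n_sac))
    return np.r_[np.zeros(n_pre), prof, np.full(n_post, amp)]


class TestVelocity:
    def test_constant_position_zero_velocity(self):
        v = compute_velocity(_trace(np.full(100, 3.0)))
        assert np.allclose(v[2:-2], 0.0)
        assert np.isnan(v[:2]).all() and np.isnan(v[-2:]).all()

    def test_linear_ramp_exact(self):
        t = np.arange(200) / 1000.0
        v = compute_velocity(_trace(10.0 * t))
        assert np.allclose(v[2:-2, 0], 10.0)

    def test_raised_cosine_peak_matches_analytic(self):
        x = _raised_cosine_saccade(n_pre=100, amp=20.0, dur_s=0.05)
        v = compute_velocity(_trace(x))
        analytic = np.pi * 20.0 / 0.050 / 2.0
        assert np.nanmax(np.abs(v[:, 0])) == pytest.approx(analytic, rel=0.02)

    def test_blink_neighbourhood_is_nan(self):
        blink = np.zeros(100, bool)
        blink[40:50] = True
        x = np.zeros(100)
        x[blink] = np.nan
        v = compute_velocity(_trace(x, blink=blink))
        assert np.isnan(v[38:52, 0]).all()
        assert np.isfinite(v[30, 0])

    def test_too_short_trace_errors(self):
        with pytest.raises(ValueError):
            compute_velocity(_trace(np.zeros(4)))


def _noisy_fixation(n, rng, sd=0.05, tau=0.02, rate=1000.0):
    theta = 1.0 / (tau * rate)
    drift = np.zeros((n, 2))
    eps = rng.standard_normal((n, 2)) * sd * np.sqrt(2 * theta)
    for k in range(1, n):
        drift[k] = drift[k - 1] * (1 - theta) + eps[k]
    return drift


class TestDetection:
    def test_fixation_noise_yields_no_events(self):
        rng = np.random.default_rng(0)
        drift = _noisy_fixation(20_000, rng)
        gaze = _trace(drift[:, 0], drift[:, 1])
        events = detect_saccades(compute_velocity(gaze), gaze)
        assert events == []

    def test_constant_trace_warns_and_returns_empty(self):
        gaze = _trace(np.full(1000, 1.0))
        with pytest.warns(UserWarning):
            assert detect_saccades(compute_velocity(gaze), gaze) == []

    def test_injected_saccade_recovered_within_2ms(self):
        rng = np.random.default_rng(1)
        drift = _noisy_fixation(20_000, rng)
        onset_idx = 10_000
        sac = _raised_cosine_saccade(onset_idx, amp=20.0, n_post=20_000 - onset_idx - 50)
        gaze = _trace(drift[:, 0] + sac, drift[:, 1])
        events = detect_saccades(compute_velocity(gaze), gaze)
        valid = [e for e in events if e.valid]
        assert len(valid) == 1
        assert abs(valid[0].onset_s - onset_idx / 1000.0) <= 0.002
        assert valid[0].amplitude == pytest.approx(20.0, abs=0.5)

    def test_two_bursts_within_50ms_merge_to_first(self):
        rng = np.random.default_rng(2)
        drift = _noisy_fixation(8000, rng)
        x = drift[:, 0].copy()
        first = _raised_cosine_saccade(0, amp=5.0, dur_s=0.02, n_post=0)
        x[3000 : 3000 + first.size] += first
        x[3000 + first.size :] += 5.0
        # second burst 30 ms after the first ends
        second_start = 3000 + first.size + 30
        x[second_start : second_start + first.size] += first
        x[second_start + first.size :] += 5.0
        gaze = _trace(x, drift[:, 1])
        events = detect_saccades(compute_velocity(gaze), gaze)
        assert len(events) == 1
        assert events[0].onset_s == pytest.approx(3.0, abs=0.003)

    def test_raising_threshold_never_adds_events(self):
        rng = np.random.default_rng(3)
        drift = _noisy_fixation(30_000, rng)
        x = drift[:, 0].copy()
        for k, pos in enumerate(range(3000, 27_000, 3000)):
            sac = _raised_cosine_saccade(0, amp=1.0 + k, dur_s=0.04, n_post=0)
            x[pos : pos + sac.size] += sac
            x[pos + sac.size :] += 1.0 + k
        gaze = _trace(x, drift[:, 1])
        v = compute_velocity(gaze)
        counts = [
            len(detect_saccades(v, gaze, SaccadeParams(lambda_threshold=lam)))
            for lam in (5, 6, 8, 10, 14, 20)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_merge_rule_is_idempotent(self):
        rng = np.random.default_rng(4)
        drift = _noisy_fixation(30_000, rng)
        x = drift[:, 0].copy()
        for pos in range(2000, 28_000, 1500):
            sac = _raised_cosine_saccade(0, amp=2.0, dur_s=0.03, n_post=0)
            x[pos : pos + sac.size] += sac
            x[pos + sac.size :] += 2.0
        gaze = _trace(x, drift[:, 1])
        events = detect_saccades(compute_velocity(gaze), gaze)
        once = merge_events(events)
        assert merge_events(once) == once

    def test_all_nan_velocity_errors(self):
        blink = np.ones(1000, bool)
        gaze = _trace(np.full(1000, np.nan), blink=blink)
        with pytest.raises(ValueError):
            detect_saccades(compute_velocity(gaze), gaze)


@pytest.fixture(scope="module")
def session():
    cfg = desk_scale_config(
        seed=31, trials_per_block=64, n_fixation_per_block=32,
        n_saccade_per_block=24, n_control_per_block=8,
    )
    sched = build_session_schedule(cfg)
    return cfg, sched


class TestExclusion:
    def test_clean_trials_kept(self, session):
        cfg, sched = session
        gaze = generate_gaze(sched, cfg, GazeParams(violation_fraction=0.0), seed=1)
        events = detect_saccades(compute_velocity(gaze), gaze)
        report = exclude_trials(sched, gaze, events, cfg.geometry)
        fix = report.merge(sched[["trial_id", "trial_type"]], on="trial_id")
        assert fix[fix.trial_type == "fixation"].kept.all()

    def test_gaze_excursion_during_stimulus_excluded(self, session):
        cfg, sched = session
        gaze = generate_gaze(
            sched, cfg,
            GazeParams(violation_fraction=0.0, landing_noise_sd_dva=0.0,
                       microsaccade_rate_hz=0.0),
            seed=2,
        )
        victim = sched[(sched.trial_type == "fixation")].iloc[0]
        i0 = int(victim.stimulus_onset_s * gaze.rate_hz)
        gaze.y[i0 : i0 + 60] += 3.0  # 3 dva excursion while stimulus is on
        events = detect_saccades(compute_velocity(gaze), gaze)
        report = exclude_trials(sched, gaze, events, cfg.geometry)
        row = report[report.trial_id == victim.trial_id].iloc[0]
        assert not row.kept and row.reason == "gaze_deviation"

    def test_out_of_window_saccade_latencies_excluded(self, session):
        # A 50 ms stimulus-to-saccade latency means the eyes arrive while the
        # grating is still on screen, so the stimulus-visibility rule (which
        # precedes the latency-window rule) claims it; a 450 ms latency is
        # claimed by the 100-400 ms window itself.
        cfg, sched = session
        sched = sched.copy()
        victims = sched[sched.trial_type == "saccade_peripheral"].iloc[:2]
        short, long_ = victims.iloc[0], victims.iloc[1]
        sched.loc[sched.trial_id == short.trial_id, "stimulus_onset_s"] = (
            short.true_saccade_onset_s - 0.050
        )
        sched.loc[sched.trial_id == long_.trial_id, "stimulus_onset_s"] = (
            long_.true_saccade_onset_s - 0.450
        )
        gaze = generate_gaze(sched, cfg, GazeParams(violation_fraction=0.0), seed=3)
        events = detect_saccades(compute_velocity(gaze), gaze)
        report = exclude_trials(sched, gaze, events, cfg.geometry).set_index("trial_id")
        assert report.loc[short.trial_id, "reason"] == "stimulus_visible_at_landing"
        assert report.loc[long_.trial_id, "reason"] == "saccade_latency_out_of_range"

    def test_bad_landing_excluded(self, session):
        cfg, sched = session
        gaze = generate_gaze(
            sched, cfg, GazeParams(violation_fraction=0.0, landing_noise_sd_dva=0.0),
            seed=4,
        )
        victim = sched[sched.trial_type == "saccade_peripheral"].iloc[0]
        t_on = victim.true_saccade_onset_s
        i_land = int((t_on + 0.055) * gaze.rate_hz)
        gaze.y[i_land : i_land + 400] += 3.0  # settle 3 dva off target
        events = detect_saccades(compute_velocity(gaze), gaze)
        report = exclude_trials(sched, gaze, events, cfg.geometry)
        row = report[report.trial_id == victim.trial_id].iloc[0]
        assert not row.kept and row.reason == "bad_landing"

    def test_single_reason_per_trial(self, session):
        cfg, sched = session
        gaze = generate_gaze(sched, cfg, GazeParams(violation_fraction=0.2), seed=5)
        events = detect_saccades(compute_velocity(gaze), gaze)
        report = exclude_trials(sched, gaze, events, cfg.geometry)
        assert (report[report.kept].reason == "none").all()
        assert (report[~report.kept].reason != "none").all()
        assert len(report) == len(sched)
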
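"""Reproducible verification studies: onset recovery, null calibration,
detector recovery, and the Bayes-factor quadrature cross-check.

These are the experiments the package runs on itself: every quantity is
recomputed from scratch by simulating cohorts (or traces) and pushing them
through the full decoding/inference (or detection) machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import run_null_cohort, run_recovery_cohort
from .eye_events import SaccadeParams, compute_velocity, detect_saccades
from .gaze import GazeTrace
from .inference import bf_from_t

FIXATION_ORDER = ("same", "near", "mid", "far")


def recovery_study(n_cohorts: int, seed: int, n_subjects: int = 10) -> dict:
    """Simulate `n_cohorts` cohorts and score onset recovery.

    Returns per-cohort onsets, pooled median absolute onset error, the
    fraction of cohorts preserving the embedded fixation ordering
    (same < near < mid < far), and the fraction reproducing the
    saccade-earlier-than-control contrast.
    """
    rng = np.random.default_rng(seed)
    frames = []
    n_ordered = n_contrast = 0
    for c in range(n_cohorts):
        res = run_recovery_cohort(seed=int(rng.integers(2**31)), n_subjects=n_subjects)
        df = res["onsets"].copy()
        df["cohort"] = c
        frames.append(df)
        g = df.set_index("condition").onset_ms
        fix = [g.get(cond) for cond in FIXATION_ORDER]
        if all(v is not None and not pd.isna(v) for v in fix) and all(
            a < b for a, b in zip(fix, fix[1:])
        ):
            n_ordered += 1
        sac, ctl = g.get("congruent"), g.get("control")
        if pd.notna(sac) and pd.notna(ctl) and sac < ctl:
            n_contrast += 1
    onsets = pd.concat(frames, ignore_index=True)
    defined = onsets.dropna(subset=["onset_ms"])
    return dict(
        onsets=onsets,
        median_abs_error_ms=float(np.median(np.abs(defined.error_ms))),
        per_condition_onset_ms=defined.groupby("condition").onset_ms.median().to_dict(),
        ordering_fraction=n_ordered / n_cohorts,
        contrast_fraction=n_contrast / n_cohorts,
        n_cohorts=n_cohorts,
    )


def null_study(n_cohorts: int, seed: int, n_subjects: int = 10) -> dict:
    """Zero-effect cohorts: how often does the onset rule false-fire?"""
    rng = np.random.default_rng(seed)
    detected = 0
    for _ in range(n_cohorts):
        out = run_null_cohort(seed=int(rng.integers(2**31)), n_subjects=n_subjects)
        detected += out["onset_ms"] is not None
    return dict(n_detected=detected, rate=detected / n_cohorts, n_cohorts=n_cohorts)


def _fixational_noise(n: int, rng: np.random.Generator, sd=0.05, tau=0.02, rate=1000.0):
    from scipy.signal import lfilter

    theta = 1.0 / (tau * rate)
    eps = rng.standard_normal((n, 2)) * sd * np.sqrt(2 * theta)
    eps[0] = 0.0
    return lfilter([1.0], [1.0, -(1.0 - theta)], eps, axis=0)


def detector_study(
    n_saccades: int = 500,
    seed: int = 0,
    amp_range: tuple[float, float] = (1.0, 20.0),
    spacing_s: float = 0.4,
    rate: float = 1000.0,
) -> dict:
    """Inject saccades of known onset/amplitude into fixational noise and
    score detector recovery, plus the false-event rate on saccade-free noise.

    Saccade durations follow a main-sequence-like scaling (20 ms + 1.5 ms per
    dva), so small 1 dva movements are brisk 21 ms events, not slow drifts.
    """
    rng = np.random.default_rng(seed)
    n = int(n_saccades * spacing_s * rate) + 1000
    pos = _fixational_noise(n, rng, rate=rate)
    true_onsets = []
    x = pos[:, 0].copy()
    for k in range(n_saccades):
        i0 = 500 + int(k * spacing_s * rate)
        amp = rng.uniform(*amp_range) * rng.choice([-1.0, 1.0])
        dur = 0.020 + 0.0015 * abs(amp)
        m = int(dur * rate)
        prof = abs(amp) * 0.5 * (1 - np.cos(np.pi * np.arange(1, m + 1) / m))
        x[i0 : i0 + m] += np.sign(amp) * prof
        x[i0 + m :] += amp
        true_onsets.append(i0 / rate)
    gaze = GazeTrace(rate_hz=rate, x=x, y=pos[:, 1], blink=np.zeros(n, bool))
    params = SaccadeParams(valid_amplitude_dva=0.5)  # validate everything >= ~1 dva
    events = detect_saccades(compute_velocity(gaze), gaze, params)

    errors = []
    hits = 0
    det_onsets = np.array([e.onset_s for e in events])
    for t in true_onsets:
        if det_onsets.size == 0:
            break
        j = np.argmin(np.abs(det_onsets - t))
        err = det_onsets[j] - t
        if abs(err) <= 0.010:  # matched within 10 ms
            hits += 1
            errors.append(abs(err))
    errors = np.asarray(errors)

    # false-event rate on saccade-free noise of the same character
    quiet = _fixational_noise(n, np.random.default_rng(seed + 1), rate=rate)
    quiet_gaze = GazeTrace(
        rate_hz=rate, x=quiet[:, 0], y=quiet[:, 1], blink=np.zeros(n, bool)
    )
    false_events = detect_saccades(compute_velocity(quiet_gaze), quiet_gaze, params)
    dur_s = n / rate
    frac_within_2ms = (
        float(np.mean(errors <= 0.002)) * hits / n_saccades if hits else 0.0
    )
    return dict(
        n_injected=n_saccades,
        detection_rate=hits / n_saccades,
        recovery_rate_2ms=frac_within_2ms,
        median_onset_error_ms=float(np.median(errors) * 1000) if hits else np.nan,
        false_events_per_100s=len(false_events) / dur_s * 100.0,
    )


def bf_oracle_study(r: float = 0.707) -> dict:
    """Compare the quadrature JZS Bayes factor with an independent
    noncentral-t x Cauchy-prior numerical-integration oracle over a grid of
    sample sizes and standardized effect sizes."""

    def oracle(t, n):
        nu = n - 1
        delta = np.linspace(-12, 12, 20001)
        like = stats.nct.pdf(t, nu, np.sqrt(n) * delta)
        prior = stats.cauchy.pdf(delta, 0, r)
        return np.trapezoid(like * prior, delta) / stats.t.pdf(t, nu)

    worst = 0.0
    n_cases = 0
    for n in (5, 10, 20):
        for d in np.linspace(0.0, 3.0, 17):
            t = d * np.sqrt(n)
            a, b = bf_from_t(t, n, r=r), oracle(t, n)
            worst = max(worst, abs(a - b) / b)
            n_cases += 1
    return dict(max_rel_error=worst, n_cases=n_cases)
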
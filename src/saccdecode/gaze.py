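"""Synthetic gaze traces: fixational jitter, microsaccades, cued saccades,
blinks, and deliberately injected fixation/landing violations.

The trace is built to be *detectable* by the velocity-based saccade detector
in `eye_events`: cued saccades follow a raised-cosine position profile whose
peak speed (pi * amplitude / (2 * duration)) towers over fixational noise,
while microsaccades are small (< 1 dva) raised-cosine jumps that stay above
a 5-sigma median-based threshold but below the 15 dva validity criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import SessionConfig
from .schedule import session_duration_s


class SchedulingError(ValueError):
    """Raised when commanded gaze events overlap in time."""


@dataclass
class GazeParams:
    """Knobs for the gaze synthesizer.

    jitter_sd_dva: stationary SD of the Ornstein-Uhlenbeck fixational drift.
    microsaccade_rate_hz: Poisson rate of small corrective jumps.
    blink_rate_hz: Poisson rate of blinks (NaN spans).
    violation_fraction: fraction of analysis trials given an injected
        exclusion-worthy defect (fixation excursion or bad saccade landing).
    """

    jitter_sd_dva: float = 0.05
    jitter_tau_s: float = 0.02
    microsaccade_rate_hz: float = 0.3
    microsaccade_max_amp_dva: float = 0.8
    microsaccade_duration_s: float = 0.018
    saccade_duration_s: float = 0.050
    landing_noise_sd_dva: float = 0.3
    blink_rate_hz: float = 0.02
    blink_duration_s: float = 0.18
    violation_fraction: float = 0.0


@dataclass
class GazeTrace:
    """Uniformly sampled eye position with blink annotations."""

    rate_hz: float
    x: np.ndarray  # dva, NaN inside blinks
    y: np.ndarray
    blink: np.ndarray  # bool
    injected_violations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["trial_id", "kind"])
    )

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.x.size) / self.rate_hz

    @property
    def n_samples(self) -> int:
        return self.x.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "x_dva": self.x,
                "y_dva": self.y,
                "blink_flag": self.blink.astype(int),
            }
        )


def _raised_cosine_step(n: int) -> np.ndarray:
    """Monotone 0->1 profile over n samples (excluding the starting sample)."""
    u = np.arange(1, n + 1) / n
    return 0.5 * (1.0 - np.cos(np.pi * u))


def generate_gaze(
    schedule: pd.DataFrame,
    config: SessionConfig,
    params: GazeParams | None = None,
    seed: int | None = None,
) -> GazeTrace:
    """Synthesize the session's gaze trace at config.gaze_rate_hz.

    The anchor position starts at the left fixation point and executes a
    raised-cosine displacement to the other point at each saccade trial's
    `true_saccade_onset_s`.  On top of the anchor ride OU fixational jitter
    and occasional microsaccadic jumps of the jitter offset (bounded so
    legitimate fixation never strays beyond ~1 dva).  A configurable fraction
    of trials receives an injected violation, recorded in
    `trace.injected_violations` so tests can audit the exclusion stage.
    """
    params = params or GazeParams()
    if schedule.empty:
        raise ValueError("schedule must contain at least one trial")
    rng = np.random.default_rng(config.seed + 1_000_003 if seed is None else seed)
    rate = config.gaze_rate_hz
    dt = 1.0 / rate
    n = int(np.ceil(session_duration_s(schedule, config) * rate)) + 1

    geom = config.geometry
    fix = {s: geom.fixation_point(s) for s in ("left", "right")}

    # ---- violations: choose trials and kinds up front --------------------
    analysis = schedule[~schedule.is_catch]
    viol_rows = []
    if params.violation_fraction > 0 and len(analysis):
        picked = rng.random(len(analysis)) < params.violation_fraction
        for row in analysis[picked].itertuples():
            if row.trial_type == "saccade_peripheral" and rng.random() < 0.5:
                viol_rows.append(dict(trial_id=row.trial_id, kind="bad_landing"))
            else:
                viol_rows.append(dict(trial_id=row.trial_id, kind="gaze_deviation"))
    violations = pd.DataFrame(viol_rows, columns=["trial_id", "kind"])
    bad_landing_ids = set(violations[violations.kind == "bad_landing"].trial_id)
    deviation_ids = set(violations[violations.kind == "gaze_deviation"].trial_id)

    # ---- anchor trajectory: fixation point + cued saccades ----------------
    anchor = np.tile(fix["left"], (n, 1))
    side = "left"
    n_sac = max(1, int(round(params.saccade_duration_s * rate)))
    prev_end = -1
    sac_trials = schedule[schedule.trial_type.str.startswith("saccade")]
    for row in sac_trials.itertuples():
        i0 = int(round(row.true_saccade_onset_s * rate))
        if i0 <= prev_end:
            raise SchedulingError(
                f"saccade command for trial {row.trial_id} overlaps the previous one"
            )
        new_side = geom.other_side(side)
        target = fix[new_side].copy()
        if row.trial_id in bad_landing_ids:
            target = target + np.array([0.0, 3.2])  # overshoot off target
        elif params.landing_noise_sd_dva > 0:
            target = target + rng.normal(0.0, params.landing_noise_sd_dva, 2)
        start = anchor[i0].copy()
        prof = _raised_cosine_step(n_sac)
        seg_end = min(i0 + n_sac, n)
        seg = prof[: seg_end - i0]
        anchor[i0:seg_end] = start + np.outer(seg, target - start)
        anchor[seg_end:] = target
        # corrective saccade ~250 ms after landing, back onto the point —
        # keeps landing errors from masquerading as fixation violations on
        # later trials (as a real observer's corrective saccade would)
        err = fix[new_side] - target
        if np.linalg.norm(err) > 0.2:
            c0 = min(seg_end + int(0.25 * rate), n - 1)
            m = max(2, int(0.02 * rate))
            c_end = min(c0 + m, n)
            cseg = _raised_cosine_step(m)[: c_end - c0]
            anchor[c0:c_end] = target + np.outer(cseg, err)
            anchor[c_end:] = fix[new_side]
        side = new_side
        prev_end = seg_end

    # ---- fixational jitter (OU) + microsaccadic offset jumps -------------
    x = anchor.copy()
    if params.jitter_sd_dva > 0:
        theta = dt / max(params.jitter_tau_s, dt)
        sig = params.jitter_sd_dva * np.sqrt(2.0 * theta)
        noise = rng.standard_normal((n, 2)) * sig
        noise[0] = 0.0
        a = 1.0 - theta
        drift = lfilter([1.0], [1.0, -a], noise, axis=0)
        x += drift

    if params.microsaccade_rate_hz > 0:
        n_ms = rng.poisson(params.microsaccade_rate_hz * n * dt)
        starts = np.sort(rng.integers(0, max(n - 2 * int(0.02 * rate), 1), n_ms))
        m = max(2, int(round(params.microsaccade_duration_s * rate)))
        offset = np.zeros(2)
        prof = _raised_cosine_step(m)
        for i0 in starts:
            # keep offsets inside a disk so fixation stays legal
            r = rng.uniform(0.1, params.microsaccade_max_amp_dva)
            ang = rng.uniform(0, 2 * np.pi)
            new_offset = np.array([r * np.cos(ang), r * np.sin(ang)]) * 0.5
            delta = new_offset - offset
            seg_end = min(i0 + m, n)
            x[i0:seg_end] += np.outer(prof[: seg_end - i0], delta)
            x[seg_end:] += delta
            offset = new_offset

    # ---- injected fixation violations: out-and-back excursion ------------
    dur = int(0.06 * rate)
    half = _raised_cosine_step(dur // 2)
    bump = np.concatenate([half, half[::-1]])
    for row in schedule[schedule.trial_id.isin(deviation_ids)].itertuples():
        i0 = int(round(row.stimulus_onset_s * rate))
        seg_end = min(i0 + bump.size, n)
        x[i0:seg_end, 1] += 3.2 * bump[: seg_end - i0]

    # ---- blinks -----------------------------------------------------------
    blink = np.zeros(n, bool)
    if params.blink_rate_hz > 0:
        n_b = rng.poisson(params.blink_rate_hz * n * dt)
        b_len = int(round(params.blink_duration_s * rate))
        for i0 in rng.integers(0, max(n - b_len, 1), n_b):
            blink[i0 : i0 + b_len] = True
    xx, yy = x[:, 0].copy(), x[:, 1].copy()
    xx[blink] = np.nan
    yy[blink] = np.nan

    return GazeTrace(rate_hz=rate, x=xx, y=yy, blink=blink, injected_violations=violations)
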
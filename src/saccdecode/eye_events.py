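"""Velocity-based saccade detection and trial exclusion rules.

Detection follows the classic median-velocity-threshold family of
algorithms: eye velocity is estimated with a 5-sample moving-window
differentiator, a robust (median-based) standard deviation is computed per
axis over the whole recording excluding blinks, and samples whose velocity
exceeds an elliptical 5-sigma criterion for at least 15 ms form saccade
events.  Events closer than 50 ms to the previous one are discarded (only
the first is kept, guarding against postsaccadic oscillations).  Events are
flagged valid when their endpoint displacement exceeds an amplitude
threshold (15 dva for cued-saccade validation; microsaccades remain in the
event list for artifact handling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Geometry
from .gaze import GazeTrace


@dataclass
class SaccadeParams:
    lambda_threshold: float = 5.0
    min_duration_s: float = 0.015
    merge_gap_s: float = 0.050
    valid_amplitude_dva: float = 15.0


@dataclass
class SaccadeEvent:
    onset_s: float
    offset_s: float
    peak_velocity: float  # dva/s
    amplitude: float  # endpoint displacement, dva
    valid: bool


def compute_velocity(gaze: GazeTrace) -> np.ndarray:
    """5-sample moving-window velocity, (n, 2) in dva/s.

    v_n = (p_{n+2} + p_{n+1} - p_{n-1} - p_{n-2}) / (6 * dt) per axis.
    The two edge samples on each side, blink samples, and samples within two
    samples of a blink are NaN.
    """
    n = gaze.n_samples
    if n < 5:
        raise ValueError("gaze trace must contain at least 5 samples")
    dt = 1.0 / gaze.rate_hz
    pos = np.column_stack([gaze.x, gaze.y])
    v = np.full((n, 2), np.nan)
    v[2:-2] = (pos[4:] + pos[3:-1] - pos[1:-3] - pos[:-4]) / (6.0 * dt)
    near_blink = gaze.blink.copy()
    for k in (1, 2):
        near_blink[k:] |= gaze.blink[:-k]
        near_blink[:-k] |= gaze.blink[k:]
    v[near_blink] = np.nan
    return v


def _median_sd(v: np.ndarray) -> float:
    """Median-based robust standard deviation: sqrt(med(v^2) - med(v)^2)."""
    v = v[np.isfinite(v)]
    return float(np.sqrt(max(np.median(v**2) - np.median(v) ** 2, 0.0)))


def detect_saccades(
    velocity: np.ndarray,
    gaze: GazeTrace,
    params: SaccadeParams | None = None,
) -> list[SaccadeEvent]:
    """Detect saccades from a velocity trace.

    The threshold ellipse is estimated from all finite velocity samples
    (blinks were already NaN'ed out by `compute_velocity`).  Onset is the
    first suprathreshold sample, offset one sample step past the last, so
    duration equals the suprathreshold sample count times dt.
    """
    params = params or SaccadeParams()
    if not np.isfinite(velocity).any():
        raise ValueError("velocity trace is all-NaN")
    dt = 1.0 / gaze.rate_hz
    sx = _median_sd(velocity[:, 0])
    sy = _median_sd(velocity[:, 1])
    if sx == 0.0 or sy == 0.0:
        warnings.warn("degenerate (constant) gaze trace: no saccades detectable")
        return []
    lam = params.lambda_threshold
    with np.errstate(invalid="ignore"):
        crit = (velocity[:, 0] / (lam * sx)) ** 2 + (velocity[:, 1] / (lam * sy)) ** 2
    above = crit > 1.0
    above &= np.isfinite(crit)

    # contiguous runs of suprathreshold samples
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]

    min_n = int(np.ceil(params.min_duration_s * gaze.rate_hz))
    pos = np.column_stack([gaze.x, gaze.y])
    speed = np.hypot(velocity[:, 0], velocity[:, 1])
    events: list[SaccadeEvent] = []
    for s, e in zip(starts, ends):
        if e - s < min_n:
            continue
        onset_s = s * dt
        if events and onset_s - events[-1].offset_s < params.merge_gap_s:
            continue  # keep the first event of a <50 ms pair
        amp = float(np.linalg.norm(pos[e - 1] - pos[s]))
        events.append(
            SaccadeEvent(
                onset_s=onset_s,
                offset_s=e * dt,
                peak_velocity=float(np.nanmax(speed[s:e])),
                amplitude=amp,
                valid=amp > params.valid_amplitude_dva,
            )
        )
    return events


def merge_events(events: list[SaccadeEvent], merge_gap_s: float = 0.050) -> list[SaccadeEvent]:
    """Apply the keep-the-first merge rule to an event list (idempotent)."""
    kept: list[SaccadeEvent] = []
    for ev in sorted(events, key=lambda e: e.onset_s):
        if kept and ev.onset_s - kept[-1].offset_s < merge_gap_s:
            continue
        kept.append(ev)
    return kept


def events_frame(events: list[SaccadeEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                onset_s=e.onset_s,
                offset_s=e.offset_s,
                peak_vel=e.peak_velocity,
                amplitude=e.amplitude,
                valid=e.valid,
            )
            for e in events
        ],
        columns=["onset_s", "offset_s", "peak_vel", "amplitude", "valid"],
    )


# ---------------------------------------------------------------------------
# trial exclusion
# ---------------------------------------------------------------------------

EXCLUSION_REASONS = (
    "none",
    "gaze_deviation",
    "no_saccade",
    "bad_landing",
    "stimulus_visible_at_landing",
    "saccade_latency_out_of_range",
)


def exclude_trials(
    schedule: pd.DataFrame,
    gaze: GazeTrace,
    events: list[SaccadeEvent],
    geometry: Geometry,
    stimulus_duration_s: float = 0.1,
    deviation_dva: float = 2.5,
    landing_dva: float = 2.5,
    latency_range_s: tuple[float, float] = (0.1, 0.4),
) -> pd.DataFrame:
    """Apply the trial-exclusion rules; one reason per excluded trial.

    Rules, in fixed order (first failing rule wins):
      1. gaze deviated > 2.5 dva from the current fixation point while the
         stimulus was on screen (for saccade trials, only up to saccade
         onset — the commanded saccade itself is not a fixation violation);
      2. saccade trials: no valid cued saccade found after the cue;
      3. saccade trials: saccade landed > 2.5 dva from the target;
      4. saccade trials: eyes arrived before the stimulus left the screen;
      5. saccade trials: stimulus-to-saccade latency outside [100, 400] ms.

    Returns a DataFrame (trial_id, kept, reason).
    """
    rate = gaze.rate_hz
    n = gaze.n_samples
    valid_events = [e for e in events if e.valid]
    rows = []
    for row in schedule.itertuples():
        i_stim = int(round(row.stimulus_onset_s * rate))
        i_off = int(round((row.stimulus_onset_s + stimulus_duration_s) * rate))
        if i_stim < 0 or i_off >= n:
            raise ValueError(f"trial {row.trial_id} window outside the gaze span")
        reason = "none"
        fix = geometry.fixation_point(row.fixation_side)

        is_sacc = row.trial_type.startswith("saccade")
        cued = None
        if is_sacc:
            cands = [
                e
                for e in valid_events
                if row.cue_onset_s <= e.onset_s <= row.cue_onset_s + 2.0
            ]
            cued = cands[0] if cands else None

        # 1. fixation must hold while the stimulus is visible
        dev_end = i_off
        if is_sacc and cued is not None:
            dev_end = min(dev_end, int(round(cued.onset_s * rate)))
        seg = np.column_stack([gaze.x[i_stim:dev_end], gaze.y[i_stim:dev_end]])
        if seg.size:
            dist = np.linalg.norm(seg - fix, axis=1)
            if np.nanmax(dist, initial=0.0) > deviation_dva:
                reason = "gaze_deviation"

        if reason == "none" and is_sacc:
            target = geometry.fixation_point(geometry.other_side(row.fixation_side))
            if cued is None:
                reason = "no_saccade"
            else:
                i_land = min(int(round(cued.offset_s * rate)) + 5, n - 1)
                landing = np.array([gaze.x[i_land], gaze.y[i_land]])
                latency = cued.onset_s - row.stimulus_onset_s
                if np.isfinite(landing).all() and np.linalg.norm(landing - target) > landing_dva:
                    reason = "bad_landing"
                elif cued.offset_s < row.stimulus_onset_s + stimulus_duration_s:
                    reason = "stimulus_visible_at_landing"
                elif not (latency_range_s[0] <= latency <= latency_range_s[1]):
                    reason = "saccade_latency_out_of_range"

        rows.append(dict(trial_id=row.trial_id, kept=reason == "none", reason=reason))
    return pd.DataFrame(rows)
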
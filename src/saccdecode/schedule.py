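"""Trial scheduling: compose a session's trial table with timing and labels.

The schedule is the single source of truth downstream: the gaze and EEG
generators read stimulus/cue/saccade times from it, the preprocessing stage
epochs around its stimulus onsets, and the decoding stage groups trials by
its type/location/SF columns.

Scheduling proceeds in four deterministic passes under one seed:

1. interleave the per-block trial-type pools (fixation, saccade split evenly
   into central/peripheral, control) in random order and overlay catch flags
   every U[11, 20] trials;
2. walk the sequence tracking which fixation point is currently fixated —
   every saccade trial flips the side for subsequent trials;
3. within each (block, type, side) group, assign stimulus locations and SF
   classes from a balanced, shuffled deck so each (type, location, SF) cell
   is filled to within +/-1;
4. lay down the session clock: stimulus onsets for fixation/control trials,
   cue onset -> saccade onset -> back-computed stimulus onset for saccade
   trials (stimulus-to-saccade latency from a truncated normal on
   [100, 400] ms).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigurationError, InfeasibilityError, SessionConfig

TRIAL_COLUMNS = [
    "trial_id",
    "block",
    "trial_type",
    "is_catch",
    "fixation_side",
    "location_id",
    "sf_class",
    "stimulus_onset_s",
    "cue_onset_s",
    "true_saccade_onset_s",
    "stim_to_saccade_ms",
]

ANALYSIS_TYPES = ("fixation", "saccade_central", "saccade_peripheral", "control")


def _balanced_deck(n: int, slots: list[tuple[int, str]], rng: np.random.Generator):
    """n draws from `slots` (location-slot x sf combinations), each combination
    repeated floor(n/len) or +1 times, in shuffled order."""
    reps, rem = divmod(n, len(slots))
    deck = slots * reps + [slots[i] for i in rng.permutation(len(slots))[:rem]]
    order = rng.permutation(n)
    return [deck[i] for i in order]


def build_session_schedule(config: SessionConfig) -> pd.DataFrame:
    """Build the full session trial table.

    Returns a DataFrame with one row per trial (see TRIAL_COLUMNS).  Catch
    trials are scheduled trials flagged `is_catch`; they retain their type,
    location and timing but are excluded from analysis downstream.
    """
    rng = np.random.default_rng(config.seed)
    geom = config.geometry

    n_sc = config.n_saccade_per_block // 2
    n_sp = config.n_saccade_per_block - n_sc

    rows: list[dict] = []
    side = "left"
    trial_id = 0
    next_catch = int(rng.integers(config.catch_interval[0], config.catch_interval[1] + 1))
    t_cursor = 0.0

    for block in range(config.n_blocks):
        pool = (
            ["fixation"] * config.n_fixation_per_block
            + ["saccade_central"] * n_sc
            + ["saccade_peripheral"] * n_sp
            + ["control"] * config.n_control_per_block
        )
        types = [pool[i] for i in rng.permutation(len(pool))]
        for ttype in types:
            is_catch = trial_id + 1 == next_catch
            if is_catch:
                next_catch += int(
                    rng.integers(config.catch_interval[0], config.catch_interval[1] + 1)
                )
            rows.append(
                dict(
                    trial_id=trial_id,
                    block=block,
                    trial_type=ttype,
                    is_catch=is_catch,
                    fixation_side=side,
                )
            )
            if ttype.startswith("saccade"):
                side = geom.other_side(side)
            trial_id += 1

    df = pd.DataFrame(rows)

    # -- location / SF assignment, balanced within (block, type, side) -----
    df["location_id"] = -1
    df["sf_class"] = ""
    for (block, ttype, side_), idx in df.groupby(
        ["block", "trial_type", "fixation_side"], sort=True
    ).groups.items():
        if ttype in ("fixation", "saccade_central"):
            cluster = geom.cluster(side_)
        else:  # control and saccade_peripheral stimuli sit in the other cluster
            cluster = geom.cluster(geom.other_side(side_))
        slots = [(loc, sf) for loc in cluster for sf in ("low", "high")]
        deck = _balanced_deck(len(idx), slots, rng)
        df.loc[idx, "location_id"] = [d[0] for d in deck]
        df.loc[idx, "sf_class"] = [d[1] for d in deck]

    if config.min_trials_per_cell > 0:
        analysis = df[~df.is_catch]
        for ttype in ANALYSIS_TYPES:
            sub = analysis[analysis.trial_type == ttype]
            if sub.empty:
                continue
            counts = sub.groupby(["location_id", "sf_class"]).size()
            if len(counts) == 0 or counts.min() < config.min_trials_per_cell:
                raise InfeasibilityError(
                    f"trial type {ttype!r} has a (location, SF) cell below "
                    f"{config.min_trials_per_cell} trials"
                )

    # -- session clock ------------------------------------------------------
    stim = np.full(len(df), np.nan)
    cue = np.full(len(df), np.nan)
    sacc = np.full(len(df), np.nan)
    lat_ms = np.full(len(df), np.nan)

    lo, hi = config.stim_to_saccade_range_ms
    mu, sd = config.stim_to_saccade_mean_ms, config.stim_to_saccade_sd_ms
    tn = stats.truncnorm((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd)

    for i, row in enumerate(df.itertuples()):
        if row.trial_type.startswith("saccade"):
            t_len = config.trial_len_saccade_s
            c = t_cursor + rng.uniform(*config.cue_delay_range_s)
            s_on = c + rng.uniform(*config.cue_to_saccade_range_s)
            lat = float(tn.rvs(random_state=rng))
            cue[i], sacc[i], lat_ms[i] = c, s_on, lat
            stim[i] = s_on - lat / 1000.0
        else:
            t_len = config.trial_len_fixation_s
            stim[i] = t_cursor + rng.uniform(*config.stim_delay_range_s)
        t_cursor += t_len

    df["stimulus_onset_s"] = stim
    df["cue_onset_s"] = cue
    df["true_saccade_onset_s"] = sacc
    df["stim_to_saccade_ms"] = lat_ms
    df.attrs["session_duration_s"] = float(t_cursor)
    return df[TRIAL_COLUMNS + []].copy()


def session_duration_s(schedule: pd.DataFrame, config: SessionConfig) -> float:
    """Total span of the session clock implied by a schedule."""
    if "session_duration_s" in schedule.attrs:
        return float(schedule.attrs["session_duration_s"])
    per_trial = np.where(
        schedule.trial_type.str.startswith("saccade"),
        config.trial_len_saccade_s,
        config.trial_len_fixation_s,
    )
    return float(per_trial.sum())
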
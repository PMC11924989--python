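"""Multi-subject synthetic cohorts: simulate, decode, infer, and compare
recovered onsets to the embedded ground truth.

This is the desk-scale engine behind the recovery and null-calibration
studies: subjects are independent seeds sharing cohort-level base
topographies, epochs are synthesized directly by the generator's signal
model, each subject is decoded into per-condition accuracy time courses, and
the cohort-level Bayes-factor onset of every condition is compared against
the latency that was embedded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import Geometry, SessionConfig, desk_scale_config
from .decoding import (
    DecodeSeries,
    aggregate,
    bin_by_saccade_latency,
    cross_test,
    crossval_same,
    map_condition,
    train_stack,
)
from .eeg import GroundTruthConfig, draw_cohort_base_topo, draw_subject_truth, generate_epochs
from .epochs import EpochSet
from .inference import bf_timecourse, detect_onset, jackknife_onset_ci
from .schedule import build_session_schedule

LATENCY_WINDOW_MS = (100.0, 400.0)


def simulate_subject_epochs(
    config: SessionConfig,
    truth_config: GroundTruthConfig,
    base_topo: np.ndarray,
    subject_idx: int,
    seed: int,
) -> EpochSet:
    """One subject's cleaned epochs under the cohort's shared ground truth."""
    rng = np.random.default_rng(seed)
    sched_seed, truth_seed, eeg_seed = rng.integers(2**31, size=3)
    cfg = config.with_(seed=int(sched_seed))
    schedule = build_session_schedule(cfg)
    truth = draw_subject_truth(
        truth_config,
        locations=sorted(cfg.geometry.locations),
        subject_rng=np.random.default_rng(int(truth_seed)),
        base_topo=base_topo,
    )
    return generate_epochs(
        schedule, truth, cfg, subject_id=f"s{subject_idx:02d}", seed=int(eeg_seed)
    )


def decode_subject(
    epochs: EpochSet,
    geometry: Geometry,
    seed: int = 0,
    k: int = 5,
    include_latency_bins: bool = False,
) -> list[DecodeSeries]:
    """All decoding schemes for one subject, aggregated per condition.

    Conditions produced (when their cells are populated): same, near, mid,
    far (fixation/control cross-location), congruent / incongruent
    (peripheral saccade trials within the 100-400 ms latency window),
    control (control trials at the retinotopically congruent location — the
    no-saccade contrast for the congruent condition), and optional
    saccade-latency bins.
    """
    meta = epochs.meta
    rng = np.random.default_rng(seed)
    series: list[DecodeSeries] = []
    lat = meta.stim_to_saccade_ms.to_numpy()
    in_window = (lat >= LATENCY_WINDOW_MS[0]) & (lat <= LATENCY_WINDOW_MS[1])

    for side in ("left", "right"):
        cluster = geometry.cluster(side)
        other_cluster = geometry.cluster(geometry.other_side(side))
        for loc in cluster:
            fix_mask = (
                (meta.trial_type == "fixation")
                & (meta.location_id == loc)
                & (meta.fixation_side == side)
            ).to_numpy()
            y = (meta.sf_class[fix_mask] == "high").to_numpy()
            n_min = min(y.sum(), (~y).sum()) if fix_mask.any() else 0
            if n_min < 2:
                continue  # cell too thin to train at all
            if n_min >= k:
                series.append(
                    crossval_same(epochs, loc, side, k=k, seed=int(rng.integers(2**31)))
                )
            stack = train_stack(epochs, loc, side, seed=int(rng.integers(2**31)))

            # cross-location: fixation trials at the other own-cluster locations
            for loc2 in cluster:
                if loc2 == loc:
                    continue
                cond = map_condition(loc, loc2, "fixation", geometry, side)
                mask = (
                    (meta.trial_type == "fixation")
                    & (meta.location_id == loc2)
                    & (meta.fixation_side == side)
                ).to_numpy()
                if mask.any():
                    series.append(cross_test(stack, epochs, mask, cond))

            # cross-location: control trials in the opposite cluster
            cong = geometry.congruent_location(loc)
            for loc2 in other_cluster:
                mask = (
                    (meta.trial_type == "control")
                    & (meta.location_id == loc2)
                    & (meta.fixation_side == side)
                ).to_numpy()
                if not mask.any():
                    continue
                cond = map_condition(loc, loc2, "control", geometry, side)
                series.append(cross_test(stack, epochs, mask, cond))
                if loc2 == cong:
                    series.append(cross_test(stack, epochs, mask, "control"))

            # peripheral saccade trials: congruent / incongruent pairs
            sacc_base = (
                (meta.trial_type == "saccade_peripheral").to_numpy()
                & (meta.fixation_side == side).to_numpy()
                & in_window
            )
            incong = geometry.incongruent_location(loc)
            for loc2, cond in ((cong, "congruent"), (incong, "incongruent")):
                mask = sacc_base & (meta.location_id == loc2).to_numpy()
                if mask.any():
                    series.append(cross_test(stack, epochs, mask, cond))

            if include_latency_bins and sacc_base.any():
                series.extend(bin_by_saccade_latency(stack, epochs, sacc_base))

    return aggregate(series, subject_id=epochs.subject_id)


def decode_cohort(
    epoch_sets: list[EpochSet],
    geometry: Geometry,
    seed: int = 0,
    include_latency_bins: bool = False,
) -> dict[str, list[DecodeSeries]]:
    """Decode every subject; returns condition -> per-subject series."""
    rng = np.random.default_rng(seed)
    by_cond: dict[str, list[DecodeSeries]] = {}
    for ep in epoch_sets:
        for s in decode_subject(
            ep,
            geometry,
            seed=int(rng.integers(2**31)),
            include_latency_bins=include_latency_bins,
        ):
            by_cond.setdefault(s.condition, []).append(s)
    return by_cond


def infer_onsets(
    cond_series: dict[str, list[DecodeSeries]],
    null_value: float = 0.5,
    jackknife: bool = False,
) -> pd.DataFrame:
    """Cohort-level BF onset (and optionally its jackknife CI) per condition."""
    rows = []
    for cond, series in sorted(cond_series.items()):
        if len(series) < 2:
            continue
        onset = detect_onset(bf_timecourse(series, null_value))
        row = dict(condition=cond, onset_ms=onset, n_subjects=len(series))
        if jackknife and len(series) >= 4:
            est = jackknife_onset_ci(series, null_value)
            row.update(
                ci_low_ms=est.ci_low_ms,
                ci_high_ms=est.ci_high_ms,
                n_permutations=est.n_permutations,
                n_absent=est.n_absent,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def expected_onsets(truth_config: GroundTruthConfig, geometry: Geometry) -> dict[str, float]:
    """Embedded latency each recovered condition should approach.

    Cross-decoding can only use components present in both training and test
    trials, so the expected latency is the max of the training-side
    availability (the 'near' invariant onset) and the test trial's embedded
    onset — e.g. the saccade conditions cannot be recovered earlier than the
    training trials carry the invariant pattern.
    """
    fx = truth_config.fixation_onsets()
    train_avail = fx["near"]
    # the aggregated control condition mixes congruent partners at different
    # eccentricities; the group-level onset is the earliest embedded latency
    # among the aggregated pairs
    control_onset = min(
        fx[geometry.ecc_label(geometry.congruent_location(loc), "left")]
        for loc in geometry.cluster("left")
    )
    return {
        "same": fx["same"],
        "near": fx["near"],
        "mid": max(fx["mid"], train_avail),
        "far": max(fx["far"], train_avail),
        "congruent": max(truth_config.onset_saccade_ms, train_avail),
        "incongruent": max(truth_config.onset_saccade_ms, train_avail),
        "control": max(control_onset, train_avail),
    }


def run_recovery_cohort(
    seed: int,
    n_subjects: int = 10,
    truth_config: GroundTruthConfig | None = None,
    session_config: SessionConfig | None = None,
    jackknife: bool = False,
    include_latency_bins: bool = False,
) -> dict:
    """Simulate + decode + infer one cohort; report recovery vs ground truth."""
    truth_config = truth_config or GroundTruthConfig()
    config = session_config or desk_scale_config()
    rng = np.random.default_rng(seed)
    base_topo = draw_cohort_base_topo(
        len(config.geometry.locations), int(rng.integers(2**31))
    )
    epoch_sets = [
        simulate_subject_epochs(config, truth_config, base_topo, i, int(rng.integers(2**31)))
        for i in range(n_subjects)
    ]
    cond_series = decode_cohort(
        epoch_sets,
        config.geometry,
        seed=int(rng.integers(2**31)),
        include_latency_bins=include_latency_bins,
    )
    onsets = infer_onsets(cond_series, jackknife=jackknife)
    expected = expected_onsets(truth_config, config.geometry)
    onsets["embedded_ms"] = onsets.condition.map(expected)
    onsets["error_ms"] = onsets.onset_ms - onsets.embedded_ms
    return dict(onsets=onsets, series=cond_series, expected=expected, config=config)


def run_null_cohort(seed: int, n_subjects: int = 10) -> dict:
    """A zero-effect cohort (fixation-only, same-location decoding).

    Used for false-positive calibration: with effect_amplitude = 0 the BF
    time course should produce no detected onset.
    """
    truth_config = GroundTruthConfig(effect_amplitude=0.0)
    config = desk_scale_config(
        trials_per_block=80, n_fixation_per_block=80, n_saccade_per_block=0,
        n_control_per_block=0,
    )
    rng = np.random.default_rng(seed)
    base_topo = draw_cohort_base_topo(
        len(config.geometry.locations), int(rng.integers(2**31))
    )
    epoch_sets = [
        simulate_subject_epochs(config, truth_config, base_topo, i, int(rng.integers(2**31)))
        for i in range(n_subjects)
    ]
    cond_series = decode_cohort(epoch_sets, config.geometry, seed=int(rng.integers(2**31)))
    bf = bf_timecourse(cond_series["same"], null_value=0.5)
    return dict(onset_ms=detect_onset(bf), bf=bf)
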
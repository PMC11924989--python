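#!/usr/bin/env python
"""Simulate one complete synthetic session: trial schedule, gaze, continuous
EEG with embedded ground-truth discriminative signals.

Writes the trial table and ground-truth summary to results/, and the bulky
gaze/EEG containers to scratch/ for the downstream drivers.
"""

from pathlib import Path

import numpy as np

from saccdecode import io as sdio
from saccdecode.config import desk_scale_config
from saccdecode.eeg import (
    GroundTruthConfig,
    draw_cohort_base_topo,
    draw_subject_truth,
    generate_eeg,
)
from saccdecode.gaze import GazeParams, generate_gaze
from saccdecode.schedule import build_session_schedule

SEED = 2026
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    cfg = desk_scale_config(seed=SEED)
    truth_cfg = GroundTruthConfig()
    schedule = build_session_schedule(cfg)
    truth = draw_subject_truth(
        truth_cfg,
        sorted(cfg.geometry.locations),
        np.random.default_rng(SEED + 1),
        draw_cohort_base_topo(8, SEED),
    )
    gaze = generate_gaze(schedule, cfg, GazeParams(violation_fraction=0.08), seed=SEED + 2)
    rec = generate_eeg(schedule, gaze, truth, cfg, seed=SEED + 3)

    schedule.to_csv(RESULTS / "trial_table.csv", index=False)
    sdio.save_gaze(SCRATCH / "gaze.tsv", gaze)
    sdio.save_recording(SCRATCH / "recording.h5", rec)

    onsets = dict(truth.onsets_ms)
    print(f"session: {len(schedule)} trials over {gaze.n_samples / gaze.rate_hz:.0f} s")
    print(f"  trial types: {schedule.trial_type.value_counts().to_dict()}")
    print(f"  catch trials flagged: {int(schedule.is_catch.sum())}")
    print(f"  embedded onsets (ms): {onsets}")
    print(f"  injected gaze violations: {len(gaze.injected_violations)}")
    print(f"wrote {RESULTS/'trial_table.csv'}, gaze/EEG under {SCRATCH}/")


if __name__ == "__main__":
    main()
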
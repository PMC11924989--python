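#!/usr/bin/env python
"""Detect saccades from the simulated gaze trace and apply the trial
exclusion rules (fixation deviation, landing accuracy, stimulus visibility,
saccade-latency window).

Reads the session written by 01_simulate_session.py; writes the event list
and the exclusion summary to results/.
"""

from pathlib import Path

import pandas as pd

from saccdecode import io as sdio
from saccdecode.config import desk_scale_config
from saccdecode.eye_events import (
    compute_velocity,
    detect_saccades,
    events_frame,
    exclude_trials,
)
from saccdecode.pipeline import summarize_exclusions

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main():
    cfg = desk_scale_config()
    schedule = pd.read_csv(RESULTS / "trial_table.csv")
    gaze = sdio.load_gaze(SCRATCH / "gaze.tsv", rate_hz=cfg.gaze_rate_hz)

    velocity = compute_velocity(gaze)
    events = detect_saccades(velocity, gaze)
    report = exclude_trials(schedule, gaze, events, cfg.geometry)
    summary = summarize_exclusions([report], [schedule])

    events_frame(events).to_csv(RESULTS / "saccade_events.csv", index=False)
    report.to_csv(RESULTS / "exclusion_report.csv", index=False)
    summary.to_csv(RESULTS / "exclusion_summary.csv", index=False)

    n_valid = sum(e.valid for e in events)
    n_sac_trials = schedule.trial_type.str.startswith("saccade").sum()
    print(f"detected {len(events)} events, {n_valid} valid (>=15 dva) "
          f"for {n_sac_trials} cued saccade trials")
    print("exclusion fractions per trial type:")
    print(summary[summary.reason == "any"][["trial_type", "n", "total", "fraction"]]
          .to_string(index=False))
    print(f"wrote events/exclusions under {RESULTS}/")


if __name__ == "__main__":
    main()
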
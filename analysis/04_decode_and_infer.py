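#!/usr/bin/env python
"""Decode a 10-subject synthetic cohort and infer onset latencies.

Trains time-resolved shrinkage-LDA classifiers per location on fixation
trials, cross-tests them across eccentricities, congruent/incongruent
saccade trials and control trials, runs the across-subject Bayes-factor time
courses, detects onsets (first run of 3 consecutive BF > 3), and attaches
leave-two-out jackknife confidence intervals.

Writes long-format accuracies and the onset table to results/.
"""

from pathlib import Path

import numpy as np

from saccdecode import io as sdio
from saccdecode.cohort import run_recovery_cohort

SEED = 2027
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    res = run_recovery_cohort(seed=SEED, n_subjects=10, jackknife=True,
                              include_latency_bins=True)
    onsets = res["onsets"]
    sdio.results_frame(res["series"]).to_csv(
        RESULTS / "decoding_accuracy.csv", index=False, float_format="%.5f"
    )
    onsets.to_csv(RESULTS / "onsets.csv", index=False, float_format="%.2f")

    print("recovered decoding onsets (10 synthetic subjects):")
    cols = [c for c in ("condition", "onset_ms", "ci_low_ms", "ci_high_ms",
                        "embedded_ms", "error_ms", "n_absent") if c in onsets]
    print(onsets[cols].to_string(index=False))
    fix = onsets.set_index("condition").onset_ms
    if all(c in fix for c in ("same", "near", "mid", "far")):
        ordered = fix["same"] < fix["near"] < fix["mid"] < fix["far"]
        print(f"fixation eccentricity ordering preserved: {bool(ordered)}")
    if "congruent" in fix.index and "control" in fix.index:
        print(f"saccade vs control onset: {fix['congruent']:.1f} vs "
              f"{fix['control']:.1f} ms (predictive acceleration: "
              f"{fix['control'] - fix['congruent']:.1f} ms)")
    print(f"wrote {RESULTS/'decoding_accuracy.csv'} and {RESULTS/'onsets.csv'}")


if __name__ == "__main__":
    main()
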
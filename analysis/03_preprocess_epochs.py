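#!/usr/bin/env python
"""Preprocess the continuous recording into cleaned epochs: downsample to
256 Hz, rereference to the mastoids, band-pass 0.1-80 Hz with a 50 Hz notch,
drop excluded/catch trials, epoch -200..+500 ms and baseline-correct.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from saccdecode import io as sdio
from saccdecode.epochs import baseline_mask
from saccdecode.preprocess import epoch_and_baseline, filter_eeg, standardize_record

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main():
    schedule = pd.read_csv(RESULTS / "trial_table.csv")
    report = pd.read_csv(RESULTS / "exclusion_report.csv")
    rec = sdio.load_recording(SCRATCH / "recording.h5")

    rec = standardize_record(rec)
    rec = filter_eeg(rec)
    keep = set(report[report.kept].trial_id)
    epochs = epoch_and_baseline(rec, schedule, keep, subject_id="demo")
    sdio.save_epochs(SCRATCH / "epochs.h5", epochs)

    m = baseline_mask(epochs.times)
    resid = np.abs(epochs.data[:, :, m].mean(axis=2)).max()
    print(f"epochs: {epochs.data.shape} (trials x channels x times) at 256 Hz")
    print(f"  kept {epochs.n_trials} of {len(schedule)} scheduled trials "
          f"({int((~report.kept).sum())} excluded, "
          f"{int(schedule.is_catch.sum())} catch)")
    print(f"  max |baseline residual| = {resid:.2e} uV (should be ~0)")
    print(f"wrote {SCRATCH/'epochs.h5'}")


if __name__ == "__main__":
    main()
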
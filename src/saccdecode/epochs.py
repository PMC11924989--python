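"""The EpochSet container: trials x channels x time at 256 Hz.

All decoding operates on this container.  The time grid spans -200..+500 ms
around stimulus onset in steps of 1/256 s and always contains t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EPOCH_RATE_HZ = 256.0
_FIRST_SAMPLE = -51  # ~ -199 ms
_LAST_SAMPLE = 128  # 500 ms
N_CHANNELS = 64


def epoch_times() -> np.ndarray:
    """The canonical epoch time grid in seconds."""
    return np.arange(_FIRST_SAMPLE, _LAST_SAMPLE + 1) / EPOCH_RATE_HZ


def baseline_mask(times: np.ndarray) -> np.ndarray:
    """Samples in the 100 ms pre-stimulus baseline window [-100, 0) ms."""
    return (times >= -0.1) & (times < 0.0)


@dataclass
class EpochSet:
    """Trials x channels x timepoints with aligned trial metadata."""

    data: np.ndarray  # (n_trials, n_channels, n_times), microvolts
    times: np.ndarray  # seconds relative to stimulus onset
    meta: pd.DataFrame  # one row per trial, aligned with data
    subject_id: str = "s00"

    def __post_init__(self):
        if self.data.shape[0] != len(self.meta):
            raise ValueError("meta row count must equal the trials dimension")
        if self.data.shape[2] != self.times.size:
            raise ValueError("times length must equal the timepoints dimension")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return EpochSet(
            data=self.data[idx],
            times=self.times,
            meta=self.meta.iloc[idx].reset_index(drop=True),
            subject_id=self.subject_id,
        )

    def apply_baseline(self) -> "EpochSet":
        """Subtract each trial/channel's mean over the baseline window."""
        m = baseline_mask(self.times)
        base = self.data[:, :, m].mean(axis=2, keepdims=True)
        return EpochSet(self.data - base, self.times, self.meta.copy(), self.subject_id)
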
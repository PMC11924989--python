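"""Continuous EEG -> cleaned, baseline-corrected epochs.

Stages mirror a conventional ERP pipeline: anti-alias downsampling to 256 Hz
with mastoid rereferencing, zero-phase 0.1-80 Hz band-pass plus 50 Hz notch,
an ocular-component rejection criterion driven by eye-movement coregistration
(variance around saccade onsets vs variance during fixation), and epoching
to -200..+500 ms with a -100..0 ms baseline.  All filtering is zero-phase
(forward-backward) so that onset latencies — the pipeline's readout — are
not biased by filter delay.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .eeg import MASTOID_CHANNELS, ContinuousRecording
from .epochs import EPOCH_RATE_HZ, EpochSet, epoch_times

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Band edges and notch for the main pipeline.

    The band-pass is a 4th-order Butterworth applied forward-backward
    (effective 8th order, zero phase); the notch is an IIR notch of quality
    Q at the mains frequency.  Passband edges are -3 dB points of the
    one-pass design.
    """

    band_hz: tuple[float, float] = (0.1, 80.0)
    notch_hz: float = 50.0
    notch_q: float = 35.0


def standardize_record(rec: ContinuousRecording) -> ContinuousRecording:
    """Downsample to 256 Hz (80 Hz-band anti-alias design) and rereference
    to the mastoid average; event sample indices are remapped to the new rate.
    """
    for ch in MASTOID_CHANNELS:
        if ch not in rec.channel_names:
            raise ValueError(f"mastoid channel {ch} missing from the record")
    eeg = rec.eeg
    rate = rec.rate_hz
    if rate != EPOCH_RATE_HZ:
        if rate < EPOCH_RATE_HZ:
            raise ValueError("generator rate below 256 Hz is not supported")
        # FIR low-pass with the passband ending at the analysis band (80 Hz)
        numtaps = 255
        fir = signal.firwin(numtaps, 88.0, fs=rate)
        eeg = signal.filtfilt(fir, [1.0], eeg, axis=1)
        ratio = rate / EPOCH_RATE_HZ
        if abs(ratio - round(ratio)) < 1e-9:
            eeg = eeg[:, :: int(round(ratio))]
        else:
            from fractions import Fraction

            frac = Fraction(EPOCH_RATE_HZ / rate).limit_denominator(1000)
            eeg = signal.resample_poly(eeg, frac.numerator, frac.denominator, axis=1)
    eeg = np.array(eeg, dtype=float, copy=True)

    idx = [rec.channel_names.index(ch) for ch in MASTOID_CHANNELS]
    ref = eeg[idx].mean(axis=0, keepdims=True)
    eeg -= ref

    events = rec.events.copy()
    events["sample_index"] = np.round(
        events["sample_index"].to_numpy() * EPOCH_RATE_HZ / rate
    ).astype(int)
    return ContinuousRecording(
        eeg=eeg, rate_hz=EPOCH_RATE_HZ, events=events, channel_names=list(rec.channel_names)
    )


def filter_eeg(rec: ContinuousRecording, config: FilterConfig | None = None) -> ContinuousRecording:
    """Zero-phase band-pass + mains notch on a standardized record."""
    config = config or FilterConfig()
    lo, hi = config.band_hz
    if rec.rate_hz < 2 * hi:
        raise ValueError(f"rate {rec.rate_hz} Hz cannot support a {hi} Hz band edge")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rec.rate_hz, output="sos")
    eeg = signal.sosfiltfilt(sos, rec.eeg, axis=1)
    b, a = signal.iirnotch(config.notch_hz, config.notch_q, fs=rec.rate_hz)
    eeg = signal.filtfilt(b, a, eeg, axis=1)
    return ContinuousRecording(
        eeg=eeg, rate_hz=rec.rate_hz, events=rec.events.copy(), channel_names=list(rec.channel_names)
    )


def highpass_for_ica(rec: ContinuousRecording, edge_hz: float = 2.0) -> ContinuousRecording:
    """2 Hz high-passed copy used only to fit the component decomposition;
    the resulting unmixing is applied back to the main (0.1 Hz) pipeline."""
    sos = signal.butter(4, edge_hz, btype="highpass", fs=rec.rate_hz, output="sos")
    return ContinuousRecording(
        eeg=signal.sosfiltfilt(sos, rec.eeg, axis=1),
        rate_hz=rec.rate_hz,
        events=rec.events.copy(),
        channel_names=list(rec.channel_names),
    )


def select_ocular_components(
    activations: np.ndarray,
    saccade_onsets_s: np.ndarray,
    fixation_spans_s: list[tuple[float, float]],
    rate_hz: float,
    window_s: tuple[float, float] = (-0.020, 0.010),
    ratio_threshold: float = 1.1,
) -> tuple[list[int], np.ndarray]:
    """Variance-ratio criterion for eye-movement components.

    For each component (row of `activations`), compute the mean variance in
    windows -20..+10 ms around each saccade onset divided by the mean
    variance over fixation spans; components with ratio strictly greater
    than 1.1 are rejected.  Returns (rejected indices, ratio per component).
    """
    saccade_onsets_s = np.asarray(saccade_onsets_s, float)
    if saccade_onsets_s.size == 0:
        warnings.warn("no saccades available; ocular criterion inapplicable")
        return [], np.full(activations.shape[0], np.nan)
    n = activations.shape[1]
    w0, w1 = (int(round(w * rate_hz)) for w in window_s)
    sac_vars = []
    for t in saccade_onsets_s:
        i = int(round(t * rate_hz))
        a, b = max(i + w0, 0), min(i + w1, n)
        if b - a >= 2:
            sac_vars.append(activations[:, a:b].var(axis=1))
    fix_vars = []
    for t0, t1 in fixation_spans_s:
        a, b = max(int(round(t0 * rate_hz)), 0), min(int(round(t1 * rate_hz)), n)
        if b - a >= 2:
            fix_vars.append(activations[:, a:b].var(axis=1))
    if not sac_vars or not fix_vars:
        warnings.warn("insufficient data for the variance-ratio criterion")
        return [], np.full(activations.shape[0], np.nan)
    ratio = np.mean(sac_vars, axis=0) / np.mean(fix_vars, axis=0)
    rejected = [int(i) for i in np.flatnonzero(ratio > ratio_threshold)]
    return rejected, ratio


def fixation_spans_from_events(
    saccade_onsets_s: np.ndarray,
    saccade_offsets_s: np.ndarray,
    total_s: float,
    pad_s: float = 0.05,
) -> list[tuple[float, float]]:
    """Complement of (padded) detected-event spans: the fixation periods.

    All detected events — including microsaccades — are excised, the
    conservative reading of "variance during fixation periods".
    """
    spans = []
    t = 0.0
    for on, off in zip(np.sort(saccade_onsets_s), np.sort(saccade_offsets_s)):
        a = max(on - pad_s, 0.0)
        if a > t:
            spans.append((t, a))
        t = max(t, off + pad_s)
    if total_s > t:
        spans.append((t, total_s))
    return spans


def clean_ocular(
    rec: ContinuousRecording,
    saccade_onsets_s: np.ndarray,
    saccade_offsets_s: np.ndarray,
    unmixing: np.ndarray | None = None,
    n_components: int | None = None,
    random_state: int = 0,
) -> tuple[ContinuousRecording, list[int], np.ndarray]:
    """Remove eye-movement components from a record.

    The decomposition is pluggable: pass an `unmixing` matrix, or FastICA is
    fit on a 2 Hz high-passed copy (the standard two-pipeline trick) and its
    weights applied to this record.  Components failing the variance-ratio
    criterion are zeroed and the record reconstructed.
    """
    if unmixing is None:
        from sklearn.decomposition import FastICA

        hp = highpass_for_ica(rec)
        ica = FastICA(
            n_components=n_components, whiten="unit-variance", random_state=random_state,
            max_iter=500,
        )
        ica.fit(hp.eeg.T)
        unmixing = ica.components_  # components x channels
    mixing = np.linalg.pinv(unmixing)
    acts = unmixing @ rec.eeg
    spans = fixation_spans_from_events(
        saccade_onsets_s, saccade_offsets_s, rec.n_samples / rec.rate_hz
    )
    rejected, ratios = select_ocular_components(
        acts, saccade_onsets_s, spans, rec.rate_hz
    )
    if rejected:
        acts = acts.copy()
        acts[rejected] = 0.0
    eeg = mixing @ acts
    out = ContinuousRecording(
        eeg=eeg, rate_hz=rec.rate_hz, events=rec.events.copy(), channel_names=list(rec.channel_names)
    )
    return out, rejected, ratios


def epoch_and_baseline(
    rec: ContinuousRecording,
    schedule: pd.DataFrame,
    keep_trial_ids: set | None = None,
    subject_id: str = "s00",
) -> EpochSet:
    """Extract -200..+500 ms stimulus-locked epochs and baseline-correct.

    Catch trials are dropped; `keep_trial_ids`, when given, restricts to the
    trials that survived exclusion.  Trials whose window falls off the record
    edge are dropped with a log entry.
    """
    if rec.rate_hz != EPOCH_RATE_HZ:
        raise ValueError("record must be standardized to 256 Hz before epoching")
    times = epoch_times()
    i_rel = np.round(times * EPOCH_RATE_HZ).astype(int)
    ev = rec.events.set_index("trial_id")["sample_index"]

    rows, data = [], []
    for row in schedule.itertuples():
        if row.is_catch:
            continue
        if keep_trial_ids is not None and row.trial_id not in keep_trial_ids:
            continue
        if row.trial_id not in ev.index:
            raise ValueError(f"no event marker for trial {row.trial_id}")
        center = int(ev.loc[row.trial_id])
        lo, hi = center + i_rel[0], center + i_rel[-1]
        if lo < 0 or hi >= rec.n_samples:
            logger.info("trial %d too close to the record edge; dropped", row.trial_id)
            continue
        data.append(rec.eeg[:, lo : hi + 1])
        rows.append(row._asdict())
    if not data:
        raise ValueError("no epochs could be extracted")
    meta = pd.DataFrame(rows).drop(columns=["Index"], errors="ignore").reset_index(drop=True)
    out = EpochSet(data=np.stack(data), times=times, meta=meta, subject_id=subject_id)
    return out.apply_baseline()
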
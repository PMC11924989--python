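"""Synthetic EEG with embedded, ground-truth discriminative structure.

Signal model
------------
Every non-catch trial adds, on top of spatially mixed pink background noise,
a class-signed pattern (+1 for high spatial frequency, -1 for low):

* a *location-specific* topography u(location), switching on 80 ms after
  stimulus onset — this is what same-location decoding reads out;
* a *location-invariant* topography w, shared by all trials of a subject,
  switching on at a latency that depends on the trial:
    - trials near the currently fixated point (own cluster): 145 ms,
    - control/cross trials at mid eccentricity: 205 ms, far: 295 ms,
    - any saccade trial: 140 ms, uniformly across eccentricities —
      the "predictive" acceleration that active vision buys.

Cross-location decoding can only succeed through components present in both
the training and the test trials, so recovered onsets are max(train
availability, test availability): same 80, near 145, mid 205, far 295 ms
under fixation, and ~145 ms on saccade trials regardless of eccentricity.
Topographies are orthonormalized per subject so no condition leaks into
another through chance overlap; subjects differ by topography perturbation,
+/-1 sample onset jitter, and amplitude scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import irfft, next_fast_len, rfft

from .config import SessionConfig
from .epochs import EPOCH_RATE_HZ, N_CHANNELS, EpochSet, epoch_times
from .gaze import GazeTrace

N_SCALP = 62
CHANNEL_NAMES = [f"E{i:02d}" for i in range(1, N_SCALP + 1)] + ["M1", "M2"]
MASTOID_CHANNELS = ("M1", "M2")


class TruthError(ValueError):
    """Raised when the ground truth lacks a condition the schedule needs."""


@dataclass(frozen=True)
class GroundTruthConfig:
    """Cohort-level ground truth: embedded onsets (ms) and amplitudes (uV).

    `effect_amplitude` scales both discriminative components; 0 produces a
    pure-noise cohort for null calibration.  Amplitudes are sized for the
    desk-scale trial counts (tens of trials per cell, not the thousands a
    real session yields), giving single-subject decoding accuracies in the
    0.7-0.9 range so that onset geometry, not raw power, is what the
    pipeline is tested on.
    """

    onset_same_ms: float = 80.0
    onset_near_ms: float = 145.0
    onset_mid_ms: float = 205.0
    onset_far_ms: float = 295.0
    onset_saccade_ms: float = 140.0
    amp_loc_uv: float = 9.0
    amp_inv_uv: float = 9.0
    effect_amplitude: float = 1.0
    ramp_ms: float = 8.0
    noise_rms_uv: float = 10.0
    noise_band_hz: tuple[float, float] = (0.3, 80.0)
    noise_white_fraction: float = 0.5  # broadband (sensor) share of noise power
    subject_topo_jitter: float = 0.15
    subject_amp_jitter: float = 0.15
    subject_onset_jitter_samples: int = 1
    ocular_artifact_uv: float = 0.0  # saccade-locked artifact for ICA tests

    def fixation_onsets(self) -> dict[str, float]:
        return {
            "same": self.onset_same_ms,
            "near": self.onset_near_ms,
            "mid": self.onset_mid_ms,
            "far": self.onset_far_ms,
        }


@dataclass
class SubjectTruth:
    """One subject's realized topographies, amplitudes and onsets."""

    loc_topo: dict[int, np.ndarray]  # location id -> 64-channel unit vector
    inv_topo: np.ndarray
    ocular_topo: np.ndarray
    amp_loc: float
    amp_inv: float
    onsets_ms: dict[str, float]  # same / near / mid / far / saccade
    ramp_ms: float
    config: GroundTruthConfig

    def invariant_onset_ms(self, trial_type: str, ecc_label: str) -> float:
        if trial_type.startswith("saccade"):
            return self.onsets_ms["saccade"]
        # own-cluster (near-eccentricity) trials carry the invariant pattern
        # from the 'near' latency; mid/far control trials later.
        key = "near" if ecc_label == "near" else ecc_label
        if key not in self.onsets_ms:
            raise TruthError(f"no embedded onset for eccentricity {ecc_label!r}")
        return self.onsets_ms[key]


def _orthonormal_rows(mat: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(mat.T)
    # fix sign so the decomposition is deterministic and close to the input
    signs = np.sign(np.einsum("ij,ji->i", mat, q))
    signs[signs == 0] = 1.0
    return (q * signs).T


def draw_subject_truth(
    config: GroundTruthConfig,
    locations: list[int],
    subject_rng: np.random.Generator,
    base_topo: np.ndarray | None = None,
) -> SubjectTruth:
    """Realize one subject's ground truth.

    `base_topo` (n_loc + 1, 64) are cohort-level topographies; each subject
    perturbs and re-orthonormalizes them, emulating anatomical variability.
    Mastoid channels carry no signal so rereferencing leaves it intact.
    """
    n_vec = len(locations) + 2  # per-location + invariant + ocular
    if base_topo is None:
        base_topo = subject_rng.standard_normal((n_vec, N_CHANNELS))
    pert = base_topo + config.subject_topo_jitter * subject_rng.standard_normal(
        base_topo.shape
    )
    pert[:, N_SCALP:] = 0.0  # silent mastoids
    # QR on the scalp block only, then pad back
    q = _orthonormal_rows(pert[:, :N_SCALP])
    topo = np.zeros((n_vec, N_CHANNELS))
    topo[:, :N_SCALP] = q

    jit = 1.0 + config.subject_amp_jitter * subject_rng.uniform(-1.0, 1.0)
    dt_ms = 1000.0 / EPOCH_RATE_HZ
    j = config.subject_onset_jitter_samples
    onsets = dict(config.fixation_onsets(), saccade=config.onset_saccade_ms)
    onsets = {
        k: v + dt_ms * subject_rng.integers(-j, j + 1) if j else v
        for k, v in onsets.items()
    }
    return SubjectTruth(
        loc_topo={loc: topo[i] for i, loc in enumerate(locations)},
        inv_topo=topo[len(locations)],
        ocular_topo=topo[len(locations) + 1],
        amp_loc=config.amp_loc_uv * config.effect_amplitude * jit,
        amp_inv=config.amp_inv_uv * config.effect_amplitude * jit,
        onsets_ms=dict(onsets),
        ramp_ms=config.ramp_ms,
        config=config,
    )


def draw_cohort_base_topo(n_locations: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_locations + 2, N_CHANNELS))


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------


def pink_noise(
    n_channels: int,
    n_samples: int,
    rate_hz: float,
    rng: np.random.Generator,
    band_hz: tuple[float, float] = (0.3, 80.0),
    rms: float = 1.0,
    mixing: np.ndarray | None = None,
    white_fraction: float = 0.5,
) -> np.ndarray:
    """Spatially mixed pink + broadband noise, band-limited, `rms` channel RMS.

    White noise is shaped in the frequency domain with a power profile
    (1 - white_fraction)/f + white_fraction (the 1/f physiological background
    plus a flat sensor-noise floor) between the band edges, then mixed across
    channels with a random diagonal-dominant matrix to give realistic
    inter-channel correlation.
    """
    n_fft = next_fast_len(n_samples)
    freqs = np.fft.rfftfreq(n_fft, 1.0 / rate_hz)
    lo, hi = band_hz
    in_band = (freqs > 0) & (freqs <= hi)
    pink_power = 1.0 / np.maximum(freqs, lo)
    pink_power /= np.mean(pink_power[in_band]) if in_band.any() else 1.0
    gain = np.sqrt((1.0 - white_fraction) * pink_power + white_fraction)
    gain[~in_band] = 0.0
    spec = rfft(rng.standard_normal((n_channels, n_fft)), axis=1)
    x = irfft(spec * gain, n=n_fft, axis=1)[:, :n_samples]
    if mixing is None:
        mixing = 0.6 * np.eye(n_channels) + rng.standard_normal(
            (n_channels, n_channels)
        ) * (0.8 / np.sqrt(n_channels))
    x = mixing @ x
    x *= rms / np.maximum(x.std(axis=1, keepdims=True), 1e-12)
    return x


# ---------------------------------------------------------------------------
# envelopes and signal insertion
# ---------------------------------------------------------------------------


def _envelope(t_s: np.ndarray, onset_s: float, ramp_s: float, end_s: float) -> np.ndarray:
    """0 before onset, raised-cosine ramp to 1, sustained until `end_s`."""
    env = np.zeros_like(t_s)
    rising = (t_s >= onset_s) & (t_s < onset_s + ramp_s)
    env[rising] = 0.5 * (1.0 - np.cos(np.pi * (t_s[rising] - onset_s) / ramp_s))
    env[(t_s >= onset_s + ramp_s) & (t_s <= end_s)] = 1.0
    return env


def _trial_components(row, truth: SubjectTruth, geometry) -> list[tuple[np.ndarray, float]]:
    """(topography, onset_s) pairs active on one trial."""
    if row.location_id not in truth.loc_topo:
        raise TruthError(f"ground truth missing location {row.location_id}")
    ecc = geometry.ecc_label(row.location_id, row.fixation_side)
    comps = [
        (truth.amp_loc * truth.loc_topo[row.location_id], truth.onsets_ms["same"] / 1e3),
        (
            truth.amp_inv * truth.inv_topo,
            truth.invariant_onset_ms(row.trial_type, ecc) / 1e3,
        ),
    ]
    return comps


# ---------------------------------------------------------------------------
# continuous recording
# ---------------------------------------------------------------------------


@dataclass
class ContinuousRecording:
    """Multichannel EEG with an event table, the raw substrate for preprocessing."""

    eeg: np.ndarray  # (n_channels, n_samples), microvolts
    rate_hz: float
    events: pd.DataFrame  # sample_index, event_code, trial_id
    channel_names: list[str] = field(default_factory=lambda: list(CHANNEL_NAMES))

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]


def generate_eeg(
    schedule: pd.DataFrame,
    gaze: GazeTrace,
    truth: SubjectTruth,
    config: SessionConfig,
    seed: int | None = None,
) -> ContinuousRecording:
    """Synthesize the continuous session EEG at config.eeg_rate_hz.

    Event markers (code 1, or 2 for catch trials) are written at every
    stimulus onset.  If the truth specifies an ocular artifact amplitude, a
    saccade-locked biphasic deflection is added for the ICA-criterion tests.
    """
    rate = config.eeg_rate_hz
    rng = np.random.default_rng(config.seed + 2_000_003 if seed is None else seed)
    dur_s = gaze.n_samples / gaze.rate_hz
    n = int(np.ceil(dur_s * rate)) + 1
    if (schedule.stimulus_onset_s.max() + 0.6) * rate > n:
        raise ValueError("gaze trace does not cover the session span")

    eeg = pink_noise(
        N_CHANNELS,
        n,
        rate,
        rng,
        band_hz=truth.config.noise_band_hz,
        rms=truth.config.noise_rms_uv,
        white_fraction=truth.config.noise_white_fraction,
    )
    # mastoids: common reference noise at reduced amplitude
    eeg[N_SCALP:] *= 0.5

    ramp_s = truth.ramp_ms / 1e3
    stim_len_s = 0.5  # discriminative pattern sustained through the epoch
    seg_n = int(round((stim_len_s + 0.05) * rate))
    t_seg = np.arange(seg_n) / rate
    for row in schedule.itertuples():
        if row.is_catch:
            continue
        i0 = int(round(row.stimulus_onset_s * rate))
        sign = 1.0 if row.sf_class == "high" else -1.0
        end = min(i0 + seg_n, n)
        for topo, onset_s in _trial_components(row, truth, config.geometry):
            env = _envelope(t_seg, onset_s, ramp_s, stim_len_s)
            eeg[:, i0:end] += sign * np.outer(topo, env[: end - i0])

    if truth.config.ocular_artifact_uv > 0:
        pulse_n = int(round(0.06 * rate))
        pulse = np.sin(np.linspace(0, 2 * np.pi, pulse_n))
        sac = schedule[schedule.trial_type.str.startswith("saccade")]
        for t_on in sac.true_saccade_onset_s.dropna():
            i0 = int(round(t_on * rate))
            end = min(i0 + pulse_n, n)
            eeg[:, i0:end] += truth.config.ocular_artifact_uv * np.outer(
                truth.ocular_topo, pulse[: end - i0]
            )

    events = pd.DataFrame(
        {
            "sample_index": np.round(schedule.stimulus_onset_s.values * rate).astype(int),
            "event_code": np.where(schedule.is_catch.values, 2, 1),
            "trial_id": schedule.trial_id.values,
        }
    )
    return ContinuousRecording(eeg=eeg, rate_hz=rate, events=events)


# ---------------------------------------------------------------------------
# direct epoch synthesis (desk-scale route)
# ---------------------------------------------------------------------------


def generate_epochs(
    schedule: pd.DataFrame,
    truth: SubjectTruth,
    config: SessionConfig,
    subject_id: str = "s00",
    seed: int | None = None,
) -> EpochSet:
    """Synthesize cleaned, baseline-corrected epochs directly.

    Shares the signal model and noise generator with the continuous route but
    skips filtering/epoching mechanics, which are validated separately; this
    is what multi-cohort recovery studies run on.  Catch trials are dropped,
    mirroring what preprocessing produces.
    """
    rng = np.random.default_rng(config.seed + 3_000_017 if seed is None else seed)
    meta = schedule[~schedule.is_catch].reset_index(drop=True).copy()
    times = epoch_times()
    n_t = times.size
    n_trials = len(meta)

    stream = pink_noise(
        N_CHANNELS,
        n_trials * n_t,
        EPOCH_RATE_HZ,
        rng,
        band_hz=truth.config.noise_band_hz,
        rms=truth.config.noise_rms_uv,
        white_fraction=truth.config.noise_white_fraction,
    )
    data = np.ascontiguousarray(
        stream.reshape(N_CHANNELS, n_trials, n_t).transpose(1, 0, 2)
    )

    ramp_s = truth.ramp_ms / 1e3
    for i, row in enumerate(meta.itertuples()):
        sign = 1.0 if row.sf_class == "high" else -1.0
        for topo, onset_s in _trial_components(row, truth, config.geometry):
            env = _envelope(times, onset_s, ramp_s, times[-1])
            if env.any():
                data[i] += sign * np.outer(topo, env)

    out = EpochSet(data=data, times=times, meta=meta, subject_id=subject_id)
    return out.apply_baseline()
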
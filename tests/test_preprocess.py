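"""Standardization, filtering, ocular-component rejection, epoching."""

import numpy as np
import pandas as pd
import pytest

from saccdecode.eeg import CHANNEL_NAMES, N_CHANNELS, ContinuousRecording
from saccdecode.epochs import baseline_mask
from saccdecode.preprocess import (
    epoch_and_baseline,
    filter_eeg,
    select_ocular_components,
    standardize_record,
)


def _rec(eeg, rate=256.0, events=None):
    if events is None:
        events = pd.DataFrame(columns=["sample_index", "event_code", "trial_id"])
    return ContinuousRecording(eeg=eeg, rate_hz=rate, events=events)


def _amp(x, freq, rate):
    """Amplitude of one frequency component via projection onto the sinusoid."""
    t = np.arange(x.size) / rate
    return 2 * np.hypot(
        np.mean(x * np.cos(2 * np.pi * freq * t)),
        np.mean(x * np.sin(2 * np.pi * freq * t)),
    )


class TestStandardize:
    def test_record_at_256_with_silent_mastoids_unchanged(self):
        rng = np.random.default_rng(0)
        eeg = rng.standard_normal((N_CHANNELS, 2000))
        eeg[62:] = 0.0
        out = standardize_record(_rec(eeg.copy()))
        assert np.allclose(out.eeg, eeg)

    def test_common_mode_rejection(self):
        rng = np.random.default_rng(1)
        eeg = rng.standard_normal((N_CHANNELS, 2000))
        base = standardize_record(_rec(eeg.copy()))
        offset = standardize_record(_rec(eeg + 7.5))
        assert np.allclose(base.eeg, offset.eeg)

    def test_downsampling_attenuates_above_band(self):
        rate = 512.0
        t = np.arange(int(rate * 8)) / rate
        eeg = np.zeros((N_CHANNELS, t.size))
        eeg[0] = np.sin(2 * np.pi * 100.0 * t) + np.sin(2 * np.pi * 10.0 * t)
        ev = pd.DataFrame({"sample_index": [2048], "event_code": [1], "trial_id": [0]})
        out = standardize_record(_rec(eeg, rate=rate, events=ev))
        assert out.rate_hz == 256.0
        sl = slice(200, -200)  # avoid filter edge effects
        a100 = _amp(out.eeg[0][sl], 100.0, 256.0)
        a10 = _amp(out.eeg[0][sl], 10.0, 256.0)
        assert a100 < 0.1  # >= 20 dB down
        assert a10 == pytest.approx(1.0, rel=0.05)
        assert out.events.sample_index.iloc[0] == 1024

    def test_missing_mastoids_error(self):
        rec = _rec(np.zeros((N_CHANNELS, 100)))
        rec.channel_names = [f"X{i}" for i in range(N_CHANNELS)]
        with pytest.raises(ValueError):
            standardize_record(rec)


class TestFilter:
    def test_mains_notch_and_band_edges(self):
        rate = 256.0
        t = np.arange(int(rate * 20)) / rate
        eeg = np.zeros((N_CHANNELS, t.size))
        eeg[0] = (
            np.sin(2 * np.pi * 50.0 * t) + np.sin(2 * np.pi * 10.0 * t) + 4.0
        )
        out = filter_eeg(_rec(eeg))
        sl = slice(512, -512)
        assert _amp(out.eeg[0][sl], 50.0, rate) < 0.05  # >= 95% reduction
        assert _amp(out.eeg[0][sl], 10.0, rate) == pytest.approx(1.0, rel=0.05)
        assert abs(out.eeg[0][sl].mean()) < 0.05  # DC removed

    def test_rate_too_low_for_band(self):
        with pytest.raises(ValueError):
            filter_eeg(_rec(np.zeros((N_CHANNELS, 1000)), rate=128.0))


class TestOcularCriterion:
    rate = 1000.0

    def _windows(self, n_onsets=40, spacing=0.5):
        onsets = spacing * np.arange(1, n_onsets + 1)
        gap = spacing - 0.1  # fixation spans keep clear of the saccade windows
        spans = [(0.05, gap)] + [(t + 0.05, t + gap) for t in onsets[:-1]]
        return onsets, spans

    def _alternating(self, n, amp):
        return amp * np.tile([1.0, -1.0], n // 2 + 1)[:n]

    def test_burst_component_rejected_noise_kept(self):
        rng = np.random.default_rng(5)
        onsets, spans = self._windows()
        n = int((onsets[-1] + 1) * self.rate)
        acts = np.vstack([rng.standard_normal(n), rng.standard_normal(n)])
        for t in onsets:  # 3x variance bursts locked to saccade onsets
            i = int(t * self.rate)
            acts[1, i - 20 : i + 10] *= 3.0
        rejected, ratios = select_ocular_components(acts, onsets, spans, self.rate)
        assert rejected == [1]
        assert ratios[0] == pytest.approx(1.0, abs=0.15)
        assert ratios[1] > 1.1

    def test_ratio_exactly_at_threshold_is_kept(self):
        # alternating +/-a sequences have exact variance a^2 over even windows,
        # pinning the ratio; rejection requires ratio STRICTLY above threshold
        onsets, spans = self._windows(n_onsets=4, spacing=1.0)
        n = int((onsets[-1] + 1) * self.rate)
        act = self._alternating(n, 1.0)
        for t in onsets:
            i = int(t * self.rate)
            act[i - 20 : i + 10] = self._alternating(30, np.sqrt(1.1))
        _, ratios = select_ocular_components(act[None], onsets, spans, self.rate)
        assert ratios[0] == pytest.approx(1.1, abs=1e-12)
        at_boundary, _ = select_ocular_components(
            act[None], onsets, spans, self.rate, ratio_threshold=float(ratios[0])
        )
        assert at_boundary == []
        below, _ = select_ocular_components(
            act[None], onsets, spans, self.rate,
            ratio_threshold=float(ratios[0]) - 1e-9,
        )
        assert below == [0]

    def test_no_saccades_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            rejected, ratios = select_ocular_components(
                np.random.default_rng(0).standard_normal((2, 1000)),
                np.array([]),
                [(0.0, 0.5)],
                self.rate,
            )
        assert rejected == [] and np.isnan(ratios).all()

    def test_planted_ocular_component_always_caught(self):
        """Criterion removes a planted saccade-locked component and keeps the
        planted stationary (neural) components across 100 seeded mixtures."""
        hits, false_alarms = 0, 0
        onsets, spans = self._windows(n_onsets=150, spacing=0.4)
        n = int((onsets[-1] + 1) * self.rate)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            acts = rng.standard_normal((5, n))
            for t in onsets:  # ocular component: saccade-locked bursts
                i = int(t * self.rate)
                acts[0, i - 20 : i + 10] *= 2.5
            rejected, _ = select_ocular_components(acts, onsets, spans, self.rate)
            hits += 0 in rejected
            false_alarms += len(set(rejected) - {0})
        assert hits >= 95
        assert false_alarms == 0


class TestEpoching:
    def _session(self):
        from saccdecode.config import desk_scale_config
        from saccdecode.schedule import build_session_schedule

        cfg = desk_scale_config(
            seed=17, trials_per_block=32, n_fixation_per_block=24,
            n_saccade_per_block=0, n_control_per_block=8,
        )
        return cfg, build_session_schedule(cfg)

    def _record_for(self, sched, value=0.0):
        dur = sched.stimulus_onset_s.max() + 1.0
        n = int(dur * 256) + 1
        eeg = np.full((N_CHANNELS, n), value)
        ev = pd.DataFrame(
            {
                "sample_index": np.round(sched.stimulus_onset_s * 256).astype(int),
                "event_code": np.where(sched.is_catch, 2, 1),
                "trial_id": sched.trial_id,
            }
        )
        return _rec(eeg, events=ev)

    def test_constant_record_gives_zero_epochs(self):
        cfg, sched = self._session()
        ep = epoch_and_baseline(self._record_for(sched, 3.3), sched)
        assert np.allclose(ep.data, 0.0)

    def test_epoch_grid_and_bookkeeping(self):
        cfg, sched = self._session()
        ep = epoch_and_baseline(self._record_for(sched), sched)
        assert ep.n_trials == (~sched.is_catch).sum()  # catch removed
        assert (ep.times == 0).any()
        assert np.allclose(np.diff(ep.times), 1 / 256)
        assert ep.times[0] >= -0.2 and ep.times[-1] == pytest.approx(0.5)

    def test_injected_step_recovered_and_baseline_zero(self):
        cfg, sched = self._session()
        rec = self._record_for(sched)
        step_at = np.round(sched.stimulus_onset_s * 256).astype(int) + int(0.1 * 256)
        for s in step_at:
            rec.eeg[:, s:] += 5.0
        ep = epoch_and_baseline(rec, sched)
        m = baseline_mask(ep.times)
        assert np.abs(ep.data[:, :, m].mean(axis=2)).max() < 1e-10
        late = ep.data[:, :, ep.times > 0.11].mean()
        assert late == pytest.approx(5.0, rel=0.05)

    def test_baseline_is_idempotent(self):
        cfg, sched = self._session()
        rec = self._record_for(sched)
        rec.eeg += np.random.default_rng(0).standard_normal(rec.eeg.shape)
        ep = epoch_and_baseline(rec, sched)
        again = ep.apply_baseline()
        assert np.allclose(again.data, ep.data)

    def test_excluded_trials_are_dropped(self):
        cfg, sched = self._session()
        rec = self._record_for(sched)
        keep = set(sched.trial_id[:10]) - set(sched.trial_id[sched.is_catch])
        ep = epoch_and_baseline(rec, sched, keep_trial_ids=keep)
        assert set(ep.meta.trial_id) == keep
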
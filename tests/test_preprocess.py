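"""Signal-conditioning contracts: resampling, referencing, filtering,
epoching, baselining and fixed segmentation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from illusioneeg.containers import ContinuousRecording, EpochSet, Event
from illusioneeg import preprocess as pp
from illusioneeg import synthetic as syn

from conftest import make_config


def _recording(data, rate=1000.0, labels=None, events=None):
    labels = labels or [f"ch{i}" for i in range(data.shape[0])]
    return ContinuousRecording(data=data, rate_hz=rate,
                               channel_labels=labels, events=events or [])


class TestResample:
    def test_four_to_one_decimation_sample_count(self):
        rec = _recording(np.random.default_rng(0).standard_normal((2, 1000)))
        out = pp.resample(rec, 250.0)
        assert out.n_samples == 250
        assert out.rate_hz == 250.0

    def test_sine_matches_analytic_evaluation_on_new_grid(self):
        rate = 1000.0
        t = np.arange(int(2 * rate)) / rate
        rec = _recording(np.sin(2 * np.pi * 10 * t)[None, :], rate)
        out = pp.resample(rec, 250.0)
        t_new = np.arange(out.n_samples) / 250.0
        ref = np.sin(2 * np.pi * 10 * t_new)
        r = np.corrcoef(out.data[0], ref)[0, 1]
        assert r > 0.999

    def test_events_remapped_and_duration_preserved(self):
        rec = _recording(np.zeros((1, 1000)),
                         events=[Event(400, "word_onset")])
        out = pp.resample(rec, 250.0)
        assert out.events[0].sample == 100
        assert abs(out.duration_s - rec.duration_s) <= 1.0 / 250.0

    def test_invalid_rates_raise(self):
        rec = _recording(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            pp.resample(rec, -5.0)
        with pytest.raises(ValueError):
            pp.resample(rec, 2000.0)


class TestRereference:
    def test_zero_mastoids_leave_data_unchanged(self):
        data = np.random.default_rng(1).standard_normal((4, 50))
        data[2:] = 0.0
        rec = _recording(data, labels=["Cz", "Pz", "M1", "M2"])
        out = pp.rereference(rec)
        assert np.allclose(out.data, rec.data)

    def test_self_reference_zeroes_everything(self):
        row = np.random.default_rng(2).standard_normal(50)
        rec = _recording(np.tile(row, (4, 1)),
                         labels=["Cz", "Pz", "M1", "M2"])
        assert np.allclose(pp.rereference(rec).data, 0.0)

    def test_matches_bruteforce_subtraction(self, rng):
        data = rng.standard_normal((4, 64))
        rec = _recording(data, labels=["Cz", "Pz", "M1", "M2"])
        expected = data - (data[2] + data[3]) / 2.0
        assert np.allclose(pp.rereference(rec).data, expected, atol=1e-12)

    def test_missing_reference_raises_with_name(self):
        rec = _recording(np.zeros((2, 10)), labels=["Cz", "Pz"])
        with pytest.raises(KeyError, match="M1"):
            pp.rereference(rec)

    def test_rereference_commutes_with_channel_average(self, rng):
        data = rng.standard_normal((4, 32))
        rec = _recording(data, labels=["Cz", "Pz", "M1", "M2"])
        ref_then_avg = pp.rereference(rec).data.mean(axis=0)
        ref = (data[2] + data[3]) / 2.0
        avg_then_ref = data.mean(axis=0) - ref
        assert np.allclose(ref_then_avg, avg_then_ref, atol=1e-12)


class TestFilters:
    def test_zero_signal_stays_zero(self):
        rec = _recording(np.zeros((2, 2000)))
        assert np.allclose(pp.fir_bandpass(rec, 0.0, 125.0).data, 0.0)

    def test_stopband_sine_heavily_attenuated(self):
        rate = 1000.0
        t = np.arange(int(4 * rate)) / rate
        rec = _recording(np.sin(2 * np.pi * 200 * t)[None, :], rate)
        out = pp.fir_bandpass(rec, 0.0, 125.0)
        core = slice(500, -500)  # avoid convolution edges
        assert (np.sqrt(np.mean(out.data[0, core] ** 2))
                < 0.05 * np.sqrt(np.mean(rec.data[0, core] ** 2)))

    def test_passband_gain_within_one_db(self):
        rate = 1000.0
        t = np.arange(int(4 * rate)) / rate
        rec = _recording(np.sin(2 * np.pi * 60 * t)[None, :], rate)
        out = pp.fir_bandpass(rec, 0.0, 125.0)
        core = slice(500, -500)
        ratio = (np.sqrt(np.mean(out.data[0, core] ** 2))
                 / np.sqrt(np.mean(rec.data[0, core] ** 2)))
        assert 10 ** (-1 / 20) < ratio < 10 ** (1 / 20)

    def test_band_outside_nyquist_raises(self):
        rec = _recording(np.zeros((1, 100)), rate=250.0)
        with pytest.raises(ValueError):
            pp.fir_bandpass(rec, 0.0, 200.0)

    def test_cheby_passband_sine_preserved_within_ripple(self):
        rate = 250.0
        t = np.arange(int(8 * rate)) / rate
        rec = _recording(np.sin(2 * np.pi * 5 * t)[None, :], rate)
        out = pp.cheby_bandlimit(rec, order=4, high_hz=40.0)
        core = slice(250, -250)
        ratio = (np.sqrt(np.mean(out.data[0, core] ** 2))
                 / np.sqrt(np.mean(rec.data[0, core] ** 2)))
        # forward-backward application doubles the 0.5 dB design ripple
        assert abs(ratio - 1.0) < 10 ** (2 * pp.CHEBY_RIPPLE_DB / 20) - 1.0 + 0.01

    def test_cheby_stopband_attenuation_exceeds_20_db(self):
        rate = 250.0
        t = np.arange(int(8 * rate)) / rate
        rec = _recording(np.sin(2 * np.pi * 80 * t)[None, :], rate)
        out = pp.cheby_bandlimit(rec, order=4, high_hz=40.0)
        core = slice(250, -250)
        ratio = (np.sqrt(np.mean(out.data[0, core] ** 2))
                 / np.sqrt(np.mean(rec.data[0, core] ** 2)))
        assert ratio < 10 ** (-20 / 20)


class TestEpoching:
    def test_boundary_event_dropped_and_counted(self):
        rec = _recording(np.zeros((1, 1000)), rate=1000.0,
                         events=[Event(0, "word_onset"),
                                 Event(500, "word_onset")])
        ep = pp.epoch_around(rec, "word_onset", (-200.0, 350.0))
        assert ep.n_epochs == 1
        assert ep.info["n_dropped"] == 1

    def test_epoching_is_pure_indexing(self, rng):
        data = rng.standard_normal((3, 2000))
        rec = _recording(data, rate=1000.0, events=[Event(1000, "word_onset")])
        ep = pp.epoch_around(rec, "word_onset", (-200.0, 350.0))
        assert np.array_equal(ep.data[0], data[:, 800:1351])
        assert ep.time_ms[0] == -200.0 and ep.time_ms[-1] == 350.0

    def test_template_peak_latency_recovered(self):
        cfg = make_config()
        from conftest import make_silent_config
        cfg = make_silent_config(n_subjects=1)
        rec = syn.generate_subject_recording(cfg, 0)
        ep = pp.epoch_around(rec, "word_onset", (-200.0, 350.0))
        roi = [ep.channel_index(c) for c in ("Fz", "FCz", "Cz", "CPz", "Pz")]
        wave = ep.data[:, roi, :].mean(axis=(0, 1))
        peak_ms = ep.time_ms[np.argmax(wave)]
        assert abs(peak_ms - cfg.p2_peak_ms) <= 1000.0 / cfg.rate_hz

    def test_no_matching_events_raises(self):
        rec = _recording(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            pp.epoch_around(rec, "word_onset", (-10.0, 10.0))


class TestBaseline:
    def _epochs(self, data, rate=1000.0):
        n_t = data.shape[2]
        time_ms = np.arange(n_t) * 1000.0 / rate - 200.0
        n = data.shape[0]
        return EpochSet(data=data, rate_hz=rate, time_ms=time_ms,
                        channel_labels=[f"ch{i}" for i in range(data.shape[1])],
                        condition=np.array([""] * n, dtype=object),
                        subject_id=np.array(["s"] * n, dtype=object),
                        stimulus_id=np.array([""] * n, dtype=object))

    def test_constant_epoch_becomes_zero(self):
        ep = self._epochs(np.full((1, 1, 500), 7.0))
        out = pp.baseline_correct(ep, (-200.0, 0.0))
        assert np.allclose(out.data, 0.0, atol=1e-12)

    def test_linear_ramp_matches_bruteforce(self, rng):
        data = rng.standard_normal((2, 3, 1)) * np.linspace(0, 1, 600)
        ep = self._epochs(data)
        out = pp.baseline_correct(ep, (-200.0, 0.0))
        mask = (ep.time_ms >= -200.0) & (ep.time_ms <= 0.0)
        expected = data - data[:, :, mask].mean(axis=2, keepdims=True)
        assert np.allclose(out.data, expected, atol=1e-12)
        # invariant: baseline mean is zero afterwards
        assert np.allclose(out.data[:, :, mask].mean(axis=2), 0.0, atol=1e-9)

    def test_window_outside_axis_raises(self):
        ep = self._epochs(np.zeros((1, 1, 100)))
        with pytest.raises(ValueError):
            pp.baseline_correct(ep, (-1000.0, -900.0))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_baseline_correction_is_idempotent(self, seed):
        data = np.random.default_rng(seed).standard_normal((2, 2, 400))
        ep = self._epochs(data)
        once = pp.baseline_correct(ep, (-200.0, 0.0))
        twice = pp.baseline_correct(once, (-200.0, 0.0))
        assert np.allclose(once.data, twice.data, atol=1e-12)


class TestSegmentFixed:
    def test_eleven_minutes_at_250_hz_gives_264_segments(self):
        rec = _recording(np.zeros((1, int(660 * 250))), rate=250.0)
        ep = pp.segment_fixed(rec, 2.5)
        assert ep.n_epochs == 264
        assert ep.alignment == "fixed_segment"

    def test_too_short_recording_raises(self):
        rec = _recording(np.zeros((1, int(2.4 * 250))), rate=250.0)
        with pytest.raises(ValueError, match="shorter"):
            pp.segment_fixed(rec, 2.5)

    def test_segments_are_consecutive_and_remainder_dropped(self, rng):
        data = rng.standard_normal((2, 1300))
        rec = _recording(data, rate=100.0)
        ep = pp.segment_fixed(rec, 2.5)  # 250 samples per segment
        assert ep.n_epochs == 5
        assert np.array_equal(ep.data[1], data[:, 250:500])
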
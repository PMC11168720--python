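"""Preprocessing: EDF round trip, filtering, R peaks, RR conditioning,
analysis-window extraction."""

import logging
import types as _types

import numpy as np
import pytest

from bhi import preprocess, synthetic_data
from bhi.types import (
    PhysioRecording,
    REDUCED_MONTAGE_MISSING,
    RRSeries,
    SeizureAnnotation,
    STANDARD_CHANNELS,
    montage_xy,
)
from conftest import make_recording


def _write_session(tmp_path, rec, annotations):
    sim = _types.SimpleNamespace(recording=rec, annotations=annotations)
    return synthetic_data.write_session(sim, tmp_path, stem="fixture")


class TestReadRecording:
    def test_edf_round_trip_preserves_signals_and_labels(self, tmp_path):
        rec, _ = make_recording(n_channels=29, fs=512.0, duration_s=12.0)
        ann = [SeizureAnnotation(3.0, 6.0, "sz1")]
        edf, ann_path = _write_session(tmp_path, rec, ann)
        out, anns = preprocess.read_recording(edf, ann_path)
        assert out.fs == 512.0
        assert out.channel_labels == list(STANDARD_CHANNELS)
        assert out.n_samples == rec.n_samples
        # 16-bit quantization: near-perfect correlation, small abs error
        for i in (0, 14, 28):
            c = np.corrcoef(out.eeg[i], rec.eeg[i])[0, 1]
            assert c > 0.9999
        assert np.corrcoef(out.ecg, rec.ecg)[0, 1] > 0.9999
        assert len(anns) == 1 and anns[0].onset_s == 3.0

    def test_reduced_montage_reads_19_channels_with_warning(self, tmp_path,
                                                            caplog):
        keep = [c for c in STANDARD_CHANNELS
                if c not in REDUCED_MONTAGE_MISSING]
        rec, _ = make_recording(fs=256.0, duration_s=12.0, channels=keep)
        edf, ann = _write_session(tmp_path, rec, [])
        with caplog.at_level(logging.WARNING, logger="bhi.preprocess"):
            out, _ = preprocess.read_recording(edf)
        assert len(out.channel_labels) == 19
        assert any("absent" in r.message for r in caplog.records)

    def test_ecg_only_file_is_an_input_error(self, tmp_path):
        from bhi._edf import write_edf

        path = tmp_path / "ecg_only.edf"
        write_edf(path, [np.sin(np.arange(2560) / 10)], ["ECG"], 256,
                  ["mV"])
        with pytest.raises(ValueError, match="EEG"):
            preprocess.read_recording(path)

    def test_annotation_dialects(self, tmp_path):
        p = tmp_path / "ann.txt"
        p.write_text("# comment\nsz1 90.5 120.0\nsz2 0:30:00 0:31:30\n")
        anns = preprocess.read_annotations(p)
        assert anns[0].onset_s == 90.5 and anns[0].offset_s == 120.0
        assert anns[1].onset_s == 1800.0 and anns[1].offset_s == 1890.0


class TestBandpassEEG:
    def _sine_rec(self, freq, fs=512.0, duration=30.0, amp=10.0):
        t = np.arange(0, duration, 1.0 / fs)
        labels = list(STANDARD_CHANNELS[:3])
        eeg = np.tile(amp * np.sin(2 * np.pi * freq * t), (3, 1))
        return PhysioRecording(eeg=eeg, ecg=np.zeros(t.size), fs=fs,
                               channel_labels=labels,
                               montage_xy=montage_xy(labels))

    def test_passband_tone_preserved(self):
        rec = self._sine_rec(10.0)
        out = preprocess.bandpass_eeg(rec)
        mid = slice(rec.n_samples // 4, 3 * rec.n_samples // 4)
        ratio = out.eeg[0, mid].std() / rec.eeg[0, mid].std()
        assert abs(ratio - 1.0) < 0.05

    def test_stopband_tone_attenuated_40db(self):
        rec = self._sine_rec(0.2, duration=60.0)
        out = preprocess.bandpass_eeg(rec)
        mid = slice(rec.n_samples // 4, 3 * rec.n_samples // 4)
        ratio = out.eeg[0, mid].std() / rec.eeg[0, mid].std()
        assert ratio < 10 ** (-40 / 20)

    def test_zero_signal_maps_to_zero_and_length_preserved(self):
        rec = self._sine_rec(10.0)
        rec.eeg[:] = 0.0
        out = preprocess.bandpass_eeg(rec)
        assert out.n_samples == rec.n_samples
        assert np.allclose(out.eeg, 0.0)

    def test_zero_phase_no_lag(self):
        rec = self._sine_rec(8.0)
        out = preprocess.bandpass_eeg(rec)
        mid = slice(rec.n_samples // 4, 3 * rec.n_samples // 4)
        x, y = rec.eeg[0, mid], out.eeg[0, mid]
        lags = np.arange(-20, 21)
        xc = [np.dot(x, np.roll(y, k)) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_low_fs_rejected(self):
        rec = self._sine_rec(10.0, fs=60.0)
        with pytest.raises(ValueError, match="too low"):
            preprocess.bandpass_eeg(rec)


class TestDetectRpeaks:
    def test_regular_train_recovered_within_one_sample(self):
        fs = 512.0
        beats = np.arange(0.5, 60, 0.8)
        ecg = synthetic_data._render_ecg(beats, fs, int(60 * fs))
        det = preprocess.detect_rpeaks(ecg, fs)
        assert len(det) == len(beats)
        rr = np.diff(det)
        assert np.all(np.abs(rr - 0.8) <= 1.0 / fs + 1e-9)

    def test_snr20db_recovery_99pct(self):
        fs = 256.0
        rng = np.random.default_rng(5)
        beats = np.arange(0.5, 120, 0.8)
        ecg = synthetic_data._render_ecg(beats, fs, int(120 * fs))
        noise = rng.standard_normal(ecg.size)
        noise *= ecg.std() / noise.std() / 10.0     # 20 dB
        det = preprocess.detect_rpeaks(ecg + noise, fs)
        # every planted beat matched within one sample (modulo a constant
        # detector offset)
        offset = np.median(det[: len(beats)] - beats[: len(det)])
        matched = sum(
            np.min(np.abs(det - (b + offset))) <= 1.0 / fs + 1e-9
            for b in beats
        )
        assert matched >= 0.99 * len(beats)

    def test_halved_amplitude_beat_still_detected(self):
        fs = 256.0
        beats = np.arange(0.5, 30, 0.8)
        ecg = synthetic_data._render_ecg(beats, fs, int(30 * fs))
        i0 = int(beats[10] * fs)
        w = int(0.1 * fs)
        ecg[i0 - w: i0 + w] *= 0.5
        det = preprocess.detect_rpeaks(ecg, fs)
        assert len(det) == len(beats)

    def test_flat_line_empty_with_warning(self):
        with pytest.warns(UserWarning):
            det = preprocess.detect_rpeaks(np.zeros(5120), 256.0)
        assert det.size == 0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            preprocess.detect_rpeaks(np.zeros(100), 256.0)


class TestRRConditioning:
    def test_single_outlier_replaced_others_untouched(self):
        rr_vals = np.full(30, 0.8)
        rr_vals[15] = 2.4
        beats = np.concatenate([[0.0], np.cumsum(rr_vals)])
        out = preprocess.correct_rr_artifacts(RRSeries.from_beats(beats))
        assert out.n_corrected == 1
        assert out.rr_s.size == 30
        untouched = np.delete(out.rr_s, 15)
        assert np.allclose(untouched, 0.8, atol=1e-9)
        assert abs(out.rr_s[15] - 0.8) < 0.2

    def test_clean_series_is_noop(self):
        beats = np.arange(0, 24, 0.8)
        out = preprocess.correct_rr_artifacts(RRSeries.from_beats(beats))
        assert out.n_corrected == 0
        assert np.allclose(out.rr_s, 0.8)

    def test_bigeminy_raises_quality_warning(self):
        rr_vals = np.tile([0.4, 1.6], 20)
        beats = np.concatenate([[0.0], np.cumsum(rr_vals)])
        out = preprocess.correct_rr_artifacts(RRSeries.from_beats(beats))
        assert out.quality_warning

    def test_sample_count_never_changes(self):
        rng = np.random.default_rng(3)
        rr_vals = 0.8 + 0.3 * rng.standard_normal(50).clip(-1.5, 4)
        rr_vals = np.clip(rr_vals, 0.3, None)
        beats = np.concatenate([[0.0], np.cumsum(rr_vals)])
        out = preprocess.correct_rr_artifacts(RRSeries.from_beats(beats))
        assert out.rr_s.size == rr_vals.size
        assert out.beat_times_s.size == beats.size

    def test_interpolation_constant_and_ramp(self):
        beats = np.concatenate([[0.0], np.cumsum(np.full(40, 1.0))])
        out = preprocess.interpolate_rr(RRSeries.from_beats(beats))
        assert np.allclose(np.diff(out.t4hz), 0.25)
        assert np.allclose(out.rr4hz, 1.0, atol=1e-9)

        rr_ramp = np.linspace(0.7, 1.1, 40)
        beats = np.concatenate([[0.0], np.cumsum(rr_ramp)])
        rrs = preprocess.interpolate_rr(RRSeries.from_beats(beats))
        expect = np.interp(rrs.t4hz, beats[1:], rr_ramp)
        assert np.allclose(rrs.rr4hz, expect, atol=5e-3)

    def test_three_beats_rejected(self):
        with pytest.raises(ValueError):
            preprocess.interpolate_rr(RRSeries.from_beats([0.0, 0.8, 1.6]))


class TestExtractWindows:
    def _rec(self, duration_s=2000.0):
        labels = list(STANDARD_CHANNELS[:2])
        n = int(duration_s * 64)
        return PhysioRecording(eeg=np.zeros((2, n)), ecg=np.zeros(n),
                               fs=64.0, channel_labels=labels,
                               montage_xy=montage_xy(labels))

    def test_default_10min_pair(self, seizure_annotation):
        wp = preprocess.extract_windows(self._rec(), seizure_annotation)
        assert wp.preictal == (300.0, 900.0)
        assert wp.postictal == (960.0, 1560.0)

    def test_short_preictal_history_excludes_event(self):
        ann = SeizureAnnotation(400.0, 460.0, "early")
        with pytest.raises(preprocess.EventExcluded, match="before onset"):
            preprocess.extract_windows(self._rec(), ann)

    def test_short_postictal_tail_excludes_event(self):
        ann = SeizureAnnotation(900.0, 1950.0, "late")
        with pytest.raises(preprocess.EventExcluded, match="after offset"):
            preprocess.extract_windows(self._rec(), ann)

    @pytest.mark.parametrize("L", [600.0, 420.0, 300.0, 120.0, 60.0])
    def test_window_lengths_and_no_ictal_overlap(self, L,
                                                 seizure_annotation):
        wp = preprocess.extract_windows(self._rec(), seizure_annotation, L)
        assert wp.preictal[1] - wp.preictal[0] == L
        assert wp.postictal[1] - wp.postictal[0] == L
        assert wp.preictal[1] <= seizure_annotation.onset_s
        assert wp.postictal[0] >= seizure_annotation.offset_s
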
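import numpy as np
import pytest

from radarbeat.signal_core import (BeatTrain, ParseError, SubjectRecording,
                                   TimeSeries, align, crop, decimate,
                                   read_beats, read_recording, write_beats,
                                   write_recording)

from conftest import make_recording


class TestTimeSeries:
    def test_invariants(self):
        with pytest.raises(ValueError):
            TimeSeries([1.0], rate=0.0)
        with pytest.raises(ValueError):
            TimeSeries([np.nan], rate=10.0)
        ts = TimeSeries([], rate=10.0)
        assert len(ts) == 0 and ts.duration == 0.0

    def test_sample_times(self):
        ts = TimeSeries(np.zeros(5), rate=10.0, t0=2.0)
        np.testing.assert_allclose(ts.times(), 2.0 + np.arange(5) / 10.0)


class TestBeatTrain:
    def test_rejects_non_increasing(self):
        with pytest.raises(ValueError):
            BeatTrain([1.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            BeatTrain([2.0, 1.0])

    def test_restrict_half_open(self):
        bt = BeatTrain([0.5, 1.0, 1.5])
        assert list(bt.restrict(0.5, 1.5).times) == [0.5, 1.0]


class TestRecordingIO:
    def test_round_trip_values_exact(self, tmp_path, small_recording):
        path = tmp_path / "rec.rec"
        write_recording(small_recording, path)
        back = read_recording(path)
        assert back.subject_id == small_recording.subject_id
        for name, ts in small_recording.channels().items():
            other = back.channels()[name]
            assert len(other) == len(ts)
            assert other.rate == ts.rate
            np.testing.assert_array_equal(other.values, ts.values)

    def test_distinct_channel_rates_preserved(self, tmp_path,
                                              small_recording):
        path = tmp_path / "rec.rec"
        write_recording(small_recording, path)
        back = read_recording(path)
        assert back.ecg.rate == 250.0
        assert back.i_ch.rate == 1000.0

    def test_toy_file_parses(self, tmp_path):
        txt = ("#subject_id=toy\n#rate_i=1000\n#rate_q=1000\n"
               "channel,t,value\n"
               "i,0.000,1.0\ni,0.001,2.0\ni,0.002,3.0\n"
               "q,0.000,4.0\nq,0.001,5.0\nq,0.002,6.0\n")
        p = tmp_path / "toy.rec"
        p.write_text(txt)
        rec = read_recording(p)
        assert len(rec.i_ch) == 3 and len(rec.q_ch) == 3
        assert rec.ecg is None

    def test_duplicate_timestamp_names_line(self, tmp_path):
        txt = ("#rate_i=1000\n#rate_q=1000\nchannel,t,value\n"
               "i,0.000,1.0\ni,0.000,2.0\n"
               "q,0.000,1.0\nq,0.001,2.0\n")
        p = tmp_path / "bad.rec"
        p.write_text(txt)
        with pytest.raises(ParseError, match="line 5.*duplicated"):
            read_recording(p)

    def test_rate_mismatch_rejected(self, tmp_path):
        txt = ("#rate_i=1000\n#rate_q=1000\nchannel,t,value\n"
               "i,0.000,1.0\ni,0.002,2.0\n"
               "q,0.000,1.0\nq,0.001,2.0\n")
        p = tmp_path / "bad.rec"
        p.write_text(txt)
        with pytest.raises(ParseError, match="spacing"):
            read_recording(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.rec"
        p.write_text("#rate_i=1000\nchannel,t\ni,0.0\n")
        with pytest.raises(ParseError, match="missing column"):
            read_recording(p)

    def test_empty_channels_round_trip(self, tmp_path):
        rec = SubjectRecording("E", None, TimeSeries([], 1000.0),
                               TimeSeries([], 1000.0))
        path = tmp_path / "empty.rec"
        write_recording(rec, path)
        back = read_recording(path)
        assert len(back.i_ch) == 0

    def test_beat_file_round_trip(self, tmp_path):
        bt = BeatTrain([0.123456789, 1.5, 2.75])
        p = tmp_path / "beats.txt"
        write_beats(bt, p)
        np.testing.assert_allclose(read_beats(p).times, bt.times,
                                   atol=1e-9)


class TestDecimate:
    def test_dc_invariance(self):
        ts = TimeSeries(np.full(1000, 3.7), 1000.0)
        out = decimate(ts, 100.0)
        np.testing.assert_allclose(out.values, 3.7, atol=1e-6)
        assert out.rate == 100.0 and out.t0 == ts.t0

    def test_sample_count_2000_to_200(self):
        ts = TimeSeries(np.zeros(2000), 1000.0)
        assert len(decimate(ts, 100.0)) == 200

    def test_alias_suppression(self):
        # 1 Hz survives; 300 Hz would alias to 0 Hz band and must be gone
        t = np.arange(4000) / 1000.0
        ts = TimeSeries(np.sin(2 * np.pi * 1.0 * t)
                        + np.sin(2 * np.pi * 300.0 * t), 1000.0)
        out = decimate(ts, 100.0)
        spec = np.abs(np.fft.rfft(out.values * np.hanning(len(out))))
        freqs = np.fft.rfftfreq(len(out), d=1 / 100.0)
        p1 = spec[np.argmin(np.abs(freqs - 1.0))]
        # the 300 Hz tone aliases to 0 Hz at a 100 Hz rate
        palias = spec[np.argmin(np.abs(freqs - 0.0))]
        assert 20 * np.log10(p1 / max(palias, 1e-12)) >= 40.0

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            decimate(TimeSeries(np.zeros(100), 1000.0), 300.0)

    def test_composition(self):
        t = np.arange(5000) / 1000.0
        ts = TimeSeries(np.sin(2 * np.pi * 2.0 * t), 1000.0)
        once = decimate(ts, 100.0)
        twice = decimate(decimate(ts, 500.0), 100.0)
        interior = slice(20, len(once) - 20)
        np.testing.assert_allclose(twice.values[interior],
                                   once.values[interior], atol=5e-3)

    def test_empty_series(self):
        out = decimate(TimeSeries([], 1000.0, t0=1.0), 100.0)
        assert len(out) == 0 and out.rate == 100.0 and out.t0 == 1.0


class TestAlign:
    def _rec(self, ecg_t0=0.0, radar_t0=0.0, duration=4.0):
        ecg = TimeSeries(np.arange(int(250 * duration)), 250.0, ecg_t0)
        i = TimeSeries(np.arange(int(1000 * duration)), 1000.0, radar_t0)
        q = TimeSeries(np.arange(int(1000 * duration)), 1000.0, radar_t0)
        return SubjectRecording("A", ecg, i, q)

    def test_late_ecg_trims_radar(self):
        rec = self._rec(ecg_t0=0.5, radar_t0=0.0)
        out = align(rec)
        # radar channels lose 500 leading samples at 1 kHz
        assert out.i_ch.values[0] == 500
        assert abs(out.i_ch.t0 - 0.5) < 1e-9
        lo, hi = out.span
        assert hi - lo <= 4.0 - 0.5 + 1e-9

    def test_idempotent(self):
        rec = self._rec(ecg_t0=0.5)
        once = align(rec)
        twice = align(once)
        for name, ts in once.channels().items():
            np.testing.assert_array_equal(ts.values,
                                          twice.channels()[name].values)
            assert ts.t0 == twice.channels()[name].t0

    def test_aligned_unchanged(self):
        rec = self._rec()
        out = align(rec)
        np.testing.assert_array_equal(out.i_ch.values, rec.i_ch.values)

    def test_disjoint_channels_rejected(self):
        rec = self._rec(ecg_t0=10.0, radar_t0=0.0)
        with pytest.raises(ValueError, match="overlap"):
            align(rec)


class TestCrop:
    def test_300s_to_200s(self):
        rec = make_recording(duration=30.0, seed=2)
        out = crop(rec, 5.0, 25.0)
        assert len(out.i_ch) == 20000
        assert len(out.ecg) == 5000
        assert abs(out.i_ch.t0 - 5.0) < 1e-9

    def test_full_span_identity(self, small_recording):
        lo, hi = small_recording.span
        out = crop(small_recording, lo, hi)
        np.testing.assert_array_equal(out.i_ch.values,
                                      small_recording.i_ch.values)

    def test_values_copied_verbatim(self, small_recording):
        out = crop(small_recording, 1.0, 3.0)
        k0 = int(np.ceil((1.0 - small_recording.i_ch.t0) * 1000 - 1e-9))
        np.testing.assert_array_equal(
            out.i_ch.values, small_recording.i_ch.values[k0:k0 + 2000])

    def test_truth_beat_outside_window_dropped(self):
        rec = make_recording(duration=30.0, seed=2)
        out = crop(rec, 5.0, 25.0)
        assert np.all(out.truth_beats.times >= 5.0)
        assert np.all(out.truth_beats.times < 25.0)

    def test_out_of_span_rejected(self, small_recording):
        with pytest.raises(ValueError, match="outside"):
            crop(small_recording, -5.0, 10.0)
        with pytest.raises(ValueError):
            crop(small_recording, 10.0, 10.0)
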
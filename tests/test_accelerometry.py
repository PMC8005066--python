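"""Unit and property tests for the accelerometry processing chain."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from armuse import accelerometry as acc
from armuse.accelerometry import Category
from conftest import reference_counts

FS = 30.0


def _sine(freq: float, amp: float, seconds: float, fs: float = FS) -> np.ndarray:
    t = np.arange(int(seconds * fs)) / fs
    sig = np.zeros((len(t), 3))
    sig[:, 0] = amp * np.sin(2 * np.pi * freq * t)
    return sig


class TestBandpass:
    def test_dc_gravity_rejected(self):
        sig = np.zeros((int(60 * FS), 3))
        sig[:, 2] = 1.0
        out = acc.bandpass_filter(sig, sample_rate=FS)
        interior = out[int(5 * FS):-int(5 * FS)]
        assert np.max(np.abs(interior)) < 1e-6

    def test_passband_1hz_gain(self):
        out = acc.bandpass_filter(_sine(1.0, 0.2, 120), sample_rate=FS)
        steady = out[int(30 * FS): int(90 * FS), 0]
        amp = np.max(np.abs(steady))
        assert 0.9 * 0.2 <= amp <= 1.0 * 0.2 + 1e-9

    def test_stopband_5hz_attenuated(self):
        out = acc.bandpass_filter(_sine(5.0, 0.2, 120), sample_rate=FS)
        steady = out[int(30 * FS): int(90 * FS), 0]
        assert np.max(np.abs(steady)) < 0.1 * 0.2

    def test_aliasing_guard(self):
        with pytest.raises(ValueError, match="sample rate"):
            acc.bandpass_filter(_sine(1.0, 0.2, 10, fs=4.0), sample_rate=4.0)


class TestEpochCounts:
    def _series(self, sig, **kw):
        return acc.epoch_counts(
            sig, start_time=pd.Timestamp("2024-03-04 09:00:00-08:00"),
            wrist="right", **kw,
        )

    def test_zero_signal_zero_counts(self):
        s = self._series(np.zeros((120, 3)))
        assert s.counts.shape == (2, 3)
        assert np.all(s.counts == 0)

    def test_calibration_anchor_one_count(self):
        # a sustained rectified mean of exactly one step_g gives one count
        sig = np.full((60, 3), acc.STEP_G)
        s = self._series(sig)
        assert np.all(s.counts == 1)

    def test_sine_count_closed_form(self):
        # mean |sin| over whole half-periods is 2/pi
        for amp in (0.1, 0.2, 0.3):
            sig = _sine(0.75, amp, 2.0)
            s = self._series(sig)
            expected = int(np.floor(amp * (2 / np.pi) / acc.STEP_G))
            assert s.counts[0, 0] == expected

    def test_trailing_partial_epoch_dropped(self):
        s = self._series(np.ones((150, 3)) * 0.1)
        assert s.n_epochs == 2

    def test_nonfinite_rejected_with_epoch_index(self):
        sig = np.zeros((180, 3))
        sig[130, 1] = np.nan
        with pytest.raises(ValueError, match=r"epoch\(s\) \[2\]"):
            self._series(sig)

    def test_matches_brute_force_reference(self):
        rng = np.random.default_rng(7)
        sig = rng.normal(0, 0.1, size=(60 * 30, 3))
        s = self._series(sig)
        np.testing.assert_array_equal(s.counts, reference_counts(sig))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(scale=st.floats(1.0, 10.0), seed=st.integers(0, 100))
    def test_amplitude_monotonicity(self, scale, seed):
        """Scaling a signal up never decreases any epoch count."""
        rng = np.random.default_rng(seed)
        sig = rng.normal(0, 0.05, size=(240, 3))
        base = self._series(sig).counts
        scaled = self._series(sig * scale).counts
        assert np.all(scaled >= base)


class TestResultant:
    @pytest.mark.parametrize(
        "xyz, expected",
        [((3, 4, 0), 5.0), ((0, 0, 0), 0.0), ((2, 2, 2), np.sqrt(12))],
    )
    def test_closed_form(self, xyz, expected):
        x, y, z = ([v] for v in xyz)
        assert acc.resultant(x, y, z)[0] == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            acc.resultant([1, 2], [1], [1, 2])


class TestNonwear:
    EPOCHS_3H = int(3 * 3600 / 2)  # 5400

    def _res(self, runs):
        """Build a resultant series from (value, n_epochs) runs."""
        return np.concatenate([np.full(n, v, dtype=float) for v, n in runs])

    def test_exact_three_hour_run_flagged(self):
        res = self._res([(5, 100), (0, self.EPOCHS_3H), (5, 100)])
        wear = acc.detect_nonwear(res)
        assert not wear[100: 100 + self.EPOCHS_3H].any()
        assert wear[:100].all() and wear[-100:].all()

    def test_just_below_three_hours_not_flagged(self):
        res = self._res([(5, 100), (0, self.EPOCHS_3H - 1), (5, 100)])
        assert acc.detect_nonwear(res).all()

    def test_entire_recording_zero(self):
        wear = acc.detect_nonwear(np.zeros(self.EPOCHS_3H + 10))
        assert not wear.any()

    def test_short_recording_all_worn(self):
        assert acc.detect_nonwear(np.zeros(100)).all()

    def test_threshold_is_strict_below(self):
        # epochs at exactly the threshold count as movement
        res = self._res([(2, self.EPOCHS_3H + 10)])
        assert acc.detect_nonwear(res).all()


def _series_from_counts(counts, wrist, tz_start):
    return acc.EpochSeries(wrist=wrist, start_time=tz_start,
                           counts=np.asarray(counts))


class TestClassify:
    @pytest.mark.parametrize(
        "right, left, expected",
        [
            ((3, 0, 0), (1, 0, 0), Category.UNI_RIGHT),
            ((1, 0, 0), (3, 0, 0), Category.UNI_LEFT),
            ((2, 0, 0), (2, 0, 0), Category.BIMANUAL),  # threshold inclusive
            ((1, 1, 1), (0, 0, 0), Category.NO_MOVEMENT),  # resultant 1.73 < 2
            ((0, 0, 0), (0, 0, 0), Category.NO_MOVEMENT),
        ],
    )
    def test_rules(self, right, left, expected, tz_start):
        r = _series_from_counts([right], "right", tz_start)
        l = _series_from_counts([left], "left", tz_start)
        assert acc.classify_epochs(r, l)[0] == expected

    def test_nonwear_epochs_invalid(self, tz_start):
        r = _series_from_counts([[3, 0, 0]] * 4, "right", tz_start)
        l = _series_from_counts([[0, 0, 0]] * 4, "left", tz_start)
        mask = acc.WearMask(wear_right=[1, 1, 0, 0], wear_left=[1, 0, 1, 0])
        codes = acc.classify_epochs(r, l, mask)
        assert codes[0] == Category.UNI_RIGHT
        assert (codes[1:] == Category.INVALID).all()

    def test_grid_mismatch_rejected(self, tz_start):
        r = _series_from_counts([[3, 0, 0]] * 3, "right", tz_start)
        l = _series_from_counts([[3, 0, 0]] * 4, "left", tz_start)
        with pytest.raises(ValueError, match="grids differ"):
            acc.classify_epochs(r, l)


class TestTimeMetrics:
    def test_counting(self):
        codes = np.array(
            [Category.UNI_RIGHT] * 10 + [Category.BIMANUAL] * 5
            + [Category.NO_MOVEMENT] * 3, dtype=np.int8,
        )
        m = acc.time_metrics(codes)
        assert (m.time_r, m.time_l, m.time_b) == (20.0, 0.0, 10.0)
        assert m.wearing_time_s == 36.0
        assert m.no_movement_s == 6.0

    def test_all_invalid(self):
        m = acc.time_metrics(np.full(10, Category.INVALID, dtype=np.int8))
        assert m.wearing_time_s == 0.0
        assert m.time_r == m.time_l == m.time_b == 0.0

    def test_empty_interval(self, tz_start):
        codes = np.full(10, Category.UNI_RIGHT, dtype=np.int8)
        times = tz_start + pd.to_timedelta(np.arange(10) * 2, unit="s")
        m = acc.time_metrics(
            codes, times,
            interval=(tz_start + pd.Timedelta(hours=1),
                      tz_start + pd.Timedelta(hours=2)),
        )
        assert m.wearing_time_s == 0.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from([-1, 0, 1, 2, 3]), min_size=1, max_size=500))
    def test_conservation(self, codes):
        """TimeR + TimeL + TimeB + no-movement time == wearing time."""
        m = acc.time_metrics(np.array(codes, dtype=np.int8))
        assert m.time_r + m.time_l + m.time_b + m.no_movement_s == pytest.approx(
            m.wearing_time_s
        )
        assert m.wearing_time_s <= len(codes) * 2.0


class TestDailySummary:
    def test_percent_and_adherence(self, tz_start):
        # one day: 1 h wear, 25% TimeR
        codes = np.array(
            [Category.UNI_RIGHT] * 450 + [Category.NO_MOVEMENT] * 1350,
            dtype=np.int8,
        )
        times = tz_start + pd.to_timedelta(np.arange(1800) * 2, unit="s")
        out = acc.daily_summary(codes, times, waking_hours=17.0)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["wearing_hours"] == pytest.approx(1.0)
        assert row["time_r_pct"] == pytest.approx(25.0)
        assert row["adherence_pct"] == pytest.approx(100.0 / 17.0)

    def test_zero_wear_day_missing_not_zero(self, tz_start):
        codes = np.full(100, Category.INVALID, dtype=np.int8)
        times = tz_start + pd.to_timedelta(np.arange(100) * 2, unit="s")
        out = acc.daily_summary(codes, times)
        assert np.isnan(out.iloc[0]["time_r_pct"])

    def test_day_indexing_across_midnight(self, tz_start):
        codes = np.full(200, Category.NO_MOVEMENT, dtype=np.int8)
        t1 = tz_start + pd.to_timedelta(np.arange(100) * 2, unit="s")
        t2 = tz_start + pd.Timedelta(days=1) + pd.to_timedelta(np.arange(100) * 2, unit="s")
        out = acc.daily_summary(codes, t1.append(t2))
        assert list(out["day"]) == [1, 2]


class TestRawIO:
    def test_roundtrip(self, tmp_path, tz_start):
        rng = np.random.default_rng(0)
        rec = acc.RawRecording("left", tz_start, rng.normal(0, 0.1, (90, 3)))
        path = tmp_path / "raw.csv"
        acc.write_raw_csv(rec, path)
        back = acc.read_raw_csv(path)
        assert back.wrist == "left"
        assert back.start_time == rec.start_time
        assert back.sample_rate == 30.0
        np.testing.assert_allclose(back.samples, rec.samples, atol=1e-5)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("x,y,z\n0,0,1\n")
        with pytest.raises(ValueError, match="missing header"):
            acc.read_raw_csv(path)


class TestAlignment:
    def test_offset_trimmed_to_common_anchor(self, tz_start):
        rng = np.random.default_rng(1)
        r = acc.RawRecording("right", tz_start, rng.normal(0, 0.1, (300, 3)))
        l = acc.RawRecording(
            "left", tz_start + pd.Timedelta(seconds=2), rng.normal(0, 0.1, (300, 3))
        )
        r2, l2 = acc.align_recordings(r, l)
        assert r2.start_time == l2.start_time == tz_start + pd.Timedelta(seconds=2)
        assert r2.n_samples == l2.n_samples == 240
        np.testing.assert_array_equal(r2.samples, r.samples[60:])
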
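"""Tests for the synthetic study generator: signals, logs, whole studies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from armuse import accelerometry as acc
from armuse import ema
from armuse import synthetic_data as sd
from armuse.accelerometry import Category


def _process(right, left):
    """Run the standard chain on a pair of synthetic recordings."""
    series = {}
    for rec in (right, left):
        filtered = acc.bandpass_filter(rec)
        series[rec.wrist] = acc.epoch_counts(filtered, rec.start_time, rec.wrist)
    mask = acc.WearMask(
        wear_right=acc.detect_nonwear(series["right"]),
        wear_left=acc.detect_nonwear(series["left"]),
    )
    return acc.classify_epochs(series["right"], series["left"], mask), mask


class TestWristSignals:
    def test_rest_noise_free_is_constant(self):
        script = [sd.Bout(60.0, "rest")]
        right, left, truth = sd.generate_wrist_signals(script, noise_sd=0.0, seed=0)
        for rec in (right, left):
            assert np.ptp(rec.samples, axis=0).max() == 0.0
            assert rec.samples[0, 2] == 1.0  # gravity only
        assert (truth.categories == Category.NO_MOVEMENT).all()

    def test_uni_right_classified_from_signal(self):
        """Pipeline classification of every epoch matches the ground truth."""
        script = [sd.Bout(120.0, "uni_right", intensity_g=0.2, frequency_hz=1.0)]
        right, left, truth = sd.generate_wrist_signals(script, noise_sd=0.0, seed=1)
        codes, _ = _process(right, left)
        assert len(codes) == 60
        np.testing.assert_array_equal(codes, truth.categories)

    def test_bimanual_drives_both_wrists(self):
        script = [sd.Bout(60.0, "bimanual", intensity_g=0.25)]
        right, left, _ = sd.generate_wrist_signals(script, noise_sd=0.0, seed=2)
        assert np.ptp(right.samples[:, 0]) > 0.3
        assert np.ptp(left.samples[:, 0]) > 0.3

    def test_nonwear_block_detected_exactly(self):
        script = [
            sd.Bout(600.0, "bimanual", intensity_g=0.25),
            sd.Bout(3 * 3600.0, "nonwear_both"),
            sd.Bout(600.0, "bimanual", intensity_g=0.25),
        ]
        right, left, truth = sd.generate_wrist_signals(script, noise_sd=0.02, seed=3)
        filtered = acc.bandpass_filter(right)
        series = acc.epoch_counts(filtered, right.start_time, "right")
        wear = acc.detect_nonwear(series)
        np.testing.assert_array_equal(wear, truth.wear_right)

    def test_same_seed_identical_output(self):
        script = [sd.Bout(30.0, "uni_left", 0.2, 1.5), sd.Bout(10.0, "rest")]
        a = sd.generate_wrist_signals(script, seed=9)
        b = sd.generate_wrist_signals(script, seed=9)
        np.testing.assert_array_equal(a[0].samples, b[0].samples)
        np.testing.assert_array_equal(a[1].samples, b[1].samples)

    def test_out_of_band_frequency_rejected(self):
        with pytest.raises(ValueError, match="pass band"):
            sd.generate_wrist_signals([sd.Bout(10.0, "uni_right", 0.2, 5.0)])

    def test_partial_epoch_duration_rejected(self):
        with pytest.raises(ValueError, match="epochs"):
            sd.generate_wrist_signals([sd.Bout(3.0, "rest")])

    def test_swapping_streams_swaps_unimanual_classes(self):
        """Feeding the streams into the pipeline with wrists swapped mirrors
        TimeR and TimeL and leaves TimeB unchanged."""
        script = [sd.Bout(60.0, "uni_right", 0.2, 1.0),
                  sd.Bout(40.0, "bimanual", 0.25, 1.2),
                  sd.Bout(20.0, "rest")]
        right, left, _ = sd.generate_wrist_signals(script, noise_sd=0.02, seed=8)
        codes, _ = _process(right, left)
        swapped_r = acc.RawRecording("right", left.start_time, left.samples)
        swapped_l = acc.RawRecording("left", right.start_time, right.samples)
        codes_sw, _ = _process(swapped_r, swapped_l)
        m, m_sw = acc.time_metrics(codes), acc.time_metrics(codes_sw)
        assert m.time_r == m_sw.time_l
        assert m.time_l == m_sw.time_r
        assert m.time_b == m_sw.time_b

    def test_left_right_symmetry(self):
        """Mirrored scripts produce mirrored TimeR/TimeL, identical TimeB."""
        script_r = [sd.Bout(60.0, "uni_right", 0.2, 1.0),
                    sd.Bout(40.0, "bimanual", 0.25, 1.2)]
        script_l = [sd.Bout(60.0, "uni_left", 0.2, 1.0),
                    sd.Bout(40.0, "bimanual", 0.25, 1.2)]
        m_r = sd.script_metrics(script_r)
        m_l = sd.script_metrics(script_l)
        assert m_r.time_r == m_l.time_l == 60.0
        assert m_r.time_l == m_l.time_r == 0.0
        assert m_r.time_b == m_l.time_b == 40.0


class TestPromptLog:
    def test_deterministic_limit_all_answered(self):
        model = sd.BehaviorModel(answer_prob=1.0, duplicate_prob=0.0,
                                 self_trigger_rate=0.0, selftrigger_compensation=0.0,
                                 undelivered_prob=0.0)
        log, truth = sd.generate_prompt_log(model, seed=4)
        assert len(log) == 30
        assert (log["type"] == "scheduled").all()
        assert log["start_time"].notna().all()
        assert log["completion_time"].notna().all()

    def test_none_answered(self):
        model = sd.BehaviorModel(answer_prob=0.0, duplicate_prob=0.0,
                                 self_trigger_rate=0.0, selftrigger_compensation=0.0,
                                 undelivered_prob=0.0)
        log, _ = sd.generate_prompt_log(model, seed=4)
        assert log["start_time"].isna().all()
        records, _ = ema.parse_prompt_log(log)
        rates = ema.response_rates(records)
        assert rates.iloc[0]["response_rate_pct"] == 0.0

    def test_min_spacing_respected(self):
        model = sd.BehaviorModel(undelivered_prob=0.0, duplicate_prob=0.0)
        log, _ = sd.generate_prompt_log(model, seed=5)
        sched = log[log["type"] == "scheduled"]
        for _, day_grp in sched.groupby(sched["notify_time"].dt.date):
            gaps = day_grp["notify_time"].sort_values().diff().dropna()
            assert (gaps >= pd.Timedelta(minutes=120)).all()

    def test_infeasible_schedule_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            sd.BehaviorModel(prompts_per_day=10, min_spacing_min=120,
                             waking_hours=10.0)

    def test_duplicates_match_truth_after_dedup(self):
        model = sd.BehaviorModel(duplicate_prob=0.5, undelivered_prob=0.0,
                                 self_trigger_rate=0.0, selftrigger_compensation=0.0)
        log, truth = sd.generate_prompt_log(model, seed=6)
        true_dups = set(truth.loc[truth["duplicate_of"].notna(), "prompt_id"])
        assert true_dups, "seed produced no duplicates; pick another"
        records, _ = ema.parse_prompt_log(log)
        kept, removed = ema.dedup_prompts(records)
        assert set(removed["prompt_id"]) == true_dups

    def test_same_seed_identical_log(self):
        model = sd.BehaviorModel()
        a, _ = sd.generate_prompt_log(model, seed=11)
        b, _ = sd.generate_prompt_log(model, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_completion_duration_around_four_minutes(self):
        model = sd.BehaviorModel(answer_prob=1.0, undelivered_prob=0.0)
        log, _ = sd.generate_prompt_log(model, seed=12)
        ans = log[log["start_time"].notna()]
        dur = (ans["completion_time"] - ans["start_time"]).dt.total_seconds() / 60
        assert 2.0 < dur.mean() < 6.0

    def test_self_triggered_have_no_notification(self):
        model = sd.BehaviorModel(self_trigger_rate=3.0)
        log, _ = sd.generate_prompt_log(model, seed=13)
        self_t = log[log["type"] == "self_triggered"]
        assert len(self_t) > 0
        assert self_t["notify_time"].isna().all()
        assert self_t["start_time"].notna().all()


class TestStudy:
    def test_total_scheduled_prompts(self, tmp_path):
        """30 participants x 5 days x 6/day = 900 scheduled prompts."""
        study = sd.generate_study(30, tmp_path / "s", seed=1, write_signals=False)
        n_sched = 0
        for pid in study.participant_ids:
            truth = pd.DataFrame(study.ground_truth(pid)["prompt_truth"])
            sched = truth[(truth["type"] == "scheduled")
                          & truth["duplicate_of"].isna()]
            n_sched += len(sched)
        assert n_sched == 900

    def test_same_seed_byte_identical(self, tmp_path):
        sd.generate_study(2, tmp_path / "a", seed=5, write_signals=False)
        sd.generate_study(2, tmp_path / "b", seed=5, write_signals=False)
        for rel in sorted(p.relative_to(tmp_path / "a")
                          for p in (tmp_path / "a").rglob("*") if p.is_file()):
            assert (tmp_path / "a" / rel).read_bytes() == \
                (tmp_path / "b" / rel).read_bytes(), rel

    def test_single_participant_allowed(self, tmp_path):
        study = sd.generate_study(1, tmp_path / "one", seed=2, write_signals=False)
        assert study.participant_ids == ["P01"]

    def test_invalid_count_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="n_participants"):
            sd.generate_study(0, tmp_path / "zero")

    def test_day_script_fills_waking_day(self):
        rng = np.random.default_rng(3)
        script = sd.generate_day_script(sd.ActivityTemplate(), rng,
                                        waking_hours=17.0)
        total = sum(b.duration_s for b in script)
        assert total == pytest.approx(17.0 * 3600.0)
        m = sd.script_metrics(script)
        # exactly one detectable non-wear block
        nw = [b for b in script if b.mode == "nonwear_both"]
        assert len(nw) == 1 and nw[0].duration_s >= 3 * 3600


class TestSummaryTier:
    def test_daily_dataset_shape_and_null(self):
        df = sd.simulate_daily_dataset(n_participants=10, seed=0)
        assert len(df) == 50
        assert df["time_r_pct"].min() > 0
        assert not df.duplicated(["participant_id", "day"]).any()

    def test_reactivity_increment_raises_timer_only(self):
        null = sd.simulate_daily_dataset(n_participants=200, seed=1)
        inj = sd.simulate_daily_dataset(n_participants=200, seed=1,
                                        reactivity_daily_increment=0.10)
        # day-5 over day-1 geometric ratio reflects the injected drift
        def ratio(df, col):
            g = df.groupby("day")[col].apply(lambda x: np.exp(np.log(x).mean()))
            return g[5] / g[1]
        assert ratio(inj, "time_r_pct") / ratio(null, "time_r_pct") == pytest.approx(
            1.10**4, rel=0.05
        )
        assert ratio(inj, "time_l_pct") == pytest.approx(ratio(null, "time_l_pct"))

    def test_window_dataset_structure(self):
        df = sd.simulate_window_dataset(n_participants=5, seed=2)
        pre = df[df["phase"] == "pre"]
        post = df[df["phase"] == "post"]
        # post rows only for answered prompts
        assert post["answered"].all()
        sched_pre = pre[pre["prompt_type"] == "scheduled"]
        assert len(sched_pre) == 5 * 30
        assert df[["time_r_s", "time_l_s", "time_b_s"]].max().max() <= 600.0

    def test_post_boost_shifts_post_only(self):
        null = sd.simulate_window_dataset(n_participants=300, seed=3)
        inj = sd.simulate_window_dataset(n_participants=300, seed=3,
                                         post_prompt_boost=1.5)
        def med(df, phase):
            return df.loc[df["phase"] == phase, "time_r_s"].median()
        assert med(inj, "post") / med(null, "post") == pytest.approx(1.5, rel=0.08)
        assert med(inj, "pre") == pytest.approx(med(null, "pre"))

    def test_expected_bias_difference_sign(self):
        d = sd.expected_bias_difference(0.5, 0.95, movement_factor=2.0)
        assert d > 0.3
        assert sd.expected_bias_difference(0.5, 0.5) == pytest.approx(0.0)
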
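import numpy as np
import pandas as pd
import pytest

import circatemp as ct
from circatemp.series import MinuteSeries

START = pd.Timestamp("2021-03-01 12:00")


def minute_series(values, channel="chest", start=START, res=1):
    ts = pd.date_range(start, periods=len(values), freq=f"{res}min")
    return MinuteSeries(ts, np.asarray(values, dtype=float), channel)


class TestMasking:
    @pytest.mark.parametrize(
        "value,expect_missing",
        [(29.5, True), (35.0, False), (30.0, False)],  # strict < 30
    )
    def test_threshold_is_strict(self, value, expect_missing):
        s = minute_series([value] * 10)
        out = ct.mask_nonphysiological(s)
        assert np.isnan(out.values[0]) == expect_missing

    def test_idempotent_and_conserves_missing_count(self):
        vals = np.array([35.0, 22.0, np.nan, 36.0, 29.9])
        s = minute_series(vals)
        once = ct.mask_nonphysiological(s)
        twice = ct.mask_nonphysiological(once)
        np.testing.assert_array_equal(once.missing, twice.missing)
        assert once.missing.sum() >= s.missing.sum()

    def test_rejects_non_chest_channel(self):
        with pytest.raises(ValueError):
            ct.mask_nonphysiological(minute_series([37.0] * 5, channel="core_pill1"))


class TestPillTrimming:
    def test_out_of_band_removed_only_inside_window(self):
        vals = np.full(120, 37.0)
        vals[10] = 38.6  # inside window, out of band -> removed
        vals[45] = 38.6  # outside window -> kept
        s = minute_series(vals, channel="core_pill1")
        out = ct.trim_pill_transients(s, START)
        assert np.isnan(out.values[10])
        assert out.values[45] == 38.6
        assert out.values[11] == 37.0  # in-band kept

    def test_ingestion_outside_span_rejected(self):
        s = minute_series([37.0] * 60, channel="core_pill1")
        with pytest.raises(ValueError):
            ct.trim_pill_transients(s, START - pd.Timedelta(hours=1))


class TestStitching:
    def test_constant_segments_cut_at_elimination(self):
        p1 = minute_series([37.0] * (48 * 60), channel="core_pill1")
        p2 = minute_series([37.2] * (48 * 60), channel="core_pill2",
                           start=START + pd.Timedelta(hours=24))
        cut = START + pd.Timedelta(hours=36)
        out = ct.stitch_pills(p1, p2, cut)
        before = np.asarray(out.timestamps < cut)
        assert np.all(out.values[before] == 37.0)
        assert np.all(out.values[~before] == 37.2)
        assert out.channel == "core"

    def test_identical_pills_identity(self):
        p1 = minute_series(np.linspace(36.8, 37.2, 48 * 60), channel="core_pill1")
        p2 = MinuteSeries(p1.timestamps, p1.values, "core_pill2")
        out = ct.stitch_pills(p1, p2, START + pd.Timedelta(hours=20))
        np.testing.assert_allclose(out.values, p1.values)

    def test_coverage_hole_flagged_missing_with_warning(self):
        p1 = minute_series([37.0] * (24 * 60), channel="core_pill1")
        p2 = minute_series([37.2] * (24 * 60), channel="core_pill2",
                           start=START + pd.Timedelta(hours=30))
        cut = START + pd.Timedelta(hours=20)
        with pytest.warns(UserWarning, match="coverage hole"):
            out = ct.stitch_pills(p1, p2, cut)
        hole = np.asarray(
            (out.timestamps >= cut) & (out.timestamps < START + pd.Timedelta(hours=30))
        )
        assert np.all(np.isnan(out.values[hole]))

    def test_stitched_noisy_pills_track_truth_no_worse_than_single_pill(self, rng):
        truth = ct.RhythmTruth(37.0, 0.4, 15.5, noise_sd=0.0)
        clean = ct.generate_temperature_series(truth, n_days=2, seed=1, channel="core_pill1")
        noise1 = rng.normal(0, 0.1, len(clean))
        noise2 = rng.normal(0, 0.1, len(clean))
        p1 = MinuteSeries(clean.timestamps, clean.values + noise1, "core_pill1")
        p2 = MinuteSeries(clean.timestamps, clean.values + noise2, "core_pill2")
        cut = START + pd.Timedelta(hours=24)
        out = ct.stitch_pills(p1, p2, cut)
        rmse = lambda s: np.sqrt(np.nanmean((s.values - clean.values) ** 2))
        assert rmse(out) <= max(rmse(p1), rmse(p2)) + 1e-12


class TestBinningAndSmoothing:
    def test_bin_mean_with_partial_and_empty_bins(self):
        vals = [36.0, 36.2, 36.4, 36.6, 36.8,  # full bin -> 36.4
                36.0, np.nan, np.nan, np.nan, 37.0,  # partial -> 36.5
                np.nan, np.nan, np.nan, np.nan, np.nan]  # empty -> missing
        out = ct.bin_5min(minute_series(vals))
        assert out.values[0] == pytest.approx(36.4)
        assert out.values[1] == pytest.approx(36.5)
        assert np.isnan(out.values[2])

    def test_binning_5min_series_is_identity(self):
        s = minute_series(np.linspace(35, 36, 60), res=5)
        out = ct.bin_5min(s)
        np.testing.assert_array_equal(out.values, s.values)

    def test_smoother_preserves_constants(self):
        s = minute_series([36.0] * 288, res=5)
        out = ct.smooth_moving_average(s)
        np.testing.assert_allclose(out.values, 36.0)

    def test_smoother_attenuates_24h_cosine_by_boxcar_factor(self):
        t = np.arange(288 * 3) * 5 / 60.0
        s = minute_series(np.cos(2 * np.pi * t / 24.0), res=5)
        out = ct.smooth_moving_average(s)
        # symmetric 13-tap (half-weight ends) attenuation of a 24-h cosine
        k = np.arange(13) - 6
        w = np.ones(13)
        w[0] = w[-1] = 0.5
        expected = np.sum(w * np.cos(2 * np.pi * k * (5 / 60) / 24)) / w.sum()
        interior = slice(12, -12)
        ratio = out.values[interior] / s.values[interior]
        finite = np.isfinite(ratio) & (np.abs(s.values[interior]) > 0.3)
        assert np.allclose(ratio[finite], expected, atol=1e-10)
        assert expected == pytest.approx(0.9971, abs=2e-3)

    def test_single_present_point_passes_through(self):
        vals = np.full(288, np.nan)
        vals[100] = 36.5
        out = ct.smooth_moving_average(minute_series(vals, res=5))
        assert out.values[100] == pytest.approx(36.5)


class TestDayProfile:
    def test_identical_days_average_to_single_day(self):
        truth = ct.RhythmTruth(35.0, 1.0, 3.0, amp12=0.4, phase12=7.0, noise_sd=0.0)
        s = ct.generate_temperature_series(truth, n_days=7, resolution=5, seed=1)
        prof = ct.day_profile(ct.bin_5min(s))
        np.testing.assert_allclose(prof.values, s.values[:288], atol=1e-12)
        assert np.all(prof.counts == 7)

    def test_averaging_reduces_noise_vs_single_day(self, rng):
        truth = ct.RhythmTruth(35.0, 1.0, 3.0, noise_sd=0.3, noise_autocorr=0.0)
        s = ct.generate_temperature_series(truth, n_days=7, resolution=5, seed=2)
        prof = ct.day_profile(ct.bin_5min(s))
        clean = truth.signal((12.0 + prof.time_hours) % 24.0)
        rmse_profile = np.sqrt(np.mean((prof.values - clean) ** 2))
        rmse_day = np.sqrt(np.mean((s.values[:288] - clean) ** 2))
        assert rmse_profile < rmse_day

    def test_bin_missing_on_all_days_stays_missing(self):
        truth = ct.RhythmTruth(35.0, 1.0, 3.0, noise_sd=0.0)
        s = ct.generate_temperature_series(truth, n_days=3, resolution=5, seed=3)
        vals = s.values.copy()
        bins = np.arange(len(vals)) % 288
        vals[bins == 17] = np.nan
        prof = ct.day_profile(s.copy_with(vals))
        assert np.isnan(prof.values[17])
        assert prof.counts[17] == 0
        assert np.isfinite(prof.values[16]) and np.isfinite(prof.values[18])


class TestHourlyMeans:
    def test_partial_hour_uses_available_minutes(self):
        truth = ct.RhythmTruth(35.0, 0.0, 0.0, noise_sd=0.0)
        s = ct.generate_temperature_series(truth, n_days=2, seed=4)
        vals = s.values.copy()
        vals[:40] = np.nan  # 20 of 60 minutes left in hour 0
        vals[40:60] = 36.0
        h = ct.hourly_means(s.copy_with(vals))
        assert h.values[0] == pytest.approx(36.0)
        assert not h.imputed[0]

    def test_fully_missing_hour_linearly_imputed_and_flagged(self):
        s = minute_series([35.0] * 60 + [np.nan] * 60 + [37.0] * (60 * 23))
        h = ct.hourly_means(s)
        assert h.values[1] == pytest.approx((35.0 + 37.0) / 2)
        assert h.imputed[1]
        assert not h.imputed[0] and not h.imputed[2]

    def test_gap_longer_than_7h_drops_the_24h_segment(self):
        truth = ct.RhythmTruth(35.0, 0.8, 3.0, noise_sd=0.1)
        s = ct.generate_temperature_series(truth, n_days=7, seed=5)
        vals = s.values.copy()
        # 8-h gap inside day 3 (hours 50..58 from start)
        vals[50 * 60:58 * 60] = np.nan
        h = ct.hourly_means(s.copy_with(vals))
        assert h.dropped_segments == [2]
        dropped = ~h.retained
        assert dropped.sum() == 24
        assert np.all(np.isnan(h.values[dropped]))
        # exactly 6 retained full days
        assert h.retained_hours == 6 * 24

    def test_7h_gap_exactly_is_not_dropped(self):
        truth = ct.RhythmTruth(35.0, 0.8, 3.0, noise_sd=0.1)
        s = ct.generate_temperature_series(truth, n_days=3, seed=6)
        vals = s.values.copy()
        vals[30 * 60:37 * 60] = np.nan  # exactly 7 h
        h = ct.hourly_means(s.copy_with(vals))
        assert h.dropped_segments == []
        assert h.imputed.sum() == 7


class TestPipeline:
    def test_minute_count_never_increases_through_mask_trim(self):
        truth = ct.RhythmTruth(35.0, 0.8, 3.0, noise_sd=0.3)
        art = ct.ArtifactConfig(sensoroff_rate=2.0, missing_rate=0.05)
        s = ct.generate_temperature_series(truth, art, n_days=3, seed=7)
        masked = ct.mask_nonphysiological(s)
        assert (~masked.missing).sum() <= (~s.missing).sum()

    def test_full_temperature_pipeline_products(self):
        subjects, _ = ct.generate_cohort(n_subjects=2, seed=10)
        streams = ct.simulate_subject_streams(subjects[0], chest_days=4, core_days=3)
        out = ct.preprocess_temperature(
            chest=streams["chest"],
            pills=(streams["core_pill1"], streams["core_pill2"]),
            ingestion_times=streams["ingestion_times"],
            elimination_time_pill1=streams["elimination_time_pill1"],
        )
        for ch in ("chest", "core"):
            assert out[ch]["profile"].values.shape == (288,)
            assert out[ch]["hourly"].retained_hours >= 24
        # stitched core must not keep ingestion transients
        core5 = out["core"]["series_5min"]
        finite = core5.values[np.isfinite(core5.values)]
        assert np.all((finite > 34.0) & (finite < 39.5))
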
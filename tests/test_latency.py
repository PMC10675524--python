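"""Resampling, quality masking, anchoring, cross-correlation and latency."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from facemimic.design import GroundTruthParams
from facemimic.latency import (
    QualityThresholds,
    aggregate_xcorr,
    apply_quality_mask,
    cross_correlation,
    group_average_timeseries,
    lag_to_ms,
    resample_emg_to_frames,
    zero_anchor,
)
from facemimic.synthetic import TrialRecording, drive

FPS = 29.97


def _trial(au12=None, quality=None, tag="generic", n=90):
    au12 = np.linspace(0, 1, n) if au12 is None else np.asarray(au12, float)
    quality = np.ones(n) if quality is None else np.asarray(quality, float)
    return TrialRecording(
        subject=0,
        trial=0,
        emotion="positive",
        presentation="live",
        emg_zm=np.zeros(10),
        emg_cs=np.zeros(10),
        au12=au12,
        au4=np.zeros(len(au12)),
        quality=quality,
        onset_index=5,
        emg_rate_hz=2.0,
        au_fps=FPS,
        software_tag=tag,
    )


class TestResample:
    def test_three_seconds_gives_90_frames(self):
        x = np.random.default_rng(0).standard_normal(6000)
        out = resample_emg_to_frames(x, 1000.0, onset_index=3000)
        assert out.shape == (90,)

    def test_constant_preserved(self):
        out = resample_emg_to_frames(np.full(4000, 2.5), 1000.0, onset_index=0)
        np.testing.assert_allclose(out, 2.5)

    def test_matches_bin_mean_oracle(self):
        x = np.arange(3000, dtype=float)
        out = resample_emg_to_frames(x, 1000.0, onset_index=0)
        # direct summation per half-open time bin
        for i in (0, 1, 45, 89):
            members = [
                v
                for s, v in enumerate(x)
                if i / FPS <= s / 1000.0 < (i + 1) / FPS
            ]
            assert out[i] == pytest.approx(np.mean(members))

    def test_short_trace_raises(self):
        with pytest.raises(ValueError):
            resample_emg_to_frames(np.zeros(1000), 1000.0, onset_index=0)


class TestQualityMask:
    def test_perfect_quality_unchanged(self):
        tr = _trial()
        masked, reason = apply_quality_mask(tr)
        assert reason == "ok"
        np.testing.assert_array_equal(masked.au12, tr.au12)

    def test_openface_zero_series_excluded(self):
        tr = _trial(au12=np.zeros(90), tag="openface_like")
        masked, reason = apply_quality_mask(tr)
        assert masked is None and reason == "zero_output"

    def test_single_bad_frame_excludes_under_any_frame_policy(self):
        q = np.ones(90)
        q[10] = 0.5
        tr = _trial(quality=q, tag="facereader_like")
        masked, reason = apply_quality_mask(tr)
        assert masked is None and reason == "low_quality"

    def test_fraction_policy_masks_but_keeps(self):
        q = np.ones(90)
        q[10] = 0.5
        tr = _trial(quality=q, tag="facereader_like")
        th = QualityThresholds(exclusion_policy="fraction", max_bad_fraction=0.1)
        masked, reason = apply_quality_mask(tr, th)
        assert reason == "ok"
        assert np.isnan(masked.au12[10]) and np.isfinite(masked.au12[11])

    def test_unknown_tag_rejected(self):
        tr = _trial()
        tr.software_tag = "mystery"
        with pytest.raises(ValueError):
            apply_quality_mask(tr)


class TestZeroAnchor:
    def test_basic_shift(self):
        np.testing.assert_allclose(zero_anchor(np.array([3.0, 4, 5])), [0, 1, 2])

    def test_idempotent(self):
        x = np.array([0.0, 1.5, -2.0])
        np.testing.assert_allclose(zero_anchor(zero_anchor(x)), zero_anchor(x))

    @given(
        hnp.arrays(np.float64, st.integers(2, 30), elements=st.floats(-1e6, 1e6))
    )
    def test_first_zero_and_differences_preserved(self, x):
        out = zero_anchor(x)
        assert out[0] == 0.0
        np.testing.assert_allclose(np.diff(out), np.diff(x), rtol=0, atol=1e-6)

    def test_missing_first_value_anchors_at_first_finite(self):
        out = zero_anchor(np.array([np.nan, 2.0, 3.0]))
        assert np.isnan(out[0]) and out[1] == 0.0 and out[2] == 1.0


class TestGroupAverage:
    def test_identical_trials_zero_se(self):
        x = np.linspace(0, 1, 10)
        df = group_average_timeseries([("c", "zm", x), ("c", "zm", x)])
        assert (df["se"].abs() < 1e-12).all()

    def test_two_trial_means(self):
        df = group_average_timeseries(
            [("c", "zm", np.array([0.0, 2.0])), ("c", "zm", np.array([0.0, 4.0]))]
        )
        np.testing.assert_allclose(df.sort_values("frame")["mean"].to_numpy(), [0.0, 3.0])

    def test_cohort_mean_tracks_drive_envelope(self):
        """Per-frame mean of anchored AU12 stays within 3 SE of the drive."""
        p = GroundTruthParams(
            seed=0, trial_gain_sd=0.0, re_intercept_sd=0.0, re_emotion_slope_sd=0.0
        )
        rng = np.random.default_rng(2)
        frames = np.arange(90)
        d = drive(frames / FPS - p.au_latency_frames / FPS, p)
        series = []
        for _ in range(100):
            noise = rng.normal(0, p.au_noise_sd, 90)
            noise = np.convolve(noise, np.ones(3) / 3, mode="same")
            series.append(("positive_video", "au12", p.au_scale * 1.0 * d + noise))
        df = group_average_timeseries(series).sort_values("frame")
        expected = p.au_scale * (d - d[0])
        resid = df["mean"].to_numpy() - expected
        ok = np.abs(resid) <= 3 * df["se"].to_numpy() + 1e-12
        assert ok.mean() >= 0.9


class TestCrossCorrelation:
    def test_autocorrelation_peak_at_zero(self, rng):
        x = rng.standard_normal(120)
        res = cross_correlation(x, x, max_lag=45)
        assert res.peak_lag == 0
        assert res.r_at(0) == pytest.approx(1.0, abs=1e-9)

    def test_injected_shift_recovered_noise_free(self):
        p = GroundTruthParams()
        x = drive(np.arange(90) / FPS, p)
        y = np.concatenate([np.zeros(4), x[:-4]])
        res = cross_correlation(x, y, max_lag=45)
        assert res.peak_lag == 4
        assert res.latency_ms == lag_to_ms(4)

    def test_symmetry_under_argument_swap(self, rng):
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        a = cross_correlation(x, y, max_lag=20, peak_search="full")
        b = cross_correlation(y, x, max_lag=20, peak_search="full")
        np.testing.assert_allclose(a.r_by_lag, b.r_by_lag[::-1], atol=1e-12)

    def test_bounded(self, rng):
        x = rng.standard_normal(95)
        y = rng.standard_normal(95)
        res = cross_correlation(x, y, max_lag=45)
        finite = res.r_by_lag[np.isfinite(res.r_by_lag)]
        assert (np.abs(finite) <= 1 + 1e-9).all()

    def test_zero_variance_flagged(self):
        res = cross_correlation(np.ones(100), np.arange(100.0), max_lag=45)
        assert not res.valid and np.isnan(res.peak_r)

    def test_full_series_convention_matches_direct_oracle(self, rng):
        """full_series method equals the fixed-length normalization computed
        independently (standardize once, divide lagged sums by T)."""
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        res = cross_correlation(x, y, max_lag=10, method="full_series", peak_search="full")
        T = 100
        x0 = (x - x.mean()) / x.std()
        y0 = (y - y.mean()) / y.std()
        for i, k in enumerate(range(-10, 11)):
            expected = sum(
                x0[t] * y0[t + k] for t in range(T) if 0 <= t + k < T
            ) / T
            assert res.r_by_lag[i] == pytest.approx(expected, abs=1e-12)

    def test_length_requirement(self):
        with pytest.raises(ValueError):
            cross_correlation(np.zeros(50), np.zeros(50), max_lag=45)


class TestAggregate:
    def test_identical_trials_equal_single_curve(self, rng):
        x = rng.standard_normal(100)
        y = np.roll(x, 3)
        res = cross_correlation(x, y, max_lag=20)
        group = aggregate_xcorr([res, res, res], [0, 0, 1], ["live"] * 3)["live"]
        np.testing.assert_allclose(group.r_by_lag, res.r_by_lag, atol=1e-12)
        assert res.peak_lag in group.peak_lags

    def test_plateau_ties_reported_as_range(self):
        res = cross_correlation(np.sin(np.arange(100) / 5), np.sin(np.arange(100) / 5), 20)
        flat = res
        flat.r_by_lag = np.round(flat.r_by_lag, 0)  # force massive ties
        group = aggregate_xcorr([flat], [0], ["c"], tie_decimals=0)["c"]
        assert len(group.peak_lags) >= 2


class TestLagConversion:
    @pytest.mark.parametrize(
        "lag,ms", [(0, 0), (1, 33), (2, 67), (3, 100), (5, 167), (6, 200), (9, 300)]
    )
    def test_nearest_millisecond(self, lag, ms):
        assert lag_to_ms(lag, 29.97) == ms

    def test_max_lag_window_near_1500_ms(self):
        assert 1.50 <= 45 / 29.97 <= 1.51

    def test_invalid_fps(self):
        with pytest.raises(ValueError):
            lag_to_ms(1, 0.0)
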
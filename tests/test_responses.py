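"""Trial responses, sign congruence and mimicry confusion metrics."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from facemimic.design import GroundTruthParams, SessionDesign
from facemimic.preprocess import PreprocParams
from facemimic.responses import (
    ConfusionCounts,
    ResponseWindows,
    classify_mimicry_trial,
    detection_metrics,
    mimicry_confusion,
    response_pairs,
    sign_congruence_accuracy,
    trial_response,
    zero_output_report,
)
from facemimic.synthetic import TrialRecording, simulate_cohort

FPS = 29.97


class TestTrialResponse:
    def test_constant_series_is_zero(self):
        assert trial_response(np.full(90, 2.5), FPS) == pytest.approx(0.0)

    def test_step_height_recovered(self):
        t = np.arange(3000) / 1000.0
        x = np.where(t >= 1.5, 0.7, 0.0)
        assert trial_response(x, 1000.0) == pytest.approx(0.7)

    def test_frame_series_matches_window_mean_oracle(self):
        x = np.zeros(90)
        x[30:75] = np.linspace(0, 1, 45, endpoint=False)
        x[75:] = 1.0
        expected = x[75:90].mean() - x[0:30].mean()
        assert trial_response(x, FPS) == pytest.approx(expected, abs=1e-12)

    def test_window_outside_series_raises(self):
        with pytest.raises(ValueError):
            trial_response(np.zeros(10), FPS)


class TestSignCongruence:
    def test_all_same_signed(self):
        df = pd.DataFrame({"emg_response": [1.0, -1, 2], "au_response": [0.5, -3, 1]})
        assert sign_congruence_accuracy(df) == 1.0

    def test_four_quadrant_symmetry(self):
        df = pd.DataFrame(
            {"emg_response": [1.0, 1.0, -1.0, -1.0], "au_response": [1.0, -1.0, -1.0, 1.0]}
        )
        assert sign_congruence_accuracy(df) == 0.5

    def test_matches_enumeration_oracle(self, rng):
        emg = rng.standard_normal(20)
        au = rng.standard_normal(20)
        df = pd.DataFrame({"emg_response": emg, "au_response": au})
        expected = sum(((e > 0) == (a > 0)) for e, a in zip(emg, au)) / 20
        assert sign_congruence_accuracy(df) == pytest.approx(expected)

    def test_exclusions_removed_from_denominator(self):
        df = pd.DataFrame(
            {
                "emg_response": [1.0, 1.0],
                "au_response": [1.0, -1.0],
                "exclude_reason": ["none", "zero_output"],
            }
        )
        assert sign_congruence_accuracy(df) == 1.0
        assert sign_congruence_accuracy(df, include_zero_output=True) == 0.5

    def test_empty_after_exclusion_raises(self):
        df = pd.DataFrame(
            {"emg_response": [1.0], "au_response": [1.0], "exclude_reason": ["artifact"]}
        )
        with pytest.raises(ValueError):
            sign_congruence_accuracy(df)


class TestClassify:
    @pytest.mark.parametrize(
        "au12,zm,expected",
        [(0.05, 0.1, "TP"), (0.0, 0.1, "FN"), (-0.2, -0.1, "TN"), (0.2, -0.1, "FP")],
    )
    def test_single_channel(self, au12, zm, expected):
        assert classify_mimicry_trial(au12, None, zm, None, "single_channel") == expected

    @pytest.mark.parametrize(
        "au12,au4,zm,cs,expected",
        [
            (0.1, -0.1, 0.2, -0.2, "TP"),
            (0.1, 0.2, 0.2, -0.2, "FN"),  # AU4 co-activation counts as non-detection
            (0.1, -0.1, 0.2, 0.3, "FP"),  # CS co-activation breaks muscular truth
            (-0.1, 0.1, -0.2, 0.1, "TN"),
        ],
    )
    def test_compound(self, au12, au4, zm, cs, expected):
        assert classify_mimicry_trial(au12, au4, zm, cs, "compound") == expected

    def test_compound_requires_all_channels(self):
        with pytest.raises(ValueError):
            classify_mimicry_trial(0.1, None, 0.1, None, "compound")


class TestDetectionMetrics:
    def test_symmetric_counts(self):
        m = detection_metrics(ConfusionCounts(tp=10, fp=10, tn=10, fn=10))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (0.5, 0.5, 0.5, 0.5)

    def test_hand_computed_example(self):
        m = detection_metrics(ConfusionCounts(tp=6, fp=2, tn=8, fn=4))
        assert m.sensitivity == pytest.approx(0.6)
        assert m.specificity == pytest.approx(0.8)
        assert m.ppv == pytest.approx(0.75)
        assert m.f1 == pytest.approx(2 * 6 / (2 * 6 + 2 + 4))

    def test_perfect_classifier(self):
        m = detection_metrics(ConfusionCounts(tp=5, tn=7))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.f1) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_undefined_ratio_is_nan_not_zero(self):
        m = detection_metrics(ConfusionCounts(tn=5, fn=5))
        assert m.sensitivity == 0.0  # tp+fn = 5
        assert math.isnan(m.ppv)  # tp+fp = 0, undefined
        assert math.isnan(detection_metrics(ConfusionCounts()).f1)


class TestConfusionOnCohorts:
    def test_counts_conserve_classified_trials(self, stats_pairs):
        counts = mimicry_confusion(stats_pairs, mode="single_channel", au_channel="au12")
        n_positive = (stats_pairs["emotion"] == "positive").sum()
        assert counts.total == n_positive

    def test_matches_bruteforce_enumeration(self, stats_pairs):
        counts = mimicry_confusion(stats_pairs, mode="compound", au_channel="au12")
        sub = stats_pairs[stats_pairs["emotion"] == "positive"]
        labels = [
            classify_mimicry_trial(
                r.au12_response, r.au4_response, r.zm_response, r.cs_response, "compound"
            )
            for r in sub.itertuples()
        ]
        assert counts.tp == labels.count("TP")
        assert counts.fp == labels.count("FP")
        assert counts.tn == labels.count("TN")
        assert counts.fn == labels.count("FN")

    def test_strong_coupling_low_noise_f1_near_one(self, fast_preproc):
        p = GroundTruthParams(
            seed=0, au_noise_sd=0.005, trial_gain_sd=0.1, re_intercept_sd=0.1,
            re_emotion_slope_sd=0.1,
        )
        d = SessionDesign(n_subjects=6, trials_per_condition=4, emg_rate_hz=500.0)
        pairs = response_pairs(simulate_cohort(d, p, seed=21), preproc=fast_preproc)
        m = detection_metrics(mimicry_confusion(pairs))
        assert m.f1 > 0.9

    def test_zero_coupling_sensitivity_near_base_rate(self, fast_preproc):
        null = GroundTruthParams(
            seed=0, zm_gain_pos_video=0.0, cs_gain_neg=0.0, live_amplification=1.0
        )
        d = SessionDesign(n_subjects=10, trials_per_condition=8, emg_rate_hz=500.0)
        pairs = response_pairs(simulate_cohort(d, null, seed=22), preproc=fast_preproc)
        m = detection_metrics(mimicry_confusion(pairs))
        base_rate = (pairs[pairs["emotion"] == "positive"]["au12_response"] > 0).mean()
        assert abs(m.sensitivity - base_rate) < 0.15


def _tiny_trial(au12, subject=0, trial=0):
    n = len(au12)
    return TrialRecording(
        subject=subject,
        trial=trial,
        emotion="positive",
        presentation="live",
        emg_zm=np.zeros(4),
        emg_cs=np.zeros(4),
        au12=np.asarray(au12, float),
        au4=np.zeros(n),
        quality=np.ones(n),
        onset_index=2,
        emg_rate_hz=2.0,
        au_fps=1.0,
    )


class TestZeroOutputReport:
    def test_no_zero_trials(self):
        trials = [_tiny_trial([0.1, 0.2, 0.3]) for _ in range(5)]
        assert zero_output_report(trials) == (0, 5, 0.0)

    def test_display_rounding_three_sig_figs(self):
        trials = [_tiny_trial([0.0, 0.0]) for _ in range(136)] + [
            _tiny_trial([0.1, 0.2]) for _ in range(164)
        ]
        n_zero, n_total, prop = zero_output_report(trials)
        assert (n_zero, n_total) == (136, 300)
        assert prop == pytest.approx(0.453, abs=1e-9)

    def test_cohort_rate_within_binomial_ci(self, fast_preproc):
        p = replace(GroundTruthParams(seed=0), p_zero_output=0.3)
        d = SessionDesign(n_subjects=6, trials_per_condition=6, emg_rate_hz=500.0)
        trials = simulate_cohort(d, p, software_tag="openface_like", seed=8)
        n_zero, n_total, prop = zero_output_report(trials)
        se = math.sqrt(0.3 * 0.7 / n_total)
        assert abs(n_zero / n_total - 0.3) < 2.58 * se


def test_windows_must_be_disjoint():
    with pytest.raises(ValueError):
        ResponseWindows(neutral_s=(0.0, 2.6), maximal_s=(2.5, 3.0))
    with pytest.raises(ValueError):
        ResponseWindows(neutral_s=(2.0, 1.0))
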
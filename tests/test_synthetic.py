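"""Generator behavior: drive shape, latent coupling, determinism, bookkeeping."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from facemimic.design import DesignError, GroundTruthParams, SessionDesign
from facemimic.preprocess import PreprocParams
from facemimic.responses import response_pairs, sign_congruence_accuracy, trial_response
from facemimic.synthetic import drive, enumerate_trials, simulate_cohort, simulate_trial

FAST = SessionDesign(n_subjects=4, trials_per_condition=2, emg_rate_hz=500.0)


class TestDrive:
    @pytest.mark.parametrize(
        "t,expected",
        [(0.5, 0.0), (1.0, 0.0), (2.5, 1.0), (2.9, 1.0), (1.75, 0.5)],
    )
    def test_ramp_shape(self, t, expected):
        assert drive(t, GroundTruthParams()) == pytest.approx(expected)

    @given(st.floats(min_value=0.0, max_value=3.0), st.floats(min_value=0.0, max_value=3.0))
    def test_monotone_and_bounded(self, t1, t2):
        p = GroundTruthParams()
        d1, d2 = drive(t1, p), drive(t2, p)
        assert 0.0 <= d1 <= 1.0
        if t1 <= t2:
            assert d1 <= d2 + 1e-12


class TestSimulateTrial:
    def test_null_generator_gives_exactly_zero_responses(self):
        """All gains and noise sources zero -> EMG and AU responses exactly 0."""
        p = GroundTruthParams(
            zm_gain_pos_video=0.0,
            cs_gain_neg=0.0,
            live_amplification=1.0,
            au_noise_sd=0.0,
            au_drift_per_frame=0.0,
            emg_baseline_sd=0.0,
        )
        rng = np.random.default_rng(0)
        tr = simulate_trial(FAST, p, "positive", "live", rng)
        assert np.all(tr.emg_zm == 0.0)
        assert np.all(tr.au12 == 0.0)
        assert trial_response(tr.au12, tr.au_fps) == 0.0

    def test_live_amplification_raises_zm_response(self, fast_preproc):
        """Mean log-amplitude ZM response is larger live than video (MC)."""
        p = GroundTruthParams(seed=0, zm_gain_pos_video=1.0, live_amplification=1.5)
        rng = np.random.default_rng(10)
        resp = {"live": [], "video": []}
        for pres in ("live", "video"):
            for _ in range(250):
                tr = simulate_trial(FAST, p, "positive", pres, rng)
                pairs = response_pairs([tr], preproc=fast_preproc)
                resp[pres].append(pairs["zm_response"].iloc[0])
        assert np.mean(resp["live"]) > np.mean(resp["video"])

    def test_seeded_determinism(self):
        p = GroundTruthParams()
        a = simulate_trial(FAST, p, "positive", "live", np.random.default_rng(5))
        b = simulate_trial(FAST, p, "positive", "live", np.random.default_rng(5))
        np.testing.assert_array_equal(a.emg_zm, b.emg_zm)
        np.testing.assert_array_equal(a.au12, b.au12)
        np.testing.assert_array_equal(a.quality, b.quality)

    def test_invalid_condition_labels_rejected(self):
        with pytest.raises(DesignError):
            simulate_trial(FAST, GroundTruthParams(), "happy", "live", np.random.default_rng(0))

    def test_zero_output_rate_matches_probability(self):
        """openface_like whole-trial zeros occur at the configured rate."""
        p = replace(GroundTruthParams(), p_zero_output=0.3)
        rng = np.random.default_rng(3)
        n = 400
        zeros = 0
        for _ in range(n):
            tr = simulate_trial(FAST, p, "negative", "video", rng, software_tag="openface_like")
            zeros += bool(np.all(tr.au12 == 0.0))
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(zeros / n - 0.3) < 2.58 * se + 1e-9

    def test_generic_tag_never_zeroed(self):
        p = replace(GroundTruthParams(), p_zero_output=1.0)
        tr = simulate_trial(FAST, p, "positive", "live", np.random.default_rng(1))
        assert not np.all(tr.au12 == 0.0)


class TestCohort:
    @pytest.mark.parametrize(
        "n_subjects,tpc,expected",
        [(2, 1, 8), (4, 2, 32), (5, 3, 60)],
    )
    def test_trial_counts(self, n_subjects, tpc, expected):
        d = SessionDesign(n_subjects=n_subjects, trials_per_condition=tpc, emg_rate_hz=500.0)
        assert len(enumerate_trials(d)) == expected

    def test_live_mishap_exclusion_drops_four(self):
        d = SessionDesign(n_subjects=5, trials_per_condition=3, emg_rate_hz=500.0)
        full = enumerate_trials(d)
        reduced = enumerate_trials(d, exclude_live_mishaps=True)
        assert len(full) - len(reduced) == 4
        # one positive-live trial from each of two subjects, one negative-live
        # from each of two others
        diff = full.merge(reduced, how="left", indicator=True)
        gone = diff[diff["_merge"] == "left_only"]
        assert (gone["presentation"] == "live").all()
        assert sorted(gone["emotion"]) == ["negative", "negative", "positive", "positive"]

    def test_cohort_determinism(self, small_design, default_params):
        a = simulate_cohort(small_design, default_params, seed=9)
        b = simulate_cohort(small_design, default_params, seed=9)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.emg_zm, tb.emg_zm)
            np.testing.assert_array_equal(ta.au12, tb.au12)

    def test_null_gains_give_chance_level_congruence(self):
        """With all gains zero, AU/EMG sign congruence sits at chance."""
        null = GroundTruthParams(
            zm_gain_pos_video=0.0, cs_gain_neg=0.0, live_amplification=1.0, seed=0
        )
        d = SessionDesign(n_subjects=20, trials_per_condition=25, emg_rate_hz=500.0)
        trials = simulate_cohort(d, null, seed=17)
        pairs = response_pairs(trials, preproc=PreprocParams.for_rate(500.0))
        acc = sign_congruence_accuracy(pairs)
        assert len(pairs) >= 2000
        assert abs(acc - 0.5) < 0.05


def test_frame_count_invariant():
    assert SessionDesign().n_frames == 90
    assert SessionDesign(trial_duration_s=2.0).n_frames == 60


def test_pad_invariant_enforced():
    with pytest.raises(DesignError):
        SessionDesign(prestimulus_pad_s=1.0)
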
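"""Generator: layout arithmetic, observer model, calibration, determinism."""


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import msite
from msite.simulate import MAIN_BLOCK_TYPES


class TestTargetOnset:
    @pytest.mark.parametrize(
        "position,expected_ms", [(1, 0), (3, 400), (9, 1600), (11, 2000)]
    )
    def test_default_timing(self, default_config, position, expected_ms):
        assert msite.target_onset_ms(position, default_config) == expected_ms

    @pytest.mark.parametrize("position", [0, 12, -3])
    def test_out_of_range_position_rejected(self, default_config, position):
        with pytest.raises(ValueError, match="position_index"):
            msite.target_onset_ms(position, default_config)


class TestSessionLayout:
    def test_main_trial_counts_match_design(self, default_config):
        layout = msite.build_session_layout(default_config, 1, 1, rng_seed=3)
        main = layout[layout.block_type.isin(MAIN_BLOCK_TYPES)]
        assert len(main) == 1008
        per_cell = main.groupby(["block_index", "target_modality"]).size()
        assert (per_cell == 56).all()
        # 50/50 higher/lower within block x modality
        per_dir = main.groupby(["block_index", "target_modality", "target_direction"]).size()
        assert (per_dir == 28).all()

    def test_reduced_layout_arithmetic(self):
        cfg = msite.DesignConfig(
            trials_per_block=6, trials_per_modality_per_block=2, n_main_blocks=2
        )
        layout = msite.build_session_layout(cfg, 1, 1, rng_seed=0)
        main = layout[layout.block_type.isin(MAIN_BLOCK_TYPES)]
        assert len(main) == 12
        assert (main.groupby("target_modality").size() == 4).all()

    def test_block_types_alternate_and_counterbalance(self, default_config):
        even = msite.build_session_layout(default_config, 1, 2, rng_seed=0)
        odd = msite.build_session_layout(default_config, 1, 3, rng_seed=0)
        seq_even = even[even.block_type.isin(MAIN_BLOCK_TYPES)].drop_duplicates("block_index")
        seq_odd = odd[odd.block_type.isin(MAIN_BLOCK_TYPES)].drop_duplicates("block_index")
        assert list(seq_even.block_type) == ["expect_early", "expect_late"] * 3
        assert list(seq_odd.block_type) == ["expect_late", "expect_early"] * 3

    def test_sequence_modality_follows_target_uncertainty(self, default_config):
        low = msite.build_session_layout(default_config, 1, 1, rng_seed=5)
        high = msite.build_session_layout(default_config, 3, 1, rng_seed=5)
        assert (low.sequence_modality == low.target_modality).all()
        main_high = high[high.block_type.isin(MAIN_BLOCK_TYPES)]
        assert (main_high.sequence_modality == "AV").all()

    def test_invalid_config_names_invariant(self):
        with pytest.raises(msite.ConfigError, match="trials_per_modality_per_block"):
            msite.build_session_layout(
                msite.DesignConfig(trials_per_block=100), 1, 1, rng_seed=0
            )
        with pytest.raises(msite.ConfigError, match="experiment_id"):
            msite.build_session_layout(msite.DesignConfig(), 9, 1, rng_seed=0)

    def test_threshold_and_training_blocks_balanced(self, default_config):
        layout = msite.build_session_layout(default_config, 1, 1, rng_seed=8)
        thr = layout[layout.block_type == "threshold"]
        assert len(thr) == 144
        assert set(thr.target_modality) == {"A", "V"}
        pos = thr.groupby(["target_modality", "target_position"]).size()
        assert (pos == 36).all()
        assert len(layout[layout.block_type == "training"]) == 24


class TestConditionSensitivity:
    def test_null_observer_all_cells_equal(self):
        obs = msite.ObserverParams(delta_A=1.0, delta_V=1.0)
        cells = [
            msite.condition_sensitivity(obs, m, te, spu, tau, match)
            for m in ("A", "V", "AV")
            for te in ("expected", "unexpected")
            for spu in ("low", "high")
            for tau in ("low", "high")
            for match in (False, True)
        ]
        assert cells == pytest.approx([1.0] * len(cells))

    def test_te_gain_is_additive(self):
        obs = msite.ObserverParams(te_gain=0.3)
        hi = msite.condition_sensitivity(obs, "AV", "expected")
        lo = msite.condition_sensitivity(obs, "AV", "unexpected")
        assert hi - lo == pytest.approx(0.3)

    def test_preference_slope_couples_av_gain_to_imbalance(self):
        # hand-evaluated composition: slope -0.5 with |delta_A - delta_V| = 0.4
        # lowers the AV cell by 0.2 relative to a balanced observer
        balanced = msite.ObserverParams(delta_A=1.2, delta_V=1.2, msi_pref_slope=-0.5)
        imbalanced = msite.ObserverParams(delta_A=1.2, delta_V=0.8, msi_pref_slope=-0.5)
        d_bal = msite.condition_sensitivity(balanced, "AV")
        d_imb = msite.condition_sensitivity(imbalanced, "AV")
        assert d_bal - d_imb == pytest.approx(0.2)

    def test_av_builds_on_better_unisensory_base(self):
        obs = msite.ObserverParams(delta_A=1.5, delta_V=1.0, msi_gain_base=0.2)
        assert msite.condition_sensitivity(obs, "AV") == pytest.approx(1.7)

    def test_invalid_enumeration_rejected(self):
        obs = msite.ObserverParams()
        with pytest.raises(ValueError, match="target_modality"):
            msite.condition_sensitivity(obs, "audio")
        with pytest.raises(ValueError, match="te_state"):
            msite.condition_sensitivity(obs, "A", te_state="late")

    @given(
        te_gain=st.floats(0, 2),
        msi=st.floats(-1, 1),
        pen=st.floats(0, 2),
        pref=st.floats(-1, 1),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_sensitivity_never_negative(self, te_gain, msi, pen, pref):
        obs = msite.ObserverParams(
            delta_A=0.2, delta_V=0.2, te_gain=te_gain, msi_gain_base=msi,
            uncertainty_penalty_uni=pen, pref_imbalance=pref, msi_pref_slope=-0.8,
        )
        for m in ("A", "V", "AV"):
            assert msite.condition_sensitivity(obs, m, "expected", "high", "high") >= 0.0


class TestResponseModel:
    def test_zero_sensitivity_gives_chance_accuracy(self, rng):
        obs = msite.ObserverParams()
        n = 20000
        direction = np.where(rng.random(n) < 0.5, "higher", "lower")
        resp, _ = msite.simulate_response(obs, np.zeros(n), direction, rng)
        acc = np.mean(resp == direction)
        assert acc == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / n))

    def test_accuracy_at_derived_75pct_delta(self, rng):
        # unbiased observer: accuracy = Phi(delta/2), so delta = 2 z(0.75)
        delta = 2 * norm.ppf(0.75)
        obs = msite.ObserverParams()
        n = 20000
        direction = np.where(rng.random(n) < 0.5, "higher", "lower")
        resp, _ = msite.simulate_response(obs, np.full(n, delta), direction, rng)
        acc = np.mean(resp == direction)
        assert acc == pytest.approx(0.75, abs=3 * np.sqrt(0.1875 / n))

    def test_extreme_criterion_forces_one_response(self, rng):
        obs = msite.ObserverParams(criterion=1e9)
        resp, _ = msite.simulate_response(
            obs, np.ones(100), np.array(["higher"] * 100, dtype=object), rng
        )
        assert (resp == "lower").all()

    def test_rt_floor_and_condition_effects(self, rng):
        obs = msite.ObserverParams(rt_te_effect_ms=100.0, rt_av_effect_ms=50.0)
        n = 4000
        direction = np.array(["higher"] * n, dtype=object)
        _, rt_base = msite.simulate_response(obs, np.ones(n), direction, rng)
        _, rt_fast = msite.simulate_response(
            obs, np.ones(n), direction, rng,
            te_state=np.array(["expected"] * n, dtype=object), is_av=np.ones(n, bool),
        )
        assert rt_base.min() >= 150.0
        assert rt_base.mean() - rt_fast.mean() == pytest.approx(150.0, abs=30.0)


class TestCalibration:
    def test_unbiased_observer_calibrates_to_closed_form(self):
        cal = msite.calibrate_threshold(msite.ObserverParams())
        assert cal.delta_A == pytest.approx(2 * norm.ppf(0.75), abs=1e-8)
        assert cal.delta_V == pytest.approx(cal.delta_A)

    def test_validation_block_hits_75pct(self, rng):
        obs = msite.ObserverParams(criterion=0.3, lapse_rate=0.02)
        cal = msite.calibrate_threshold(obs)
        n = 10000
        direction = np.where(rng.random(n) < 0.5, "higher", "lower")
        resp, _ = msite.simulate_response(obs, np.full(n, cal.delta_A), direction, rng)
        acc = np.mean(resp == direction)
        assert acc == pytest.approx(0.75, abs=3 * np.sqrt(0.1875 / n))

    def test_biased_observer_compensates_with_higher_delta(self):
        biased = msite.calibrate_threshold(msite.ObserverParams(criterion=0.5))
        unbiased = msite.calibrate_threshold(msite.ObserverParams())
        assert biased.delta_A > unbiased.delta_A
        assert msite.accuracy_2afc(
            msite.ObserverParams(criterion=0.5), biased.delta_A
        ) == pytest.approx(0.75, abs=1e-9)

    def test_unreachable_accuracy_raises(self):
        with pytest.raises(msite.CalibrationError, match="unreachable"):
            msite.calibrate_threshold(msite.ObserverParams(criterion=50.0))

    def test_frequency_offset_scales_with_baseline_sensitivity(self):
        cal = msite.calibrate_threshold(msite.ObserverParams(delta_A=2.0, delta_V=1.0))
        assert cal.freq_offset_V == pytest.approx(2 * cal.freq_offset_A)


class TestCohort:
    def test_cohort_size_and_structure(self, full_cohort):
        trials, truth = full_cohort
        assert truth.subject_id.nunique() == 120
        main = trials[trials.block_type.isin(MAIN_BLOCK_TYPES)]
        assert len(main) == 120 * 1008

    def test_same_seed_is_byte_identical(self):
        cfg = msite.DesignConfig(n_subjects_per_experiment=1)
        a_trials, a_truth = msite.generate_cohort(cfg, master_seed=5)
        b_trials, b_truth = msite.generate_cohort(cfg, master_seed=5)
        pd.testing.assert_frame_equal(a_trials, b_trials)
        pd.testing.assert_frame_equal(a_truth, b_truth)
        c_trials, _ = msite.generate_cohort(cfg, master_seed=6)
        assert not a_trials.equals(c_trials)

    def test_position_probabilities_recovered(self, full_cohort):
        trials, _ = full_cohort
        main = trials[trials.block_type.isin(MAIN_BLOCK_TYPES)]
        for block_type, p in [("expect_early", 0.86), ("expect_late", 0.43)]:
            sub = main[main.block_type == block_type]
            n = len(sub)
            assert n >= 10000
            frac = (sub.target_position == "early").mean()
            assert frac == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / n))

    def test_observer_validation_rejects_bad_params(self):
        with pytest.raises(ValueError, match="lapse_rate"):
            msite.ObserverParams(lapse_rate=0.5).validate()
        with pytest.raises(ValueError, match="rt_sigma"):
            msite.ObserverParams(rt_sigma=0.0).validate()

    def test_sensitivity_recovery_dprime_converges_to_delta_over_sqrt2(self, rng):
        # analysis-side estimator consistency at 10,000 trials per cell
        obs = msite.ObserverParams(criterion=0.1)
        delta = 1.6
        n = 10000
        direction = np.where(rng.random(n) < 0.5, "higher", "lower")
        resp, _ = msite.simulate_response(obs, np.full(n, delta), direction, rng)
        higher = direction == "higher"
        d = msite.dprime_2afc(
            int((resp[higher] == "higher").sum()), int(higher.sum()),
            int((resp[~higher] == "higher").sum()), int((~higher).sum()),
        )
        assert d == pytest.approx(delta / np.sqrt(2), abs=0.05)

    def test_miss_probability_produces_none_responses(self, rng):
        obs = msite.ObserverParams(miss_prob=0.2)
        cfg = msite.DesignConfig(n_subjects_per_experiment=1)
        layout = msite.build_session_layout(cfg, 1, 1, rng_seed=1)
        sess = msite.simulate_session(layout, obs, rng, calibration=None)
        frac = (sess.response == "none").mean()
        assert 0.1 < frac < 0.3
        assert sess.loc[sess.response == "none", "rt_ms"].isna().all()
        assert not sess.loc[sess.response == "none", "correct"].any()
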
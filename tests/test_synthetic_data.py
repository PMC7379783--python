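import numpy as np
import pytest

from calfcontrib import (
    ScenarioError,
    TrialParams,
    generate_cohort,
    generate_trial,
    grf_profile,
)
from calfcontrib.model import moment_arm_matrix


class TestGrfProfile:
    def test_zero_at_contact_onset(self):
        p = TrialParams()
        np.testing.assert_allclose(grf_profile(0.0, p), 0.0, atol=1e-9)

    def test_zero_at_toe_off(self):
        p = TrialParams()
        np.testing.assert_allclose(grf_profile(p.stance_duration, p), 0.0, atol=1e-9)

    def test_ap_zero_at_braking_fraction(self):
        p = TrialParams(braking_fraction=0.4)
        f = grf_profile(0.4 * p.stance_duration, p)
        assert f[0] == pytest.approx(0.0, abs=1e-9)

    def test_ap_sign_pattern(self):
        p = TrialParams(braking_fraction=0.5)
        t = np.linspace(0.01, p.stance_duration - 0.01, 200)
        f = grf_profile(t, p)
        braking = t < 0.5 * p.stance_duration
        assert np.all(f[braking, 0] <= 0)
        assert np.all(f[~braking, 0] >= 0)

    def test_ap_integral_antisymmetric_template(self):
        p = TrialParams(braking_fraction=0.5)
        t = np.linspace(0, p.stance_duration, 4001)
        ap = grf_profile(t, p)[:, 0]
        impulse = np.trapezoid(ap, t)
        scale = np.trapezoid(np.abs(ap), t)
        assert abs(impulse) < 1e-6 * scale

    def test_vertical_double_hump(self):
        p = TrialParams()
        t = np.linspace(0, p.stance_duration, 2001)
        v = grf_profile(t, p)[:, 2]
        assert np.all(v >= -1e-12)
        assert np.max(v) == pytest.approx(
            p.peak_vgrf_bw * p.body_mass * 9.81, rel=1e-3
        )
        # two interior local maxima
        interior = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
        assert int(interior.sum()) == 2

    def test_out_of_range(self):
        p = TrialParams()
        with pytest.raises(ScenarioError, match="out of range"):
            grf_profile(p.stance_duration + 0.01, p)


class TestGenerateTrial:
    def test_seeded_determinism_bit_identical(self, model):
        p = TrialParams(seed=7, noise_sd_marker=0.001, noise_sd_force=2.0)
        a = generate_trial(model, p)
        b = generate_trial(model, p)
        np.testing.assert_array_equal(a.recording.forces, b.recording.forces)
        np.testing.assert_array_equal(a.recording.cop, b.recording.cop)
        for name in a.recording.markers:
            np.testing.assert_array_equal(
                a.recording.markers[name], b.recording.markers[name]
            )
        np.testing.assert_array_equal(a.truth_forces, b.truth_forces)

    def test_different_seeds_differ(self, model):
        a = generate_trial(model, TrialParams(seed=1, noise_sd_force=2.0))
        b = generate_trial(model, TrialParams(seed=2, noise_sd_force=2.0))
        assert not np.array_equal(a.recording.forces, b.recording.forces)

    def test_moment_conservation_exact(self, model, noiseless_trial):
        # R . truth_forces == truth_moments at every pre-noise frame
        R = moment_arm_matrix(model).values
        reconstructed = noiseless_trial.truth_forces @ R.T
        resid = np.abs(reconstructed - noiseless_trial.truth_moments.values)
        bound = 1e-6 * (
            1 + np.linalg.norm(noiseless_trial.truth_moments.values, axis=1)
        )
        assert np.all(resid.max(axis=1) <= bound)

    def test_truth_forces_within_bounds(self, model, noiseless_trial):
        f_max = model.f_max
        assert np.all(noiseless_trial.truth_forces >= -1e-9)
        assert np.all(noiseless_trial.truth_forces <= f_max[None, :] + 1e-6)

    def test_vgrf_crosses_threshold_exactly_twice(self, noiseless_trial):
        v = noiseless_trial.recording.vgrf
        crossings = np.sum(np.diff((v > 10.0).astype(int)) != 0)
        assert crossings == 2

    def test_stance_duration_round_trip(self, model):
        from calfcontrib import detect_stance

        trial = generate_trial(model, TrialParams(seed=5, stance_duration=0.22))
        hs, to = detect_stance(trial.recording.force_time, trial.recording.vgrf)
        assert to - hs == pytest.approx(0.22, abs=0.002)

    def test_infeasible_params_raise(self, model):
        with pytest.raises(ScenarioError, match="infeasible scenario"):
            generate_trial(model, TrialParams(seed=1, peak_vgrf_bw=9.0))

    def test_invalid_params_raise(self, model):
        with pytest.raises(ScenarioError):
            generate_trial(model, TrialParams(braking_fraction=1.5))
        with pytest.raises(ScenarioError):
            generate_trial(model, TrialParams(stance_duration=0.9, stride_duration=0.7))


class TestGenerateCohort:
    def test_shape_and_labels(self, model):
        trials = generate_cohort(model, 3, (0.175, 0.415), seed=9)
        assert len(trials) == 6
        assert {t.subject for t in trials} == {0, 1, 2}
        assert {t.condition for t in trials} == {0.175, 0.415}

    def test_single_subject_rejected(self, model):
        with pytest.raises(ScenarioError, match=">= 2 subjects"):
            generate_cohort(model, 1, (0.175, 0.415))

    def test_single_condition_rejected(self, model):
        with pytest.raises(ScenarioError, match=">= 2 conditions"):
            generate_cohort(model, 3, (0.255,))

    def test_unknown_muscle_in_effect(self, model):
        with pytest.raises(KeyError, match="unknown muscle"):
            generate_cohort(
                model, 2, (0.175, 0.415), effect={"Biceps": {0.175: 0.1}}, seed=1
            )

    def test_effect_shifts_truth_contribution(self, model):
        effect = {"Gastrocnemius lateralis": {0.175: 0.6, 0.415: -0.4}}
        trials = generate_cohort(model, 3, (0.175, 0.415), effect=effect, seed=21)
        gl = list(trials[0].muscle_order).index("Gastrocnemius lateralis")
        light = [t.truth_contribution()[gl] for t in trials if t.condition == 0.175]
        heavy = [t.truth_contribution()[gl] for t in trials if t.condition == 0.415]
        assert np.mean(light) > np.mean(heavy)

    def test_effect_preserves_moment_balance(self, model):
        effect = {"Gastrocnemius lateralis": {0.175: 0.5}}
        trials = generate_cohort(model, 2, (0.175, 0.415), effect=effect, seed=22)
        R = moment_arm_matrix(model).values
        t = next(t for t in trials if t.condition == 0.175)
        resid = np.abs(t.truth_forces @ R.T - t.truth_moments.values)
        bound = 1e-6 * (1 + np.linalg.norm(t.truth_moments.values, axis=1))
        assert np.all(resid.max(axis=1) <= bound)

    def test_seeded_cohort_determinism(self, model):
        a = generate_cohort(model, 2, (0.175, 0.415), seed=4)
        b = generate_cohort(model, 2, (0.175, 0.415), seed=4)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.truth_forces, tb.truth_forces)
            np.testing.assert_array_equal(ta.recording.forces, tb.recording.forces)


@pytest.mark.slow
class TestNullCohortRejectionRate:
    def test_truth_level_anova_type_I_near_nominal(self, model):
        # no condition effect: per-muscle ANOVA on truth contributions should
        # reject at roughly the nominal rate (loose bounds, modest replicates)
        from calfcontrib import rm_anova

        n_rep, n_subj = 40, 6
        conditions = (0.175, 0.415)
        gl = 6  # gastrocnemius lateralis column
        rejections = 0
        for rep in range(n_rep):
            trials = generate_cohort(model, n_subj, conditions, seed=1000 + rep)
            data = np.zeros((n_subj, len(conditions)))
            for t in trials:
                j = conditions.index(t.condition)
                data[t.subject, j] = t.truth_contribution()[gl]
            if rm_anova(data).p_value < 0.05:
                rejections += 1
        assert rejections / n_rep < 0.25
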
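"""Design construction, mixed-model fitting, pruning, R², shapes, contrasts."""

import numpy as np
import pandas as pd
import pytest

from reefhdr import (
    ConfigurationError,
    HDRModel,
    ModelFitError,
    ModelSpec,
    build_design,
    classify_shape,
    compact_letters,
    prepare_groups,
    r2_from_components,
    simulate_dataset,
)
from reefhdr.simulate import SimulationScenario, noise_free_scenario


@pytest.fixture(scope="module")
def nf_groups():
    obs, _ = simulate_dataset(noise_free_scenario(
        seed=5, n_studies=8, hdrs_per_study=6, levels_per_hdr=5,
        reps_per_level=2))
    groups, _ = prepare_groups(obs)
    return groups


def facet_stratum(groups, facet="substrate_3d_amount"):
    return [g for g in groups if g.facet == facet]


class TestBuildDesign:
    def test_frame_bookkeeping(self, nf_groups):
        frame, log = build_design(nf_groups)
        assert len(frame) == sum(g.n_obs for g in nf_groups)
        assert {"lnrr", "x", "x2", "study", "hdr"} <= set(frame.columns)
        np.testing.assert_allclose(frame["x2"], frame["x"] ** 2)

    def test_rows_missing_requested_moderator_dropped(self, nf_groups):
        groups = [g.copy_shallow() for g in facet_stratum(nf_groups)]
        for o in groups[0].observations[:2]:
            o.depth_zone = None
        spec = ModelSpec(moderators=("depth_zone",))
        frame, log = build_design(groups, spec)
        assert log.n_dropped_missing == 2
        assert len(frame) == log.n_input_rows - 2

    def test_unknown_moderator_is_configuration_error(self, nf_groups):
        with pytest.raises(ConfigurationError):
            build_design(nf_groups, ModelSpec(moderators=("wave_exposure",)))


class TestFit:
    def test_noise_free_recovers_generating_curve(self, nf_groups):
        res = HDRModel.from_groups(facet_stratum(nf_groups), ModelSpec()).fit()
        assert res.beta1 == pytest.approx(1.2, abs=1e-6)
        assert res.beta2 == pytest.approx(-0.6, abs=1e-6)
        assert res.n_study == 8

    def test_single_study_is_rejected(self, nf_groups):
        one_study = [g for g in facet_stratum(nf_groups) if g.study_id == "study000"]
        with pytest.raises(ModelFitError, match="grouping"):
            HDRModel.from_groups(one_study * 3, ModelSpec()).fit()

    def test_variance_components_nonnegative_and_r2_ordered(self, small_groups):
        res = HDRModel.from_groups(facet_stratum(small_groups), ModelSpec()).fit()
        vc = res.variance_components
        assert vc["study_intercept_var"] >= 0
        assert vc["study_slope_var"] >= 0
        assert vc["hdr_intercept_var"] >= 0
        assert vc["residual_var"] > 0
        cs_bound = np.sqrt(vc["study_intercept_var"] * vc["study_slope_var"])
        assert abs(vc["study_intercept_slope_cov"]) <= cs_bound + 1e-12
        assert 0 <= res.r2_marginal <= res.r2_conditional <= 1

    def test_summary_mentions_key_quantities(self, small_groups):
        res = HDRModel.from_groups(facet_stratum(small_groups), ModelSpec()).fit()
        text = res.summary()
        for token in ("R2 marginal", "shape:", "REML", "Variance components"):
            assert token in text


class TestPrune:
    def test_null_interaction_removed_strong_retained(self, small_groups):
        # het_cv does not modulate the generating slope: its interaction is null
        spec = ModelSpec(moderators=("het_cv",), interactions=("x:het_cv",))
        res = HDRModel.from_groups(facet_stratum(small_groups), spec).fit()
        if res.audit_trail:  # removed: audit records term and p at removal
            step = res.audit_trail[0]
            assert step.term == "x:het_cv" and step.p_value > 0.05
            assert "x:het_cv" not in res.spec.interactions
        else:
            assert "x:het_cv" in res.spec.interactions

    def test_main_effects_never_removed(self, small_groups):
        spec = ModelSpec(moderators=("het_cv", "organismal_group"),
                         interactions=("x:het_cv", "x:organismal_group"))
        res = HDRModel.from_groups(facet_stratum(small_groups), spec).fit()
        terms = set(res.params.index)
        assert "x" in terms and "x2" in terms and "het_cv" in terms

    def test_removal_is_largest_p_first(self, small_groups):
        spec = ModelSpec(moderators=("het_cv", "organismal_group"),
                         interactions=("x:het_cv", "x:organismal_group"))
        res = HDRModel.from_groups(facet_stratum(small_groups), spec).fit()
        # each recorded removal must have exceeded alpha at its step
        for step in res.audit_trail:
            assert step.p_value > 0.05
        steps = [s.step for s in res.audit_trail]
        assert steps == sorted(steps)


class TestR2:
    def test_component_arithmetic(self):
        assert r2_from_components(1.0, 1.0, 2.0) == (0.25, 0.5)

    def test_no_random_variance_collapses_to_marginal(self):
        m, c = r2_from_components(1.0, 0.0, 3.0)
        assert m == c

    def test_all_zero_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert r2_from_components(0.0, 0.0, 0.0) == (0.0, 0.0)

    def test_pure_noise_covariate_barely_moves_marginal_r2(self, small_groups, rng):
        # in a mixed model the variance components are re-estimated when a
        # covariate is added, so marginal R² is only monotone up to that
        # re-estimation; a pure-noise covariate must not shift it materially
        stratum = facet_stratum(small_groups)
        base = HDRModel.from_groups(stratum, ModelSpec()).fit()
        frame = base.frame.copy()
        frame["noise_cov"] = rng.normal(size=len(frame))
        withnoise = HDRModel(frame, ModelSpec(moderators=("noise_cov",))).fit()
        assert withnoise.r2_marginal >= base.r2_marginal - 0.01


class TestShapeClassifier:
    @pytest.mark.parametrize("b1,b2,p1,p2,expected,vertex", [
        (1.0, -0.1, 0.001, 0.30, "linear_increasing", None),
        (-1.0, 0.1, 0.001, 0.30, "linear_decreasing", None),
        (0.1, 0.0, 0.40, 0.90, "flat", None),
        (2.0, -1.0, 0.001, 0.001, "saturating", 1.0),
        (2.0, -2.0, 0.001, 0.001, "hump", 0.5),
        (3.0, -1.0, 0.001, 0.001, "saturating", 1.5),
        (-1.0, -2.0, 0.001, 0.001, "linear_decreasing", -0.25),
        (-1.0, 1.0, 0.001, 0.001, "u_shaped", 0.5),
        (0.0, -2.0, 0.90, 0.001, "hump", 0.0),
    ])
    def test_truth_table(self, b1, b2, p1, p2, expected, vertex):
        shape = classify_shape(b1, b2, p1, p2, alpha=0.05)
        if expected == "hump" and vertex == 0.0:
            # boundary convention: vertex exactly 0 -> declining throughout
            assert shape.value == "linear_decreasing"
        else:
            assert shape.value == expected
        if vertex is not None and shape.vertex is not None and vertex != 0.0:
            assert shape.vertex == pytest.approx(vertex)

    def test_significant_zero_curvature_guarded(self):
        with pytest.raises(ValueError):
            classify_shape(1.0, 0.0, 0.01, 0.01)


class TestPredictAndContrasts:
    def test_prediction_matches_polynomial(self, nf_groups):
        res = HDRModel.from_groups(facet_stratum(nf_groups), ModelSpec()).fit()
        curve = res.predict_curve([0.0, 0.5, 1.0])
        b0 = res.coef("Intercept")
        expect = b0 + res.beta1 * np.array([0, 0.5, 1.0]) \
            + res.beta2 * np.array([0, 0.25, 1.0])
        np.testing.assert_allclose(curve["predicted"], expect, atol=1e-10)
        # noise-free: CI collapses onto the prediction
        assert (curve["ci_high"] - curve["ci_low"]).max() < 1e-5

    def test_no_extrapolation_outside_unit_interval(self, nf_groups):
        res = HDRModel.from_groups(facet_stratum(nf_groups), ModelSpec()).fit()
        with pytest.raises(ConfigurationError):
            res.predict_curve([-0.1, 0.5])

    def test_three_level_factor_emits_three_contrasts(self):
        sc = SimulationScenario(
            seed=9, n_studies=12, hdrs_per_study=6, levels_per_hdr=5,
            reps_per_level=2,
            organismal_groups=("microinvertebrates", "macroinvertebrates", "fish"),
            group_multipliers={"microinvertebrates": 1.0,
                               "macroinvertebrates": 1.0, "fish": 3.0,
                               "large_macroinvertebrates": 1.0,
                               "microalgae": 1.0, "macroalgae": 1.0},
            facet_curves={"substrate_3d_amount": (1.2, -0.6)},
        )
        obs, _ = simulate_dataset(sc)
        groups, _ = prepare_groups(obs)
        spec = ModelSpec(moderators=("organismal_group",),
                         interactions=("x:organismal_group",))
        res = HDRModel.from_groups(groups, spec).fit(prune=False)
        tab = res.pairwise_contrasts("organismal_group")
        assert len(tab) == 3
        # fish slope is 3x: significantly different from both invertebrate groups
        fish_rows = tab[(tab.level_a == "fish") | (tab.level_b == "fish")]
        assert (fish_rows["p_holm"] <= 0.05).all()
        letters = tab.attrs["cld"]
        assert letters["fish"] != letters["microinvertebrates"]
        assert set(letters) == {"fish", "microinvertebrates", "macroinvertebrates"}

    def test_single_level_factor_gives_empty_table(self, nf_groups):
        res = HDRModel.from_groups(facet_stratum(nf_groups), ModelSpec()).fit()
        tab = res.pairwise_contrasts("organismal_group")
        if res.frame["organismal_group"].nunique() < 2:
            assert tab.empty


class TestCompactLetters:
    def test_identical_levels_share_a_letter(self):
        letters = compact_letters(["a1", "a2"], {"a1": 0.0, "a2": 0.0}, {})
        assert letters["a1"] == letters["a2"] == "a"

    def test_separated_levels_get_distinct_letters(self):
        sig = {("lo", "hi"): True, ("lo", "mid"): False, ("mid", "hi"): False}
        letters = compact_letters(["lo", "mid", "hi"],
                                  {"lo": 0.0, "mid": 1.0, "hi": 2.0}, sig)
        assert letters["lo"] != letters["hi"]
        assert set(letters["mid"]) & set(letters["lo"])
        assert set(letters["mid"]) & set(letters["hi"])
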
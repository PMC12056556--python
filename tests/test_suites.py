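"""Model batteries: stratification, pooling, determinism, moderation recovery."""

import dataclasses

import pandas as pd
import pytest

from reefhdr import (
    OTHER_POOLED,
    build_design,
    prepare_groups,
    run_environment_suite,
    run_facet_suite,
    run_group_suite,
    run_process_suite,
    simulate_dataset,
)
from reefhdr.model import ModelSpec
from reefhdr.simulate import (
    DEFAULT_PROCESS_CURVES,
    ModeratorEffects,
    SimulationScenario,
)


@pytest.fixture(scope="module")
def facet_result(small_groups):
    return run_facet_suite(small_groups, "richness")


class TestFacetSuite:
    def test_strongest_generated_facet_has_largest_linear_term(self, facet_result):
        tab = facet_result.comparison_table.dropna(subset=["beta1"])
        best = tab.loc[tab["beta1"].idxmax(), "stratum"]
        assert best == "substrate_3d_amount"

    def test_all_six_facets_accounted_for(self, facet_result):
        tab = facet_result.comparison_table
        assert len(tab) == 6
        assert set(tab["stratum"]) == {
            "substrate_3d_amount", "substrate_2d_amount", "substrate_complexity",
            "feature_size", "feature_variation", "feature_richness"}

    def test_empty_stratum_reported_as_skipped(self, small_groups):
        no3d = [g for g in small_groups if g.facet != "substrate_3d_amount"]
        res = run_facet_suite(no3d, "richness")
        assert "substrate_3d_amount" in res.skipped
        assert "no data" in res.skipped["substrate_3d_amount"]

    def test_rejects_noncommunity_metric(self, small_groups):
        with pytest.raises(ValueError):
            run_facet_suite(small_groups, "grazing")

    def test_determinism_same_input_same_table(self, small_groups):
        a = run_facet_suite(small_groups, "richness").comparison_table
        b = run_facet_suite(small_groups, "richness").comparison_table
        pd.testing.assert_frame_equal(a, b)

    def test_stratum_independence(self, small_groups):
        base = run_facet_suite(small_groups, "richness")
        perturbed = []
        for g in small_groups:
            g2 = g.copy_shallow()
            if g2.facet == "feature_size":
                g2.lnrr = g2.lnrr * 3.0  # corrupt one stratum only
            perturbed.append(g2)
        res = run_facet_suite(perturbed, "richness")
        row_a = base.comparison_table.set_index("stratum").loc["substrate_3d_amount"]
        row_b = res.comparison_table.set_index("stratum").loc["substrate_3d_amount"]
        assert row_a["beta1"] == row_b["beta1"]


class TestGroupSuite:
    def test_minor_facets_pool_losslessly(self, small_groups):
        frame, _ = build_design(small_groups, ModelSpec())
        pooled = frame[frame["facet_pooled"] == OTHER_POOLED]
        minor = frame[frame["facet"].isin(
            ["substrate_complexity", "feature_size", "feature_variation",
             "feature_richness"])]
        assert len(pooled) == len(minor) > 0

    def test_one_model_per_group_present(self, small_groups):
        res = run_group_suite(small_groups)
        fitted = set(res.fits)
        assert fitted <= {"microinvertebrates", "macroinvertebrates"}
        assert len(fitted) == 2
        # groups without data are reported, not silently absent
        assert "fish" in res.skipped

    def test_single_metric_drops_metric_term(self, small_groups):
        res = run_group_suite(small_groups)
        fit = res.fits["microinvertebrates"]
        assert any(t == "response_metric" for t, _ in fit.dropped_terms)


class TestProcessSuite:
    @pytest.fixture(scope="class")
    def process_groups(self):
        sc = SimulationScenario(
            seed=21, n_studies=14, hdrs_per_study=4, levels_per_hdr=5,
            reps_per_level=2,
            response_metrics=("grazing", "predation", "recruitment", "body_size"))
        obs, _ = simulate_dataset(sc)
        groups, _ = prepare_groups(obs)
        return groups

    def test_each_process_modelled_separately(self, process_groups):
        res = run_process_suite(process_groups)
        assert set(res.fits) == {"grazing", "predation", "recruitment", "body_size"}

    def test_grazing_signs_match_generating_curve(self, process_groups):
        res = run_process_suite(process_groups)
        fit = res.fits["grazing"]
        b1, b2 = DEFAULT_PROCESS_CURVES["grazing"]
        assert fit.beta1 * b1 > 0  # negative slope recovered
        assert fit.beta2 * b2 > 0  # positive curvature recovered

    def test_missing_process_skipped(self, small_groups):
        res = run_process_suite(small_groups)  # community data only
        assert set(res.skipped) == {"grazing", "predation", "recruitment",
                                    "body_size"}


class TestEnvironmentSuite:
    def test_latitude_moderation_recovered(self):
        sc = SimulationScenario(
            seed=31, n_studies=24, hdrs_per_study=4, levels_per_hdr=5,
            reps_per_level=2,
            facet_curves={"substrate_3d_amount": (1.2, -0.6)},
            moderator_effects=ModeratorEffects(latitude_slope_per_degree=-0.02))
        obs, _ = simulate_dataset(sc)
        groups, _ = prepare_groups(obs)
        res = run_environment_suite(groups, "facet_models", "richness")
        fit = res.fits["substrate_3d_amount"]
        assert "x:latitude_c" in fit.spec.interactions
        assert fit.coef("x:latitude_c") < 0
        assert fit.p_value("x:latitude_c") < 0.05

    def test_single_level_moderator_dropped_and_logged(self):
        sc = SimulationScenario(seed=33, n_studies=10, hdrs_per_study=3,
                                levels_per_hdr=4, reps_per_level=2)
        obs, _ = simulate_dataset(sc)
        for o in obs:
            o.depth_zone = "low_intertidal"
        groups, _ = prepare_groups(obs)
        res = run_environment_suite(groups, "facet_models", "richness")
        fit = next(iter(res.fits.values()))
        assert ("depth_zone", "single observed level") in fit.dropped_terms

    def test_which_argument_validated(self, small_groups):
        with pytest.raises(ValueError):
            run_environment_suite(small_groups, "everything")
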
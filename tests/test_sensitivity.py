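"""Exclusion rules, delta tables, and publication-bias diagnostics."""

import dataclasses

import numpy as np
import pytest

from reefhdr import (
    build_design,
    drop_confounded,
    drop_discrete,
    drop_large_studies,
    drop_multifacet,
    drop_small_hdrs,
    prepare_groups,
    publication_bias_check,
    run_exclusion_suite,
    run_facet_suite,
    simulate_dataset,
)
from reefhdr.model import ModelSpec
from reefhdr.sensitivity import counts
from reefhdr.simulate import SimulationScenario


class TestRules:
    def test_small_hdr_threshold(self, small_groups, obs_factory):
        from reefhdr import HDRGroup

        sizes = {3: None, 4: None, 5: None}
        groups = []
        for size in sizes:
            obs = [obs_factory(het=float(i % size), plot=f"p{size}{i}")
                   for i in range(size)]
            groups.append(HDRGroup(hdr_id=f"g{size}", study_id="s1",
                                   observations=obs))
        kept = drop_small_hdrs(4)(groups)
        assert {g.hdr_id for g in kept} == {"g4", "g5"}

    def test_discrete_filter_and_noop_delta(self, small_groups):
        continuous_only = [g for g in small_groups if not g.is_discrete]
        rule = drop_discrete()
        assert len(rule(small_groups)) == len(continuous_only)
        # on all-continuous data the rule is a no-op and deltas vanish
        base = run_facet_suite(continuous_only, "richness")
        _, delta = run_exclusion_suite(
            continuous_only, lambda g: run_facet_suite(g, "richness"),
            rules=[rule], base=base)
        est = delta[delta["estimable"] == True]  # noqa: E712
        assert np.allclose(est["delta_beta1"], 0.0)
        assert np.allclose(est["delta_beta2"], 0.0)

    def test_flag_based_rules(self, small_groups):
        flagged = []
        for g in small_groups[:4]:
            g2 = g.copy_shallow()
            g2.observations = [dataclasses.replace(
                o, design_flags=frozenset({"multi_facet", "large_study"}))
                for o in g2.observations]
            flagged.append(g2)
        mixed = flagged + [g for g in small_groups[4:]]
        bad_studies = {g.study_id for g in flagged}
        for rule in (drop_multifacet(), drop_large_studies()):
            kept = rule(mixed)
            assert not ({g.study_id for g in kept} & bad_studies)

    def test_large_studies_quantile_fallback(self, small_groups):
        # thin out half the studies so per-study sizes differ, then cut at
        # the median: only the small half survives
        thinned = [g for g in small_groups
                   if int(g.study_id[-3:]) >= 6 or g.facet == "substrate_3d_amount"]
        kept = drop_large_studies(0.5)(thinned)
        kept_ids = {g.study_id for g in kept}
        assert kept_ids == {s for s in {g.study_id for g in thinned}
                            if int(s[-3:]) < 6}

    def test_rules_idempotent_and_composable(self, small_groups):
        r1, r2 = drop_small_hdrs(8), drop_discrete()
        once = r1(small_groups)
        assert [g.hdr_id for g in r1(once)] == [g.hdr_id for g in once]
        ab = r2(r1(small_groups))
        ba = r1(r2(small_groups))
        assert [g.hdr_id for g in ab] == [g.hdr_id for g in ba]

    def test_counts_consistent(self, small_groups):
        c = counts(small_groups)
        after = counts(drop_small_hdrs(8)(small_groups))
        assert 0 <= after["n_obs"] <= c["n_obs"]
        assert 0 <= after["n_hdr"] <= c["n_hdr"]


class TestExclusionSuite:
    def test_confounded_inflation_detected(self):
        sc = SimulationScenario(
            seed=17, n_studies=18, hdrs_per_study=4, levels_per_hdr=5,
            reps_per_level=2, confounded_fraction=1 / 3,
            confound_inflation=2.0,
            facet_curves={"substrate_3d_amount": (1.2, -0.6)})
        obs, _ = simulate_dataset(sc)
        groups, _ = prepare_groups(obs)
        _, delta = run_exclusion_suite(
            groups, lambda g: run_facet_suite(g, "richness"),
            rules=[drop_confounded()])
        row = delta.set_index("stratum").loc["substrate_3d_amount"]
        assert row["estimable"]
        assert row["delta_beta1"] < 0  # removing inflated studies lowers slope
        assert row["n_study_after"] == 12

    def test_rule_emptying_stratum_marked_not_estimable(self, small_groups):
        _, delta = run_exclusion_suite(
            small_groups, lambda g: run_facet_suite(g, "richness"),
            rules=[drop_small_hdrs(10_000)])
        assert not delta["estimable"].any()


class TestPublicationBias:
    def _frame(self, scenario):
        obs, _ = simulate_dataset(scenario)
        groups, _ = prepare_groups(obs)
        stratum = [g for g in groups if g.facet == "substrate_3d_amount"]
        return build_design(stratum, ModelSpec())[0]

    def test_planted_year_trend_detected(self):
        sc = SimulationScenario(
            seed=23, n_studies=30, hdrs_per_study=4, levels_per_hdr=5,
            reps_per_level=2, pub_year_trend_per_decade=1.0,
            facet_curves={"substrate_3d_amount": (1.2, -0.6)})
        res = publication_bias_check(self._frame(sc), ModelSpec())
        assert res.coef("pub_year_std") > 0
        assert res.p_value("pub_year_std") < 0.05

    def test_constant_covariates_dropped(self):
        sc = SimulationScenario(seed=25, n_studies=8, hdrs_per_study=3,
                                levels_per_hdr=4, reps_per_level=2,
                                facet_curves={"substrate_3d_amount": (1.2, -0.6)})
        frame = self._frame(sc)
        frame["pub_year"] = 2005
        res = publication_bias_check(frame, ModelSpec())
        assert ("pub_year_std", "constant covariate") in res.dropped_terms
        assert "pub_year_std" not in res.params.index
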
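"""Synthetic multi-study generator with known truth.

Emulates the statistical structure the analysis assumes: many studies, each
contributing HDR groups whose responses follow quadratic curves on the
standardized heterogeneity gradient, with correlated study-level random
intercepts and slopes, HDR-level intercepts, and multiplicative lognormal
noise.  Responses are generated as

    y = baseline_scale * exp(u0_s + w_j + slope_sj * x + beta2 * x^2 + eps)

with ``slope_sj = beta1 * group_multiplier + u1_s + moderator slope terms``,
so that the lnRR pipeline (within-HDR baseline at x = 0) recovers the fixed
slope and curvature up to baseline sampling noise.  Raw heterogeneity is
emitted through per-study affine unit transforms (raw = a_s * x + b_s), so
the standardization stage is genuinely exercised; a configurable fraction of
HDRs carries discrete ordinal descriptors instead.

Every generating parameter, including the per-study random effects, is
returned in a truth sidecar so recovery tests can compare estimates against
known values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datatypes import (
    DEPTH_ZONES,
    FACETS,
    SEASONS,
    SUBSTRATE_TYPES,
    Observation,
)
from .exceptions import ConfigurationError

#: discrete ordinal labels used for generated discrete HDRs (ordering built in
#: to ``standardize.resolve_level_order`` via numeric interpretation)
def _discrete_labels(k: int) -> list[str]:
    return [str(i) for i in range(k)]


@dataclass(frozen=True)
class ModeratorEffects:
    """Environment-dependent additions to the heterogeneity slope.

    All default to zero: the core scenario isolates the HDR structure, and
    environmental moderation is switched on explicitly by scenario variants.
    ``latitude_slope_per_degree`` multiplies (latitude - 30); the interaction
    term applies to summer observations only.
    """

    latitude_slope_per_degree: float = 0.0
    depth_offsets: dict = field(default_factory=dict)
    substrate_offsets: dict = field(default_factory=dict)
    season_offsets: dict = field(default_factory=dict)
    lat_season_interaction: float = 0.0

    def slope_term(self, latitude: float, depth: str, substrate: str,
                   season: str) -> float:
        out = self.latitude_slope_per_degree * (latitude - 30.0)
        out += self.depth_offsets.get(depth, 0.0)
        out += self.substrate_offsets.get(substrate, 0.0)
        out += self.season_offsets.get(season, 0.0)
        if season == "summer":
            out += self.lat_season_interaction * (latitude - 30.0)
        return out


@dataclass(frozen=True)
class Variances:
    """Random-effect and residual variances on the log-response scale."""

    study_intercept: float = 0.04
    study_slope: float = 0.04
    intercept_slope_corr: float = 0.0
    hdr_intercept: float = 0.01
    residual: float = 0.09


#: default facet curves (beta1, beta2): substrate 3D amount strongest and
#: saturating, feature richness null, the rest intermediate
DEFAULT_FACET_CURVES = {
    "substrate_3d_amount": (1.2, -0.6),
    "substrate_2d_amount": (0.6, -0.2),
    "substrate_complexity": (0.5, -0.2),
    "feature_size": (0.5, -0.25),
    "feature_variation": (0.3, -0.1),
    "feature_richness": (0.0, 0.0),
}

#: slope multipliers by organismal group; the two well-studied invertebrate
#: groups sit at 1.0 so the facet-stratum slope truth equals the facet beta1
DEFAULT_GROUP_MULTIPLIERS = {
    "microinvertebrates": 1.0,
    "macroinvertebrates": 1.0,
    "large_macroinvertebrates": 0.6,
    "fish": 0.8,
    "microalgae": 0.9,
    "macroalgae": 0.5,
}

DEFAULT_PROCESS_CURVES = {
    "grazing": (-0.5, 0.3),
    "predation": (0.4, -0.2),
    "recruitment": (0.5, -0.2),
    "body_size": (0.2, 0.0),
}


@dataclass(frozen=True)
class SimulationScenario:
    """Full parameterization of the synthetic multi-study generator."""

    seed: int = 0
    n_studies: int = 40
    hdrs_per_study: int = 6
    levels_per_hdr: int = 8
    reps_per_level: int = 3
    facet_curves: dict = field(default_factory=lambda: dict(DEFAULT_FACET_CURVES))
    group_multipliers: dict = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MULTIPLIERS))
    process_curves: dict = field(default_factory=lambda: dict(DEFAULT_PROCESS_CURVES))
    moderator_effects: ModeratorEffects = field(default_factory=ModeratorEffects)
    variances: Variances = field(default_factory=Variances)
    baseline_response_scale: float = 10.0
    discrete_fraction: float = 0.1
    confounded_fraction: float = 0.0
    confound_inflation: float = 2.0
    pub_year_trend_per_decade: float = 0.0
    response_metrics: tuple[str, ...] = ("richness",)
    organismal_groups: tuple[str, ...] = ("microinvertebrates", "macroinvertebrates")
    jitter_grid: bool = False

    def validate(self) -> None:
        v = self.variances
        if min(v.study_intercept, v.study_slope, v.hdr_intercept, v.residual) < 0:
            raise ConfigurationError("variances must be non-negative")
        if not -1.0 <= v.intercept_slope_corr <= 1.0:
            raise ConfigurationError("intercept-slope correlation must be in [-1, 1]")
        for frac in (self.discrete_fraction, self.confounded_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError("fractions must be in [0, 1]")
        if self.baseline_response_scale <= 0:
            raise ConfigurationError("baseline_response_scale must be positive")
        if self.levels_per_hdr < 2 or self.reps_per_level < 1:
            raise ConfigurationError("need >= 2 levels and >= 1 rep per level")

    def n_observations(self) -> int:
        return (self.n_studies * self.hdrs_per_study
                * self.levels_per_hdr * self.reps_per_level)


def noise_free_scenario(seed: int = 0, **overrides) -> SimulationScenario:
    """Deterministic limit: all random-effect variances 0, residual sd 1e-8.

    Slope multipliers are 1 for every group so each facet stratum's
    generating curve is exactly its (beta1, beta2).
    """
    return SimulationScenario(
        seed=seed,
        variances=Variances(0.0, 0.0, 0.0, 0.0, 1e-16),
        group_multipliers={g: 1.0 for g in DEFAULT_GROUP_MULTIPLIERS},
        discrete_fraction=0.0,
        **overrides,
    )


def null_scenario(seed: int = 0, **overrides) -> SimulationScenario:
    """All curves flat (beta1 = beta2 = 0 everywhere); noise as default."""
    return SimulationScenario(
        seed=seed,
        facet_curves={f: (0.0, 0.0) for f in FACETS},
        process_curves={p: (0.0, 0.0) for p in DEFAULT_PROCESS_CURVES},
        group_multipliers={g: 1.0 for g in DEFAULT_GROUP_MULTIPLIERS},
        **overrides,
    )


def simulate_dataset(
    scenario: SimulationScenario,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[Observation], dict]:
    """Generate observations plus a truth sidecar.

    The sidecar holds the full scenario, the per-study random effects and
    unit transforms, and the effective (beta1, beta2) per facet/process.
    Identical scenarios (same seed) produce identical output.
    """
    scenario.validate()
    rng = rng or np.random.default_rng(scenario.seed)
    v = scenario.variances
    cov01 = v.intercept_slope_corr * np.sqrt(v.study_intercept * v.study_slope)
    cov = np.array([[v.study_intercept, cov01], [cov01, v.study_slope]])
    sd_resid = np.sqrt(v.residual)

    facets = list(scenario.facet_curves)
    metrics = list(scenario.response_metrics)
    groups_cycle = list(scenario.organismal_groups)

    n_confounded = int(round(scenario.confounded_fraction * scenario.n_studies))
    observations: list[Observation] = []
    studies_truth = {}

    for s in range(scenario.n_studies):
        study_id = f"study{s:03d}"
        u0, u1 = rng.multivariate_normal([0.0, 0.0], cov)
        latitude = float(rng.uniform(0.0, 60.0))
        depth = DEPTH_ZONES[rng.integers(len(DEPTH_ZONES))]
        season = SEASONS[rng.integers(len(SEASONS))]
        substrate = SUBSTRATE_TYPES[rng.integers(len(SUBSTRATE_TYPES))]
        pub_year = int(rng.integers(1990, 2024))
        a_s = float(rng.uniform(0.5, 50.0))
        b_s = float(rng.uniform(0.0, 10.0))
        confounded = s < n_confounded
        year_shift = scenario.pub_year_trend_per_decade * (pub_year - 2005) / 10.0

        studies_truth[study_id] = {
            "u0": float(u0), "u1": float(u1), "latitude": latitude,
            "depth_zone": depth, "season": season, "substrate_type": substrate,
            "pub_year": pub_year, "a": a_s, "b": b_s, "confounded": confounded,
        }

        for j in range(scenario.hdrs_per_study):
            facet = facets[(s + j) % len(facets)]
            metric = metrics[j % len(metrics)]
            group = groups_cycle[(s + j) % len(groups_cycle)]
            w = rng.normal(0.0, np.sqrt(v.hdr_intercept))
            if metric in scenario.process_curves:
                beta1, beta2 = scenario.process_curves[metric]
                mult = 1.0
            else:
                beta1, beta2 = scenario.facet_curves[facet]
                mult = scenario.group_multipliers[group]
            slope = beta1 * mult + u1 + scenario.moderator_effects.slope_term(
                latitude, depth, substrate, season) + year_shift
            if confounded:
                slope *= scenario.confound_inflation

            discrete = rng.random() < scenario.discrete_fraction
            xg = np.linspace(0.0, 1.0, scenario.levels_per_hdr)
            if scenario.jitter_grid and not discrete:
                # discrete descriptors stay on the even grid their ordinal
                # mapping implies; continuous gradients may be irregular
                inner = np.sort(rng.uniform(0.0, 1.0, scenario.levels_per_hdr - 2))
                xg = np.concatenate([[0.0], inner, [1.0]])
            labels = _discrete_labels(scenario.levels_per_hdr)
            n_species = int(rng.poisson(20)) + 1

            flags = []
            if confounded:
                flags.append("confounded_site_date_substrate")
            flags = frozenset(flags)

            for li, x in enumerate(xg):
                for r in range(scenario.reps_per_level):
                    eps = rng.normal(0.0, sd_resid)
                    eta = u0 + w + slope * x + beta2 * x * x + eps
                    y = scenario.baseline_response_scale * np.exp(eta)
                    observations.append(Observation(
                        study_id=study_id,
                        plot_id=f"{study_id}_h{j}_l{li}_r{r}",
                        site=f"S{j}",
                        date="2020-06-15",
                        substrate_context="ctx",
                        het_raw=labels[li] if discrete else float(a_s * x + b_s),
                        het_metric="ordinal_index" if discrete else "rugosity",
                        facet=facet,
                        response_value=float(y),
                        response_metric=metric,
                        organismal_group=group,
                        latitude_abs=latitude,
                        depth_zone=depth,
                        season=season,
                        substrate_type=substrate,
                        n_species=n_species if metric == "abundance" else None,
                        sample_size=scenario.reps_per_level,
                        pub_year=pub_year,
                        is_discrete_het=discrete,
                        design_flags=flags,
                    ))

    truth = {
        "scenario": _scenario_dict(scenario),
        "studies": studies_truth,
        "facet_curves": dict(scenario.facet_curves),
        "process_curves": dict(scenario.process_curves),
        "group_multipliers": dict(scenario.group_multipliers),
    }
    return observations, truth


def _scenario_dict(scenario: SimulationScenario) -> dict:
    d = dataclasses.asdict(scenario)
    d["response_metrics"] = list(scenario.response_metrics)
    d["organismal_groups"] = list(scenario.organismal_groups)
    return d


def true_curve(
    scenario: SimulationScenario,
    facet: str,
    x,
    moderator_profile: Optional[dict] = None,
) -> np.ndarray:
    """Noise-free fixed-effect lnRR at x for a facet (oracle for recovery).

    ``moderator_profile`` may supply latitude / depth_zone / substrate_type /
    season and an organismal group; absent entries contribute nothing
    (reference conditions), so the curve is anchored at 0 for x = 0.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ConfigurationError("x must lie within [0, 1]")
    if facet in scenario.facet_curves:
        beta1, beta2 = scenario.facet_curves[facet]
    elif facet in scenario.process_curves:
        beta1, beta2 = scenario.process_curves[facet]
    else:
        raise ConfigurationError(f"unknown facet or process {facet!r}")
    profile = moderator_profile or {}
    mult = scenario.group_multipliers.get(profile.get("organismal_group"), 1.0)
    slope = beta1 * mult
    if {"latitude", "depth_zone", "substrate_type", "season"} & set(profile):
        slope += scenario.moderator_effects.slope_term(
            profile.get("latitude", 30.0),
            profile.get("depth_zone", ""),
            profile.get("substrate_type", ""),
            profile.get("season", ""),
        )
    return slope * x + beta2 * x * x
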
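"""The four model batteries: facets, organismal groups, processes, environment.

Each suite fits the quadratic mixed model separately per stratum (facet,
organismal group, or ecological process) — never pooled across strata — and
collects the linear term, quadratic term, R² pair and shape into a long
comparison table.  Strata with too few studies are skipped with a recorded
reason rather than failing the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .datatypes import (
    COMMUNITY_METRICS,
    FACETS,
    ORGANISMAL_GROUPS,
    PROCESS_METRICS,
    HDRGroup,
)
from .exceptions import ModelFitError
from .model import HDRModel, HDRModelResults, ModelSpec

_INVERTEBRATES = ("microinvertebrates", "macroinvertebrates")


@dataclass
class SuiteResult:
    """Fits and comparison table for one model battery."""

    suite_name: str
    fits: dict[str, HDRModelResults] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    comparison_table: Optional[pd.DataFrame] = None

    def build_table(self) -> pd.DataFrame:
        rows = []
        for stratum, fit in self.fits.items():
            rows.append({
                "suite": self.suite_name,
                "stratum": stratum,
                "beta1": fit.beta1, "se1": fit.se("x"), "p1": fit.p_value("x"),
                "beta2": fit.beta2, "se2": fit.se("x2"), "p2": fit.p_value("x2"),
                "r2_marginal": fit.r2_marginal,
                "r2_conditional": fit.r2_conditional,
                "shape": fit.shape.value,
                "n_obs": fit.n_obs, "n_hdr": fit.n_hdr, "n_study": fit.n_study,
                "converged": fit.converged,
            })
        for stratum, reason in self.skipped.items():
            rows.append({"suite": self.suite_name, "stratum": stratum,
                         "shape": f"skipped: {reason}"})
        self.comparison_table = pd.DataFrame(rows).sort_values("stratum").reset_index(drop=True)
        return self.comparison_table


def _n_studies(groups: Sequence[HDRGroup]) -> int:
    return len({g.study_id for g in groups})


def _fit_stratum(result: SuiteResult, stratum: str, groups: list[HDRGroup],
                 spec: ModelSpec, min_studies: int = 2) -> None:
    if not groups:
        result.skipped[stratum] = "no data"
        return
    if _n_studies(groups) < min_studies:
        result.skipped[stratum] = f"fewer than {min_studies} studies"
        return
    try:
        result.fits[stratum] = HDRModel.from_groups(groups, spec).fit()
    except ModelFitError as e:
        result.skipped[stratum] = f"fit error: {e}"


def run_facet_suite(
    groups: Sequence[HDRGroup],
    response_metric: str,
    alpha: float = 0.05,
    extra_moderators: tuple[str, ...] = (),
    extra_interactions: tuple[str, ...] = (),
) -> SuiteResult:
    """One model per heterogeneity facet for aggregated micro- and
    macroinvertebrate data on one community metric (richness or abundance).

    Covariates: organismal group, the HDR heterogeneity CV (with its x
    interaction as a prunable candidate), and per-HDR species count for
    abundance models.
    """
    if response_metric not in ("richness", "abundance"):
        raise ValueError("facet suite runs on richness or abundance")
    pool = [g for g in groups
            if g.organismal_group in _INVERTEBRATES
            and g.response_metric == response_metric]
    moderators: tuple[str, ...] = ("organismal_group", "het_cv")
    if response_metric == "abundance":
        moderators += ("n_species",)
    spec = ModelSpec(
        moderators=moderators + extra_moderators,
        interactions=("x:het_cv",) + extra_interactions,
        alpha=alpha,
    )
    result = SuiteResult(suite_name=f"facet_{response_metric}")
    for facet in FACETS:
        _fit_stratum(result, facet, [g for g in pool if g.facet == facet], spec)
    result.build_table()
    return result


def run_group_suite(
    groups: Sequence[HDRGroup],
    alpha: float = 0.05,
    extra_moderators: tuple[str, ...] = (),
    extra_interactions: tuple[str, ...] = (),
) -> SuiteResult:
    """One model per organismal group, pooling all community response metrics.

    The four minor facets enter as a single ``other_pooled`` level; response
    metric type interacts with heterogeneity and facet (prunable candidates).
    """
    pool = [g for g in groups if g.response_metric in COMMUNITY_METRICS]
    spec = ModelSpec(
        moderators=("facet_pooled", "response_metric", "het_cv") + extra_moderators,
        interactions=("x:facet_pooled", "x:response_metric",
                      "facet_pooled:response_metric", "x:het_cv") + extra_interactions,
        alpha=alpha,
    )
    result = SuiteResult(suite_name="organismal_groups")
    for og in ORGANISMAL_GROUPS:
        _fit_stratum(result, og, [g for g in pool if g.organismal_group == og], spec)
    result.build_table()
    return result


def run_process_suite(
    groups: Sequence[HDRGroup],
    alpha: float = 0.05,
) -> SuiteResult:
    """One model per ecological process (grazing, predation, recruitment,
    body size) with facet and organismal group as covariates."""
    pool = [g for g in groups if g.response_metric in PROCESS_METRICS]
    spec = ModelSpec(
        moderators=("facet_pooled", "organismal_group", "het_cv"),
        interactions=("x:het_cv",),
        alpha=alpha,
    )
    result = SuiteResult(suite_name="processes")
    for proc in PROCESS_METRICS:
        _fit_stratum(result, proc,
                     [g for g in pool if g.response_metric == proc], spec)
    result.build_table()
    return result


_ENV_MODERATORS = ("substrate_type", "depth_zone", "latitude_c", "season")


def _eligible_interaction(term: str, groups: list[HDRGroup],
                          min_studies: int = 2) -> bool:
    """An interaction candidate is included only when every participating
    factor level is observed in at least ``min_studies`` studies."""
    factor_fields = {"season": "season", "substrate_type": "substrate_type",
                     "depth_zone": "depth_zone"}
    for var in term.split(":"):
        f = factor_fields.get(var)
        if f is None:
            continue
        per_level: dict[str, set] = {}
        for g in groups:
            v = getattr(g.observations[0], f)
            if v is not None:
                per_level.setdefault(v, set()).add(g.study_id)
        if not per_level or any(len(s) < min_studies for s in per_level.values()):
            return False
    return True


def run_environment_suite(
    groups: Sequence[HDRGroup],
    which: str = "facet_models",
    response_metric: str = "richness",
    alpha: float = 0.05,
) -> SuiteResult:
    """Re-run the facet or organismal-group battery with environmental
    moderators (substrate type, depth zone, centred absolute latitude,
    season) plus the candidate interactions latitude x season and
    x x substrate type, each included only where every participating factor
    level has enough studies, then pruned."""
    if which not in ("facet_models", "group_models"):
        raise ValueError("which must be 'facet_models' or 'group_models'")
    candidates = tuple(
        t for t in ("latitude_c:season", "x:substrate_type", "x:latitude_c")
        if _eligible_interaction(t, list(groups))
    )
    if which == "facet_models":
        res = run_facet_suite(groups, response_metric, alpha=alpha,
                              extra_moderators=_ENV_MODERATORS,
                              extra_interactions=candidates)
        res.suite_name = f"environment_facet_{response_metric}"
    else:
        res = run_group_suite(groups, alpha=alpha,
                              extra_moderators=_ENV_MODERATORS,
                              extra_interactions=candidates)
        res.suite_name = "environment_groups"
    res.build_table()
    return res
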
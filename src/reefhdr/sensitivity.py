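"""Exclusion-rule sensitivity analyses and publication-bias diagnostics.

Each exclusion rule is a pure filter on HDR groups; rules compose and are
idempotent.  A suite is re-run on the filtered data and the per-stratum
change in the linear and quadratic terms (and significance flips) is
reported relative to the base run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import HDRGroup
from .model import HDRModel, ModelSpec
from .suites import SuiteResult


@dataclass(frozen=True)
class ExclusionRule:
    """A named, pure filter on HDR groups."""

    name: str
    description: str
    filter: Callable[[Sequence[HDRGroup]], list[HDRGroup]]
    threshold: Optional[float] = None

    def __call__(self, groups: Sequence[HDRGroup]) -> list[HDRGroup]:
        return self.filter(groups)


def _study_flagged(group: HDRGroup, flag: str) -> bool:
    return any(flag in o.design_flags for o in group.observations)


def drop_large_studies(quantile: float = 0.95) -> ExclusionRule:
    """Exclude studies flagged ``large_study`` at ingest; when no flags are
    present, fall back to excluding studies above the given quantile of
    per-study observation count (leverage-based exclusion)."""

    def f(groups: Sequence[HDRGroup]) -> list[HDRGroup]:
        flagged = {g.study_id for g in groups if _study_flagged(g, "large_study")}
        if flagged:
            return [g for g in groups if g.study_id not in flagged]
        counts: dict[str, int] = {}
        for g in groups:
            counts[g.study_id] = counts.get(g.study_id, 0) + g.n_obs
        if not counts:
            return list(groups)
        cut = float(np.quantile(list(counts.values()), quantile))
        return [g for g in groups if counts[g.study_id] <= cut]

    return ExclusionRule("drop_large_studies",
                         f"studies flagged large or above the {quantile:.0%} "
                         "observation-count quantile", f, threshold=quantile)


def drop_small_hdrs(min_size: int = 4) -> ExclusionRule:
    """Exclude HDR groups with fewer than ``min_size`` observations."""

    def f(groups: Sequence[HDRGroup]) -> list[HDRGroup]:
        return [g for g in groups if g.n_obs >= min_size]

    return ExclusionRule("drop_small_hdrs",
                         f"HDRs with fewer than {min_size} data points",
                         f, threshold=min_size)


def drop_discrete() -> ExclusionRule:
    """Exclude HDR groups built on discrete ordinal heterogeneity."""

    def f(groups: Sequence[HDRGroup]) -> list[HDRGroup]:
        return [g for g in groups if not g.is_discrete]

    return ExclusionRule("drop_discrete", "discrete heterogeneity descriptors", f)


def drop_multifacet() -> ExclusionRule:
    """Exclude studies flagged as measuring multiple facets on one gradient."""

    def f(groups: Sequence[HDRGroup]) -> list[HDRGroup]:
        bad = {g.study_id for g in groups if _study_flagged(g, "multi_facet")}
        return [g for g in groups if g.study_id not in bad]

    return ExclusionRule("drop_multifacet", "multi-facet studies", f)


def drop_confounded() -> ExclusionRule:
    """Exclude studies whose gradients are confounded with site, date or
    substrate (ingest-supplied flag)."""

    def f(groups: Sequence[HDRGroup]) -> list[HDRGroup]:
        bad = {g.study_id for g in groups
               if _study_flagged(g, "confounded_site_date_substrate")}
        return [g for g in groups if g.study_id not in bad]

    return ExclusionRule("drop_confounded",
                         "studies confounding heterogeneity with site/date/substrate", f)


DEFAULT_RULES = (
    drop_large_studies(),
    drop_small_hdrs(),
    drop_discrete(),
    drop_multifacet(),
    drop_confounded(),
)


def counts(groups: Sequence[HDRGroup]) -> dict[str, int]:
    return {
        "n_obs": sum(g.n_obs for g in groups),
        "n_hdr": len(groups),
        "n_study": len({g.study_id for g in groups}),
    }


def run_exclusion_suite(
    groups: Sequence[HDRGroup],
    suite_runner: Callable[[Sequence[HDRGroup]], SuiteResult],
    rules: Sequence[ExclusionRule] = DEFAULT_RULES,
    base: Optional[SuiteResult] = None,
    alpha: float = 0.05,
) -> tuple[dict[str, SuiteResult], pd.DataFrame]:
    """Apply each rule independently, re-run the suite, and tabulate deltas.

    The delta table reports, per rule and stratum, the change in the linear
    and quadratic terms and whether significance (at ``alpha``) flipped;
    strata emptied by a rule appear as not estimable.
    """
    base = base or suite_runner(groups)
    results: dict[str, SuiteResult] = {}
    rows = []
    base_tab = base.comparison_table.set_index("stratum")
    for rule in rules:
        filtered = rule(groups)
        res = suite_runner(filtered)
        results[rule.name] = res
        after = res.comparison_table.set_index("stratum")
        c_before, c_after = counts(groups), counts(filtered)
        for stratum in base_tab.index:
            row = {"rule": rule.name, "stratum": stratum,
                   "n_obs_before": c_before["n_obs"], "n_obs_after": c_after["n_obs"],
                   "n_hdr_before": c_before["n_hdr"], "n_hdr_after": c_after["n_hdr"],
                   "n_study_before": c_before["n_study"],
                   "n_study_after": c_after["n_study"]}
            b = base_tab.loc[stratum]
            estimable = (stratum in after.index
                         and pd.notna(after.loc[stratum].get("beta1"))
                         and pd.notna(b.get("beta1")))
            if estimable:
                a = after.loc[stratum]
                row.update({
                    "estimable": True,
                    "delta_beta1": float(a["beta1"] - b["beta1"]),
                    "delta_beta2": float(a["beta2"] - b["beta2"]),
                    "sig_flip_x": bool((b["p1"] <= alpha) != (a["p1"] <= alpha)),
                    "sig_flip_x2": bool((b["p2"] <= alpha) != (a["p2"] <= alpha)),
                })
            else:
                row.update({"estimable": False, "delta_beta1": np.nan,
                            "delta_beta2": np.nan, "sig_flip_x": None,
                            "sig_flip_x2": None})
            rows.append(row)
    delta = pd.DataFrame(rows)
    return results, delta


def publication_bias_check(frame: pd.DataFrame, spec: ModelSpec):
    """Augment a model with standardized sample size and publication year.

    The two covariates' coefficients and p-values are the bias diagnostic;
    a constant covariate is dropped with a note.  Returns the fitted
    :class:`~reefhdr.model.HDRModelResults` (the dropped-term log records
    any degenerate covariate).
    """
    frame = frame.copy()
    added = []
    dropped = []
    for col in ("sample_size", "pub_year"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.nunique(dropna=True) < 2:
            dropped.append((f"{col}_std", "constant covariate"))
            continue
        frame[f"{col}_std"] = (vals - vals.mean()) / vals.std(ddof=1)
        added.append(f"{col}_std")
    aug = replace(spec, moderators=spec.moderators + tuple(added))
    res = HDRModel(frame, aug).fit()
    res.dropped_terms = list(res.dropped_terms) + dropped
    return res
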
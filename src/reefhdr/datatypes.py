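"""Domain types: observations, HDR groups, and controlled vocabularies.

An *HDR group* (heterogeneity-diversity relationship group) is the
within-study unit over which heterogeneity is standardized to [0, 1] and
the lnRR baseline is computed: all observations sharing study, facet,
response metric, organismal group, and (unless the small-sample extension
rule fired) site, date and substrate context.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

# -- controlled vocabularies -------------------------------------------------

#: The six heterogeneity facets distinguished at ingest.
FACETS = (
    "substrate_3d_amount",
    "substrate_2d_amount",
    "substrate_complexity",
    "feature_size",
    "feature_variation",
    "feature_richness",
)

#: Pooled label applied by the organismal-group suite to the four minor
#: facets; never valid at ingest.
OTHER_POOLED = "other_pooled"

#: Facets relabelled to OTHER_POOLED in group-level models.
POOLABLE_FACETS = frozenset(
    {"substrate_complexity", "feature_size", "feature_variation", "feature_richness"}
)

COMMUNITY_METRICS = ("richness", "diversity", "evenness", "abundance", "biomass")
PROCESS_METRICS = ("grazing", "predation", "recruitment", "body_size")
RESPONSE_METRICS = COMMUNITY_METRICS + PROCESS_METRICS

ORGANISMAL_GROUPS = (
    "microalgae",
    "macroalgae",
    "microinvertebrates",
    "macroinvertebrates",
    "large_macroinvertebrates",
    "fish",
)

DEPTH_ZONES = ("high_intertidal", "low_intertidal", "shallow_subtidal", "deep_subtidal")
SEASONS = ("winter", "spring", "summer", "autumn")
SUBSTRATE_TYPES = ("biogenic", "rock")

DESIGN_FLAGS = ("confounded_site_date_substrate", "multi_facet", "large_study")


@dataclass
class Observation:
    """One measured response at one heterogeneity level within one plot.

    ``het_raw`` holds the heterogeneity value in the study's original units
    for continuous metrics, or an ordinal level label when
    ``is_discrete_het`` is true.  ``latitude_abs`` is absolute decimal
    degrees; ``depth_zone``, ``season`` and ``substrate_type`` are the
    boreal-standardized environmental context fields.
    """

    study_id: str
    plot_id: str
    site: str
    date: str
    substrate_context: str
    het_raw: object  # float or ordinal label
    het_metric: str
    facet: str
    response_value: float
    response_metric: str
    organismal_group: str
    latitude_abs: Optional[float] = None
    depth_zone: Optional[str] = None
    season: Optional[str] = None
    substrate_type: Optional[str] = None
    n_species: Optional[int] = None
    sample_size: Optional[int] = None
    pub_year: Optional[int] = None
    is_discrete_het: bool = False
    design_flags: frozenset = frozenset()

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if not np.isfinite(self.response_value) or self.response_value < 0:
            problems.append(f"response_value must be >= 0, got {self.response_value!r}")
        if self.latitude_abs is not None and not (0.0 <= self.latitude_abs <= 90.0):
            problems.append(f"latitude_abs must be in [0, 90], got {self.latitude_abs!r}")
        if self.facet not in FACETS:
            problems.append(f"unknown facet {self.facet!r}")
        if self.response_metric not in RESPONSE_METRICS:
            problems.append(f"unknown response_metric {self.response_metric!r}")
        if self.organismal_group not in ORGANISMAL_GROUPS:
            problems.append(f"unknown organismal_group {self.organismal_group!r}")
        if self.depth_zone is not None and self.depth_zone not in DEPTH_ZONES:
            problems.append(f"unknown depth_zone {self.depth_zone!r}")
        if self.season is not None and self.season not in SEASONS:
            problems.append(f"unknown season {self.season!r}")
        if self.substrate_type is not None and self.substrate_type not in SUBSTRATE_TYPES:
            problems.append(f"unknown substrate_type {self.substrate_type!r}")
        if not self.is_discrete_het:
            try:
                v = float(self.het_raw)
                if not np.isfinite(v):
                    problems.append("het_raw must be finite for continuous metrics")
            except (TypeError, ValueError):
                problems.append(
                    f"het_raw must be numeric when is_discrete_het is false, got {self.het_raw!r}"
                )
        for flag in self.design_flags:
            if flag not in DESIGN_FLAGS:
                problems.append(f"unknown design flag {flag!r}")
        return problems


@dataclass
class HDRGroup:
    """A within-study heterogeneity gradient and its derived quantities.

    ``het_standardized``, ``het_cv`` and ``lnrr`` start as ``None`` and are
    filled by the standardize and effect-size stages.  ``lnrr`` is aligned
    with ``observations``; entries excluded from analysis (zero responses at
    non-baseline levels) are NaN.
    """

    hdr_id: str
    study_id: str
    observations: list[Observation]
    het_standardized: Optional[np.ndarray] = None
    het_cv: Optional[float] = None
    cv_on_mapped: bool = False
    lnrr: Optional[np.ndarray] = None
    baseline_mean: Optional[float] = None
    collapse_level: int = 0  # 0 none, 1 site, 2 +date, 3 +substrate

    @property
    def facet(self) -> str:
        return self.observations[0].facet

    @property
    def response_metric(self) -> str:
        return self.observations[0].response_metric

    @property
    def organismal_group(self) -> str:
        return self.observations[0].organismal_group

    @property
    def is_discrete(self) -> bool:
        return self.observations[0].is_discrete_het

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    def het_levels(self) -> list:
        """Distinct raw heterogeneity values/labels, in first-seen order."""
        seen: dict = {}
        for o in self.observations:
            seen.setdefault(o.het_raw, None)
        return list(seen)

    def copy_shallow(self) -> "HDRGroup":
        g = dataclasses.replace(self, observations=list(self.observations))
        if g.het_standardized is not None:
            g.het_standardized = np.array(g.het_standardized)
        if g.lnrr is not None:
            g.lnrr = np.array(g.lnrr)
        return g


@dataclass
class ValidationReport:
    """Row-level ingest outcomes: accepted count plus rejected rows."""

    n_input: int = 0
    n_accepted: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (row number, reason)

    def to_text(self) -> str:
        lines = [
            f"rows read:     {self.n_input}",
            f"rows accepted: {self.n_accepted}",
            f"rows rejected: {len(self.rejected)}",
        ]
        for row, reason in self.rejected:
            lines.append(f"  row {row}: {reason}")
        return "\n".join(lines)

    def rejected_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rejected, columns=["row", "reason"])
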
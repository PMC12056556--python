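"""End-to-end preparation: observations -> standardized, effect-sized HDR groups."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .datatypes import HDRGroup, Observation
from .effect_sizes import compute_lnrr
from .exceptions import BaselineUndefinedError, DegenerateGradientError
from .grouping import GroupingLog, build_hdr_groups
from .standardize import standardize_group


@dataclass
class PipelineLog:
    grouping: GroupingLog = None
    dropped_groups: list[tuple[str, str]] = field(default_factory=list)
    n_zero_response_excluded: int = 0


def prepare_groups(
    observations: list[Observation],
    min_replicates: int = 3,
    level_orders: Optional[Mapping[str, Sequence[str]]] = None,
) -> tuple[list[HDRGroup], PipelineLog]:
    """Group, standardize and effect-size observations.

    Groups that turn out degenerate at the standardization or baseline stage
    (zero-variance gradient, zero baseline mean) are dropped and recorded in
    the returned log, mirroring how unusable gradients are handled at the
    grouping stage.
    """
    groups, glog = build_hdr_groups(observations, min_replicates=min_replicates)
    log = PipelineLog(grouping=glog)
    kept: list[HDRGroup] = []
    for g in groups:
        try:
            standardize_group(g, level_orders=level_orders)
        except DegenerateGradientError as e:
            log.dropped_groups.append((g.hdr_id, f"degenerate gradient: {e}"))
            continue
        try:
            vec = compute_lnrr(g)
        except BaselineUndefinedError as e:
            log.dropped_groups.append((g.hdr_id, f"undefined baseline: {e}"))
            continue
        log.n_zero_response_excluded += vec.n_excluded_zero
        kept.append(g)
    return kept, log
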
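"""Aggregation of observations into HDR groups.

Observations are grouped within each study by facet, response metric and
organismal group, and by site, date and substrate context.  When a study's
cell yields any group smaller than ``min_replicates``, the grouping for that
cell is extended by collapsing site, then date, then substrate context (in
that order) until every group meets the threshold or the cell is flagged
unusable.  Groups with fewer than two distinct heterogeneity levels carry no
gradient and are dropped with a logged reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .datatypes import HDRGroup, Observation

#: grouping keys per collapse level; level 0 = no collapse
_LEVEL_KEYS = (
    ("site", "date", "substrate_context"),
    ("date", "substrate_context"),
    ("substrate_context",),
    (),
)


@dataclass
class GroupingLog:
    """Audit of the grouping stage."""

    n_input: int = 0
    n_retained: int = 0
    dropped: list[tuple[str, str, int]] = field(default_factory=list)  # (unit, reason, n_obs)
    collapsed_cells: list[tuple[str, int]] = field(default_factory=list)  # (cell, level)

    def n_dropped_obs(self) -> int:
        return sum(n for _, _, n in self.dropped)


def build_hdr_groups(
    observations: list[Observation],
    min_replicates: int = 3,
) -> tuple[list[HDRGroup], GroupingLog]:
    """Partition observations into HDR groups.

    Returns the retained groups plus a :class:`GroupingLog`; every input
    observation is either in exactly one returned group or accounted for in
    the log's dropped entries.  The result is independent of input row order
    (observations are sorted on the full grouping key first).
    """
    log = GroupingLog(n_input=len(observations))

    def cell_key(o: Observation):
        return (o.study_id, o.facet, o.response_metric, o.organismal_group)

    def sort_key(o: Observation):
        return cell_key(o) + (o.site, o.date, o.substrate_context, str(o.het_raw),
                              o.plot_id, o.response_value)

    ordered = sorted(observations, key=sort_key)

    cells: dict[tuple, list[Observation]] = {}
    for o in ordered:
        cells.setdefault(cell_key(o), []).append(o)

    groups: list[HDRGroup] = []
    for key in sorted(cells):
        cell_obs = cells[key]
        cell_label = "/".join(key)
        level, grouped = _group_cell(cell_obs, min_replicates)
        if grouped is None:
            log.dropped.append((cell_label, "fewer than min_replicates even fully collapsed",
                                len(cell_obs)))
            continue
        if level > 0:
            log.collapsed_cells.append((cell_label, level))
        for subkey in sorted(grouped):
            members = grouped[subkey]
            hdr_id = "|".join(key + subkey) if subkey else "|".join(key)
            if len({str(m.het_raw) for m in members}) < 2:
                log.dropped.append((hdr_id, "single heterogeneity level", len(members)))
                continue
            groups.append(
                HDRGroup(hdr_id=hdr_id, study_id=key[0], observations=members,
                         collapse_level=level)
            )
    log.n_retained = sum(g.n_obs for g in groups)
    return groups, log


def _group_cell(cell_obs: list[Observation], min_replicates: int):
    """Group one study cell, collapsing keys until all groups are big enough.

    Returns ``(level, {subkey: observations})`` or ``(level, None)`` when even
    the fully collapsed grouping falls short.
    """
    for level, keys in enumerate(_LEVEL_KEYS):
        grouped: dict[tuple, list[Observation]] = {}
        for o in cell_obs:
            subkey = tuple(getattr(o, k) for k in keys)
            grouped.setdefault(subkey, []).append(o)
        if all(len(v) >= min_replicates for v in grouped.values()):
            return level, grouped
    return len(_LEVEL_KEYS) - 1, None
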
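"""Heterogeneity standardization and the gradient-breadth covariate.

Continuous heterogeneity is z-transformed then min-max mapped to [0, 1]
within each HDR group (the composition is itself an affine map, so the
result equals a plain min-max rescaling — asserted as a property test).
Discrete ordinal descriptors map level i of k to (i-1)/(k-1), matching the
two- and three-level conventions (0/1 and 0/0.5/1).  The coefficient of
variation (CV) of the raw values, in original units, captures how broad a
gradient each HDR spans and enters the models as a covariate.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from .datatypes import HDRGroup
from .exceptions import ConfigurationError, DegenerateGradientError, UndefinedCVError

#: Orderings recognised without explicit configuration.
BUILTIN_LEVEL_ORDERS: tuple[tuple[str, ...], ...] = (
    ("absent", "present"),
    ("low", "high"),
    ("low", "medium", "high"),
    ("low", "intermediate", "high"),
    ("none", "low", "medium", "high"),
)


def transform_continuous(het_raw: Sequence[float]) -> np.ndarray:
    """Z-transform then min-max map continuous heterogeneity to [0, 1].

    Raises :class:`DegenerateGradientError` when all values are equal
    (zero variance leaves no gradient); callers drop such groups.
    """
    x = np.asarray(het_raw, dtype=float)
    if x.size < 2:
        raise DegenerateGradientError("need at least two heterogeneity values")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise DegenerateGradientError("zero variance in heterogeneity values")
    z = (x - x.mean()) / sd
    return (z - z.min()) / (z.max() - z.min())


def transform_discrete(
    levels: Sequence[str],
    order: Sequence[str],
) -> np.ndarray:
    """Map ordinal labels to evenly spaced values in [0, 1].

    ``order`` lists the distinct levels from lowest to highest heterogeneity;
    level i of k maps to (i-1)/(k-1).  Unknown labels raise
    :class:`ConfigurationError`.
    """
    order = list(order)
    k = len(order)
    if k < 2:
        raise ConfigurationError("discrete ordering needs at least two levels")
    if len(set(order)) != k:
        raise ConfigurationError("duplicate labels in level ordering")
    pos = {lab: i / (k - 1) for i, lab in enumerate(order)}
    out = np.empty(len(levels), dtype=float)
    for j, lab in enumerate(levels):
        if lab not in pos:
            raise ConfigurationError(
                f"level {lab!r} not in supplied ordering {order!r}"
            )
        out[j] = pos[lab]
    return out


def compute_cv(het_raw: Sequence[float]) -> float:
    """Coefficient of variation: sample sd (n-1) over mean, original units.

    Raises :class:`UndefinedCVError` for non-positive means, where the ratio
    loses meaning.
    """
    x = np.asarray(het_raw, dtype=float)
    m = x.mean()
    if m <= 0:
        raise UndefinedCVError(f"CV undefined for mean {m}")
    return float(x.std(ddof=1) / m)


def resolve_level_order(
    labels: Sequence[str],
    level_orders: Optional[Mapping[str, Sequence[str]]] = None,
    het_metric: Optional[str] = None,
) -> list[str]:
    """Determine the ordinal ordering for a set of discrete labels.

    Precedence: an explicit per-metric ordering from ``level_orders``, then a
    built-in vocabulary (absent<present, low<medium<high, ...), then numeric
    interpretation of the labels.  Anything else is a configuration error.
    """
    distinct = sorted(set(labels))
    if level_orders and het_metric is not None and het_metric in level_orders:
        order = [str(v) for v in level_orders[het_metric]]
        if not set(distinct) <= set(order):
            raise ConfigurationError(
                f"labels {distinct} not covered by configured order {order} "
                f"for metric {het_metric!r}"
            )
        return [lab for lab in order if lab in set(distinct)]
    for vocab in BUILTIN_LEVEL_ORDERS:
        if set(distinct) <= set(vocab):
            return [lab for lab in vocab if lab in set(distinct)]
    try:
        return sorted(distinct, key=float)
    except ValueError:
        raise ConfigurationError(
            f"no ordering known for discrete levels {distinct}; supply one "
            "via level_orders"
        )


def standardize_group(
    group: HDRGroup,
    level_orders: Optional[Mapping[str, Sequence[str]]] = None,
) -> HDRGroup:
    """Fill ``het_standardized``, ``het_cv`` and ``cv_on_mapped`` in place.

    For discrete descriptors the CV has no original units; it is computed on
    the mapped [0, 1] values and flagged via ``cv_on_mapped``.
    """
    if group.is_discrete:
        labels = [str(o.het_raw) for o in group.observations]
        order = resolve_level_order(labels, level_orders,
                                    group.observations[0].het_metric)
        het01 = transform_discrete(labels, order)
        group.het_standardized = het01
        try:
            group.het_cv = compute_cv(het01)
        except UndefinedCVError:
            group.het_cv = None
        group.cv_on_mapped = True
    else:
        raw = np.array([float(o.het_raw) for o in group.observations])
        group.het_standardized = transform_continuous(raw)
        try:
            group.het_cv = compute_cv(raw)
        except UndefinedCVError:
            group.het_cv = None
        group.cv_on_mapped = False
    return group
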
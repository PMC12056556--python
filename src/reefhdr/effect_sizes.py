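"""Per-observation log response ratios against the lowest-heterogeneity baseline.

For each HDR group, lnRR_i = ln(y_i / mean(min(y))) where mean(min(y)) is
the arithmetic mean response over all observations at the group's lowest
standardized heterogeneity level.  Baseline observations themselves are
retained as data points (their lnRR scatters around 0 and carries residual
-variance information); zero responses away from the baseline cannot be
log-transformed and are excluded (NaN) with a logged count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import HDRGroup
from .exceptions import BaselineUndefinedError, DataError

_BASELINE_TOL = 1e-12


@dataclass
class EffectSizeVector:
    """lnRR values for one HDR group, aligned with its observations."""

    lnrr: np.ndarray  # NaN where excluded
    baseline_mean: float
    baseline_level: float  # standardized het value of the baseline
    n_excluded_zero: int


def compute_lnrr(group: HDRGroup) -> EffectSizeVector:
    """Compute lnRR for a standardized HDR group and attach it to the group.

    Raises
    ------
    BaselineUndefinedError
        When the baseline mean response is zero.
    DataError
        When the group is not standardized or has negative responses.
    """
    if group.het_standardized is None:
        raise DataError(f"group {group.hdr_id} has not been standardized")
    het01 = np.asarray(group.het_standardized, dtype=float)
    y = np.array([o.response_value for o in group.observations], dtype=float)
    if np.any(y < 0):
        raise DataError(f"negative response values in group {group.hdr_id}")

    lo = het01.min()
    at_base = het01 <= lo + _BASELINE_TOL
    baseline_mean = float(y[at_base].mean())
    if baseline_mean <= 0:
        raise BaselineUndefinedError(
            f"baseline mean response is {baseline_mean} in group {group.hdr_id}"
        )

    lnrr = np.full(y.shape, np.nan)
    ok = y > 0
    lnrr[ok] = np.log(y[ok] / baseline_mean)
    n_excluded = int(np.sum(~ok))

    group.lnrr = lnrr
    group.baseline_mean = baseline_mean
    return EffectSizeVector(
        lnrr=lnrr,
        baseline_mean=baseline_mean,
        baseline_level=float(lo),
        n_excluded_zero=n_excluded,
    )


def effect_sizes_frame(groups: list[HDRGroup]) -> pd.DataFrame:
    """Tidy export: one row per observation with hdr_id, het01 and lnrr."""
    rows = []
    for g in groups:
        if g.lnrr is None:
            continue
        for i, (x, r) in enumerate(zip(g.het_standardized, g.lnrr)):
            rows.append({"hdr_id": g.hdr_id, "obs": i, "het01": float(x),
                         "lnrr": float(r)})
    return pd.DataFrame(rows, columns=["hdr_id", "obs", "het01", "lnrr"])
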
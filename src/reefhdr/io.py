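"""CSV ingest with a configurable column mapping.

The reader accepts any column naming via ``schema_config`` (canonical field
name -> CSV column name); omitted entries default to the canonical names.
Rows failing type coercion or vocabulary validation are reported with their
row numbers rather than aborting the read.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional

import pandas as pd

from .datatypes import Observation, ValidationReport
from .exceptions import ConfigurationError, DataError

REQUIRED_FIELDS = (
    "study_id",
    "plot_id",
    "site",
    "date",
    "substrate_context",
    "het_raw",
    "het_metric",
    "facet",
    "response_value",
    "response_metric",
    "organismal_group",
)

OPTIONAL_FIELDS = (
    "latitude_abs",
    "depth_zone",
    "season",
    "substrate_type",
    "n_species",
    "sample_size",
    "pub_year",
    "is_discrete_het",
    "design_flags",
)

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f", ""}


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return isinstance(v, str) and v.strip() == ""


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot interpret {v!r} as a boolean")


def read_dataset(
    path,
    schema_config: Optional[Mapping[str, str]] = None,
) -> tuple[list[Observation], ValidationReport]:
    """Read a per-observation CSV into validated :class:`Observation` records.

    Parameters
    ----------
    path : str or PathLike
        UTF-8 CSV with a header row.
    schema_config : mapping, optional
        Canonical field name -> column name in the file.  Fields not listed
        are looked up under their canonical names.

    Returns
    -------
    (observations, report)
        Valid observations and a :class:`ValidationReport` listing rejected
        rows by CSV row number (header = row 1, first data row = row 2).

    Raises
    ------
    ConfigurationError
        If a required column cannot be resolved.
    DataError
        If the file has no data rows.
    """
    mapping = dict(schema_config or {})
    colmap = {f: mapping.get(f, f) for f in REQUIRED_FIELDS + OPTIONAL_FIELDS}

    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise DataError(f"empty input file: {path}")
    if df.empty:
        raise DataError(f"no data rows in {path}")

    for f in REQUIRED_FIELDS:
        if colmap[f] not in df.columns:
            raise ConfigurationError(
                f"required column {colmap[f]!r} (field {f!r}) not found in {path}"
            )

    report = ValidationReport(n_input=len(df))
    observations: list[Observation] = []

    for idx, row in enumerate(df.itertuples(index=False)):
        rowno = idx + 2  # header is row 1
        rec = dict(zip(df.columns, row))
        try:
            obs = _row_to_observation(rec, colmap)
        except ValueError as e:
            report.rejected.append((rowno, str(e)))
            continue
        problems = obs.validate()
        if problems:
            report.rejected.append((rowno, "; ".join(problems)))
            continue
        observations.append(obs)

    report.n_accepted = len(observations)
    return observations, report


def _row_to_observation(rec: dict, colmap: Mapping[str, str]) -> Observation:
    def get(field):
        col = colmap[field]
        return rec.get(col)

    is_discrete = False
    raw_flag = get("is_discrete_het")
    if not _is_missing(raw_flag):
        is_discrete = _parse_bool(raw_flag)

    het_raw = get("het_raw")
    if _is_missing(het_raw):
        raise ValueError("het_raw is missing")
    if not is_discrete:
        het_raw = float(het_raw)

    rv = get("response_value")
    if _is_missing(rv):
        raise ValueError("response_value is missing")
    response_value = float(rv)

    def opt_float(field):
        v = get(field)
        return None if _is_missing(v) else float(v)

    def opt_int(field):
        v = get(field)
        return None if _is_missing(v) else int(float(v))

    def opt_str(field):
        v = get(field)
        return None if _is_missing(v) else str(v).strip()

    flags = get("design_flags")
    design_flags = frozenset(
        t.strip() for t in str(flags).split(";") if t.strip()
    ) if not _is_missing(flags) else frozenset()

    return Observation(
        study_id=str(get("study_id")).strip(),
        plot_id=str(get("plot_id")).strip(),
        site=str(get("site")).strip(),
        date=str(get("date")).strip(),
        substrate_context=str(get("substrate_context")).strip(),
        het_raw=het_raw,
        het_metric=str(get("het_metric")).strip(),
        facet=str(get("facet")).strip(),
        response_value=response_value,
        response_metric=str(get("response_metric")).strip(),
        organismal_group=str(get("organismal_group")).strip(),
        latitude_abs=opt_float("latitude_abs"),
        depth_zone=opt_str("depth_zone"),
        season=opt_str("season"),
        substrate_type=opt_str("substrate_type"),
        n_species=opt_int("n_species"),
        sample_size=opt_int("sample_size"),
        pub_year=opt_int("pub_year"),
        is_discrete_het=is_discrete,
        design_flags=design_flags,
    )


def observations_to_frame(observations: list[Observation]) -> pd.DataFrame:
    """Tidy DataFrame view of observations (one row each, canonical columns)."""
    cols = list(REQUIRED_FIELDS + OPTIONAL_FIELDS)
    rows = []
    for o in observations:
        d = {f: getattr(o, f) for f in cols if f != "design_flags"}
        d["design_flags"] = ";".join(sorted(o.design_flags))
        rows.append(d)
    return pd.DataFrame(rows, columns=cols)


def write_dataset(observations: list[Observation], path) -> None:
    """Write observations in the same CSV schema :func:`read_dataset` accepts."""
    observations_to_frame(observations).to_csv(path, index=False)
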
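"""Tabular schemas, CSV readers/writers and validation.

All pipeline inputs are UTF-8 CSV files with snake_case headers and ISO
8601 timestamps that carry an explicit UTC offset (e.g.
``2020-04-01T06:30:00-07:00`` or ``...Z``).  Readers validate every row
and abort with a :class:`SchemaError` naming the offending rows, so a
run never proceeds on silently-misparsed data.

Tables
------
detections.csv
    project_id, station_id, timestamp, species, is_human,
    is_research_personnel, is_domestic
deployments.csv
    project_id, station_id, latitude, longitude, start, end
periods.csv
    project_id, period_label (A/B), start, end, comparison_type
    (between_year/within_year), human_change_override (optional:
    A_higher/B_higher)
traits.csv
    species, body_mass_kg, trophic_level, diet_breadth, habitat_breadth,
    diel_activity, brain_mass_g (optional), family
project_covariates.csv
    project_id, hmi, openness, stringency_control, stringency_treatment
hunting.csv
    project_id, species, hunted
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "read_detections",
    "write_detections",
    "read_deployments",
    "write_deployments",
    "read_periods",
    "write_periods",
    "read_traits",
    "read_project_covariates",
    "read_hunting",
    "write_table",
    "validate_project",
    "normalize_species",
]

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}

# ISO 8601 with explicit offset: ...+HH:MM, ...-HHMM, or Z
_OFFSET_RE = re.compile(r"(?:Z|[+-]\d{2}:?\d{2})$")


class SchemaError(ValueError):
    """Input file violates the documented schema."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_timestamps(series: pd.Series, path, column) -> pd.Series:
    """Parse ISO timestamps requiring an explicit UTC offset; returns UTC."""
    raw = series.astype(str).str.strip()
    no_offset = ~raw.str.contains(_OFFSET_RE)
    if no_offset.any():
        rows = (series.index[no_offset] + 2).tolist()[:10]  # 1-based + header
        raise SchemaError(
            f"{path}: column '{column}' has timestamp(s) without a UTC offset "
            f"at file line(s) {rows}"
        )
    parsed = pd.to_datetime(raw, utc=True, errors="coerce", format="ISO8601")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        rows = (series.index[bad] + 2).tolist()[:10]
        raise SchemaError(f"{path}: column '{column}' unparseable timestamp(s) at line(s) {rows}")
    return parsed


def _parse_bool(series: pd.Series, path, column) -> pd.Series:
    if series.dtype == bool:
        return series
    lowered = series.astype(str).str.strip().str.lower()
    mapped = lowered.map(_BOOL_MAP)
    if mapped.isna().any():
        rows = (series.index[mapped.isna()] + 2).tolist()[:10]
        raise SchemaError(f"{path}: column '{column}' non-boolean value(s) at line(s) {rows}")
    return mapped.astype(bool)


def normalize_species(series: pd.Series) -> pd.Series:
    """Whitespace/case normalization used for trait matching."""
    return series.astype(str).str.strip().str.replace(r"\s+", " ", regex=True).str.lower()


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    cols = ["project_id", "station_id", "timestamp", "species", "is_human",
            "is_research_personnel", "is_domestic"]
    _require_columns(df, cols, path)
    df = df[cols].copy()
    df["timestamp"] = _parse_timestamps(df["timestamp"], path, "timestamp")
    for c in ("is_human", "is_research_personnel", "is_domestic"):
        df[c] = _parse_bool(df[c], path, c)
    for c in ("project_id", "station_id", "species"):
        df[c] = df[c].astype(str)
    empty = (df["project_id"].str.len() == 0) | (df["station_id"].str.len() == 0)
    if empty.any():
        raise SchemaError(f"{path}: empty project_id/station_id at line(s) "
                          f"{(df.index[empty] + 2).tolist()[:10]}")
    bad = df["is_research_personnel"] & ~df["is_human"]
    if bad.any():
        raise SchemaError(f"{path}: is_research_personnel implies is_human; violated at "
                          f"line(s) {(df.index[bad] + 2).tolist()[:10]}")
    return df


def write_detections(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%S+00:00")
    out.to_csv(path, index=False)


def read_deployments(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    cols = ["project_id", "station_id", "latitude", "longitude", "start", "end"]
    _require_columns(df, cols, path)
    df = df[cols].copy()
    df["start"] = _parse_timestamps(df["start"], path, "start")
    df["end"] = _parse_timestamps(df["end"], path, "end")
    df["latitude"] = pd.to_numeric(df["latitude"])
    df["longitude"] = pd.to_numeric(df["longitude"])
    if ((df["latitude"].abs() > 90) | (df["longitude"].abs() > 180)).any():
        raise SchemaError(f"{path}: coordinates out of bounds")
    if (df["start"] >= df["end"]).any():
        raise SchemaError(f"{path}: deployment start must precede end")
    return df


def write_deployments(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for c in ("start", "end"):
        out[c] = pd.to_datetime(out[c], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%S+00:00")
    out.to_csv(path, index=False)


def read_periods(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    cols = ["project_id", "period_label", "start", "end", "comparison_type"]
    _require_columns(df, cols, path)
    if "human_change_override" not in df.columns:
        df["human_change_override"] = np.nan
    df = df[cols + ["human_change_override"]].copy()
    df["start"] = _parse_timestamps(df["start"], path, "start")
    df["end"] = _parse_timestamps(df["end"], path, "end")
    if not df["period_label"].isin(["A", "B"]).all():
        raise SchemaError(f"{path}: period_label must be 'A' or 'B'")
    if not df["comparison_type"].isin(["between_year", "within_year"]).all():
        raise SchemaError(f"{path}: comparison_type must be between_year or within_year")
    ok_override = df["human_change_override"].isna() | df["human_change_override"].isin(
        ["A_higher", "B_higher"])
    if not ok_override.all():
        raise SchemaError(f"{path}: human_change_override must be A_higher or B_higher")
    if (df["start"] >= df["end"]).any():
        raise SchemaError(f"{path}: period start must precede end")
    for pid, grp in df.groupby("project_id"):
        if sorted(grp["period_label"]) != ["A", "B"]:
            raise SchemaError(f"{path}: project {pid} must define exactly periods A and B")
        if grp["comparison_type"].nunique() != 1:
            raise SchemaError(f"{path}: project {pid} has inconsistent comparison_type")
        a, b = grp.sort_values("period_label")[["start", "end"]].itertuples(index=False)
        if max(a.start, b.start) < min(a.end, b.end):
            raise SchemaError(f"{path}: project {pid} periods overlap")
    return df


def write_periods(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for c in ("start", "end"):
        out[c] = pd.to_datetime(out[c], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%S+00:00")
    out.to_csv(path, index=False)


def read_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    cols = ["species", "body_mass_kg", "trophic_level", "diet_breadth",
            "habitat_breadth", "diel_activity", "family"]
    _require_columns(df, cols, path)
    if "brain_mass_g" not in df.columns:
        df["brain_mass_g"] = np.nan
    df = df[cols + ["brain_mass_g"]].copy()
    df["species"] = normalize_species(df["species"])
    if (pd.to_numeric(df["body_mass_kg"]) <= 0).any():
        raise SchemaError(f"{path}: body_mass_kg must be positive")
    if not df["trophic_level"].isin(["carnivore", "omnivore", "herbivore"]).all():
        raise SchemaError(f"{path}: trophic_level must be carnivore/omnivore/herbivore")
    if not df["diel_activity"].isin(["diurnal", "cathemeral", "nocturnal"]).all():
        raise SchemaError(f"{path}: diel_activity must be diurnal/cathemeral/nocturnal")
    if not df["diet_breadth"].between(1, 4).all():
        raise SchemaError(f"{path}: diet_breadth must be in 1..4")
    if not df["habitat_breadth"].between(1, 9).all():
        raise SchemaError(f"{path}: habitat_breadth must be in 1..9")
    if (df["family"].astype(str).str.len() == 0).any():
        raise SchemaError(f"{path}: family must be nonempty")
    return df


def read_project_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    cols = ["project_id", "hmi", "openness", "stringency_control", "stringency_treatment"]
    _require_columns(df, cols, path)
    df = df[cols].copy()
    if not df["hmi"].between(0, 1).all():
        raise SchemaError(f"{path}: hmi must be in [0, 1]")
    if not df["openness"].isin(["open", "closed"]).all():
        raise SchemaError(f"{path}: openness must be open or closed")
    for c in ("stringency_control", "stringency_treatment"):
        if not df[c].between(0, 100).all():
            raise SchemaError(f"{path}: {c} must be in [0, 100]")
    return df


def read_hunting(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["project_id", "species", "hunted"], path)
    df = df[["project_id", "species", "hunted"]].copy()
    df["species"] = normalize_species(df["species"])
    df["hunted"] = _parse_bool(df["hunted"], path, "hunted")
    if df.duplicated(["project_id", "species"]).any():
        raise SchemaError(f"{path}: duplicate (project_id, species) rows")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Generic CSV writer for intermediate outputs (UTC ISO timestamps)."""
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[c]):
            out[c] = pd.to_datetime(out[c], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%S+00:00")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def validate_project(detections: pd.DataFrame, deployments: pd.DataFrame,
                     periods: pd.DataFrame, min_stations: int = 7,
                     min_effort_days: float = 7.0) -> pd.DataFrame:
    """Project-level inclusion report (report-only; mutates nothing).

    A station is retained when it accrues at least ``min_effort_days``
    camera-days in each period; a project is included when it retains at
    least ``min_stations`` stations and has a detectable human signal
    (camera-recorded human detections, or an expert override on its
    periods).

    Returns a DataFrame with one row per project: ``project_id``,
    ``included``, ``reason``, ``n_stations_retained``.
    """
    from .events import compute_effort  # local import; events does not import io

    rows = []
    for pid, per in periods.groupby("project_id"):
        depl = deployments[deployments["project_id"] == pid]
        dets = detections[detections["project_id"] == pid]
        effort = compute_effort(depl, per)
        if effort.empty:
            rows.append((pid, False, "no effort in periods", 0))
            continue
        wide = effort.pivot_table(index="station_id", columns="period_label",
                                  values="camera_days", aggfunc="sum", fill_value=0.0)
        for lab in ("A", "B"):
            if lab not in wide.columns:
                wide[lab] = 0.0
        retained = wide[(wide["A"] >= min_effort_days) & (wide["B"] >= min_effort_days)]
        n_ret = len(retained)
        human_ok = bool((dets["is_human"] & ~dets["is_research_personnel"]).any()) or \
            per["human_change_override"].notna().any()
        if n_ret < min_stations:
            rows.append((pid, False, f"stations<{min_stations}", n_ret))
        elif not human_ok:
            rows.append((pid, False, "no human signal", n_ret))
        else:
            rows.append((pid, True, "", n_ret))
    return pd.DataFrame(rows, columns=["project_id", "included", "reason",
                                       "n_stations_retained"])
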
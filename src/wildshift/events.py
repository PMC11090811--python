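"""Independent detection events, sampling effort and count aggregation.

Consecutive raw detections of the same species at the same station are
chained into one independent event while the gap to the previous raw
detection stays at or below the independence window (default 30 min); a
gap strictly greater than the window starts a new event.  Effort is the
fractional-day overlap between camera deployments and a comparison
period, and counts are aggregated per project x species x period with
per-station detail.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import normalize_species

__all__ = [
    "build_events",
    "compute_effort",
    "filter_analysis_species",
    "aggregate_counts",
    "HUMAN_SPECIES",
]

HUMAN_SPECIES = "human"


def build_events(detections: pd.DataFrame, window_minutes: float = 30.0) -> pd.DataFrame:
    """Collapse raw detections into independent detection events.

    A new event starts iff the time since the immediately preceding raw
    detection of the same species at the same station exceeds
    ``window_minutes`` (gap-based chaining).  Human rows are labelled
    with species ``"human"`` and keep their research-personnel flag.

    Returns a DataFrame: project_id, station_id, species, is_human,
    is_research_personnel, event_start, n_images.
    """
    if window_minutes < 0:
        raise ValueError("window_minutes must be nonnegative")
    df = detections.copy()
    df["species"] = np.where(df["is_human"], HUMAN_SPECIES, df["species"])
    key = ["project_id", "station_id", "species", "is_research_personnel"]
    df = df.sort_values(key + ["timestamp"], kind="mergesort").reset_index(drop=True)

    same_group = (df[key] == df[key].shift()).all(axis=1)
    gap = df["timestamp"].diff()
    new_event = ~same_group | (gap > pd.Timedelta(minutes=window_minutes))
    event_id = new_event.cumsum()

    grouped = df.groupby(event_id, sort=True)
    events = grouped.agg(
        project_id=("project_id", "first"),
        station_id=("station_id", "first"),
        species=("species", "first"),
        is_human=("is_human", "first"),
        is_research_personnel=("is_research_personnel", "first"),
        is_domestic=("is_domestic", "first"),
        event_start=("timestamp", "first"),
        n_images=("timestamp", "size"),
    ).reset_index(drop=True)
    return events


def compute_effort(deployments: pd.DataFrame, periods: pd.DataFrame) -> pd.DataFrame:
    """Camera-days per station and period from deployment/period overlap.

    ``camera_days`` is the summed fractional-day length of the
    intersections between a station's deployments and the period;
    stations with zero overlap are omitted.
    """
    rows = []
    for per in periods.itertuples(index=False):
        depl = deployments[deployments["project_id"] == per.project_id]
        lo = np.maximum(depl["start"].values, np.datetime64(per.start.tz_convert("UTC").tz_localize(None)))
        hi = np.minimum(depl["end"].values, np.datetime64(per.end.tz_convert("UTC").tz_localize(None)))
        days = (hi - lo) / np.timedelta64(1, "D")
        days = np.clip(days.astype(float), 0.0, None)
        sub = pd.DataFrame({
            "project_id": per.project_id,
            "station_id": depl["station_id"].values,
            "period_label": per.period_label,
            "camera_days": days,
        })
        rows.append(sub[sub["camera_days"] > 0])
    if not rows:
        return pd.DataFrame(columns=["project_id", "station_id", "period_label", "camera_days"])
    out = pd.concat(rows, ignore_index=True)
    return (out.groupby(["project_id", "station_id", "period_label"], as_index=False)
               ["camera_days"].sum())


def filter_analysis_species(events: pd.DataFrame, traits: pd.DataFrame,
                            min_body_mass_kg: float = 1.0):
    """Split events into the wild-mammal analysis stream and the human stream.

    Retains wild mammal species with body mass >= ``min_body_mass_kg``
    (boundary inclusive) after dropping domestic animals; humans go to a
    separate stream with research-personnel events removed.  Species
    missing from the trait table are reported with a warning and
    dropped.

    Returns ``(animal_events, human_events)``.
    """
    humans = events[events["is_human"] & ~events["is_research_personnel"]].copy()

    animals = events[~events["is_human"] & ~events["is_domestic"]].copy()
    animals["species"] = normalize_species(animals["species"])
    tr = traits.set_index(normalize_species(traits["species"]))
    known = animals["species"].isin(tr.index)
    missing = sorted(animals.loc[~known, "species"].unique())
    if missing:
        warnings.warn(f"species missing from trait table, dropped: {', '.join(missing)}")
    animals = animals[known]
    mass = animals["species"].map(tr["body_mass_kg"])
    animals = animals[mass >= min_body_mass_kg]
    return animals.reset_index(drop=True), humans.reset_index(drop=True)


def _label_period(events: pd.DataFrame, periods: pd.DataFrame) -> pd.Series:
    """Period label for each event by [start, end) membership, else NaN."""
    lab = pd.Series(np.nan, index=events.index, dtype=object)
    for per in periods.itertuples(index=False):
        m = (events["project_id"] == per.project_id) & \
            (events["event_start"] >= per.start) & (events["event_start"] < per.end)
        lab[m] = per.period_label
    return lab


def aggregate_counts(events: pd.DataFrame, periods: pd.DataFrame) -> pd.DataFrame:
    """Per-station event counts by project, species and period.

    Events outside both periods are dropped.  If the events carry a
    ``day_night`` column, night/day counts are included.

    Returns a long DataFrame: project_id, species, period_label,
    station_id, n_events [, n_night, n_day].
    """
    ev = events.copy()
    ev["period_label"] = _label_period(ev, periods)
    ev = ev[ev["period_label"].notna()]
    keys = ["project_id", "species", "period_label", "station_id"]
    agg = {"n_events": ("event_start", "size")}
    if "day_night" in ev.columns:
        ev["_night"] = (ev["day_night"] == "night").astype(int)
        agg["n_night"] = ("_night", "sum")
    out = ev.groupby(keys, as_index=False).agg(**agg)
    if "n_night" in out.columns:
        out["n_day"] = out["n_events"] - out["n_night"]
    return out


def population_totals(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum per-station counts to project x species x period totals."""
    cols = [c for c in ("n_events", "n_night", "n_day") if c in counts.columns]
    return counts.groupby(["project_id", "species", "period_label"], as_index=False)[cols].sum()
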
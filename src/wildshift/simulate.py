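"""Synthetic camera-trap studies with known ground truth.

Generates complete multi-project studies — detections, deployments,
periods, traits, project covariates, hunting status — whose statistical
structure mirrors the two-stage analysis: per-station independent-event
counts are NB2-overdispersed around an effort x rate mean with a
log-scale treatment effect that varies by project, family and species
random effects plus moderator slopes; event timestamps are drawn from
day/night mixtures (day and night windows computed from the solar
module for each station and date) whose night-time proportion shifts by
a target log risk ratio under treatment; human detections are Poisson
with a configured fold change between periods.

All randomness flows from a single :class:`numpy.random.Generator`
keyed by ``config.seed`` with a fixed draw order, so every table is
reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import solar

__all__ = ["SimConfig", "simulate_study", "simulate_counts", "simulate_worked_population"]

_TROPHIC_LEVELS = ("carnivore", "omnivore", "herbivore")
_DIEL = ("diurnal", "cathemeral", "nocturnal")


@dataclass
class SimConfig:
    """Parameterization of the synthetic study generator.

    Defaults generate studies at the scale used throughout the test
    suite: 10 projects x 15 species, 10 stations per project and 60-day
    comparison periods, which satisfies the inclusion criteria
    (>= 7 stations, >= 7 days) by construction.
    """

    seed: int = 0
    n_projects: int = 10
    species_pool_size: int = 15
    stations_per_project: int = 10
    period_length_days: int = 60
    families_per_pool: int = 5
    # lognormal baseline detection rate, events/day per population
    baseline_rate_meanlog: float = float(np.log(0.15))
    baseline_rate_sdlog: float = 0.6
    nb_theta: float = 2.0
    true_mean_beta: float = 0.0
    sigma_project: float = 0.2
    sigma_family: float = 0.1
    sigma_species: float = 0.15
    #: slopes on centred moderators; keys: "hmi" (per (hmi-0.5)),
    #: "openness" (open vs closed), "carnivore_hmi" (extra HMI slope for
    #: carnivores: the plantable trophic-group x HMI interaction)
    moderator_slopes: dict = field(default_factory=dict)
    baseline_nocturnality: float = 0.35
    true_mean_rr: float = 0.0
    #: uniform-log range of the human detection-rate fold change
    #: (treatment over control)
    human_fold_range: tuple = (1.5, 8.0)
    human_rate_per_day: float = 0.5
    comparison_type: str = "between_year"
    lat_range: tuple = (-55.0, 55.0)
    domestic_rate_per_day: float = 0.005
    personnel_rate_per_day: float = 0.005

    def validate(self) -> None:
        if self.stations_per_project < 7 or self.period_length_days < 7:
            raise ValueError("stations_per_project and period_length_days must be >= 7")
        if not (0.0 < self.baseline_nocturnality < 1.0):
            raise ValueError("baseline_nocturnality must be in (0, 1)")
        if min(self.sigma_project, self.sigma_family, self.sigma_species) < 0:
            raise ValueError("random-effect SDs must be nonnegative")
        lo, hi = self.lat_range
        if lo < -66.0 or hi > 66.0:
            raise ValueError("latitudes beyond +/-66 deg risk empty day/night windows; "
                             "restrict lat_range to at most (-66, 66)")


def _draw_traits(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.species_pool_size
    fam = rng.integers(0, cfg.families_per_pool, size=n)
    mass = np.exp(rng.normal(2.0, 1.5, size=n))
    mass = np.clip(mass, 1.0, 4600.0)
    brain = 10.0 * (mass ** 0.7) * np.exp(rng.normal(0.0, 0.3, size=n))
    has_brain = rng.random(n) < 0.9
    return pd.DataFrame({
        "species": [f"species {i:03d}" for i in range(n)],
        "body_mass_kg": np.round(mass, 3),
        "trophic_level": rng.choice(_TROPHIC_LEVELS, size=n, p=[0.3, 0.3, 0.4]),
        "diet_breadth": rng.integers(1, 5, size=n),
        "habitat_breadth": rng.integers(1, 10, size=n),
        "diel_activity": rng.choice(_DIEL, size=n, p=[0.35, 0.3, 0.35]),
        "brain_mass_g": np.where(has_brain, np.round(brain, 2), np.nan),
        "family": [f"family{f}" for f in fam],
    })


def simulate_counts(cfg: SimConfig):
    """Draw the statistical skeleton of a study (no timestamps).

    Returns a dict with:

    ``counts``
        Per project x species x station x period ('control'/'treatment')
        rows: n_events, n_night, n_day, camera_days.
    ``traits``, ``covariates``, ``hunting``
        Input tables in the standard schemas.
    ``truth``
        Per-population true log rate change and realized log risk
        ratio, plus the generating configuration.

    The full :func:`simulate_study` builds on exactly this skeleton and
    then materializes detections; recovery experiments can use the
    skeleton directly.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    traits = _draw_traits(cfg, rng)
    fam_codes = pd.Categorical(traits["family"]).codes

    u_fam_amount = rng.normal(0.0, cfg.sigma_family, size=cfg.families_per_pool)
    u_spec_amount = rng.normal(0.0, cfg.sigma_species, size=cfg.species_pool_size)
    u_fam_rr = rng.normal(0.0, cfg.sigma_family, size=cfg.families_per_pool)
    u_spec_rr = rng.normal(0.0, cfg.sigma_species, size=cfg.species_pool_size)
    is_carn = (traits["trophic_level"] == "carnivore").to_numpy(float)

    slopes = cfg.moderator_slopes
    days = float(cfg.period_length_days)

    cov_rows, count_rows, hunt_rows, truth_pops = [], [], [], []
    for p in range(cfg.n_projects):
        pid = f"proj{p:02d}"
        hmi = float(rng.uniform(0.05, 0.95))
        openness = "open" if rng.random() < 0.4 else "closed"
        str_c = float(rng.uniform(5, 40))
        str_t = float(rng.uniform(30, 90))
        cov_rows.append((pid, hmi, openness, str_c, str_t))
        u_proj_amount = rng.normal(0.0, cfg.sigma_project)
        u_proj_rr = rng.normal(0.0, cfg.sigma_project)

        for s in range(cfg.species_pool_size):
            sp = traits["species"].iloc[s]
            lam = float(np.exp(rng.normal(cfg.baseline_rate_meanlog, cfg.baseline_rate_sdlog)))
            beta = (cfg.true_mean_beta + u_proj_amount + u_fam_amount[fam_codes[s]]
                    + u_spec_amount[s]
                    + slopes.get("hmi", 0.0) * (hmi - 0.5)
                    + slopes.get("openness", 0.0) * (1.0 if openness == "open" else 0.0)
                    + slopes.get("carnivore_hmi", 0.0) * is_carn[s] * (hmi - 0.5))
            rr = (cfg.true_mean_rr + u_proj_rr + u_fam_rr[fam_codes[s]] + u_spec_rr[s])
            n_l = cfg.baseline_nocturnality
            n_h = float(np.clip(n_l * np.exp(rr), 0.01, 0.97))
            rr_real = float(np.log(n_h / n_l))

            mu_c = days * lam
            mu_t = days * lam * np.exp(beta)
            th = cfg.nb_theta
            y_c = rng.negative_binomial(th, th / (th + mu_c), size=cfg.stations_per_project)
            y_t = rng.negative_binomial(th, th / (th + mu_t), size=cfg.stations_per_project)
            x_c = rng.binomial(y_c, n_l)
            x_t = rng.binomial(y_t, n_h)
            for st in range(cfg.stations_per_project):
                sid = f"{pid}-st{st:02d}"
                count_rows.append((pid, sp, sid, "control", int(y_c[st]), int(x_c[st]), days))
                count_rows.append((pid, sp, sid, "treatment", int(y_t[st]), int(x_t[st]), days))
            if rng.random() < 0.9:
                hunt_rows.append((pid, sp, bool(rng.random() < 0.4)))
            truth_pops.append({
                "project_id": pid, "species": sp, "true_beta": float(beta),
                "true_rr": rr_real, "baseline_rate": lam,
                "nocturnality_control": n_l, "nocturnality_treatment": n_h,
            })

    counts = pd.DataFrame(count_rows, columns=[
        "project_id", "species", "station_id", "period_label", "n_events",
        "n_night", "camera_days"])
    counts["n_day"] = counts["n_events"] - counts["n_night"]
    covariates = pd.DataFrame(cov_rows, columns=[
        "project_id", "hmi", "openness", "stringency_control", "stringency_treatment"])
    hunting = pd.DataFrame(hunt_rows, columns=["project_id", "species", "hunted"])

    # human counts: Poisson, configured fold change (treatment higher)
    lo, hi = cfg.human_fold_range
    folds = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_projects))
    human_rows = []
    for p in range(cfg.n_projects):
        pid = f"proj{p:02d}"
        for st in range(cfg.stations_per_project):
            sid = f"{pid}-st{st:02d}"
            hc = rng.poisson(cfg.human_rate_per_day * days)
            ht = rng.poisson(cfg.human_rate_per_day * folds[p] * days)
            human_rows.append((pid, sid, "control", int(hc), days))
            human_rows.append((pid, sid, "treatment", int(ht), days))
    human_counts = pd.DataFrame(human_rows, columns=[
        "project_id", "station_id", "period_label", "n_events", "camera_days"])

    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "populations": truth_pops,
        "human_fold_changes": {f"proj{p:02d}": float(folds[p])
                               for p in range(cfg.n_projects)},
    }
    return {"counts": counts, "human_counts": human_counts, "traits": traits,
            "covariates": covariates, "hunting": hunting, "truth": truth,
            "rng": rng}


def _period_windows(cfg: SimConfig, rng: np.random.Generator):
    """Start dates of the two raw periods; which raw label is treatment is random."""
    if cfg.comparison_type == "between_year":
        a0 = pd.Timestamp("2019-06-01", tz="UTC")
        b0 = pd.Timestamp("2020-06-01", tz="UTC")
    else:
        a0 = pd.Timestamp("2020-01-10", tz="UTC")
        b0 = pd.Timestamp("2020-04-01", tz="UTC")
    return a0, b0


def _sun_windows(lat, lon, dates):
    """Vectorized sunrise/sunset (UTC) per date via the closed-form hour angle."""
    jd_noon = 2440587.5 + dates.asi8 / 1e9 / 86400.0 + 0.5
    decl, eot = solar.solar_declination_eot(jd_noon)
    noon_min = 720.0 - 4.0 * lon - eot
    cos_h0 = -np.tan(np.deg2rad(lat)) * np.tan(np.deg2rad(decl))
    if np.any(np.abs(cos_h0) >= 1.0):
        raise ValueError("polar day/night at this latitude/date; day or night window "
                         "is empty — keep latitudes within the configured range")
    h0 = np.rad2deg(np.arccos(cos_h0))
    sunrise = noon_min - 4.0 * h0
    sunset = noon_min + 4.0 * h0
    return sunrise, sunset  # minutes from the date's UTC midnight


def _place_times(rng, period_start, days, lat, lon, n_events, night_flags):
    """Uniform times inside the day or night solar window of random dates."""
    dates_idx = rng.integers(0, days, size=n_events)
    base = pd.DatetimeIndex([period_start + pd.Timedelta(days=int(d)) for d in dates_idx])
    sunrise, sunset = _sun_windows(lat, lon, base)
    margin = 2.0  # minutes away from the terminator
    u = rng.random(n_events)
    minutes = np.where(
        night_flags,
        # night: sunset of the date to sunrise of the next day
        sunset + margin + u * ((sunrise + 1440.0) - sunset - 2 * margin),
        sunrise + margin + u * (sunset - sunrise - 2 * margin),
    )
    return base + pd.to_timedelta(np.round(minutes * 60.0), unit="s")


def _enforce_independence(df: pd.DataFrame, window_minutes: float = 30.0) -> pd.DataFrame:
    """Push colliding same-station/species detections apart (> window gaps)."""
    gap = pd.Timedelta(minutes=window_minutes + 1)
    key = ["project_id", "station_id", "species"]
    df = df.sort_values(key + ["timestamp"], kind="mergesort").reset_index(drop=True)
    for _ in range(100):
        same = (df[key] == df[key].shift()).all(axis=1)
        bad = same & (df["timestamp"].diff() <= pd.Timedelta(minutes=window_minutes))
        if not bad.any():
            break
        df.loc[bad, "timestamp"] = df["timestamp"].shift()[bad] + gap
        df = df.sort_values(key + ["timestamp"], kind="mergesort").reset_index(drop=True)
    return df


def simulate_study(config: SimConfig | None = None):
    """Generate a full synthetic study.

    Returns ``(tables, truth)`` where ``tables`` holds DataFrames in the
    documented input schemas: detections, deployments, periods, traits,
    project_covariates, hunting.
    """
    cfg = config or SimConfig()
    sk = simulate_counts(cfg)
    rng = sk["rng"]  # continue the single stream
    counts, human = sk["counts"], sk["human_counts"]

    a0, b0 = _period_windows(cfg, rng)
    days = int(cfg.period_length_days)
    # which raw label carries the treatment (higher human activity)
    treat_is_b = rng.random(cfg.n_projects) < 0.5

    lat_lo, lat_hi = cfg.lat_range
    proj_lat = rng.uniform(lat_lo, lat_hi, size=cfg.n_projects)
    proj_lon = rng.uniform(-180.0, 180.0, size=cfg.n_projects)

    period_rows, depl_rows, det_rows = [], [], []
    station_coords = {}
    for p in range(cfg.n_projects):
        pid = f"proj{p:02d}"
        period_rows.append((pid, "A", a0, a0 + pd.Timedelta(days=days), cfg.comparison_type, np.nan))
        period_rows.append((pid, "B", b0, b0 + pd.Timedelta(days=days), cfg.comparison_type, np.nan))
        for st in range(cfg.stations_per_project):
            sid = f"{pid}-st{st:02d}"
            lat = float(np.clip(proj_lat[p] + rng.normal(0, 0.05), lat_lo, lat_hi))
            lon = float(np.clip(proj_lon[p] + rng.normal(0, 0.05), -180.0, 180.0))
            station_coords[sid] = (lat, lon)
            for start in (a0, b0):
                depl_rows.append((pid, sid, lat, lon, start, start + pd.Timedelta(days=days)))

    label_of = {}
    for p in range(cfg.n_projects):
        pid = f"proj{p:02d}"
        label_of[(pid, "treatment")] = "B" if treat_is_b[p] else "A"
        label_of[(pid, "control")] = "A" if treat_is_b[p] else "B"

    def _start_of(pid, period):
        return b0 if label_of[(pid, period)] == "B" else a0

    for row in counts.itertuples(index=False):
        if row.n_events == 0:
            continue
        lat, lon = station_coords[row.station_id]
        flags = np.concatenate([np.ones(row.n_night, bool), np.zeros(row.n_day, bool)])
        ts = _place_times(rng, _start_of(row.project_id, row.period_label), days,
                          lat, lon, row.n_events, flags)
        for t in ts:
            det_rows.append((row.project_id, row.station_id, t, row.species,
                             False, False, False))

    for row in human.itertuples(index=False):
        if row.n_events == 0:
            continue
        lat, lon = station_coords[row.station_id]
        flags = rng.random(row.n_events) < 0.15  # humans mostly diurnal
        ts = _place_times(rng, _start_of(row.project_id, row.period_label), days,
                          lat, lon, row.n_events, flags)
        for t in ts:
            det_rows.append((row.project_id, row.station_id, t, "Homo sapiens",
                             True, False, False))

    # nuisance detections exercised by the filters: research personnel
    # servicing cameras and a domestic species
    for p in range(cfg.n_projects):
        pid = f"proj{p:02d}"
        for kind, rate in (("personnel", cfg.personnel_rate_per_day),
                           ("domestic", cfg.domestic_rate_per_day)):
            n = int(rng.poisson(rate * days * cfg.stations_per_project * 2))
            for _ in range(n):
                st = int(rng.integers(0, cfg.stations_per_project))
                sid = f"{pid}-st{st:02d}"
                lat, lon = station_coords[sid]
                start = a0 if rng.random() < 0.5 else b0
                ts = _place_times(rng, start, days, lat, lon, 1, np.array([False]))
                if kind == "personnel":
                    det_rows.append((pid, sid, ts[0], "Homo sapiens", True, True, False))
                else:
                    det_rows.append((pid, sid, ts[0], "canis familiaris",
                                     False, False, True))

    detections = pd.DataFrame(det_rows, columns=[
        "project_id", "station_id", "timestamp", "species", "is_human",
        "is_research_personnel", "is_domestic"])
    detections = _enforce_independence(detections)
    detections = detections.sort_values(
        ["project_id", "station_id", "timestamp"], kind="mergesort").reset_index(drop=True)

    deployments = pd.DataFrame(depl_rows, columns=[
        "project_id", "station_id", "latitude", "longitude", "start", "end"])
    periods = pd.DataFrame(period_rows, columns=[
        "project_id", "period_label", "start", "end", "comparison_type",
        "human_change_override"])

    truth = sk["truth"]
    truth["treatment_raw_label"] = {f"proj{p:02d}": ("B" if treat_is_b[p] else "A")
                                    for p in range(cfg.n_projects)}
    tables = {
        "detections": detections,
        "deployments": deployments,
        "periods": periods,
        "traits": sk["traits"],
        "project_covariates": sk["covariates"],
        "hunting": sk["hunting"],
    }
    return tables, truth


def simulate_worked_population(rates=(0.1, 0.2), nocturnalities=(0.4, 0.6),
                               n_stations: int = 10, days: float = 100.0):
    """Deterministic expected-count tables for a single population.

    No sampling: every station's event count equals rate x days and the
    night share equals the stated nocturnality, so the fitted rate
    effect is exactly ``ln(rates[1]/rates[0])`` and the log risk ratio
    exactly ``ln(nocturnalities[1]/nocturnalities[0])``.

    Returns ``(counts, effort)`` in the shapes taken by
    :func:`wildshift.effects.fit_rate_effect` and the timing totals.
    """
    rows = []
    for st in range(n_stations):
        for period, rate, noct in zip(("control", "treatment"), rates, nocturnalities):
            n = rate * days
            rows.append((f"st{st:02d}", period, n, noct * n, days))
    df = pd.DataFrame(rows, columns=["station_id", "period_label", "n_events",
                                     "n_night", "camera_days"])
    counts = df[["station_id", "period_label", "n_events", "n_night"]].copy()
    effort = df[["station_id", "period_label", "camera_days"]].copy()
    return counts, effort
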
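"""End-to-end orchestration of the two-stage analysis.

Stages: input validation -> independent events -> solar day/night
labels -> period orientation -> stage-one effect sizes (amount and
timing) -> moderator assembly -> stage-two meta-regression (global
model, interaction screen, data-subset screens) for both responses.
Every intermediate table is written to the output directory together
with a JSON run report listing inclusions and exclusions with reasons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, design, effects, events, io, meta, moderators, solar

log = logging.getLogger("wildshift")

__all__ = ["RunConfig", "run_pipeline"]

#: fixed terms of the global meta-regression (complete-data moderators)
GLOBAL_TERMS = ("trophic_group", "diet_breadth", "habitat_breadth",
                "diel_activity", "openness", "hmi", "stringency_change",
                "comparison_type")


@dataclass
class RunConfig:
    detections: str
    deployments: str
    periods: str
    traits: str
    project_covariates: str
    hunting: str | None = None
    outdir: str = "wildshift_out"
    window_minutes: float = 30.0
    min_detections_timing: int = 10
    min_stations: int = 7
    min_effort_days: float = 7.0
    min_body_mass_kg: float = 1.0
    correlation_threshold: float = 0.6
    do_amount: bool = True
    do_timing: bool = True
    do_subsets: bool = True
    do_meta: bool = True
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path):
        import yaml
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _station_coords(deployments: pd.DataFrame) -> pd.DataFrame:
    return (deployments.groupby("station_id", as_index=False)
            .agg(latitude=("latitude", "first"), longitude=("longitude", "first")))


def _stage_one(counts, effort, plans, cfg, report):
    """Per-population amount and timing effect sizes, oriented by the plans."""
    amount_rows, timing_rows = [], []
    for pid, plan in plans.items():
        relabel = {plan.control_label: "control", plan.treatment_label: "treatment"}
        eff_p = effort[effort["project_id"] == pid].copy()
        eff_p["period_label"] = eff_p["period_label"].map(relabel)
        shared = design._shared_stations(eff_p)
        cnt_p = counts[counts["project_id"] == pid].copy()
        cnt_p["period_label"] = cnt_p["period_label"].map(relabel)
        for sp, grp in cnt_p.groupby("species"):
            full = effects.attach_zero_counts(
                grp[["station_id", "period_label", "n_events"]], eff_p)
            if cfg.do_amount:
                try:
                    r = effects.fit_rate_effect(full, eff_p, shared_stations=shared,
                                                project_id=pid, species=sp)
                    if r.converged:
                        amount_rows.append(r)
                    else:
                        report["excluded_amount"].append(
                            {"project_id": pid, "species": sp, "reason": "non-convergence"})
                except (ValueError, np.linalg.LinAlgError) as exc:
                    report["excluded_amount"].append(
                        {"project_id": pid, "species": sp, "reason": str(exc)})
            if cfg.do_timing and {"n_night", "n_day"} <= set(grp.columns):
                tot = grp.groupby("period_label")[["n_events", "n_night", "n_day"]].sum()
                if {"control", "treatment"} <= set(tot.index):
                    t = effects.fit_nocturnality_effect(
                        int(tot.loc["treatment", "n_night"]), int(tot.loc["treatment", "n_events"]),
                        int(tot.loc["control", "n_night"]), int(tot.loc["control", "n_events"]),
                        project_id=pid, species=sp,
                        min_detections=cfg.min_detections_timing)
                    if t is None:
                        report["excluded_timing"].append(
                            {"project_id": pid, "species": sp,
                             "reason": f"<{cfg.min_detections_timing} detections in a period"})
                    else:
                        timing_rows.append(t)
                else:
                    report["excluded_timing"].append(
                        {"project_id": pid, "species": sp, "reason": "missing period"})
    amount = pd.DataFrame([vars(r) for r in amount_rows])
    timing = pd.DataFrame([vars(t) for t in timing_rows])
    return amount, timing


def _stage_two(effects_df, mods, cfg, response):
    """Global model + interaction screen + subset screens for one response."""
    y = effects_df["beta" if response == "amount" else "rr"].to_numpy(float)
    v = effects_df["var"].to_numpy(float)
    data = mods.merge(effects_df[["project_id", "species"]],
                      on=["project_id", "species"], how="right")
    groups = pd.DataFrame({"project": data["project_id"], "family": data["family"],
                           "species": data["species"]})
    terms = [t for t in GLOBAL_TERMS]

    std, scaling = moderators.standardize(data)
    screen = moderators.correlation_screen(
        std[[c for c in moderators.CONTINUOUS_MODERATORS if c in std.columns]],
        threshold=cfg.correlation_threshold)

    X = meta.build_design(std, terms)
    spec = meta.MetaModelSpec(response=response, fixed_terms=tuple(terms))
    fit = meta.fit_meta(y, v, X, groups, spec)
    null_fit = meta.fit_meta(y, v, meta.build_design(std, []), groups,
                             meta.MetaModelSpec(response=response))
    het = meta.i_squared(fit)
    r2 = meta.pseudo_r2(fit, null_fit)

    sel_table, retained_terms, reml_fit = meta.select_interactions(
        y, v, std, groups, terms)

    subsets = {}
    if cfg.do_subsets:
        for var, extra in (("hunted", ("hunted:hmi",)),
                           ("relative_brain_size", ()),
                           ("human_fold_change", ())):
            try:
                tab, preferred = meta.subset_model_selection(
                    y, v, std, groups, terms, var, extra_candidates=extra)
                subsets[var] = {"table": tab.to_dict(orient="records"),
                                "preferred_terms": preferred}
            except ValueError as exc:
                subsets[var] = {"error": str(exc)}

    pooled = meta.fit_meta(y, v, meta.build_design(std, []), groups,
                           meta.MetaModelSpec(response=response))
    return {
        "k": int(fit.k),
        "pooled_mean": pooled.coef.loc["intercept"].to_dict(),
        "global_coefficients": fit.coef.round(6).reset_index()
                                   .rename(columns={"index": "term"})
                                   .to_dict(orient="records"),
        "sigma2": fit.sigma2,
        "i2": {"levels": het.i2_level, "total": het.i2_total,
               "typical_sampling_variance": het.typical_v},
        "pseudo_r2": r2,
        "interaction_selection": sel_table.to_dict(orient="records"),
        "retained_terms": retained_terms,
        "retained_model_coefficients": reml_fit.coef.round(6).reset_index()
                                           .rename(columns={"index": "term"})
                                           .to_dict(orient="records"),
        "subset_selection": subsets,
        "correlation_screen_flagged": screen[screen["flagged"]].to_dict(orient="records"),
        "scaling": {k: list(vv) for k, vv in scaling.items()},
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full two-stage analysis; returns the run report dict."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": cfg.seed,
                    "excluded_projects": [], "excluded_amount": [],
                    "excluded_timing": []}

    detections = io.read_detections(cfg.detections)
    deployments = io.read_deployments(cfg.deployments)
    periods = io.read_periods(cfg.periods)
    traits = io.read_traits(cfg.traits)
    covariates = io.read_project_covariates(cfg.project_covariates)
    hunting = io.read_hunting(cfg.hunting) if cfg.hunting else None

    inclusion = io.validate_project(detections, deployments, periods,
                                    min_stations=cfg.min_stations,
                                    min_effort_days=cfg.min_effort_days)
    io.write_table(inclusion, out / "project_inclusion.csv")
    report["excluded_projects"] = inclusion[~inclusion["included"]].to_dict(orient="records")
    keep = set(inclusion.loc[inclusion["included"], "project_id"])
    detections = detections[detections["project_id"].isin(keep)]
    periods = periods[periods["project_id"].isin(keep)]

    ev = events.build_events(detections, window_minutes=cfg.window_minutes)
    animals, humans = events.filter_analysis_species(ev, traits, cfg.min_body_mass_kg)
    effort = events.compute_effort(deployments, periods)
    io.write_table(effort, out / "effort.csv")

    coords = _station_coords(deployments).set_index("station_id")
    missing = set(animals["station_id"]) - set(coords.index)
    if missing:
        raise ValueError(f"stations without deployment coordinates: {sorted(missing)[:5]}")
    alt = solar.sun_altitude(coords.loc[animals["station_id"], "latitude"].to_numpy(),
                             coords.loc[animals["station_id"], "longitude"].to_numpy(),
                             animals["event_start"])
    animals = animals.assign(day_night=solar.classify_day_night(alt))
    io.write_table(animals, out / "events.csv")

    animal_counts = events.aggregate_counts(animals, periods)
    human_counts = events.aggregate_counts(humans, periods)

    plans = {}
    for pid, per in periods.groupby("project_id"):
        hc = human_counts[human_counts["project_id"] == pid]
        try:
            plans[pid] = design.orient_periods(
                hc, effort[effort["project_id"] == pid], per)
        except design.OrientationError as exc:
            report["excluded_projects"].append(
                {"project_id": pid, "included": False, "reason": str(exc)})
    io.write_table(pd.DataFrame([vars(p) for p in plans.values()]),
                   out / "period_plans.csv")

    amount, timing = _stage_one(animal_counts, effort, plans, cfg, report)
    io.write_table(amount, out / "effects_amount.csv")
    io.write_table(timing, out / "effects_timing.csv")
    report["k_amount"] = int(len(amount))
    report["k_timing"] = int(len(timing))

    pops = pd.concat([amount[["project_id", "species"]] if len(amount) else None,
                      timing[["project_id", "species"]] if len(timing) else None]
                     ).drop_duplicates().reset_index(drop=True)
    fold = pd.DataFrame([
        {"project_id": pid, "human_fold_change": design.human_fold_change(plan)}
        for pid, plan in plans.items() if plan.orientation_source == "camera"])
    mods = moderators.build_moderators(
        pops, traits, covariates, hunting, fold,
        comparison_types=periods[["project_id", "comparison_type"]])
    io.write_table(mods, out / "moderators.csv")

    results = {}
    if cfg.do_meta and cfg.do_amount and len(amount):
        results["amount"] = _stage_two(amount, mods, cfg, "amount")
    if cfg.do_meta and cfg.do_timing and len(timing):
        results["timing"] = _stage_two(timing, mods, cfg, "timing")
    report["results"] = results

    with open(out / "meta_results.json", "w") as fh:
        json.dump(results, fh, indent=1, default=float)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    log.info("pipeline complete: k_amount=%s k_timing=%s",
             report["k_amount"], report["k_timing"])
    return report
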
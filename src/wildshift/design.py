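"""Treatment/control orientation of comparison periods.

Each project supplies two raw periods labelled A and B.  The treatment
period is the one with the higher human detection rate, estimated with
the same effort-offset NB model used for animals (so orientation and
effect sizes share one effort correction); when cameras recorded no
usable human signal an expert override can orient the periods instead.
Downstream animal effect sizes are expressed treatment vs control
regardless of calendar order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effects import attach_zero_counts, fit_rate_effect

__all__ = ["PeriodPlan", "orient_periods", "human_fold_change", "OrientationError"]


class OrientationError(ValueError):
    """Project has no detectable change in human activity."""


@dataclass
class PeriodPlan:
    project_id: str
    control_label: str                 # raw label (A/B) of the control period
    treatment_label: str
    comparison_type: str
    human_effect: float                # log rate change, treatment vs control (NaN if override)
    human_effect_var: float
    orientation_source: str            # "camera" | "override"


def orient_periods(human_counts: pd.DataFrame, effort: pd.DataFrame,
                   periods: pd.DataFrame, min_effect: float = 0.0) -> PeriodPlan:
    """Orient one project's periods into control and treatment.

    Parameters
    ----------
    human_counts
        Per-station human event counts with columns station_id,
        period_label (A/B), n_events; may be empty.
    effort
        station_id, period_label, camera_days for the same project.
    periods
        The project's two rows from the periods table (labels A and B,
        optional ``human_change_override``).
    min_effect
        Minimum |log rate change| that counts as a detectable camera
        signal; below it the override (if any) is used.

    Raises
    ------
    OrientationError
        No camera signal above ``min_effect`` and no override.
    """
    project_id = str(periods["project_id"].iloc[0])
    comparison_type = str(periods["comparison_type"].iloc[0])
    override = periods["human_change_override"].dropna()
    override = str(override.iloc[0]) if len(override) else None

    beta = var = None
    if len(human_counts) and human_counts["n_events"].sum() > 0:
        # fit with B as the provisional "treatment"; sign decides orientation
        eff = effort.copy()
        eff["period_label"] = eff["period_label"].map({"A": "control", "B": "treatment"})
        cnt = human_counts.copy()
        cnt["period_label"] = cnt["period_label"].map({"A": "control", "B": "treatment"})
        cnt = attach_zero_counts(cnt, eff)
        shared = _shared_stations(eff)
        fit = fit_rate_effect(cnt, eff, shared_stations=shared,
                              project_id=project_id, species="human")
        if fit.converged and abs(fit.beta) > min_effect:
            beta, var = fit.beta, fit.var

    if beta is not None:
        if beta > 0:
            control, treatment = "A", "B"
            effect = beta
        else:
            control, treatment = "B", "A"
            effect = -beta
        return PeriodPlan(project_id, control, treatment, comparison_type,
                          float(effect), float(var), "camera")
    if override is not None:
        treatment = "A" if override == "A_higher" else "B"
        control = "B" if treatment == "A" else "A"
        return PeriodPlan(project_id, control, treatment, comparison_type,
                          float("nan"), float("nan"), "override")
    raise OrientationError(
        f"project {project_id}: no detectable change in human activity and no override")


def _shared_stations(effort: pd.DataFrame) -> bool:
    by_period = effort.groupby("period_label")["station_id"].agg(set)
    if len(by_period) < 2:
        return False
    inter = set.intersection(*by_period.tolist())
    return len(inter) > 0


def human_fold_change(plan: PeriodPlan) -> float:
    """Multiplicative change in human detection rate, exp(human_effect)."""
    return float(np.exp(plan.human_effect))
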
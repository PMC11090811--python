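"""Moderator assembly: species traits, landscape covariates and screening.

Builds the per-population (project x species) moderator table used in
the stage-two meta-regression: trophic group (body-size class crossed
with trophic level), diet and habitat breadth, diel activity, relative
brain size, hunting status, habitat openness, human modification index
(HMI), stringency change, comparison type and camera-measured human
fold change.  Continuous moderators are z-standardized (mean 0, unit
sample SD) with the scaling stored for back-transformation, and
pairwise Pearson correlations are screened against |r| >= 0.6
(flagged with a warning, not removed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "trophic_group",
    "relative_brain_size",
    "build_moderators",
    "standardize",
    "destandardize",
    "correlation_screen",
    "stringency_change",
    "CONTINUOUS_MODERATORS",
]

#: continuous moderators standardized before modelling
CONTINUOUS_MODERATORS = ("diet_breadth", "habitat_breadth", "hmi",
                         "stringency_change", "relative_brain_size",
                         "human_fold_change")

_MASS_SPLIT_KG = 20.0  # small: [1, 20) kg; large: [20, 4600] kg


def trophic_group(body_mass_kg: float, trophic_level: str) -> str:
    """Six-level factor: small/large x carnivore/omnivore/herbivore.

    The 20 kg boundary is assigned to "large".
    """
    if body_mass_kg < 1.0:
        raise ValueError("species below 1 kg should have been filtered out")
    if trophic_level not in ("carnivore", "omnivore", "herbivore"):
        raise ValueError(f"unknown trophic level {trophic_level!r}")
    size = "small" if body_mass_kg < _MASS_SPLIT_KG else "large"
    return f"{size} {trophic_level}"


def relative_brain_size(brain_mass_g: float, body_mass_g: float) -> float:
    """ln(brain mass) / ln(body mass), both in grams (> 1 g)."""
    if brain_mass_g <= 1.0 or body_mass_g <= 1.0:
        raise ValueError("masses must exceed 1 g for a stable log ratio")
    return float(np.log(brain_mass_g) / np.log(body_mass_g))


def stringency_change(control_median: float, treatment_median: float) -> float:
    """Signed difference in median stringency, treatment minus control."""
    return float(treatment_median) - float(control_median)


def build_moderators(populations: pd.DataFrame, traits: pd.DataFrame,
                     covariates: pd.DataFrame, hunting: pd.DataFrame | None = None,
                     human_fold: pd.DataFrame | None = None,
                     comparison_types: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble the moderator row for each project x species population.

    ``populations`` needs project_id and species columns; the trait and
    project covariate tables supply the rest.  Hunting status and human
    fold change are optional (left missing where unavailable, for the
    subset analyses).
    """
    tr = traits.set_index("species")
    out = populations[["project_id", "species"]].copy()
    out["family"] = out["species"].map(tr["family"])
    mass = out["species"].map(tr["body_mass_kg"])
    level = out["species"].map(tr["trophic_level"])
    out["trophic_group"] = [trophic_group(m, l) for m, l in zip(mass, level)]
    out["diet_breadth"] = out["species"].map(tr["diet_breadth"]).astype(float)
    out["habitat_breadth"] = out["species"].map(tr["habitat_breadth"]).astype(float)
    out["diel_activity"] = out["species"].map(tr["diel_activity"])
    brain = out["species"].map(tr["brain_mass_g"])
    out["relative_brain_size"] = [
        relative_brain_size(b, m * 1000.0) if np.isfinite(b) else np.nan
        for b, m in zip(brain, mass)
    ]
    cov = covariates.set_index("project_id")
    out["openness"] = out["project_id"].map(cov["openness"])
    out["hmi"] = out["project_id"].map(cov["hmi"]).astype(float)
    out["stringency_change"] = out["project_id"].map(
        cov["stringency_treatment"] - cov["stringency_control"]).astype(float)
    if hunting is not None and len(hunting):
        h = hunting.set_index(["project_id", "species"])["hunted"]
        out["hunted"] = pd.MultiIndex.from_frame(out[["project_id", "species"]]).map(h)
    else:
        out["hunted"] = np.nan
    if human_fold is not None and len(human_fold):
        hf = human_fold.set_index("project_id")["human_fold_change"]
        out["human_fold_change"] = out["project_id"].map(hf).astype(float)
    else:
        out["human_fold_change"] = np.nan
    if comparison_types is not None and len(comparison_types):
        ct = comparison_types.drop_duplicates("project_id").set_index("project_id")
        out["comparison_type"] = out["project_id"].map(ct["comparison_type"])
    return out


def standardize(moderators: pd.DataFrame, columns=None):
    """z-score continuous columns; returns (standardized frame, scaling record).

    The scaling record maps column -> (mean, sd) using the sample SD
    (ddof=1); missing values are ignored in the scaling and preserved.
    """
    columns = [c for c in (columns or CONTINUOUS_MODERATORS) if c in moderators.columns]
    out = moderators.copy()
    scaling = {}
    for c in columns:
        x = pd.to_numeric(out[c])
        sd = float(x.std(ddof=1))
        if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, abs(float(x.mean()))):
            raise ValueError(f"column {c!r} has zero variance; cannot standardize")
        mean = float(x.mean())
        out[c] = (x - mean) / sd
        scaling[c] = (mean, sd)
    return out, scaling


def destandardize(moderators: pd.DataFrame, scaling: dict) -> pd.DataFrame:
    out = moderators.copy()
    for c, (mean, sd) in scaling.items():
        if c in out.columns:
            out[c] = pd.to_numeric(out[c]) * sd + mean
    return out


def correlation_screen(moderators: pd.DataFrame, threshold: float = 0.6) -> pd.DataFrame:
    """Pairwise Pearson |r| among numeric moderators; flags pairs >= threshold.

    Flagged pairs are reported (warning-level), never removed.
    """
    num = moderators.select_dtypes(include=[np.number])
    if len(num) < 3:
        raise ValueError("correlation screen needs at least 3 rows")
    rows = []
    cols = list(num.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            pair = num[[a, b]].dropna()
            if len(pair) < 3 or pair[a].std() == 0 or pair[b].std() == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(pair[a], pair[b])[0, 1])
            rows.append((a, b, r, bool(np.isfinite(r) and abs(r) >= threshold)))
    return pd.DataFrame(rows, columns=["var_a", "var_b", "pearson_r", "flagged"])
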
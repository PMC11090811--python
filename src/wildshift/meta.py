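"""Multilevel random-effects meta-regression.

Effect sizes ``y_i`` with known sampling variances ``v_i`` are modelled
as

    y = X beta + Z_p u_p + Z_f u_f + Z_s u_s + e,   e_i ~ N(0, v_i)

with independent random intercepts for project, taxonomic family and
species-within-family (the nesting proxies phylogenetic relatedness at
the family level).  Variance components are estimated by REML (or full
ML when models with different fixed effects are compared), maximizing
the profiled (restricted) likelihood over log-variances by bounded
quasi-Newton with multiple restarts; ``beta = (X'V^-1X)^-1 X'V^-1 y``
with standard errors from ``(X'V^-1X)^-1``.

Also provides multilevel I^2 heterogeneity, pseudo-R^2, AICc model
selection over candidate interaction/quadratic terms, and
percent-change effect translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MetaModelSpec",
    "MetaFit",
    "HeterogeneityReport",
    "build_design",
    "fit_meta",
    "i_squared",
    "pseudo_r2",
    "aicc",
    "select_interactions",
    "subset_model_selection",
    "percent_change",
    "significance_label",
]

#: reference levels reproducing the reported intercept: diurnal,
#: large herbivore, closed habitat, between-year ("seasonal") comparison
REFERENCE_LEVELS = {
    "diel_activity": "diurnal",
    "trophic_group": "large herbivore",
    "openness": "closed",
    "comparison_type": "between_year",
}

_CATEGORICAL = set(REFERENCE_LEVELS) | {"hunted"}

LEVELS = ("project", "family", "species")


@dataclass
class MetaModelSpec:
    response: str = "amount"                      # amount | timing
    fixed_terms: tuple = ()                       # moderator terms beyond intercept
    random_terms: tuple = LEVELS
    estimation: str = "REML"                      # REML | ML


@dataclass
class MetaFit:
    spec: MetaModelSpec
    coef: pd.DataFrame                            # estimate, se, z, p, ci_low, ci_high
    sigma2: dict
    loglik: float
    k: int
    converged: bool
    y: np.ndarray = field(repr=False)
    v: np.ndarray = field(repr=False)
    X: pd.DataFrame = field(repr=False)
    groups: pd.DataFrame = field(repr=False)

    @property
    def p_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def n_params(self) -> int:
        return self.p_fixed + len(self.sigma2)

    @property
    def total_sigma2(self) -> float:
        return float(sum(self.sigma2.values()))


@dataclass
class HeterogeneityReport:
    i2_level: dict
    i2_total: float
    typical_v: float


def _dummy(series: pd.Series, name: str) -> pd.DataFrame:
    levels = sorted(series.astype(str).unique())
    ref = REFERENCE_LEVELS.get(name)
    if name == "hunted":
        ref = "False"
    if ref in levels:
        levels = [ref] + [l for l in levels if l != ref]
    cols = {}
    for lev in levels[1:]:
        cols[f"{name}[{lev}]"] = (series.astype(str) == lev).astype(float)
    return pd.DataFrame(cols, index=series.index)


def _term_columns(term: str, data: pd.DataFrame) -> pd.DataFrame:
    """Columns for one term: a variable name, 'a:b' interaction or 'x^2'."""
    if ":" in term:
        left, right = term.split(":", 1)
        L = _term_columns(left.strip(), data)
        R = _term_columns(right.strip(), data)
        cols = {}
        for lc in L.columns:
            for rc in R.columns:
                cols[f"{lc}:{rc}"] = L[lc] * R[rc]
        return pd.DataFrame(cols, index=data.index)
    if term.endswith("^2"):
        base = term[:-2].strip()
        return pd.DataFrame({term: pd.to_numeric(data[base]) ** 2}, index=data.index)
    if term in _CATEGORICAL or data[term].dtype == object or data[term].dtype == bool:
        return _dummy(data[term], term)
    return pd.DataFrame({term: pd.to_numeric(data[term]).astype(float)}, index=data.index)


def build_design(data: pd.DataFrame, terms) -> pd.DataFrame:
    """Design matrix with intercept, treatment-coded categoricals and interactions.

    ``terms`` use variable names, ``a:b`` for interactions and ``x^2``
    for quadratics (``a*b`` expands to ``a + b + a:b``).  Reference
    levels follow :data:`REFERENCE_LEVELS`.
    """
    X = pd.DataFrame({"intercept": np.ones(len(data))}, index=data.index)
    expanded: list[str] = []
    for t in terms:
        if "*" in t:
            a, b = (s.strip() for s in t.split("*", 1))
            expanded += [a, b, f"{a}:{b}"]
        else:
            expanded.append(t)
    seen = set(X.columns)
    for t in expanded:
        for name, col in _term_columns(t, data).items():
            if name not in seen:
                X[name] = col.astype(float)
                seen.add(name)
    return X


def _z_matrices(groups: pd.DataFrame, random_terms) -> list[np.ndarray]:
    Zs = []
    for level in random_terms:
        if level == "species":
            labels = groups["family"].astype(str) + "/" + groups["species"].astype(str)
        else:
            labels = groups[level].astype(str)
        codes = pd.Categorical(labels).codes
        Z = np.zeros((len(groups), codes.max() + 1))
        Z[np.arange(len(groups)), codes] = 1.0
        Zs.append(Z)
    return Zs


def _profile_nll(log_s2, y, v, X, ZZt, reml):
    k, p = X.shape
    V = np.diag(v).astype(float)
    for s2, G in zip(np.exp(log_s2), ZZt):
        V += s2 * G
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e12
    ldet_V = 2.0 * np.log(np.diag(L)).sum()
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    try:
        beta = np.linalg.solve(XtViX, Vi_X.T @ y)
    except np.linalg.LinAlgError:
        return 1e12
    r = y - X @ beta
    quad = float(r @ np.linalg.solve(V, r))
    if reml:
        s, ldet_XtViX = np.linalg.slogdet(XtViX)
        if s <= 0:
            return 1e12
        ll = -0.5 * ((k - p) * np.log(2 * np.pi) + ldet_V + ldet_XtViX + quad)
        # metafor's REML log-likelihood convention adds +0.5 ln|X'X|
        s2_, ldet_XtX = np.linalg.slogdet(X.T @ X)
        ll += 0.5 * ldet_XtX
    else:
        ll = -0.5 * (k * np.log(2 * np.pi) + ldet_V + quad)
    return -ll


def fit_meta(y, v, X: pd.DataFrame, groups: pd.DataFrame,
             spec: MetaModelSpec | None = None) -> MetaFit:
    """Fit the multilevel meta-regression.

    Parameters
    ----------
    y, v
        Effect sizes and their sampling variances (v > 0).
    X
        Fixed-effects design matrix (see :func:`build_design`).
    groups
        DataFrame with ``project``, ``family``, ``species`` columns.
    spec
        Estimation method and random structure; defaults to REML with
        all three levels.
    """
    spec = spec or MetaModelSpec()
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("sampling variances must be positive")
    k, p = X.shape
    if k <= p + 3:
        raise ValueError(f"too few effects (k={k}) for {p} fixed parameters")
    Xv = X.to_numpy(float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < p:
        # name the offending columns for the caller
        _, R = np.linalg.qr(Xv)
        bad = [X.columns[j] for j in range(p) if abs(R[j, j]) < 1e-8]
        raise ValueError(f"singular design matrix; collinear column(s): {bad}")

    Zs = _z_matrices(groups, spec.random_terms)
    ZZt = [Z @ Z.T for Z in Zs]
    reml = spec.estimation.upper() == "REML"
    nq = len(ZZt)

    if nq == 0:
        # fixed-effect model: variance components pinned to zero
        s2 = np.array([])
        loglik = -_profile_nll(s2, y, v, Xv, ZZt, reml)
        converged_flag = True
    else:
        tau_guess = max(np.var(y) - np.mean(v), 1e-4)
        starts = [np.full(nq, np.log(tau_guess / nq)),
                  np.full(nq, np.log(1e-4)),
                  np.log(tau_guess) + np.array([0.0, -2.0, -1.0])[:nq]]
        best = None
        for s0 in starts:
            res = optimize.minimize(_profile_nll, s0, args=(y, v, Xv, ZZt, reml),
                                    method="L-BFGS-B", bounds=[(-30.0, 5.0)] * nq,
                                    options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500})
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        s2 = np.exp(best.x)
        s2[s2 < 2e-13] = 0.0
        loglik = -float(best.fun)
        converged_flag = bool(best.success)

    V = np.diag(v).astype(float)
    for s2_l, G in zip(s2, ZZt):
        V += s2_l * G
    Vi_X = np.linalg.solve(V, Xv)
    XtViX_inv = np.linalg.inv(Xv.T @ Vi_X)
    beta = XtViX_inv @ (Vi_X.T @ y)
    se = np.sqrt(np.diag(XtViX_inv))
    z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    coef = pd.DataFrame({
        "estimate": beta, "se": se, "z": z, "p": pval,
        "ci_low": beta - 1.959963984540054 * se,
        "ci_high": beta + 1.959963984540054 * se,
    }, index=X.columns)
    sigma2 = dict(zip(spec.random_terms, s2.tolist()))
    return MetaFit(spec=spec, coef=coef, sigma2=sigma2, loglik=loglik,
                   k=k, converged=converged_flag, y=y, v=v, X=X,
                   groups=groups.reset_index(drop=True))


def i_squared(fit: MetaFit) -> HeterogeneityReport:
    """Multilevel I^2 using the typical sampling variance.

    ``tilde_v = (k-1) sum(w) / (sum(w)^2 - sum(w^2))`` with ``w = 1/v``;
    each level's I^2 is its variance share of (all components +
    tilde_v), and the total is their sum.
    """
    w = 1.0 / fit.v
    k = fit.k
    tv = (k - 1) * w.sum() / (w.sum() ** 2 - (w ** 2).sum())
    denom = fit.total_sigma2 + tv
    levels = {lev: 100.0 * s2 / denom for lev, s2 in fit.sigma2.items()}
    return HeterogeneityReport(i2_level=levels, i2_total=float(sum(levels.values())),
                               typical_v=float(tv))


def pseudo_r2(fit: MetaFit, null_fit: MetaFit) -> float:
    """Percent of summed variance components explained vs the intercept-only model."""
    if fit.k != null_fit.k or not np.allclose(fit.y, null_fit.y):
        raise ValueError("pseudo_r2 requires fits on the same data")
    tot_null = null_fit.total_sigma2
    if tot_null <= 0:
        return 0.0
    return 100.0 * max(0.0, (tot_null - fit.total_sigma2) / tot_null)


def aicc(fit: MetaFit) -> float:
    """Small-sample corrected AIC; p counts fixed coefficients and variance components."""
    p = fit.n_params
    k = fit.k
    if p == 0:
        raise ValueError("model has no parameters")
    if k <= p + 1:
        raise ValueError(f"AICc undefined: k={k} <= p+1={p + 1}")
    return -2.0 * fit.loglik + 2.0 * p + 2.0 * p * (p + 1) / (k - p - 1)


def significance_label(p: float) -> str:
    if p < 0.05:
        return "significant"
    if p < 0.10:
        return "marginal"
    return "ns"


#: candidate interaction / nonlinear terms screened against the global model
CANDIDATE_TERMS = ("hmi:openness", "trophic_group:hmi", "trophic_group:openness", "hmi^2")


def _fit_terms(y, v, data, terms, groups, estimation):
    X = build_design(data, terms)
    return fit_meta(y, v, X, groups, MetaModelSpec(fixed_terms=tuple(terms),
                                                   estimation=estimation))


def select_interactions(y, v, data: pd.DataFrame, groups: pd.DataFrame,
                        global_terms, candidates=CANDIDATE_TERMS):
    """AICc screen of candidate terms added singly to the global model.

    All comparison fits use ML; the retained model (lowest AICc, unless
    a simpler nested model is within 2 AICc) is refit by REML.

    Returns ``(table, retained_terms, reml_fit)``.
    """
    rows = []
    fits = {}
    for label, extra in [("global", [])] + [(c, [c]) for c in candidates]:
        terms = list(global_terms) + extra
        try:
            f = _fit_terms(y, v, data, terms, groups, "ML")
            rows.append((label, aicc(f), f.loglik, f.n_params, f.converged))
            fits[label] = f
        except ValueError as exc:  # pragma: no cover - degenerate candidates
            rows.append((label, np.nan, np.nan, np.nan, False))
    table = pd.DataFrame(rows, columns=["model", "aicc", "loglik", "n_params",
                                        "converged"]).sort_values("aicc")
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    # a candidate is supported when it sits within 2 AICc of the best model
    # and the simpler nested global model does not have more support
    global_aicc = float(table.set_index("model").loc["global", "aicc"])
    table["supported"] = (table["delta_aicc"] <= 2.0) & (
        (table["model"] == "global") | (table["aicc"] < global_aicc))

    retained = table.iloc[0]["model"]
    terms = list(global_terms) + ([] if retained == "global" else [retained])
    reml_fit = _fit_terms(y, v, data, terms, groups, "REML")
    return table.reset_index(drop=True), terms, reml_fit


def subset_model_selection(y, v, data: pd.DataFrame, groups: pd.DataFrame,
                           global_terms, subset_var: str, extra_candidates=()):
    """Compare the global model with candidates adding a partially observed moderator.

    Rows with missing ``subset_var`` are dropped; the global model refit
    on the subset is the baseline, and candidates are reported as
    preferred only when their AICc is lower.

    Returns ``(table, preferred_terms)``.
    """
    mask = data[subset_var].notna().to_numpy()
    if mask.sum() <= len(global_terms) + 6:
        raise ValueError(f"subset for {subset_var} too small ({int(mask.sum())} rows)")
    ys, vs = np.asarray(y)[mask], np.asarray(v)[mask]
    ds, gs = data.loc[mask], groups.loc[mask]

    rows = []
    models = {"global": list(global_terms)}
    models[subset_var] = list(global_terms) + [subset_var]
    for cand in extra_candidates:
        models[cand] = list(global_terms) + [cand]
    for label, terms in models.items():
        f = _fit_terms(ys, vs, ds, terms, gs, "ML")
        rows.append((label, aicc(f), f.loglik, f.n_params))
    table = pd.DataFrame(rows, columns=["model", "aicc", "loglik", "n_params"])
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    table = table.sort_values("aicc").reset_index(drop=True)

    base = float(table.set_index("model").loc["global", "aicc"])
    better = table[(table["aicc"] < base) & (table["model"] != "global")]
    preferred = better.iloc[0]["model"] if len(better) else "global"
    return table, models[preferred] if preferred != "global" else list(global_terms)


def percent_change(fit: MetaFit, predictor: str, from_value: float, to_value: float,
                   warn_range=None) -> float:
    """Percent change in the exponentiated response along one predictor.

    ``100 * (exp(yhat_to) - exp(yhat_from)) / exp(yhat_from)`` with all
    other covariates held at reference/zero (so only the named
    predictor's coefficient enters).
    """
    if predictor not in fit.coef.index:
        raise KeyError(f"predictor {predictor!r} not in model")
    if warn_range is not None:
        lo, hi = warn_range
        if not (lo <= from_value <= hi and lo <= to_value <= hi):
            import warnings
            warnings.warn(f"{predictor}: values outside observed range [{lo}, {hi}]")
    b = float(fit.coef.loc[predictor, "estimate"])
    return 100.0 * float(np.expm1(b * (to_value - from_value)))
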
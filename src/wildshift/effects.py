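"""Stage-one effect sizes for single populations.

Amount of activity: the treatment coefficient of a negative-binomial
(NB2) regression of per-station independent-event counts with a
log(camera-days) offset, and optionally a station random intercept
(integrated by a Laplace approximation) when the same stations sampled
both periods.  The coefficient is the log detection-rate ratio,
treatment over control, with its squared standard error from the
observed information at the optimum.

Timing of activity: the log risk ratio of the nocturnality index
N = night / (night + day), treatment over control, with the standard
two-proportion sampling variance 1/x_h - 1/n_h + 1/x_l - 1/n_l, and a
0.5 continuity correction applied to all cells of both periods whenever
any cell is zero.  Populations need at least ``min_detections`` (10)
detections in each period to enter the timing analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "RateEffect",
    "NocturnalityEffect",
    "fit_rate_effect",
    "nocturnality_index",
    "fit_nocturnality_effect",
    "interpret_rr",
]

_THETA_CAP = 1e6


@dataclass
class RateEffect:
    project_id: str
    species: str
    beta: float
    var: float
    theta: float
    sigma_station: float
    converged: bool
    n_events_control: int
    n_events_treatment: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.var))


@dataclass
class NocturnalityEffect:
    project_id: str
    species: str
    rr: float
    var: float
    n_h: int
    n_l: int
    x_h: int
    x_l: int


def _nb2_loglik_parts(y, eta, theta):
    mu = np.exp(eta)
    ll = (special.gammaln(y + theta) - special.gammaln(theta) - special.gammaln(y + 1)
          + theta * np.log(theta) + y * eta - (y + theta) * np.log(mu + theta))
    return ll, mu


def _nb2_nll(params, y, treat, log_eff):
    b0, b1, log_theta = params
    theta = np.exp(min(log_theta, np.log(_THETA_CAP)))
    eta = b0 + b1 * treat + log_eff
    with np.errstate(over="ignore", invalid="ignore"):
        ll, mu = _nb2_loglik_parts(y, eta, theta)
        return -float(ll.sum())


def _nb2_nll_grad(params, y, treat, log_eff):
    b0, b1, log_theta = params
    theta = np.exp(min(log_theta, np.log(_THETA_CAP)))
    eta = np.clip(b0 + b1 * treat + log_eff, -500, 500)
    mu = np.exp(eta)
    d_eta = theta * (y - mu) / (mu + theta)
    d_theta = (special.polygamma(0, y + theta) - special.polygamma(0, theta)
               + np.log(theta) + 1.0 - np.log(mu + theta) - (y + theta) / (mu + theta))
    g = np.array([d_eta.sum(), (d_eta * treat).sum(), (d_theta * theta).sum()])
    return -g


def _nb2_hessian(params, y, treat, log_eff):
    """Analytic Hessian of the negative NB2 log-likelihood in (b0, b1, log_theta)."""
    b0, b1, log_theta = params
    theta = np.exp(min(log_theta, np.log(_THETA_CAP)))
    eta = b0 + b1 * treat + log_eff
    mu = np.exp(eta)
    w = theta * mu * (y + theta) / (mu + theta) ** 2          # -d2ll/deta2
    cross = (y - mu) * mu / (mu + theta) ** 2 * theta         # d2ll/(deta dlogtheta)
    d1 = (special.polygamma(0, y + theta) - special.polygamma(0, theta)
          + np.log(theta) + 1.0 - np.log(mu + theta) - (y + theta) / (mu + theta))
    d2 = (special.polygamma(1, y + theta) - special.polygamma(1, theta)
          + 1.0 / theta - 2.0 / (mu + theta) + (y + theta) / (mu + theta) ** 2)
    dtt = (theta ** 2 * d2 + theta * d1).sum()                # d2ll/dlogtheta2
    H = np.empty((3, 3))
    H[0, 0] = w.sum()
    H[0, 1] = H[1, 0] = (w * treat).sum()
    H[1, 1] = (w * treat * treat).sum()
    H[0, 2] = H[2, 0] = -cross.sum()
    H[1, 2] = H[2, 1] = -(cross * treat).sum()
    H[2, 2] = -dtt
    return H


def _laplace_nll(params, y, treat, log_eff, station_idx, n_stations):
    """Negative Laplace-approximate marginal log-likelihood with station intercepts."""
    b0, b1, log_theta, log_sigma = params
    theta = np.exp(min(log_theta, np.log(_THETA_CAP)))
    sigma2 = max(np.exp(2.0 * log_sigma), 1e-14)
    eta0 = b0 + b1 * treat + log_eff

    u = np.zeros(n_stations)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        # inner Newton for the per-station modes (independent 1-D problems)
        for _ in range(50):
            mu = np.exp(eta0 + u[station_idx])
            score_i = theta * (y - mu) / (mu + theta)
            w_i = theta * mu * (y + theta) / (mu + theta) ** 2
            score = np.bincount(station_idx, weights=score_i, minlength=n_stations) - u / sigma2
            hess = np.bincount(station_idx, weights=w_i, minlength=n_stations) + 1.0 / sigma2
            step = score / hess
            u_new = u + np.clip(step, -5.0, 5.0)
            if np.max(np.abs(u_new - u)) < 1e-10:
                u = u_new
                break
            u = u_new

        mu = np.exp(eta0 + u[station_idx])
        ll, _ = _nb2_loglik_parts(y, eta0 + u[station_idx], theta)
        w_i = theta * mu * (y + theta) / (mu + theta) ** 2
        W = np.bincount(station_idx, weights=w_i, minlength=n_stations)
        marg = ll.sum() - (u ** 2).sum() / (2.0 * sigma2) - 0.5 * np.log1p(sigma2 * W).sum()
        return -float(marg)


def _numeric_hessian(fun, x, args, eps=1e-4):
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            fpp = fun(x + ei + ej, *args)
            fpm = fun(x + ei - ej, *args)
            fmp = fun(x - ei + ej, *args)
            fmm = fun(x - ei - ej, *args)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * eps * eps)
    return H


def fit_rate_effect(counts, effort, shared_stations: bool,
                    project_id: str = "", species: str = "") -> RateEffect:
    """Fit the NB2 detection-rate model for one population.

    Parameters
    ----------
    counts
        DataFrame with columns station_id, period_label, n_events (one
        row per station x period; stations with effort but no events
        must appear with 0 — use :func:`attach_zero_counts`).
    effort
        DataFrame with station_id, period_label, camera_days (> 0).
    shared_stations
        Include a station random intercept (same locations sampled in
        both periods); otherwise a fixed-effects NB2 regression.

    Returns
    -------
    RateEffect
        ``beta`` is the log rate ratio treatment/control (period B is
        treatment here; orient beforehand), ``var`` its squared SE.
    """
    df = effort.merge(counts[["station_id", "period_label", "n_events"]],
                      on=["station_id", "period_label"], how="left")
    df["n_events"] = df["n_events"].fillna(0).astype(float)
    if not set(df["period_label"]) >= {"control", "treatment"}:
        raise ValueError("effort must cover both a 'control' and a 'treatment' period")
    y = df["n_events"].to_numpy(float)
    if y.sum() == 0:
        raise ValueError("all counts are zero; rate effect undefined")
    treat = (df["period_label"] == "treatment").to_numpy(float)
    log_eff = np.log(df["camera_days"].to_numpy(float))

    n_c = int(y[treat == 0].sum())
    n_t = int(y[treat == 1].sum())

    rate = max(y.sum() / np.exp(log_eff).sum(), 1e-8)
    x0 = np.array([np.log(rate), 0.0, np.log(2.0)])

    if not shared_stations:
        x, converged = _newton_nb2(x0, y, treat, log_eff)
        H = _nb2_hessian(x, y, treat, log_eff)
        theta = float(np.exp(min(x[2], np.log(_THETA_CAP))))
        sigma = 0.0
    else:
        stations = df["station_id"].astype("category")
        idx = stations.cat.codes.to_numpy()
        S = len(stations.cat.categories)
        lb_sig = -7.0
        x0 = np.append(x0, np.log(0.3))
        args = (y, treat, log_eff, idx, S)
        bounds = [(-20, 20), (-20, 20), (np.log(1e-3), np.log(_THETA_CAP)), (lb_sig, 3.0)]
        res = optimize.minimize(_laplace_nll, x0, args=args, method="L-BFGS-B",
                                bounds=bounds,
                                options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500})
        x, converged = res.x, bool(res.success)
        if not converged and np.isfinite(res.fun):
            # the line-search can abort on a flat dispersion direction at an
            # otherwise clean optimum; judge by the gradient instead
            g = optimize.approx_fprime(res.x, _laplace_nll, 1e-6, *args)
            at_bound = [not (lo + 1e-6 < xi < hi - 1e-6) for xi, (lo, hi) in zip(res.x, bounds)]
            g = np.where(at_bound, 0.0, g)  # ignore active bounds
            converged = bool(np.max(np.abs(g)) < 0.05)
        at_boundary = x[3] <= lb_sig + 1e-6
        if at_boundary:
            # sigma -> 0: information for log_sigma vanishes; profile it out
            H3 = _numeric_hessian(lambda p, *a: _laplace_nll(np.append(p, x[3]), *a),
                                  x[:3], args)
            H = np.full((4, 4), np.nan)
            H[:3, :3] = H3
        else:
            H = _numeric_hessian(_laplace_nll, x, args)
        theta = float(np.exp(min(x[2], np.log(_THETA_CAP))))
        sigma = float(np.exp(x[3])) if not at_boundary else 0.0
        H = H[:3, :3] if at_boundary else H

    beta = float(x[1])
    var = np.nan
    for block in (H, H[:2, :2]):
        # fall back to the beta block when the dispersion direction is flat
        # (theta at the Poisson-limit cap makes the full Hessian singular)
        try:
            v = float(np.linalg.inv(block)[1, 1])
        except np.linalg.LinAlgError:
            continue
        if np.isfinite(v) and v > 0:
            var = v
            break
    else:
        converged = False
    if not np.isfinite(var):
        converged = False
    return RateEffect(project_id, species, beta, var, theta, sigma, converged, n_c, n_t)


def _newton_nb2(x0, y, treat, log_eff):
    """Block-coordinate Newton on the NB2 negative log-likelihood.

    Alternates exact Newton steps on the regression block (b0, b1) with
    damped 1-D Newton on log(theta); keeps beta sharp even when the
    dispersion direction is flat (theta at the Poisson-limit cap).
    """
    log_cap = np.log(_THETA_CAP)
    args = (y, treat, log_eff)
    x = x0.copy()
    f = _nb2_nll(x, *args)

    def _line_search(x, step, f):
        t = 1.0
        for _ in range(40):
            x_new = x - t * step
            x_new[2] = min(x_new[2], log_cap)
            f_new = _nb2_nll(x_new, *args)
            if np.isfinite(f_new) and f_new <= f + 1e-12:
                return x_new, f_new
            t *= 0.5
        return x, f

    for _ in range(200):
        # regression block at fixed dispersion
        for _ in range(60):
            g = _nb2_nll_grad(x, *args)
            if np.max(np.abs(g[:2])) < 1e-11:
                break
            H = _nb2_hessian(x, *args)
            try:
                step_b = np.linalg.solve(H[:2, :2], g[:2])
            except np.linalg.LinAlgError:
                return _bfgs_nb2(x0, args)
            x, f = _line_search(x, np.array([step_b[0], step_b[1], 0.0]), f)

        # dispersion step
        g = _nb2_nll_grad(x, *args)
        at_cap = x[2] >= log_cap - 1e-9 and g[2] < 0
        if np.max(np.abs(g[:2])) < 1e-9 and (abs(g[2]) < 1e-8 or at_cap):
            return x, True
        H = _nb2_hessian(x, *args)
        step_t = g[2] / H[2, 2] if H[2, 2] > 0 else np.sign(g[2]) * 0.5
        x_prev = x.copy()
        x, f = _line_search(x, np.array([0.0, 0.0, float(step_t)]), f)
        if np.max(np.abs(x - x_prev)) < 1e-12 and np.max(np.abs(g[:2])) < 1e-9:
            return x, True  # dispersion direction numerically flat
    return _bfgs_nb2(x0, args)


def _bfgs_nb2(x0, args):
    res = optimize.minimize(_nb2_nll, x0, args=args,
                            jac=_nb2_nll_grad, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 500})
    return res.x, bool(np.isfinite(res.fun))


def attach_zero_counts(counts, effort):
    """Expand counts so every station x period with effort has a row (0 fill)."""
    base = effort[["station_id", "period_label"]].drop_duplicates()
    out = base.merge(counts, on=["station_id", "period_label"], how="left")
    out["n_events"] = out["n_events"].fillna(0).astype(int)
    return out


def nocturnality_index(n_night: int, n_day: int) -> float:
    """N = night detections / all detections, pooled over a project's stations."""
    total = n_night + n_day
    if total <= 0:
        raise ValueError("nocturnality index undefined with zero detections")
    return n_night / total


def fit_nocturnality_effect(x_h: int, n_h: int, x_l: int, n_l: int,
                            project_id: str = "", species: str = "",
                            min_detections: int = 10):
    """Log risk ratio of nocturnality, treatment (h) vs control (l).

    ``x`` are night detections, ``n`` total detections per period.
    Returns ``None`` (exclusion, not an error) when either period has
    fewer than ``min_detections`` detections.  When any of x_h, x_l,
    n_h - x_h, n_l - x_l is zero, 0.5 is added to every cell of both
    periods (so n increases by 1) before computing rr and its variance.
    """
    if n_h < min_detections or n_l < min_detections:
        return None
    xh, nh, xl, nl = float(x_h), float(n_h), float(x_l), float(n_l)
    if min(xh, xl, nh - xh, nl - xl) == 0:
        xh += 0.5
        xl += 0.5
        nh += 1.0
        nl += 1.0
    rr = float(np.log((xh / nh) / (xl / nl)))
    var = float(1.0 / xh - 1.0 / nh + 1.0 / xl - 1.0 / nl)
    return NocturnalityEffect(project_id, species, rr, var,
                              int(n_h), int(n_l), int(x_h), int(x_l))


def interpret_rr(rr: float) -> str:
    """Sign rule: positive rr = more nocturnal under higher human activity."""
    if rr > 0:
        return "more nocturnal"
    if rr < 0:
        return "less nocturnal"
    return "no change"
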
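"""Deterministic small datasets shared by tests and the frozen-oracle scripts.

Each generator is a pure function of its instance index, so the exact
data behind the frozen reference values in tests/data/ can be rebuilt
at test time without shipping the tables themselves.
"""

import numpy as np
import pandas as pd


def nb_glmm_instance(i: int):
    """Station x period NB2 counts with a station random intercept."""
    rng = np.random.default_rng(1000 + i)
    n_stations = int(rng.integers(8, 25))
    lam = float(rng.uniform(0.05, 0.4))
    beta = float(rng.normal(0.0, 0.5))
    sigma = float(rng.uniform(0.2, 0.8))
    theta = float(rng.uniform(0.8, 5.0))
    days = rng.uniform(30.0, 120.0, size=2 * n_stations)
    treat = np.tile([0.0, 1.0], n_stations)
    u = rng.normal(0.0, sigma, size=n_stations)
    mu = days * lam * np.exp(beta * treat + np.repeat(u, 2))
    y = rng.negative_binomial(theta, theta / (theta + mu))
    df = pd.DataFrame({
        "station_id": np.repeat([f"s{j:02d}" for j in range(n_stations)], 2),
        "period_label": np.tile(["control", "treatment"], n_stations),
        "camera_days": days,
        "n_events": y.astype(int),
    })
    truth = {"beta": beta, "sigma": sigma, "theta": theta, "lam": lam}
    return df, truth


def meta_instance(i: int):
    """Three-level meta-regression dataset with two moderators."""
    rng = np.random.default_rng(2000 + i)
    n_proj = int(rng.integers(8, 15))
    n_fam = int(rng.integers(4, 8))
    n_spec = int(rng.integers(12, 25))
    fam_of_spec = rng.integers(0, n_fam, size=n_spec)
    sig_p, sig_f, sig_s = rng.uniform(0.05, 0.4, size=3)
    b = rng.normal(0.0, 0.3, size=3)  # intercept, x1, x2
    u_p = rng.normal(0.0, sig_p, size=n_proj)
    u_f = rng.normal(0.0, sig_f, size=n_fam)
    u_s = rng.normal(0.0, sig_s, size=n_spec)

    rows = []
    for p in range(n_proj):
        species = rng.choice(n_spec, size=int(rng.integers(6, n_spec + 1)), replace=False)
        for s in species:
            f = fam_of_spec[s]
            x1, x2 = rng.normal(0.0, 1.0, size=2)
            v = float(rng.uniform(0.01, 0.2))
            y = (b[0] + b[1] * x1 + b[2] * x2 + u_p[p] + u_f[f] + u_s[s]
                 + rng.normal(0.0, np.sqrt(v)))
            rows.append((f"p{p:02d}", f"f{f:02d}", f"sp{s:03d}", x1, x2, y, v))
    df = pd.DataFrame(rows, columns=["project", "family", "species", "x1", "x2", "yi", "vi"])
    truth = {"beta": b.tolist(), "sigma2": [sig_p ** 2, sig_f ** 2, sig_s ** 2]}
    return df, truth
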
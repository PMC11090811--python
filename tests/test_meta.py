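"""Multilevel meta-regression: estimation, heterogeneity, model selection."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from _datasets import meta_instance
from wildshift import meta

META_ORACLE = json.loads((Path(__file__).parent / "data" / "meta_oracle.json").read_text())


def _simple_data(k=40, seed=0, tau2=0.05):
    rng = np.random.default_rng(seed)
    v = rng.uniform(0.01, 0.1, size=k)
    y = 0.3 + rng.normal(0, np.sqrt(tau2), size=k) + rng.normal(0, np.sqrt(v))
    groups = pd.DataFrame({"project": [f"p{i}" for i in range(k)],
                           "family": [f"f{i % 5}" for i in range(k)],
                           "species": [f"s{i % 10}" for i in range(k)]})
    X = pd.DataFrame({"intercept": np.ones(k)})
    return y, v, X, groups


class TestFitMeta:
    def test_matches_reference_multilevel_fits(self):
        """REML and ML estimates agree with the frozen rma.mv reference."""
        for i, oracle in enumerate(META_ORACLE):
            df, _ = meta_instance(i)
            X = meta.build_design(df, ["x1", "x2"])
            g = df[["project", "family", "species"]]
            fit = meta.fit_meta(df["yi"], df["vi"], X, g)
            np.testing.assert_allclose(fit.coef["estimate"], oracle["beta"], atol=1e-4)
            np.testing.assert_allclose(fit.coef["se"], oracle["se"], atol=1e-4)
            np.testing.assert_allclose(list(fit.sigma2.values()), oracle["sigma2"],
                                       atol=1e-4)
            assert fit.loglik == pytest.approx(oracle["loglik_reml"], abs=1e-4)
            ml = meta.fit_meta(df["yi"], df["vi"], X, g,
                               meta.MetaModelSpec(estimation="ML"))
            assert ml.loglik == pytest.approx(oracle["loglik_ml"], abs=1e-4)

    def test_fixed_effect_limit_is_inverse_variance_weighted_mean(self):
        y, v, X, groups = _simple_data(seed=1, tau2=0.0)
        fit = meta.fit_meta(y, v, X, groups)
        # with all variance components at ~0 the intercept must be the
        # inverse-variance weighted mean
        if fit.total_sigma2 < 1e-10:
            expected = np.sum(y / v) / np.sum(1 / v)
            assert fit.coef.loc["intercept", "estimate"] == pytest.approx(expected,
                                                                          abs=1e-10)
        w = 1 / (v + fit.total_sigma2)
        expected = np.sum(w * y) / np.sum(w)
        assert fit.coef.loc["intercept", "estimate"] == pytest.approx(expected, abs=1e-8)

    def test_equal_variance_zero_heterogeneity_mean(self):
        rng = np.random.default_rng(3)
        k = 50
        v = np.full(k, 0.04)
        y = 0.1 + rng.normal(0, np.sqrt(0.04), size=k)
        groups = pd.DataFrame({"project": [f"p{i}" for i in range(k)],
                               "family": "f0", "species": [f"s{i}" for i in range(k)]})
        groups["family"] = [f"f{i}" for i in range(k)]
        X = pd.DataFrame({"intercept": np.ones(k)})
        fit = meta.fit_meta(y, v, X, groups)
        assert fit.total_sigma2 < 0.03
        assert fit.coef.loc["intercept", "estimate"] == pytest.approx(y.mean(), abs=0.02)

    def test_single_level_matches_classical_random_effects_reml(self):
        """One grouping level + intercept = classical REML meta-analysis."""
        y, v, X, groups = _simple_data(k=60, seed=5, tau2=0.08)
        fit = meta.fit_meta(y, v, X, groups,
                            meta.MetaModelSpec(random_terms=("project",)))
        # independent oracle: classical 1-D REML fixed-point iteration
        tau2 = 0.01
        for _ in range(2000):
            w = 1 / (v + tau2)
            mu = np.sum(w * y) / np.sum(w)
            tau2_new = max(0.0, float(
                np.sum(w ** 2 * ((y - mu) ** 2 - v)) / np.sum(w ** 2)
                + 1.0 / np.sum(w)))
            if abs(tau2_new - tau2) < 1e-13:
                break
            tau2 = tau2_new
        w = 1 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        assert fit.sigma2["project"] == pytest.approx(tau2, abs=2e-4)
        assert fit.coef.loc["intercept", "estimate"] == pytest.approx(mu, abs=1e-4)

    def test_singular_design_names_columns(self):
        y, v, X, groups = _simple_data()
        X = X.assign(dup1=1.0)
        with pytest.raises(ValueError, match="collinear"):
            meta.fit_meta(y, v, X, groups)

    def test_too_few_effects_rejected(self):
        y, v, X, groups = _simple_data(k=4)
        with pytest.raises(ValueError, match="too few"):
            meta.fit_meta(y, v, X, groups)


class TestHeterogeneity:
    def test_zero_components_zero_i2(self):
        y, v, X, groups = _simple_data(seed=2)
        fit = meta.fit_meta(y, v, X, groups)
        fit.sigma2 = {lev: 0.0 for lev in fit.sigma2}
        rep = meta.i_squared(fit)
        assert rep.i2_total == 0.0

    def test_total_fifty_percent_when_sigma2_equals_typical_v(self):
        y, v, X, groups = _simple_data(seed=2)
        v = np.full_like(v, 0.05)
        fit = meta.fit_meta(y, v, X, groups)
        fit.v = v
        fit.sigma2 = {"project": 0.05, "family": 0.0, "species": 0.0}
        rep = meta.i_squared(fit)
        # equal v makes the typical sampling variance exactly v
        assert rep.typical_v == pytest.approx(0.05)
        assert rep.i2_total == pytest.approx(50.0)

    def test_matches_direct_formula(self):
        y, v, X, groups = _simple_data(seed=7)
        fit = meta.fit_meta(y, v, X, groups)
        rep = meta.i_squared(fit)
        w = 1 / v
        tv = (len(v) - 1) * w.sum() / (w.sum() ** 2 - (w ** 2).sum())
        expected = 100 * fit.total_sigma2 / (fit.total_sigma2 + tv)
        assert rep.i2_total == pytest.approx(expected)
        assert sum(rep.i2_level.values()) == pytest.approx(rep.i2_total)


class TestPseudoR2AndAicc:
    def test_pseudo_r2_identities(self):
        y, v, X, groups = _simple_data(seed=8, tau2=0.1)
        fit = meta.fit_meta(y, v, X, groups)
        assert meta.pseudo_r2(fit, fit) == 0.0
        full = meta.fit_meta(y, v, X, groups)
        full.sigma2 = {lev: 0.0 for lev in full.sigma2}
        assert meta.pseudo_r2(full, fit) == pytest.approx(100.0)

    def test_aicc_formula(self):
        y, v, X, groups = _simple_data(k=50, seed=9)
        fit = meta.fit_meta(y, v, X, groups, meta.MetaModelSpec(estimation="ML"))
        fit.loglik = -100.0
        fit.sigma2 = {"project": 0.1, "family": 0.1}  # p = 1 fixed + 2 = 3
        assert meta.aicc(fit) == pytest.approx(206.0 + 24 / 46)
        assert meta.aicc(fit) == pytest.approx(206.5217, abs=1e-4)

    def test_aicc_domain_errors(self):
        y, v, X, groups = _simple_data(k=50)
        fit = meta.fit_meta(y, v, X, groups)
        fit.k = 2  # k <= p + 1
        with pytest.raises(ValueError, match="AICc undefined"):
            meta.aicc(fit)
        empty = meta.MetaFit(spec=meta.MetaModelSpec(), coef=fit.coef.iloc[:0],
                             sigma2={}, loglik=-1.0, k=50, converged=True,
                             y=y, v=v, X=X.iloc[:, :0], groups=groups)
        with pytest.raises(ValueError, match="no parameters"):
            meta.aicc(empty)


class TestSelection:
    @staticmethod
    def _interaction_data(seed, slope):
        rng = np.random.default_rng(seed)
        k = 150
        data = pd.DataFrame({
            "hmi": rng.random(k),
            "trophic_group": rng.choice(["large herbivore", "small carnivore",
                                         "large omnivore"], size=k),
            "openness": rng.choice(["open", "closed"], size=k),
        })
        carn = (data["trophic_group"] == "small carnivore").astype(float)
        v = np.full(k, 0.04)
        groups = pd.DataFrame({"project": [f"p{i % 10}" for i in range(k)],
                               "family": [f"f{i % 5}" for i in range(k)],
                               "species": [f"s{i % 15}" for i in range(k)]})
        # heterogeneity enters through the grouping levels, matching the
        # random structure the meta-model can express
        u_p = dict(zip(sorted(groups["project"].unique()),
                       rng.normal(0, 0.12, 10)))
        u_s = dict(zip(sorted(groups["species"].unique()),
                       rng.normal(0, 0.10, 15)))
        y = 0.1 * data["hmi"] + slope * carn * data["hmi"] \
            + groups["project"].map(u_p) + groups["species"].map(u_s) \
            + rng.normal(0, np.sqrt(v))
        return y, v, data, groups

    def test_planted_interaction_wins_aicc(self):
        y, v, data, groups = self._interaction_data(seed=21, slope=1.5)
        table, retained, fit = meta.select_interactions(
            y, v, data, groups, ["trophic_group", "openness", "hmi"])
        assert table.iloc[0]["model"] == "trophic_group:hmi"
        assert "trophic_group:hmi" in retained
        assert fit.spec.estimation == "REML"

    def test_no_interaction_rarely_selects_candidates(self):
        # under a null interaction the global model is the modal winner and
        # no single spurious candidate dominates (the AICc penalty exceeds
        # the expected chi-square gain of an irrelevant term)
        winners = []
        for s in range(8):
            y, v, data, groups = self._interaction_data(seed=100 + s, slope=0.0)
            table, retained, _ = meta.select_interactions(
                y, v, data, groups, ["trophic_group", "openness", "hmi"])
            winners.append(table.iloc[0]["model"])
        wins_global = winners.count("global")
        assert wins_global >= 3
        assert all(winners.count(c) <= wins_global for c in set(winners))

    def test_duplicate_column_candidate_errors_cleanly(self):
        y, v, data, groups = self._interaction_data(seed=3, slope=0.0)
        with pytest.raises(ValueError, match="collinear"):
            meta.fit_meta(y, v,
                          meta.build_design(data, ["hmi", "hmi"]).assign(hmi2=data["hmi"]),
                          groups)

    def test_subset_selection_prefers_true_signal_and_ignores_noise(self):
        rng = np.random.default_rng(31)
        k = 120
        data = pd.DataFrame({"hmi": rng.random(k),
                             "hunted": rng.choice([True, False], size=k),
                             "noise_var": rng.normal(size=k)})
        data.loc[rng.random(k) < 0.15, "noise_var"] = np.nan
        hunted = data["hunted"].astype(float)
        v = np.full(k, 0.04)
        groups = pd.DataFrame({"project": [f"p{i % 10}" for i in range(k)],
                               "family": [f"f{i % 5}" for i in range(k)],
                               "species": [f"s{i % 15}" for i in range(k)]})
        y_signal = 0.8 * hunted + rng.normal(0, np.sqrt(v))
        table, preferred = meta.subset_model_selection(
            y_signal, v, data, groups, ["hmi"], "hunted")
        assert "hunted" in preferred
        y_noise = rng.normal(0, np.sqrt(v))
        table2, preferred2 = meta.subset_model_selection(
            y_noise, v, data, groups, ["hmi"], "noise_var")
        assert preferred2 == ["hmi"]

    def test_subset_without_missingness_matches_full_fit(self):
        y, v, data, groups = self._interaction_data(seed=12, slope=0.0)
        data = data.assign(extra=np.random.default_rng(0).normal(size=len(data)))
        table, preferred = meta.subset_model_selection(
            y, v, data, groups, ["trophic_group", "hmi"], "extra")
        full = meta.fit_meta(y, v, meta.build_design(data, ["trophic_group", "hmi"]),
                             groups, meta.MetaModelSpec(estimation="ML"))
        row = table.set_index("model").loc["global"]
        assert row["loglik"] == pytest.approx(full.loglik, abs=1e-6)


class TestPercentChange:
    def _fit(self):
        y, v, X, groups = _simple_data(seed=13)
        return meta.fit_meta(y, v, X, groups)

    @pytest.mark.parametrize("b,delta,expected", [
        (np.log(1.25), 1.0, 25.0), (0.37, 0.0, 0.0), (np.log(2), 1.0, 100.0)])
    def test_exponential_identities(self, b, delta, expected):
        fit = self._fit()
        fit.coef.loc["intercept", "estimate"] = b
        assert meta.percent_change(fit, "intercept", 0.0, delta) == pytest.approx(expected)

    def test_unknown_predictor_rejected_and_range_warned(self):
        fit = self._fit()
        with pytest.raises(KeyError):
            meta.percent_change(fit, "nope", 0, 1)
        with pytest.warns(UserWarning, match="outside observed range"):
            meta.percent_change(fit, "intercept", 0, 5, warn_range=(0, 1))


class TestSignificance:
    def test_thresholds(self):
        assert meta.significance_label(0.01) == "significant"
        assert meta.significance_label(0.07) == "marginal"
        assert meta.significance_label(0.2) == "ns"
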
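"""GLM fitting, stepwise selection, Mantel, envelopes, CE shifts, forecasting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tipflow.envmodel import (
    ce_shift_association,
    climatic_envelopes,
    fit_poisson_glm,
    forecast_transposition,
    holdout_validation,
    restricted_mantel,
    stepwise_select,
    zscore_climate,
)
from tipflow.synth import BIO_VARS


@pytest.fixture
def climate_table():
    rng = np.random.default_rng(0)
    n = 50
    rows = []
    for epoch in ("current", "future"):
        df = pd.DataFrame(rng.normal(10, 3, size=(n, 19)), columns=BIO_VARS)
        df.insert(0, "epoch", epoch)
        df.insert(0, "accession", [f"a{i}" for i in range(n)])
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


class TestZscore:
    def test_current_columns_standardized(self, climate_table):
        z, _ = zscore_climate(climate_table)
        cur = z[z["epoch"] == "current"]
        assert np.allclose(cur[BIO_VARS].mean(), 0.0, atol=1e-10)
        assert np.allclose(cur[BIO_VARS].std(ddof=0), 1.0, atol=1e-10)

    def test_future_uses_current_statistics(self, climate_table):
        z, ref = zscore_climate(climate_table)
        raw = climate_table.copy()
        i = raw.index[raw["epoch"] == "future"][0]
        raw.loc[i, "BIO05"] = ref.loc["BIO05", "mean"]
        z2, _ = zscore_climate(raw)
        assert z2.loc[i, "BIO05"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_column_named_in_error(self, climate_table):
        bad = climate_table.copy()
        bad["BIO07"] = 1.0
        with pytest.raises(ValueError, match="BIO07"):
            zscore_climate(bad)

    def test_missing_reference_epoch(self, climate_table):
        with pytest.raises(ValueError, match="epoch"):
            zscore_climate(climate_table[climate_table["epoch"] == "future"])


def _design(n=500, seed=0):
    rng = np.random.default_rng(seed)
    data = pd.DataFrame({
        "PC1": rng.normal(size=n), "PC2": rng.normal(size=n),
        "PC3": rng.normal(size=n),
        "modifier": rng.binomial(1, 0.3, size=n).astype(float),
        "BIO04": rng.normal(size=n), "BIO12": rng.normal(size=n),
        "noise1": rng.normal(size=n), "noise2": rng.normal(size=n),
    }, index=[f"a{i}" for i in range(n)])
    return data, rng


class TestPoissonGlm:
    def test_intercept_only_recovers_log_mean_with_zero_pve(self):
        data, rng = _design(n=1000, seed=1)
        y = rng.poisson(5.0, size=1000)
        fit = fit_poisson_glm(y, data, [])
        assert fit.params["Intercept"] == pytest.approx(np.log(5.0), abs=0.05)
        assert fit.pve == pytest.approx(0.0, abs=0.01)

    def test_duplicated_covariate_raises_with_term_names(self):
        data, rng = _design(n=200, seed=2)
        data["BIO04_copy"] = data["BIO04"]
        y = rng.poisson(3.0, size=200)
        with pytest.raises(ValueError, match="collinear"):
            fit_poisson_glm(y, data, ["BIO04", "BIO04_copy"])

    def test_non_integer_counts_rejected(self):
        data, _ = _design(n=10)
        with pytest.raises(ValueError, match="non-negative integers"):
            fit_poisson_glm(np.full(10, 1.5), data, ["BIO04"])

    def test_matches_independent_grid_search_mle(self):
        # 2-parameter toy problem: intercept + one covariate
        data, rng = _design(n=300, seed=3)
        y = rng.poisson(np.exp(0.8 + 0.5 * data["BIO04"].to_numpy()))
        fit = fit_poisson_glm(y, data, ["BIO04"])

        def nll(b0, b1):
            eta = b0 + b1 * data["BIO04"].to_numpy()
            return np.sum(np.exp(eta) - y * eta)

        # iteratively refined grid search, independent of IRLS
        c0, c1, w = 0.8, 0.5, 1.0
        for _ in range(40):
            g0 = np.linspace(c0 - w, c0 + w, 21)
            g1 = np.linspace(c1 - w, c1 + w, 21)
            vals = np.array([[nll(a, b) for b in g1] for a in g0])
            i, j = np.unravel_index(np.argmin(vals), vals.shape)
            c0, c1, w = g0[i], g1[j], w / 4
        assert fit.params["Intercept"] == pytest.approx(c0, abs=1e-6)
        assert fit.params["BIO04"] == pytest.approx(c1, abs=1e-6)

    def test_pve_nondecreasing_in_nested_designs(self):
        data, rng = _design(n=400, seed=4)
        y = rng.poisson(np.exp(1.0 + 0.3 * data["BIO04"].to_numpy()))
        terms, pves = [], []
        for t in ["PC1", "BIO04", "noise1", "noise2"]:
            terms.append(t)
            pves.append(fit_poisson_glm(y, data, terms).pve)
        assert all(b >= a - 1e-12 for a, b in zip(pves, pves[1:]))
        assert all(0 <= v <= 1 for v in pves)


class TestStepwise:
    def test_independent_candidates_add_nothing(self):
        data, rng = _design(n=800, seed=5)
        y = rng.poisson(3.0, size=800)
        fit, trace = stepwise_select(y, data, ["PC1", "modifier"],
                                     ["noise1", "noise2"])
        assert fit.terms == ["PC1", "modifier"]
        added = [t for t in trace if t["added"]]
        assert not added
        assert all(t["delta_pve"] <= 0.01 for t in trace)

    def test_planted_fixed_effect_selected(self):
        data, rng = _design(n=800, seed=6)
        y = rng.poisson(np.exp(1.0 + 0.5 * data["BIO04"].to_numpy()))
        fit, trace = stepwise_select(y, data, ["PC1"],
                                     ["BIO04", "noise1", "noise2"],
                                     allow_gxe=False)
        added = [t["candidate"] for t in trace if t["added"]]
        assert added == ["BIO04"]

    def test_planted_interaction_enters_with_main_effect(self):
        data, rng = _design(n=1000, seed=7)
        eta = (0.8 + np.log(3.4) * data["modifier"]
               + 0.5 * data["modifier"] * data["BIO04"])
        y = rng.poisson(np.exp(eta))
        fit, trace = stepwise_select(y, data, ["PC1", "PC2", "PC3", "modifier"],
                                     ["BIO04", "BIO12", "noise1"])
        added = [t for t in trace if t["added"]]
        assert added[0]["candidate"] == "BIO04"
        assert "modifier:BIO04" in fit.terms and "BIO04" in fit.terms


class TestMantel:
    def test_power_case_reaches_permutation_floor(self):
        rng = np.random.default_rng(8)
        n = 40
        bio = rng.normal(size=n)
        counts = 2.0 * bio + rng.normal(0, 0.01, size=n)
        K = np.eye(n)
        r, p = restricted_mantel(counts, bio, K, n_perm=1000, seed=1)
        assert r > 0.5
        assert p == pytest.approx(1 / 1001)

    def test_asymmetric_kinship_rejected(self):
        K = np.eye(4)
        K[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            restricted_mantel(np.ones(4), np.ones(4), K)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(9)
        n = 30
        ps = []
        for i in range(40):
            counts = rng.poisson(5, size=n).astype(float)
            bio = rng.normal(size=n)
            latent = rng.normal(size=(n, 4))
            K = np.corrcoef(latent)
            _, p = restricted_mantel(counts, bio, K, n_perm=199, seed=100 + i)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestEnvelopes:
    def test_three_factor_climate_concentrates_variance(self):
        rng = np.random.default_rng(10)
        n = 400
        factors = rng.normal(size=(n, 3))
        load = rng.normal(size=(3, 19))
        X = factors @ load + 0.3 * rng.normal(size=(n, 19))
        z = pd.DataFrame((X - X.mean(0)) / X.std(0), columns=BIO_VARS)
        ce = climatic_envelopes(z)
        assert ce.variance_fractions.sum() > 0.8
        assert np.all(np.diff(ce.variance_fractions) <= 1e-12)
        # orthonormal loadings, deterministic sign
        np.testing.assert_allclose(ce.loadings.T @ ce.loadings, np.eye(3),
                                   atol=1e-10)
        for c in ce.loadings.columns:
            v = ce.loadings[c].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_isotropic_climate_spreads_variance(self):
        rng = np.random.default_rng(11)
        z = pd.DataFrame(rng.normal(size=(3000, 19)), columns=BIO_VARS)
        ce = climatic_envelopes(z)
        assert np.all(ce.variance_fractions < 0.085)
        assert np.all(ce.variance_fractions > 0.035)

    def test_duplicated_accessions_get_identical_scores(self):
        rng = np.random.default_rng(12)
        z = pd.DataFrame(rng.normal(size=(30, 19)), columns=BIO_VARS)
        zz = pd.concat([z, z.iloc[:1]], ignore_index=True)
        ce = climatic_envelopes(zz)
        np.testing.assert_allclose(ce.scores.iloc[0], ce.scores.iloc[-1], atol=1e-10)

    def test_too_few_nondegenerate_variables(self):
        z = pd.DataFrame(np.ones((20, 19)), columns=BIO_VARS)
        z["BIO01"] = np.arange(20.0)
        with pytest.raises(ValueError, match="non-degenerate"):
            climatic_envelopes(z)


class TestCeShift:
    def _setup(self, seed=13, n=200):
        rng = np.random.default_rng(seed)
        scores = pd.DataFrame(rng.normal(size=(n, 3)),
                              columns=["CE1", "CE2", "CE3"],
                              index=[f"a{i}" for i in range(n)])
        pcs = pd.DataFrame(rng.normal(size=(n, 3)), columns=["PC1", "PC2", "PC3"],
                           index=scores.index)
        return rng, scores, pcs

    def test_planted_ce2_shift_detected(self):
        rng, scores, pcs = self._setup()
        top = (scores["CE2"] > scores["CE2"].quantile(0.9)).to_numpy()
        prob = np.where(top, 0.8, 0.05)
        carriers = {"gene_hot": rng.binomial(1, prob).astype(float)}
        res = ce_shift_association(carriers, scores, pcs, fdr=0.05)
        row = res[(res["gene_id"] == "gene_hot") & (res["ce"] == "CE2")].iloc[0]
        assert row["delta_ce"] > 0
        assert row["significant"]

    def test_environment_permutation_erases_planted_signal(self):
        rng, scores, pcs = self._setup(seed=14)
        top = (scores["CE2"] > scores["CE2"].quantile(0.9)).to_numpy()
        carriers = {"gene_hot": rng.binomial(1, np.where(top, 0.8, 0.05)).astype(float)}
        res = ce_shift_association(carriers, scores, pcs, fdr=0.05,
                                   permute_env=True, seed=15)
        row = res[(res["gene_id"] == "gene_hot") & (res["ce"] == "CE2")].iloc[0]
        assert not row["significant"]

    def test_small_carrier_sets_skipped_with_warning(self):
        rng, scores, pcs = self._setup(seed=16)
        y = np.zeros(len(scores))
        y[:2] = 1.0
        with pytest.warns(UserWarning, match="fewer than"):
            res = ce_shift_association({"tiny": y}, scores, pcs)
        assert res.empty

    def test_bh_matches_textbook_step_up(self):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.04, 0.03, 0.2])
        reject, q, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        # textbook oracle
        order = np.argsort(p)
        m = len(p)
        thresh = 0.05 * (np.arange(1, m + 1)) / m
        passed = p[order] <= thresh
        k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
        expect_reject = np.zeros(m, dtype=bool)
        expect_reject[order[:k]] = True
        np.testing.assert_array_equal(reject, expect_reject)
        qs = p[order] * m / np.arange(1, m + 1)
        qs = np.minimum.accumulate(qs[::-1])[::-1]
        np.testing.assert_allclose(q[order], qs)


class TestForecastAndHoldout:
    def _fit(self, seed=17, beta=0.5, beta_gxe=0.0, n=600):
        data, rng = _design(n=n, seed=seed)
        eta = (1.0 + np.log(2.0) * data["modifier"] + beta * data["BIO04"]
               + beta_gxe * data["modifier"] * data["BIO04"])
        y = rng.poisson(np.exp(eta))
        terms = ["modifier", "BIO04"] + (["modifier:BIO04"] if beta_gxe else [])
        fit = fit_poisson_glm(y, data, terms)
        data = data.assign(group=(np.arange(n) % 3))
        return fit, data, rng

    def test_identity_forecast_is_exactly_zero(self):
        fit, data, _ = self._fit()
        clim = data[["BIO04"]]
        res = forecast_transposition(fit, data, clim, clim)
        assert np.max(np.abs(res.per_accession["delta"])) <= 1e-12

    def test_single_covariate_log_change_is_beta_dz(self):
        fit, data, _ = self._fit(seed=18)
        beta = fit.params["BIO04"]
        cur = data[["BIO04"]]
        fut = cur + 0.7
        res = forecast_transposition(fit, data, cur, fut)
        log_change = np.log(res.per_accession["pred_future"]
                            / res.per_accession["pred_current"])
        np.testing.assert_allclose(log_change, beta * 0.7, rtol=1e-9)

    def test_opposed_main_and_interaction_split_carrier_direction(self):
        fit, data, _ = self._fit(seed=19, beta=-0.4, beta_gxe=0.9, n=2000)
        cur = data[["BIO04"]]
        fut = cur + 1.0  # warming shift
        res = forecast_transposition(fit, data, cur, fut)
        bm = res.by_modifier.set_index("modifier")
        assert bm.loc[0, "delta_mean"] < 0 < bm.loc[1, "delta_mean"]

    def test_missing_future_bio_variable(self):
        fit, data, _ = self._fit(seed=20)
        cur = data[["BIO04"]]
        with pytest.raises(ValueError, match="BIO04"):
            forecast_transposition(fit, data, cur, cur.drop(columns="BIO04"))

    def test_holdout_flags_planted_outlier_and_validates_designs(self):
        data, rng = _design(n=200, seed=21)
        eta = 1.2 + np.log(2.0) * data["modifier"] + 0.6 * data["modifier"] * data["BIO04"]
        y = rng.poisson(np.exp(eta)).astype(float)
        y[7] *= 10  # corrupted accession
        designs = {
            "GxE": ["modifier", "BIO04", "modifier:BIO04"],
            "G": ["modifier"],
        }
        res = holdout_validation(y, data, designs, n_sets=40, set_size=40,
                                 outlier_sd=4.0, seed=22)
        assert data.index[7] in res.outliers
        assert res.predictive_variance["GxE"] <= res.predictive_variance["G"]

    def test_holdout_set_size_must_be_smaller_than_panel(self):
        data, rng = _design(n=50, seed=23)
        y = rng.poisson(3, size=50)
        with pytest.raises(ValueError, match="set_size"):
            holdout_validation(y, data, {"G": ["modifier"]}, set_size=50)
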
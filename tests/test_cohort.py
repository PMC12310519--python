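import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import KFold

from sgmkit.cohort import (
    CohortTable,
    age_correlation,
    breusch_pagan,
    cv_regression,
    jsh_divergence,
    predicted_vs_observed,
    regime_contrast,
)
from sgmkit.connectome import Connectome


def make_table(n=200, seed=0, **columns):
    rng = np.random.default_rng(seed)
    ages = 10 ** rng.uniform(-2, 1.4, n)
    df = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)], "age_years": ages})
    for name, val in columns.items():
        df[name] = val(np.log10(ages), rng) if callable(val) else val
    return CohortTable(df)


class TestCohortTable:
    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame({"subject_id": ["a", "a"], "age_years": [1.0, 2.0]})
        with pytest.raises(ValueError, match="duplicated"):
            CohortTable(df)

    def test_nonpositive_age_rejected(self):
        df = pd.DataFrame({"subject_id": ["a", "b"], "age_years": [1.0, 0.0]})
        with pytest.raises(ValueError, match="positive"):
            CohortTable(df)


class TestAgeCorrelation:
    def test_perfect_linear_function_of_log_age(self):
        tab = make_table(n=50, x=lambda la, rng: 2 * la)
        r, p, n = age_correlation(tab, "x")
        assert r == pytest.approx(1.0)
        assert p < 1e-30
        assert n == 50

    def test_independent_column_has_small_r(self):
        tab = make_table(n=200, seed=3, x=lambda la, rng: rng.normal(size=la.size))
        r, p, _ = age_correlation(tab, "x")
        assert abs(r) < 0.15

    def test_null_p_values_roughly_uniform(self):
        ps = []
        for seed in range(40):
            tab = make_table(n=100, seed=seed, x=lambda la, rng: rng.normal(size=la.size))
            ps.append(age_correlation(tab, "x")[1])
        ps = np.array(ps)
        assert 0.1 < np.mean(ps) < 0.9
        assert (ps < 0.05).mean() < 0.25

    def test_zero_variance_rejected(self):
        tab = make_table(n=20, x=1.0)
        with pytest.raises(ValueError, match="variance"):
            age_correlation(tab, "x")


class TestCvRegression:
    def test_noiseless_quadratic_is_recovered(self):
        tab = make_table(n=120, seed=1, x=lambda la, rng: rng.uniform(-2, 2, la.size))
        tab.df["y"] = 3 * tab.df["x"] ** 2 - tab.df["x"] + 0.5
        res = cv_regression(tab, ["x"], "y", degree=2, k=10, seed=0, target_transform=None)
        assert res.adj_r2 > 0.99

    def test_pure_noise_target_has_no_skill(self):
        scores = []
        for seed in range(5):
            tab = make_table(n=200, seed=seed, x=lambda la, rng: rng.normal(size=la.size))
            tab.df["y"] = np.random.default_rng(seed + 100).normal(size=200)
            scores.append(cv_regression(tab, ["x"], "y", seed=seed, target_transform=None).adj_r2)
        assert np.mean(scores) <= 0.05

    def test_out_of_fold_predictions_cannot_see_their_own_fold(self):
        """Mark the subjects of one CV fold with an indicator target: if the
        model were (incorrectly) fitted on the full data it would predict the
        indicator perfectly; honest out-of-fold prediction cannot."""
        n, k, seed = 120, 10, 7
        tab = make_table(n=n, seed=2, x=lambda la, rng: rng.normal(size=la.size))
        fold0_idx = next(iter(KFold(n_splits=k, shuffle=True, random_state=seed).split(np.zeros(n))))[1]
        marker = np.zeros(n)
        marker[fold0_idx] = 1.0
        tab.df["marker"] = marker
        tab.df["y"] = marker
        res = cv_regression(tab, ["marker"], "y", degree=2, k=k, seed=seed, target_transform=None)
        preds_fold0 = res.predictions["predicted"].to_numpy()[fold0_idx]
        assert np.all(np.abs(preds_fold0 - 1.0) > 0.5)  # trained without any marker=1 examples

    def test_age_target_is_modeled_in_log10_years(self):
        tab = make_table(n=100, seed=4, x=lambda la, rng: la + rng.normal(0, 0.01, la.size))
        res = cv_regression(tab, ["x"], "age_years", seed=0)
        assert res.target_transform == "log10"
        assert res.adj_r2 > 0.95
        nat = res.predictions["predicted_natural"].to_numpy()
        assert np.allclose(nat, 10 ** res.predictions["predicted"].to_numpy())


class TestPredictedVsObserved:
    def test_identity(self):
        x = np.linspace(0, 1, 50)
        slope, intercept, r2 = predicted_vs_observed(x, x)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_constant_offset_appears_in_intercept(self):
        obs = np.linspace(0, 1, 50)
        pred = obs + 5
        slope, intercept, _ = predicted_vs_observed(pred, obs)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(-5.0)

    def test_constant_predictions_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            predicted_vs_observed(np.ones(20), np.linspace(0, 1, 20))


class TestBreuschPagan:
    def test_constant_residuals_give_zero_statistic(self):
        lm, p = breusch_pagan(np.full(100, 2.0), np.linspace(0, 1, 100))
        assert lm == 0.0
        assert p == 1.0

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.diagnostic import het_breuschpagan

        rng = np.random.default_rng(0)
        x = rng.normal(size=(300, 2))
        resid = rng.normal(size=300) * (1 + 0.8 * np.abs(x[:, 0]))
        lm, p = breusch_pagan(resid, x)
        exog = np.column_stack([np.ones(300), x])
        lm_sm, p_sm, *_ = het_breuschpagan(resid, exog)
        assert lm == pytest.approx(lm_sm, rel=1e-8)
        assert p == pytest.approx(p_sm, rel=1e-8)

    def test_power_against_variance_growing_with_x_squared(self):
        # variance proportional to x^2 is only visible to the LM auxiliary
        # regression when the design carries the quadratic term, as a fitted
        # degree-2 polynomial model's design does
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.uniform(-2, 2, 500)
            resid = rng.normal(size=500) * np.abs(x)
            design = np.column_stack([x, x**2])
            _, p = breusch_pagan(resid, design)
            hits += p < 0.01
        assert hits >= 4

    def test_null_distribution_not_anticonservative(self):
        rejections = 0
        for seed in range(50):
            rng = np.random.default_rng(seed + 500)
            x = rng.uniform(-2, 2, 200)
            resid = rng.normal(size=200)
            _, p = breusch_pagan(resid, x)
            rejections += p < 0.05
        assert rejections <= 8


class TestJshDivergence:
    def test_identical_distributions(self):
        p = np.array([0.2, 0.3, 0.5])
        assert jsh_divergence(p, p) == 0.0

    def test_disjoint_supports_give_one(self):
        p = np.array([0.5, 0.5, 0.0, 0.0])
        q = np.array([0.0, 0.0, 0.5, 0.5])
        assert jsh_divergence(p, q) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(30))
        q = rng.dirichlet(np.ones(30))
        assert jsh_divergence(p, q) == pytest.approx(jsh_divergence(q, p), abs=1e-12)

    def test_matches_literal_two_term_kl_oracle(self):
        def kl(a, b):
            m = a > 0
            return float(np.sum(a[m] * np.log2(a[m] / b[m])))

        rng = np.random.default_rng(2)
        for _ in range(10):
            p = rng.dirichlet(np.ones(20))
            q = rng.dirichlet(np.ones(20))
            m = (p + q) / 2
            oracle = 0.5 * kl(p, m) + 0.5 * kl(q, m)
            assert jsh_divergence(p, q) == pytest.approx(oracle, abs=1e-10)

    def test_unnormalized_inputs_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            jsh_divergence(np.array([0.5, 0.6]), np.array([0.5, 0.5]))


class TestRegimeContrast:
    def test_identical_connectomes_have_zero_connectome_effect(self, conn12, grid):
        rc = regime_contrast(conn12, conn12, grid=grid, n_draws=40, seed=0, n_permutations=50)
        assert rc.jsh_connectome == pytest.approx(0.0, abs=1e-12)
        assert rc.difference == pytest.approx(rc.jsh_alpha, abs=1e-12)

    def test_equal_bands_have_zero_alpha_effect(self, conn12, grid):
        rc = regime_contrast(
            conn12, conn12, grid=grid, n_draws=80,
            weak=(0.4, 0.6), strong=(0.4, 0.6), seed=1, n_permutations=50,
        )
        # same band, independent draws: alpha effect is pure Monte-Carlo noise
        assert rc.jsh_alpha < 0.02

    def test_jittered_connectome_pair_alpha_dominates(self, conn12, grid):
        rng = np.random.default_rng(3)
        w = conn12.weights * np.exp(rng.normal(0, 0.05, conn12.weights.shape))
        w = (w + w.T) / 2
        jittered = Connectome(conn12.labels, w, conn12.distances)
        rc = regime_contrast(conn12, jittered, grid=grid, n_draws=100, seed=4, n_permutations=300)
        assert rc.jsh_alpha > rc.jsh_connectome
        assert rc.p_value < 0.05
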
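"""Rank coupling, univariate/multivariate perturbation, and ε-DP release."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dataflush import (
    HoldoutLedger,
    HoldoutViolationError,
    ParametricTarget,
    PerturbationPlan,
    fit_conditional_chain,
    fit_smoothed_cdf,
    make_noise_model,
    perturb_multivariate,
    perturb_residuals,
    perturb_univariate,
    privatize,
    rank_matched_uniforms,
)
from dataflush.schema import ColumnSpec, TableSchema
from dataflush.simulate import gen_survey_microdata, survey_schema


class TestRankCoupling:
    def test_rank_preservation_small(self):
        rc = rank_matched_uniforms([3.0, 1.0, 2.0], 0)
        u = rc.uniforms
        assert u[1] < u[2] < u[0]

    def test_single_observation(self):
        rc = rank_matched_uniforms([7.0], 1)
        assert 0 < rc.uniforms[0] < 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_matched_uniforms([], 0)

    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=200),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_rank_identity_property(self, z, seed):
        z = np.asarray(z)
        u = rank_matched_uniforms(z, seed).uniforms
        assert np.all((u > 0) & (u < 1))
        # strict order of z is always reproduced in u; ties are broken somehow
        i, j = np.meshgrid(np.arange(z.size), np.arange(z.size), indexing="ij")
        strict = z[i] < z[j]
        assert np.all(u[i][strict] < u[j][strict])

    def test_spearman_is_one_for_continuous_sample(self, rng):
        z = rng.normal(size=10**4)
        u = rank_matched_uniforms(z, 5).uniforms
        assert stats.spearmanr(z, u).statistic == pytest.approx(1.0)

    def test_uniform_marginal(self, rng):
        z = rng.normal(size=10**4)
        u = rank_matched_uniforms(z, 9).uniforms
        assert stats.kstest(u, "uniform").pvalue > 1e-3


class TestPerturbUnivariate:
    def test_small_noise_uniform_target_is_near_identity(self, rng):
        z = rng.normal(size=500)
        plan = PerturbationPlan(noise=make_noise_model("laplace", 1e-10), m=1, seed=3)
        target = ParametricTarget(stats.uniform(0, 1), name="uniform")
        out = perturb_univariate(z, target, plan).univariate().ravel()
        from dataflush._rng import named_rng

        u = rank_matched_uniforms(z, named_rng(3, "coupling")).uniforms
        # H reduces to the identity: output is the rank-coupled uniforms
        assert np.max(np.abs(out - u)) < 1e-6
        assert stats.spearmanr(out, z).statistic == pytest.approx(1.0)

    def test_distribution_preserved_normal_target(self, rng):
        z = rng.normal(size=2000)
        plan = PerturbationPlan(noise=make_noise_model("laplace", 1.0), m=1, seed=4)
        out = perturb_univariate(z, ParametricTarget(stats.norm(0, 1)), plan)
        assert stats.kstest(out.univariate().ravel(), stats.norm.cdf).pvalue > 0.001

    def test_distribution_preserved_under_huge_privacy_noise(self, rng):
        # the privacy-inference configuration: Laplace(0, 1/ε), ε = 0.01
        z = rng.normal(size=2000)
        target = ParametricTarget(stats.norm(z.mean(), z.std(ddof=1)))
        plan = PerturbationPlan(noise=make_noise_model("laplace", 100.0), m=1, seed=4)
        out = perturb_univariate(z, target, plan)
        assert stats.kstest(out.univariate().ravel(), target.cdf).pvalue > 0.001

    def test_copies_share_uniforms_by_default(self, rng):
        z = rng.normal(size=50)
        plan = PerturbationPlan(noise=make_noise_model("laplace", 1e-12), m=3, seed=8)
        out = perturb_univariate(z, ParametricTarget(stats.uniform(0, 1)), plan).univariate()
        # with vanishing noise all copies collapse onto the shared uniforms
        assert np.max(np.abs(out[:, 0] - out[:, 1])) < 1e-9
        assert np.max(np.abs(out[:, 0] - out[:, 2])) < 1e-9

    def test_smoothed_empirical_target(self, rng):
        z = rng.normal(size=1000)
        target = fit_smoothed_cdf(rng.normal(size=500))
        plan = PerturbationPlan(noise=make_noise_model("gaussian", 1.0), m=1, seed=6)
        out = perturb_univariate(z, target, plan)
        assert stats.kstest(out.univariate().ravel(), target.cdf).pvalue > 0.001


def _toy_table(rng, n=400):
    a = rng.normal(size=n)
    b = 0.7 * a + rng.normal(0, np.sqrt(1 - 0.49), n)
    c = rng.binomial(1, 1 / (1 + np.exp(-a)))
    df = pd.DataFrame({"a": a, "b": b, "c": c})
    schema = TableSchema([
        ColumnSpec("a", "continuous"),
        ColumnSpec("b", "continuous"),
        ColumnSpec("c", "binary"),
    ])
    return df, schema


class TestPerturbMultivariate:
    def test_single_column_chain_matches_univariate(self, rng):
        z = rng.normal(size=300)
        df = pd.DataFrame({"a": z})
        schema = TableSchema([ColumnSpec("a", "continuous")])
        chain = fit_conditional_chain(df, schema)
        plan = PerturbationPlan(noise=make_noise_model("laplace", 0.5), m=2, seed=12)
        out_multi = perturb_multivariate(df, chain, plan).values[:, 0, :]
        out_uni = perturb_univariate(z, chain.conditional_target(0), plan).univariate()
        np.testing.assert_allclose(out_multi, out_uni)

    def test_bivariate_correlation_preserved(self, rng):
        n = 5000
        a = rng.normal(size=n)
        b = 0.7 * a + rng.normal(0, np.sqrt(1 - 0.49), n)
        df = pd.DataFrame({"a": a, "b": b})
        schema = TableSchema([ColumnSpec("a", "continuous"), ColumnSpec("b", "continuous")])
        chain = fit_conditional_chain(df, schema)
        plan = PerturbationPlan(noise=make_noise_model("laplace", 0.01), m=1, seed=13)
        out = perturb_multivariate(df, chain, plan)
        r = np.corrcoef(out.values[:, 0, 0], out.values[:, 1, 0])[0, 1]
        assert abs(r - 0.7) < 0.05

    def test_identifier_preserved_and_roundtrips(self, rng, tmp_path):
        df, schema = _toy_table(rng, n=120)
        df.index = np.arange(1000, 1120)  # nontrivial record ids
        chain = fit_conditional_chain(df, schema)
        plan = PerturbationPlan(noise=make_noise_model("laplace", 0.05), m=1, seed=3)
        out = perturb_multivariate(df, chain, plan)
        f = out.frame(0)
        path = tmp_path / "copy.csv"
        f.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert np.array_equal(back["record_id"].to_numpy(), df.index.to_numpy())
        rho = stats.spearmanr(df["a"], f["a"]).statistic
        assert rho > 0.9  # small noise keeps the identifier link

    def test_cross_record_independence(self, rng):
        # across records at fixed copy, perturbed values are independent
        df, schema = _toy_table(rng, n=2000)
        chain = fit_conditional_chain(df, schema)
        plan = PerturbationPlan(noise=make_noise_model("laplace", 1.0), m=1, seed=5)
        v = perturb_multivariate(df, chain, plan).values[:, 0, 0]
        r = np.corrcoef(v[:-1], v[1:])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(v))


class TestPerturbResiduals:
    def test_zero_variance_returns_fitted_means(self, rng):
        mu = rng.normal(size=50)
        y = mu + rng.normal(size=50)
        plan = PerturbationPlan(noise=make_noise_model("laplace", 1.0), m=4, seed=2)
        out = perturb_residuals(y, mu, 0.0, plan)
        np.testing.assert_array_equal(out, np.repeat(mu[:, None], 4, axis=1))

    def test_perturbed_residuals_follow_target(self, rng):
        n = 1000
        x = rng.normal(size=n)
        mu = 2.0 + 0.5 * x
        y = mu + rng.normal(0, 0.8, n)
        plan = PerturbationPlan(noise=make_noise_model("laplace", 100.0), m=1, seed=7)
        out = perturb_residuals(y, mu, 0.64, plan)
        eps = (out[:, 0] - mu)
        assert stats.kstest(eps, stats.norm(0, 0.8).cdf).pvalue > 0.001

    def test_negative_variance_rejected(self):
        plan = PerturbationPlan(noise=make_noise_model("laplace", 1.0))
        with pytest.raises(ValueError):
            perturb_residuals([1.0], [1.0], -1.0, plan)


class TestPrivatize:
    def test_budget_scale_seventeen_variables(self, rng):
        # overall ε = 1 over 17 variables → per-variable Laplace scale 17
        df, schema = gen_survey_microdata(600, seed=1)
        out, budget = privatize(df, schema, epsilon=1.0, seed=4)
        assert budget.p == 17
        assert budget.per_variable_scale == pytest.approx(17.0)
        assert budget.consumed == schema.variable_names
        assert len(budget.consumed) == 17

    def test_logged_noise_follows_budget_laplace(self, rng):
        df, schema = gen_survey_microdata(600, seed=2)
        out, budget = privatize(df, schema, epsilon=1.0, seed=5)
        noise = out.noise_draws
        assert noise.size == out.n * 17
        lap = make_noise_model("laplace", budget.per_variable_scale)
        assert stats.kstest(noise, lap.cdf).pvalue > 0.001

    def test_large_epsilon_release_matches_holdout_target(self, rng):
        n = 2000
        df = pd.DataFrame({"a": rng.normal(size=n)})
        schema = TableSchema([ColumnSpec("a", "continuous")])
        out, _ = privatize(df, schema, epsilon=1e9, seed=9)
        # zero-noise limit: release follows the holdout-fitted target
        chain_target_vals = out.values[:, 0, 0]
        # compare against the smoothed CDF of the full sample; KS should be tiny
        target = fit_smoothed_cdf(df["a"])
        assert stats.kstest(chain_target_vals, target.cdf).statistic < 0.06

    def test_marginals_preserved_on_toy_table(self, rng):
        df, schema = _toy_table(rng, n=400)
        out, _ = privatize(df, schema, epsilon=1.0, seed=11)
        rel = out.frame(0)
        # continuous marginals agree with the raw table at α = 0.001
        for col in ("a", "b"):
            p = stats.ks_2samp(df[col], rel[col]).pvalue
            assert p > 0.001

    def test_holdout_ledger_guards_fixed_split(self, rng, tmp_path):
        df, schema = _toy_table(rng, n=200)
        ledger = HoldoutLedger(tmp_path / "ledger.json")
        privatize(df, schema, epsilon=1.0, seed=1, ledger=ledger)
        privatize(df, schema, epsilon=1.0, seed=1, ledger=ledger)  # same split OK
        ledger2 = HoldoutLedger(tmp_path / "ledger.json")  # reload from disk
        with pytest.raises(HoldoutViolationError):
            privatize(df, schema, epsilon=1.0, seed=2, ledger=ledger2)

    def test_dp_requires_disjoint_fit_rows(self, rng):
        df, schema = _toy_table(rng, n=200)
        chain = fit_conditional_chain(df, schema)
        plan = PerturbationPlan(noise=make_noise_model("laplace", 3.0), m=1, seed=1,
                                dp_mode=True, epsilon=1.0)
        with pytest.raises(HoldoutViolationError):
            perturb_multivariate(df, chain, plan)

    def test_epsilon_must_be_positive(self, rng):
        df, schema = _toy_table(rng, n=100)
        with pytest.raises(ValueError):
            privatize(df, schema, epsilon=0.0)
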
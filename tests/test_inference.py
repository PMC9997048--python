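"""Monte-Carlo pivotal steps, CI inversion, and the TLP regression solver."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from dataflush import (
    Estimate,
    PerturbationPlan,
    PivotalSpec,
    ParametricTarget,
    bias_correct,
    confidence_interval,
    flush_ci_for_regression,
    gen_highdim_regression,
    make_noise_model,
    monte_carlo_pivotal,
    normal_mean_spec,
    tlp_regression,
)
from dataflush.simulate import RegressionSimConfig
from dataflush.tlp import TLPWorkspace, choose_k_cv


class TestBiasCorrect:
    def test_identity_when_draws_equal_estimate(self):
        B, tc = bias_correct(2.5, [2.5, 2.5, 2.5])
        assert B == 0.0 and tc == 2.5

    def test_symmetric_draws_cancel(self):
        B, tc = bias_correct(1.0, [1.1, 0.9, 1.3, 0.7])
        assert B == pytest.approx(0.0)
        assert tc == pytest.approx(1.0)

    def test_printed_arithmetic(self):
        B, tc = bias_correct(2.0, [2.5, 2.5])
        assert B == pytest.approx(0.5)
        assert tc == pytest.approx(2.5)

    def test_classical_sign_flag(self):
        B, tc = bias_correct(2.0, [2.5, 2.5], sign="classical")
        assert B == pytest.approx(0.5)
        assert tc == pytest.approx(1.5)

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            bias_correct(1.0, [])


class TestConfidenceInterval:
    def test_symmetric_quantiles_give_symmetric_interval(self):
        draws = np.concatenate([np.linspace(-2, -1, 50), np.linspace(1, 2, 50)])
        lo, hi = confidence_interval(0.0, 1.0, draws, alpha=0.5)
        assert lo == pytest.approx(-hi)

    def test_exact_t_interval_recovered(self):
        # analytically supplied quantiles reproduce the closed-form t interval:
        # with 10001 draws the empirical 2.5%/97.5% quantiles hit grid points
        levels = np.linspace(0.0, 1.0, 10001)
        levels[0], levels[-1] = 1e-9, 1 - 1e-9
        q = stats.t(4).ppf(levels)
        lo, hi = confidence_interval(0.0, 1.0, q, alpha=0.05)
        assert lo == pytest.approx(-stats.t(4).ppf(0.975), abs=1e-12)
        assert hi == pytest.approx(stats.t(4).ppf(0.975), abs=1e-12)

    def test_pivot_inversion_direction(self):
        # T = (θ̂-θ)/se with all T* = 1 → θ ∈ [θ̂c - se, θ̂c - se]
        lo, hi = confidence_interval(5.0, 2.0, np.ones(100), alpha=0.5)
        assert lo == pytest.approx(3.0) and hi == pytest.approx(3.0)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            confidence_interval(0.0, 1.0, [0.1, 0.2], alpha=0.05)

    def test_bad_alpha_or_se_rejected(self):
        with pytest.raises(ValueError):
            confidence_interval(0.0, 1.0, np.zeros(100), alpha=0.0)
        with pytest.raises(ValueError):
            confidence_interval(0.0, 0.0, np.zeros(100), alpha=0.5)


class TestMonteCarloPivotal:
    def test_constant_estimator_gives_zero_pivotals(self, rng):
        spec = PivotalSpec(
            name="const",
            estimate=lambda z: Estimate(theta=3.0, se=1.0),
            target_builder=lambda e: ParametricTarget(stats.norm(0, 1)),
        )
        plan = PerturbationPlan(noise=make_noise_model("laplace", 1.0), seed=2)
        draws = monte_carlo_pivotal(rng.normal(size=20), spec, D=50, plan=plan)
        np.testing.assert_array_equal(draws.t_star, np.zeros(50))

    def test_normal_mean_t_quantile(self, rng):
        z = rng.normal(size=5)
        plan = PerturbationPlan(noise=make_noise_model("laplace", 100.0), seed=21)
        draws = monte_carlo_pivotal(z, normal_mean_spec(), D=20000, plan=plan)
        q = np.quantile(draws.t_star, 0.975)
        assert abs(q - stats.t(4).ppf(0.975)) < 0.08  # MC error at D = 2e4

    def test_draws_are_independent_across_d(self, rng):
        z = rng.normal(size=10)
        plan = PerturbationPlan(noise=make_noise_model("laplace", 1.0), seed=3)
        d = monte_carlo_pivotal(z, normal_mean_spec(), D=4000, plan=plan)
        r = np.corrcoef(d.theta_star[:-1], d.theta_star[1:])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(d.theta_star.size)

    def test_failed_estimator_draws_topped_up(self, rng):
        calls = {"i": 0}

        def flaky(z):
            calls["i"] += 1
            if calls["i"] % 5 == 0:
                return Estimate(theta=np.nan, se=np.nan)
            return Estimate(theta=float(np.mean(z)), se=1.0)

        spec = PivotalSpec(name="flaky", estimate=flaky,
                           target_builder=lambda e: ParametricTarget(stats.norm(0, 1)))
        plan = PerturbationPlan(noise=make_noise_model("laplace", 1.0), seed=4)
        draws = monte_carlo_pivotal(rng.normal(size=10), spec, D=100, plan=plan)
        assert draws.t_star.size == 100
        assert draws.n_failed > 0


def _brute_force_best_subset(X, y, K, exclude):
    n, p = X.shape
    others = [j for j in range(p) if j != exclude]
    best = np.inf
    for k in range(K + 1):
        for S in combinations(others, k):
            cols = sorted(S + ((exclude,) if exclude is not None else ()))
            if not cols:
                best = min(best, 0.5 * float(y @ y))
                continue
            b, *_ = np.linalg.lstsq(X[:, cols], y, rcond=None)
            r = y - X[:, cols] @ b
            best = min(best, 0.5 * float(r @ r))
    return best


class TestTLPRegression:
    def test_orthonormal_noiseless_exact_recovery(self):
        X = np.eye(3)
        y = np.array([5.0, 0.0, 0.0])
        fit = tlp_regression(X, y, K=1, exclude=0)
        np.testing.assert_allclose(fit.beta, [5.0, 0.0, 0.0], atol=1e-10)

    def test_matches_exhaustive_subset_search(self):
        for i in range(20):
            rng = np.random.default_rng(300 + i)
            p = int(rng.integers(5, 11))
            K = int(rng.integers(1, 4))
            l = int(rng.integers(0, p))
            X = rng.standard_normal((20, p))
            beta = np.zeros(p)
            beta[rng.choice(p, 3, replace=False)] = rng.normal(0, 2, 3)
            y = X @ beta + rng.normal(0, 0.5, 20)
            fit = tlp_regression(X, y, K=K, exclude=l)
            assert fit.objective == pytest.approx(
                _brute_force_best_subset(X, y, K, l), abs=1e-6)

    def test_objective_path_non_increasing(self, rng):
        X = rng.standard_normal((60, 20))
        beta = np.zeros(20)
        beta[:4] = [2.0, -1.5, 1.0, 0.5]
        y = X @ beta + rng.normal(0, 1.0, 60)
        fit = tlp_regression(X, y, K=4, exclude=0)
        path = np.asarray(fit.objective_path)
        assert np.all(np.diff(path) <= 1e-10)

    def test_active_set_respects_constraint(self, rng):
        X = rng.standard_normal((50, 15))
        y = X[:, :5] @ np.ones(5) + rng.normal(0, 1, 50)
        fit = tlp_regression(X, y, K=3, exclude=7)
        assert fit.active.size <= 3
        assert 7 not in fit.active  # exclude is reported separately
        assert fit.beta[7] != 0.0

    def test_se_positive_and_finite(self, rng):
        X = rng.standard_normal((80, 10))
        y = X[:, 0] * 2 + rng.normal(0, 1, 80)
        fit = tlp_regression(X, y, K=2, exclude=0)
        assert np.isfinite(fit.se) and fit.se > 0

    def test_invalid_k_rejected(self, rng):
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        with pytest.raises(ValueError):
            tlp_regression(X, y, K=0, exclude=1)
        with pytest.raises(ValueError):
            tlp_regression(X, y, K=5, exclude=1)

    def test_cv_choice_recovers_sparsity_order(self, rng):
        beta = np.zeros(10)
        beta[:3] = 1.0
        cfg = RegressionSimConfig(n=150, p=10, beta=beta, sigma=0.3, rho=0.3, seed=5)
        X, y, _ = gen_highdim_regression(cfg)
        k = choose_k_cv(X, y, exclude=5, seed=0)
        assert 2 <= k <= 5  # truth needs 3 penalized signals


@pytest.fixture(scope="module")
def sim():
    beta = np.zeros(20)
    beta[:3] = 1.0
    cfg = RegressionSimConfig(n=160, p=20, beta=beta, sigma=0.5, rho=0.5, seed=31)
    X, y, _ = gen_highdim_regression(cfg)
    return X, y


class TestFlushCIRegression:
    def test_interval_contains_strong_signal(self, sim):
        X, y = sim
        res = flush_ci_for_regression(X[:80], y[:80], 0, D=300, seed=9,
                                      holdout=(X[80:], y[80:]))
        lo, hi = res.ci
        assert lo < 1.0 < hi
        assert res.D == 300 and res.t_star.size == 300

    def test_deterministic_under_fixed_seed(self, sim):
        X, y = sim
        a = flush_ci_for_regression(X, y, 1, D=200, seed=17)
        b = flush_ci_for_regression(X, y, 1, D=200, seed=17)
        assert a.ci == b.ci and a.theta_hat == b.theta_hat and a.B == b.B

    def test_near_noiseless_interval_shrinks_onto_truth(self):
        beta = np.zeros(8)
        beta[:2] = [1.0, -2.0]
        cfg = RegressionSimConfig(n=120, p=8, beta=beta, sigma=1e-4, rho=0.0, seed=3)
        X, y, _ = gen_highdim_regression(cfg)
        res = flush_ci_for_regression(X, y, 0, D=200, seed=5)
        lo, hi = res.ci
        assert lo < 1.0 < hi
        assert hi - lo < 0.01

    def test_bias_relation_holds(self, sim):
        X, y = sim
        res = flush_ci_for_regression(X, y, 2, D=200, seed=23)
        assert res.B == pytest.approx(res.theta_star.mean() - res.theta_hat)
        assert res.theta_c == pytest.approx(res.theta_hat + res.B)
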
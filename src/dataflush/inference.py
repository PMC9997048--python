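"""Monte-Carlo pivotal inference on perturbed copies of the data.

Given an estimator θ̂ and a studentized pivot ``T = (θ̂ - θ)/se``, the
procedure is:

Step 1
    Generate D independent perturbed samples whose records follow the
    plug-in target ``R = F(θ)|θ=θ̂``, re-apply the estimator to each, and
    form the perturbed pivotals ``T*_d = (θ̂*_d - θ̂)/se*_d``.  Because
    each perturbed sample is an exact i.i.d. draw from R, the conditional
    law of T* given the data equals the law of T — so the empirical T*
    distribution can stand in for the unknown pivotal distribution.
Step 2
    Bias estimate ``B̂ = D⁻¹ Σ (θ̂*_d - θ̂)`` and corrected estimate
    ``θ̂c = θ̂ + B̂``.
Step 3
    Invert the pivot at the empirical α/2 and 1-α/2 quantiles of T*:
    ``[θ̂c - q_hi·se, θ̂c - q_lo·se]``.

Two estimators are wired in: the normal-mean t pivotal (whose T* is exactly
t_{n-1}) and the TLP-constrained high-dimensional regression coefficient
with residual perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import stats

from ._rng import named_rng
from .distributions import ParametricTarget, TargetDistribution, make_noise_model
from .perturb import PerturbationPlan, perturb_residuals, perturb_univariate
from .tlp import TLPFit, TLPWorkspace, choose_k_cv, tlp_regression  # noqa: F401 (re-export)

__all__ = [
    "Estimate",
    "PivotalSpec",
    "PivotalDraws",
    "InferenceResult",
    "normal_mean_spec",
    "monte_carlo_pivotal",
    "bias_correct",
    "confidence_interval",
    "flush_ci_for_regression",
    "flush_cis_for_regression",
    "tlp_regression",
    "choose_k_cv",
]


@dataclass
class Estimate:
    theta: float
    se: float | None = None


@dataclass
class PivotalSpec:
    """Estimator + plug-in target builder for a studentized location pivot.

    ``estimate`` maps a sample to an :class:`Estimate`; ``target_builder``
    maps that estimate to the target distribution ``F(θ̂)`` the perturbed
    records must follow.  ``batch_estimate``, if given, maps an (n, D)
    block of perturbed samples to vectors of θ̂* and se* in one shot.
    """

    name: str
    estimate: Callable[[np.ndarray], Estimate]
    target_builder: Callable[[Estimate], TargetDistribution]
    batch_estimate: Callable[[np.ndarray], tuple] | None = None


def normal_mean_spec() -> PivotalSpec:
    """Normal-mean t pivotal: θ̂ = Ȳ, se = S/√n, plug-in target N(Ȳ, S²)."""

    def estimate(z: np.ndarray) -> Estimate:
        z = np.asarray(z, dtype=float).ravel()
        s = float(z.std(ddof=1))
        est = Estimate(theta=float(z.mean()), se=s / np.sqrt(z.size))
        est.scale = s  # sample SD, needed by the plug-in target
        return est

    def build(est: Estimate) -> TargetDistribution:
        return ParametricTarget(stats.norm(est.theta, est.scale), name="normal-plugin")

    def batch(vals: np.ndarray):
        n = vals.shape[0]
        return vals.mean(axis=0), vals.std(axis=0, ddof=1) / np.sqrt(n)

    return PivotalSpec(name="mean-t", estimate=estimate, target_builder=build,
                       batch_estimate=batch)


@dataclass
class PivotalDraws:
    t_star: np.ndarray
    theta_star: np.ndarray
    theta_hat: Estimate
    n_failed: int = 0


def monte_carlo_pivotal(
    sample, spec: PivotalSpec, D: int, plan: PerturbationPlan
) -> PivotalDraws:
    """Step 1: D independent perturbed samples and their pivotal values.

    Each perturbed sample is generated with its own fresh rank-coupled
    uniforms (independence across d), records following ``F(θ̂)``.
    Estimator failures (non-finite θ̂* or se*) are dropped and the draw
    count topped back up; the dropped count is reported.
    """
    if D < 2:
        raise ValueError("D must be at least 2")
    sample = np.asarray(sample, dtype=float).ravel()
    est = spec.estimate(sample)
    target = spec.target_builder(est)

    thetas, ses = [], []
    n_failed = 0
    need = D
    for round_ in range(6):
        if need <= 0:
            break
        block_plan = replace(plan, m=need, share_uniforms=False,
                             seed=None if plan.seed is None else plan.seed + 7919 * round_)
        vals = perturb_univariate(sample, target, block_plan).univariate()
        if spec.batch_estimate is not None:
            th, se = spec.batch_estimate(vals)
            th, se = np.asarray(th, float), np.asarray(se, float)
        else:
            th = np.empty(need)
            se = np.empty(need)
            for d in range(need):
                try:
                    e = spec.estimate(vals[:, d])
                    th[d], se[d] = e.theta, e.se
                except Exception:
                    th[d] = se[d] = np.nan
        ok = np.isfinite(th) & np.isfinite(se) & (se > 0)
        n_failed += int(need - ok.sum())
        thetas.append(th[ok])
        ses.append(se[ok])
        need = D - sum(a.size for a in thetas)
    theta_star = np.concatenate(thetas)[:D]
    se_star = np.concatenate(ses)[:D]
    if theta_star.size < D:
        raise RuntimeError(f"estimator failed too often: {theta_star.size}/{D} draws")
    t_star = (theta_star - est.theta) / se_star
    return PivotalDraws(t_star=t_star, theta_star=theta_star, theta_hat=est, n_failed=n_failed)


def bias_correct(theta_hat: float, theta_star_draws, sign: str = "additive"):
    """Step 2: ``B̂ = mean(θ̂*) - θ̂`` and the corrected estimate.

    The default convention adds the bias estimate (``θ̂c = θ̂ + B̂``, i.e.
    θ̂c equals the mean of the perturbed estimates); ``sign="classical"``
    subtracts it instead.
    """
    draws = np.asarray(theta_star_draws, dtype=float).ravel()
    if draws.size == 0:
        raise ValueError("need at least one perturbed estimate")
    B = float(draws.mean() - theta_hat)
    if sign == "additive":
        theta_c = theta_hat + B
    elif sign == "classical":
        theta_c = theta_hat - B
    else:
        raise ValueError("sign must be 'additive' or 'classical'")
    return B, float(theta_c)


def confidence_interval(theta_c: float, se: float, t_star_draws, alpha: float):
    """Step 3: invert ``T = (θ̂ - θ)/se`` at empirical T* quantiles.

    Returns ``[θ̂c - q_hi·se, θ̂c - q_lo·se]`` with q the α/2 and 1-α/2
    empirical quantiles (linear interpolation).
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    if not (se > 0):
        raise ValueError("se must be positive")
    t = np.asarray(t_star_draws, dtype=float).ravel()
    if t.size < max(2, int(np.ceil(2.0 / alpha))):
        raise ValueError(f"too few draws ({t.size}) for alpha={alpha}")
    q_lo, q_hi = np.quantile(t, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(theta_c - q_hi * se), float(theta_c - q_lo * se)


@dataclass
class InferenceResult:
    theta_hat: float
    se: float
    B: float
    theta_c: float
    ci: tuple
    alpha: float
    D: int
    t_star: np.ndarray = field(repr=False, default=None)
    theta_star: np.ndarray = field(repr=False, default=None)
    n_failed: int = 0
    meta: dict = field(default_factory=dict)

    def to_dict(self, draws: bool = False) -> dict:
        d = {
            "theta_hat": self.theta_hat,
            "se": self.se,
            "bias_estimate": self.B,
            "theta_corrected": self.theta_c,
            "ci": [self.ci[0], self.ci[1]],
            "alpha": self.alpha,
            "D": self.D,
            "n_failed_draws": self.n_failed,
            "t_star_quantiles": {
                q: float(np.quantile(self.t_star, float(q)))
                for q in ("0.025", "0.25", "0.5", "0.75", "0.975")
            }
            if self.t_star is not None
            else None,
            **self.meta,
        }
        if draws and self.t_star is not None:
            d["t_star"] = [float(v) for v in self.t_star]
        return d


# ---------------------------------------------------------------------------
# Regression CI pipeline
# ---------------------------------------------------------------------------


def _holdout_mu_sigma(Xh: np.ndarray, yh: np.ndarray, tau: float | None,
                      seed: int | None):
    """Fit μ̂ and σ̂² on the holdout with the sparse constrained estimator.

    Using the same selection methodology as the inference fit keeps μ̂
    sparse, so coefficients absent from the holdout model contribute no
    holdout noise to the perturbed copies (a full OLS μ̂ would leak its
    per-coordinate estimation error into every copy and widen the spread of
    the corrected estimate beyond what the pivotal draws reflect).
    """
    n, p = Xh.shape
    k_mu = choose_k_cv(Xh, yh, exclude=None, tau=tau,
                       seed=None if seed is None else seed + 101)
    fit = TLPWorkspace(Xh, K=k_mu, tau=tau, exclude=None, refine=False).fit(yh)
    return fit.beta, fit.sigma2


def flush_cis_for_regression(
    X,
    y,
    coefs,
    D: int = 1000,
    epsilon: float = 0.01,
    alpha: float = 0.05,
    K: int | None = None,
    tau: float | None = None,
    seed: int | None = None,
    holdout: tuple | None = None,
    holdout_fraction: float = 0.5,
    sign: str = "additive",
) -> dict:
    """Confidence intervals for several coefficients sharing perturbed copies.

    The holdout supplies μ̂ and σ̂²; the residuals of the inference sample
    are perturbed D times with Laplace(0, 1/ε) noise toward the target
    N(0, σ̂²); the TLP regression (coordinate l unpenalized) is refit on
    every copy; Steps 1-3 yield one interval per requested coefficient
    (0-based indices).
    """
    if D < 100:
        raise ValueError("D must be at least 100")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape

    if holdout is not None:
        Xh, yh = np.asarray(holdout[0], float), np.asarray(holdout[1], float).ravel()
        Xi, yi = X, y
    else:
        rng = named_rng(seed, "holdout-split")
        n_hold = int(round(holdout_fraction * n))
        if n_hold < 2 or n - n_hold < 2:
            raise ValueError("too few rows to split into holdout and inference parts")
        perm = rng.permutation(n)
        hi, ii = perm[:n_hold], perm[n_hold:]
        Xh, yh, Xi, yi = X[hi], y[hi], X[ii], y[ii]

    beta_h, sigma2 = _holdout_mu_sigma(Xh, yh, tau, seed)
    mu = Xi @ beta_h

    plan = PerturbationPlan(
        noise=make_noise_model("laplace", 1.0 / epsilon),
        m=D,
        seed=seed,
        share_uniforms=False,
    )
    y_star = perturb_residuals(yi, mu, sigma2, plan)  # (n_i, D)

    results = {}
    for l in coefs:
        k_l = K if K is not None else choose_k_cv(Xh, yh, exclude=l, tau=tau,
                                                  seed=None if seed is None else seed + l)
        ws = TLPWorkspace(Xi, K=k_l, tau=tau, exclude=l, refine=False)
        fit0 = ws.fit(yi)
        theta_hat, se_hat = float(fit0.beta[l]), fit0.se
        th = np.empty(D)
        se = np.empty(D)
        XtY = Xi.T @ y_star  # (p, D)
        yy = np.einsum("id,id->d", y_star, y_star)
        for d in range(D):
            f = ws.fit_gram(XtY[:, d], float(yy[d]))
            th[d], se[d] = f.beta[l], f.se if f.se is not None else np.nan
        ok = np.isfinite(th) & np.isfinite(se) & (se > 0)
        n_failed = int(D - ok.sum())
        t_star = (th[ok] - theta_hat) / se[ok]
        theta_star = th[ok]
        B, theta_c = bias_correct(theta_hat, theta_star, sign=sign)
        ci = confidence_interval(theta_c, se_hat, t_star, alpha)
        results[l] = InferenceResult(
            theta_hat=theta_hat,
            se=se_hat,
            B=B,
            theta_c=theta_c,
            ci=ci,
            alpha=alpha,
            D=D,
            t_star=t_star,
            theta_star=theta_star,
            n_failed=n_failed,
            meta={"coef": int(l), "K": int(k_l), "epsilon": epsilon,
                  "sigma2_holdout": sigma2, "n_inference": int(Xi.shape[0]),
                  "n_holdout": int(Xh.shape[0]), "seed": seed},
        )
    return results


def flush_ci_for_regression(X, y, l: int, D: int = 1000, epsilon: float = 0.01,
                            alpha: float = 0.05, **kwargs) -> InferenceResult:
    """Single-coefficient convenience wrapper around the shared pipeline."""
    return flush_cis_for_regression(X, y, [l], D=D, epsilon=epsilon, alpha=alpha, **kwargs)[l]
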
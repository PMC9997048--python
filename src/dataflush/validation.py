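"""Statistical audits of perturbed output.

Distribution-preservation checks (KS for numeric targets, chi-square for
discrete ones), the rank-coupling Spearman check, the pivotal-density
experiment (T* against t_{n-1}), and the coverage simulation harness for the
high-dimensional-regression confidence intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import named_rng
from .distributions import TargetDistribution, make_noise_model
from .inference import flush_cis_for_regression, monte_carlo_pivotal, normal_mean_spec
from .perturb import PerturbationPlan
from .schema import TableSchema
from .simulate import RegressionSimConfig, gen_highdim_regression

__all__ = [
    "KSResult",
    "CoverageConfig",
    "CoverageReport",
    "AuditReport",
    "ks_check",
    "chi_square_check",
    "spearman_check",
    "pivotal_density_check",
    "coverage_simulation",
    "audit_table",
]


@dataclass
class KSResult:
    statistic: float
    pvalue: float
    alpha: float
    reject: bool


def ks_check(sample, target: TargetDistribution, alpha: float = 0.05) -> KSResult:
    """One-sample Kolmogorov test of a sample against a target CDF."""
    sample = np.asarray(sample, dtype=float).ravel()
    if sample.size < 10:
        raise ValueError("need at least 10 observations for a KS check")
    if np.unique(sample).size == 1 and target.support == "continuous":
        # degenerate sample against a continuous target: statistic >= 1/2
        stat = max(target.cdf(sample[0]), 1.0 - target.cdf(sample[0]))
        return KSResult(statistic=float(stat), pvalue=0.0, alpha=alpha, reject=True)
    res = stats.kstest(sample, target.cdf)
    return KSResult(statistic=float(res.statistic), pvalue=float(res.pvalue),
                    alpha=alpha, reject=bool(res.pvalue < alpha))


def chi_square_check(sample, target: TargetDistribution, alpha: float = 0.05) -> KSResult:
    """Chi-square goodness of fit of discrete draws against target probs."""
    sample = np.asarray(sample, dtype=float).ravel()
    codes = np.asarray(target.codes, dtype=float)
    counts = np.array([(sample == c).sum() for c in codes], dtype=float)
    expected = np.asarray(target.probs, dtype=float) * sample.size
    keep = expected > 0
    res = stats.chisquare(counts[keep], expected[keep])
    return KSResult(statistic=float(res.statistic), pvalue=float(res.pvalue),
                    alpha=alpha, reject=bool(res.pvalue < alpha))


def spearman_check(raw, perturbed) -> float:
    """Spearman rank correlation between raw and perturbed first component."""
    raw = np.asarray(raw, dtype=float).ravel()
    per = np.asarray(perturbed, dtype=float).ravel()
    if raw.size != per.size or raw.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    return float(stats.spearmanr(raw, per).statistic)


def pivotal_density_check(n: int, D: int, epsilon: float = 0.01,
                          seed: int | None = None) -> float:
    """KS distance of D perturbed-t draws against t_{n-1}.

    Runs the normal-mean experiment: one fixed standard-normal sample of
    size n, Laplace(0, 1/ε) noise, plug-in target N(Ȳ, S²).
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = named_rng(seed, "pivotal-sample")
    z = rng.normal(size=n)
    plan = PerturbationPlan(noise=make_noise_model("laplace", 1.0 / epsilon),
                            seed=None if seed is None else seed + 1)
    draws = monte_carlo_pivotal(z, normal_mean_spec(), D=D, plan=plan)
    return float(stats.kstest(draws.t_star, stats.t(df=n - 1).cdf).statistic)


# ---------------------------------------------------------------------------
# Coverage simulation
# ---------------------------------------------------------------------------


@dataclass
class CoverageConfig:
    """Replicated-CI experiment on the sparse-regression simulation."""

    p: int = 50
    n: int = 100
    D: int = 1000
    reps: int = 500
    coefs: tuple = (0,)  # 0-based coefficient indices
    epsilon: float = 0.01
    alpha: float = 0.05
    sigma: float = 0.5
    rho: float = 0.5
    beta_nonzero: tuple = (1.0, 1.0, 1.0)  # leading true coefficients
    K: int | None = None
    seed: int | None = None
    scale: float = 1.0  # single desk-scale factor applied to reps and D

    def true_beta(self) -> np.ndarray:
        b = np.zeros(self.p)
        b[: len(self.beta_nonzero)] = self.beta_nonzero
        return b

    @property
    def eff_reps(self) -> int:
        return max(int(round(self.reps * self.scale)), 1)

    @property
    def eff_D(self) -> int:
        return max(int(round(self.D * self.scale)), 100)


@dataclass
class CoverageReport:
    config: dict
    coverage: dict  # coef -> percent of replications whose CI contains truth
    mean_width: dict
    reps: int
    mc_se: dict = field(default_factory=dict)  # binomial Monte-Carlo SE, in points

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"config": self.config, "reps": self.reps, "coverage_percent": self.coverage,
             "mc_se_points": self.mc_se, "mean_ci_width": self.mean_width},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "CoverageReport":
        d = json.loads(text)
        return cls(config=d["config"], coverage=d["coverage_percent"],
                   mean_width=d["mean_ci_width"], reps=d["reps"],
                   mc_se=d.get("mc_se_points", {}))


def coverage_simulation(config: CoverageConfig, progress=None) -> CoverageReport:
    """Empirical coverage of the Monte-Carlo pivotal CIs over replications.

    Each replication simulates a fresh inference sample and an independent
    holdout of the same size from the same design, constructs the interval
    for every requested coefficient, and records containment of the truth.
    """
    beta = config.true_beta()
    hits = {l: 0 for l in config.coefs}
    widths = {l: 0.0 for l in config.coefs}
    reps, D = config.eff_reps, config.eff_D
    base_seed = 0 if config.seed is None else int(config.seed)
    for r in range(reps):
        rep_seed = (base_seed + 1_000_003 * (r + 1)) % (2**31 - 1)
        sim = RegressionSimConfig(n=2 * config.n, p=config.p, beta=beta,
                                  sigma=config.sigma, rho=config.rho, seed=rep_seed)
        X, y, _ = gen_highdim_regression(sim)
        Xi, yi = X[: config.n], y[: config.n]
        Xh, yh = X[config.n:], y[config.n:]
        results = flush_cis_for_regression(
            Xi, yi, list(config.coefs), D=D, epsilon=config.epsilon,
            alpha=config.alpha, K=config.K, seed=rep_seed + 1, holdout=(Xh, yh),
        )
        for l, res in results.items():
            lo, hi = res.ci
            if lo <= beta[l] <= hi:
                hits[l] += 1
            widths[l] += hi - lo
        if progress is not None:
            progress(r + 1, reps)
    coverage = {str(l): 100.0 * hits[l] / reps for l in config.coefs}
    mc_se = {
        str(l): 100.0 * float(np.sqrt(max(c := hits[l] / reps, 1e-12) * (1 - c) / reps))
        for l in config.coefs
    }
    mean_width = {str(l): widths[l] / reps for l in config.coefs}
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()}
    cfg["eff_reps"], cfg["eff_D"] = reps, D
    return CoverageReport(config=cfg, coverage=coverage, mean_width=mean_width,
                          reps=reps, mc_se=mc_se)


# ---------------------------------------------------------------------------
# Table audit
# ---------------------------------------------------------------------------


@dataclass
class AuditReport:
    per_variable: dict
    spearman_first: float | None
    summary: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"per_variable": self.per_variable, "spearman_first_component": self.spearman_first,
             "summary": self.summary},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def audit_table(raw: pd.DataFrame, perturbed: pd.DataFrame, schema: TableSchema,
                alpha: float = 0.05) -> AuditReport:
    """Before/after comparison of marginals, column by column.

    Numeric columns get a two-sample KS statistic, discrete columns a
    chi-square against the raw (release-part) category frequencies; the
    first schema variable additionally gets the Spearman identifier check
    when row counts match.
    """
    per = {}
    names = [nm for nm in schema.variable_names if nm in perturbed.columns]
    for nm in names:
        spec = schema[nm]
        if spec.is_discrete:
            raw_codes = spec.codes(raw[nm]).to_numpy()
            per_codes = spec.codes(perturbed[nm]).to_numpy()
            levels = np.unique(np.concatenate([raw_codes, per_codes]))
            obs = np.array([(per_codes == c).sum() for c in levels], dtype=float)
            exp = np.array([(raw_codes == c).sum() for c in levels], dtype=float)
            exp = exp / exp.sum() * obs.sum()
            keep = exp > 0
            res = stats.chisquare(obs[keep], exp[keep])
            per[nm] = {"test": "chi-square", "statistic": float(res.statistic),
                       "pvalue": float(res.pvalue), "reject": bool(res.pvalue < alpha)}
        else:
            res = stats.ks_2samp(raw[nm].to_numpy(float), perturbed[nm].to_numpy(float))
            per[nm] = {"test": "ks-2sample", "statistic": float(res.statistic),
                       "pvalue": float(res.pvalue), "reject": bool(res.pvalue < alpha)}
    first = names[0] if names else None
    rho = None
    if first is not None and len(raw) == len(perturbed):
        spec = schema[first]
        a = spec.codes(raw[first]) if spec.is_discrete else raw[first]
        b = spec.codes(perturbed[first]) if spec.is_discrete else perturbed[first]
        rho = spearman_check(a.to_numpy(float), b.to_numpy(float))
    summary = {}
    for nm in names:
        if not schema[nm].is_discrete:
            summary[nm] = {
                "raw_mean": float(raw[nm].mean()), "raw_sd": float(raw[nm].std()),
                "perturbed_mean": float(perturbed[nm].mean()),
                "perturbed_sd": float(perturbed[nm].std()),
            }
    return AuditReport(per_variable=per, spearman_first=rho, summary=summary)
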
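"""Seeded synthetic-data generators used throughout the package and tests.

Three families: the sparse high-dimensional regression with AR(1) predictor
correlation, a Poisson GLM with configurable covariate dispersion, and
mixed-type weighted survey microdata shaped like a census extract (16
demographic covariates plus an income response and a person weight).
All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, toeplitz

from ._rng import named_rng
from .schema import ColumnSpec, TableSchema

__all__ = [
    "RegressionSimConfig",
    "gen_highdim_regression",
    "gen_poisson_glm",
    "gen_survey_microdata",
    "survey_schema",
]


@dataclass
class RegressionSimConfig:
    """y = Xβ + N(0, σ²) with X rows i.i.d. N(0, Σ), Σ_jk = ρ^|j-k|."""

    n: int
    p: int
    beta: np.ndarray
    sigma: float = 0.5
    rho: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.size != self.p:
            raise ValueError("beta must have length p")
        if not (abs(self.rho) < 1):
            raise ValueError("|rho| must be < 1")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


def gen_highdim_regression(config: RegressionSimConfig):
    """Simulate the sparse linear model; returns (X, y, truth dict)."""
    rng = named_rng(config.seed, "regression-sim")
    cov = toeplitz(config.rho ** np.arange(config.p))
    L = cholesky(cov, lower=True)
    X = rng.standard_normal((config.n, config.p)) @ L.T
    y = X @ config.beta + rng.normal(0.0, config.sigma, config.n)
    truth = {"beta": config.beta.copy(), "sigma": config.sigma, "rho": config.rho}
    return X, y, truth


def gen_poisson_glm(n: int, p: int, beta, covariate_sd: float = 1.0,
                    seed: int | None = None, max_eta: float = 20.0):
    """Poisson counts with log link: counts ~ Poisson(exp(X_std β)).

    Covariates are drawn with the configured dispersion and standardized
    inside the linear predictor (equivalently, β is scaled inversely with
    the covariate SD), so large-dispersion settings stay numerically sound
    while the comparison across dispersion levels remains interpretable.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.size != p:
        raise ValueError("beta must have length p")
    rng = named_rng(seed, "poisson-sim")
    X = rng.normal(0.0, covariate_sd, size=(n, p))
    eta = (X / covariate_sd) @ beta
    if np.any(np.abs(eta) > max_eta):
        eta = np.clip(eta, -max_eta, max_eta)
    counts = rng.poisson(np.exp(eta))
    return X, counts


# ---------------------------------------------------------------------------
# Survey microdata
# ---------------------------------------------------------------------------

_NOMINAL_LEVELS = {
    "region": [f"R{i}" for i in range(1, 10)],        # 9 levels
    "metro": [f"M{i}" for i in range(1, 6)],          # 5
    "mortgage": ["own", "mortgaged", "rent"],          # 3
    "marital": [f"S{i}" for i in range(1, 7)],        # 6
    "race": [f"G{i}" for i in range(1, 7)],           # 6
    "english": ["none", "some", "fluent"],             # 3
    "education": [f"E{i}" for i in range(1, 8)],      # 7
    "employment": ["employed", "unemployed", "nonlabor"],  # 3
    "occupation": [f"O{i}" for i in range(1, 14)],    # 13
    "migration": ["house", "state", "abroad"],         # 3
}


def survey_schema() -> TableSchema:
    """Schema for the synthetic survey table: 17 variables plus a weight.

    Mirrors the layout of a census-style person extract — age first (the
    identifier variable for rank coupling), 15 further demographic
    covariates, a continuous income response, and an integer person weight.
    """
    cols = [
        ColumnSpec("age", "empirical"),
        ColumnSpec("region", "nominal", levels=_NOMINAL_LEVELS["region"]),
        ColumnSpec("log_metro_pop", "empirical"),
        ColumnSpec("metro", "nominal", levels=_NOMINAL_LEVELS["metro"]),
        ColumnSpec("mortgage", "nominal", levels=_NOMINAL_LEVELS["mortgage"]),
        ColumnSpec("sex", "binary"),
        ColumnSpec("marital", "nominal", levels=_NOMINAL_LEVELS["marital"]),
        ColumnSpec("race", "nominal", levels=_NOMINAL_LEVELS["race"]),
        ColumnSpec("hispanic", "binary"),
        ColumnSpec("english", "nominal", levels=_NOMINAL_LEVELS["english"]),
        ColumnSpec("insured", "binary"),
        ColumnSpec("education", "nominal", levels=_NOMINAL_LEVELS["education"]),
        ColumnSpec("employment", "nominal", levels=_NOMINAL_LEVELS["employment"]),
        ColumnSpec("occupation", "nominal", levels=_NOMINAL_LEVELS["occupation"]),
        ColumnSpec("migration", "nominal", levels=_NOMINAL_LEVELS["migration"]),
        ColumnSpec("veteran", "binary"),
        ColumnSpec("income", "continuous"),
        ColumnSpec("perwt", "continuous", weight_column=True),
    ]
    return TableSchema(cols)


def _softmax_draw(rng, logits):
    z = logits - logits.max(axis=1, keepdims=True)
    probs = np.exp(z)
    probs /= probs.sum(axis=1, keepdims=True)
    cum = probs.cumsum(axis=1)
    u = rng.uniform(size=(logits.shape[0], 1))
    return (cum >= u).argmax(axis=1)


def gen_survey_microdata(n: int, seed: int | None = None,
                         schema: TableSchema | None = None):
    """Generate weighted mixed-type survey microdata with planted dependence.

    Planted structure: insurance coverage depends logistically on age
    (log-odds slope 0.04 per year around age 50); income is log-normal with
    mean increasing in education and age; employment status depends on age;
    weights are positive integers.  Returns (DataFrame, TableSchema).
    """
    if n < 50:
        raise ValueError("n must be at least 50 for a plausible survey table")
    sch = schema if schema is not None else survey_schema()
    rng = named_rng(seed, "survey-sim")

    age = np.round(np.clip(rng.normal(50, 19, n), 18, 95)).astype(int)
    age_c = (age - 50.0) / 10.0

    def nominal(name, logits=None):
        k = len(_NOMINAL_LEVELS[name])
        if logits is None:
            logits = np.tile(rng.normal(0, 0.5, k), (n, 1))
        return np.asarray(_NOMINAL_LEVELS[name])[_softmax_draw(rng, logits)]

    region = nominal("region")
    log_metro_pop = np.round(rng.normal(13.0, 1.5, n) + 0.1 * (region == "R1"), 3)
    metro = nominal("metro")
    mortgage = nominal("mortgage")
    sex = rng.binomial(1, 0.5, n)
    marital = nominal("marital")
    race = nominal("race")
    hispanic = rng.binomial(1, 0.12, n)
    english = nominal("english")
    insured = rng.binomial(1, 1.0 / (1.0 + np.exp(-(2.3 + 0.4 * age_c))))
    edu_logits = np.tile(np.linspace(-0.6, 0.6, 7), (n, 1)) + 0.1 * age_c[:, None]
    education = np.asarray(_NOMINAL_LEVELS["education"])[_softmax_draw(rng, edu_logits)]
    edu_rank = np.array([int(e[1]) for e in education], dtype=float)
    emp_logits = np.column_stack([
        1.2 - 0.5 * np.abs(age_c), -0.8 * np.ones(n), -0.2 + 0.45 * np.abs(age_c)
    ])
    employment = np.asarray(_NOMINAL_LEVELS["employment"])[_softmax_draw(rng, emp_logits)]
    occupation = nominal("occupation")
    migration = nominal("migration")
    veteran = rng.binomial(1, 0.08, n)
    log_income = (9.5 + 0.25 * edu_rank + 0.15 * age_c - 0.08 * age_c**2
                  + 0.3 * (employment == "employed") + rng.normal(0, 0.7, n))
    income = np.round(np.exp(log_income), 2)
    perwt = rng.integers(1, 31, n)

    df = pd.DataFrame({
        "age": age, "region": region, "log_metro_pop": log_metro_pop, "metro": metro,
        "mortgage": mortgage, "sex": sex, "marital": marital, "race": race,
        "hispanic": hispanic, "english": english, "insured": insured,
        "education": education, "employment": employment, "occupation": occupation,
        "migration": migration, "veteran": veteran, "income": income, "perwt": perwt,
    })
    return df, sch
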
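"""Rank-coupled perturbation, the chain-rule multivariate scheme, and ε-DP.

The univariate scheme draws i.i.d. ``Uniform[0,1]`` values, relabels them so
their ranks match the raw sample's ranks, adds independent noise ``e`` and
maps through ``H = R⁻¹(G(·))``.  The multivariate scheme applies the same map
per variable through the probability chain rule: the first variable keeps the
rank coupling (the raw data's identifier), later variables use fresh
uniforms and conditional targets built from the already-perturbed prefix of
the same record.  The ε-DP mode splits the privacy budget equally over the
``p`` variables — Laplace noise of scale ``p/ε`` per variable — and enforces
the holdout discipline: targets are fitted on a fixed, never-released random
subset of the raw data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import named_rng
from .distributions import (
    ConditionalChainModel,
    NoiseModel,
    ParametricTarget,
    TargetDistribution,
    convolve_uniform_noise,
    fit_conditional_chain,
    make_noise_model,
)
from .schema import TableSchema

__all__ = [
    "RankCoupling",
    "PerturbationPlan",
    "PrivacyBudget",
    "PerturbedData",
    "HoldoutLedger",
    "HoldoutViolationError",
    "rank_matched_uniforms",
    "perturb_univariate",
    "perturb_multivariate",
    "perturb_residuals",
    "privatize",
]


# ---------------------------------------------------------------------------
# Rank coupling
# ---------------------------------------------------------------------------


@dataclass
class RankCoupling:
    """Uniforms relabeled to carry the raw sample's ranks.

    ``uniforms[i]`` has the same rank among the uniforms as ``z[i]`` has in
    the raw sample; marginally the uniforms are an i.i.d. Uniform[0,1]
    sample.  ``order`` is the permutation sorting the raw sample (ties
    broken by a seeded random permutation).
    """

    uniforms: np.ndarray
    order: np.ndarray
    seed: int | None = None


def _sort_order(z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    tie_break = rng.permutation(z.size)
    return np.lexsort((tie_break, z))


def rank_matched_uniforms(z, rng_seed=None) -> RankCoupling:
    """Draw i.i.d. uniforms and relabel them to match the ranks of ``z``."""
    z = np.asarray(z, dtype=float).ravel()
    if z.size == 0:
        raise ValueError("cannot rank-couple an empty sample")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    order = _sort_order(z, rng)
    u = np.empty(z.size)
    u[order] = np.sort(rng.uniform(size=z.size))
    seed = rng_seed if isinstance(rng_seed, (int, np.integer)) else None
    return RankCoupling(uniforms=u, order=order, seed=seed)


def _rank_matched_matrix(z: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """Fresh rank-matched uniforms per copy: (n, m), each column coupled."""
    order = _sort_order(z, rng)
    raw = np.sort(rng.uniform(size=(z.size, m)), axis=0)
    u = np.empty_like(raw)
    u[order, :] = raw
    return u


# ---------------------------------------------------------------------------
# Plans, budgets, containers
# ---------------------------------------------------------------------------


@dataclass
class PerturbationPlan:
    """How to perturb: noise model, copies, seed, privacy mode.

    ``share_uniforms`` controls whether the m copies reuse one rank-coupled
    uniform sample for the first component (the conditional-independence
    reading of the scheme) or draw fresh coupled uniforms per copy
    (independent perturbed samples, as Monte-Carlo inference requires).
    """

    noise: NoiseModel
    m: int = 1
    seed: int | None = None
    dp_mode: bool = False
    epsilon: float | None = None
    share_uniforms: bool = True

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be a positive integer")
        if self.dp_mode:
            if self.epsilon is None or not (self.epsilon > 0):
                raise ValueError("dp_mode requires epsilon > 0")
            if self.noise.family != "laplace":
                raise ValueError("dp_mode requires laplace noise")


@dataclass
class PrivacyBudget:
    """Equal split of a pure-ε budget over p variables (Laplace scale p/ε)."""

    epsilon: float
    p: int
    consumed: list = field(default_factory=list)

    def __post_init__(self):
        if not (self.epsilon > 0) or self.p < 1:
            raise ValueError("require epsilon > 0 and p >= 1")

    @property
    def per_variable_scale(self) -> float:
        return self.p / self.epsilon

    def consume(self, name: str) -> float:
        if len(self.consumed) >= self.p:
            raise ValueError("privacy budget exhausted: all variables consumed")
        self.consumed.append(name)
        return self.per_variable_scale

    def to_dict(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "p": self.p,
            "per_variable_scale": self.per_variable_scale,
            "consumed": list(self.consumed),
        }


@dataclass
class PerturbedData:
    """n × p × m array of perturbed values plus record identifiers.

    ``values`` holds numeric codes for discrete columns; ``frame`` decodes
    them back to the declared levels when a schema is attached.
    """

    values: np.ndarray  # (n, p, m)
    ids: np.ndarray
    columns: list
    plan: PerturbationPlan
    schema: TableSchema | None = None
    provenance: dict = field(default_factory=dict)
    noise_draws: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[2]

    def univariate(self) -> np.ndarray:
        """(n, m) view for single-variable perturbations."""
        if self.values.shape[1] != 1:
            raise ValueError("not a univariate perturbation")
        return self.values[:, 0, :]

    def frame(self, copy: int = 0) -> pd.DataFrame:
        vals = self.values[:, :, copy]
        df = pd.DataFrame(vals, columns=self.columns)
        if self.schema is not None:
            for nm in self.columns:
                spec = self.schema[nm]
                if spec.is_discrete:
                    df[nm] = spec.labels(df[nm].to_numpy().astype(int)).to_numpy()
        df.insert(0, "record_id", self.ids)
        return df

    def to_long(self) -> pd.DataFrame:
        frames = []
        for j in range(self.m):
            f = self.frame(j)
            f.insert(1, "copy", j)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Core perturbation operations
# ---------------------------------------------------------------------------


def perturb_univariate(z, target: TargetDistribution, plan: PerturbationPlan) -> PerturbedData:
    """Perturb one variable: ``Z*_ij = R⁻¹(G(U_i + e_ij))``.

    Marginally every ``Z*_ij`` follows ``target`` exactly, for any noise
    scale, because ``G(U + e)`` is uniform.
    """
    z = np.asarray(z, dtype=float).ravel()
    if z.size == 0:
        raise ValueError("empty sample")
    rng_c = named_rng(plan.seed, "coupling")
    rng_n = named_rng(plan.seed, "noise")
    G = convolve_uniform_noise(plan.noise)
    e = plan.noise.sample((z.size, plan.m), rng_n)
    if plan.share_uniforms:
        u = rank_matched_uniforms(z, rng_c).uniforms[:, None]
    else:
        u = _rank_matched_matrix(z, plan.m, rng_c)
    v = G.cdf(u + e)
    vals = np.asarray(target.quantile(v), dtype=float)
    return PerturbedData(
        values=vals[:, None, :],
        ids=np.arange(z.size),
        columns=["value"],
        plan=plan,
        provenance={"target": target.describe()},
    )


def perturb_multivariate(
    data: pd.DataFrame,
    chain: ConditionalChainModel,
    plan: PerturbationPlan,
    budget: PrivacyBudget | None = None,
) -> PerturbedData:
    """Chain-rule perturbation of a multivariate table.

    Component 1 is rank-matched as in the univariate scheme (one shared
    coupled uniform sample across the m copies); components l >= 2 draw
    fresh uniforms per copy and use the chain's conditional target given the
    already-perturbed prefix of the same record/copy.  In dp_mode every
    component's noise is Laplace with the budget's per-variable scale.
    """
    schema = chain.schema
    if schema is None:
        raise ValueError("chain carries no schema; fit it with fit_conditional_chain")
    missing = [nm for nm in chain.order if nm not in data.columns]
    if missing:
        raise ValueError(f"data lacks chain columns: {missing}")
    n, p, m = len(data), len(chain), plan.m
    if n == 0:
        raise ValueError("empty data")

    if plan.dp_mode:
        idx_hash = f"{int(pd.util.hash_pandas_object(data.index).sum()) & 0xFFFFFFFFFFFFFFFF:x}"
        if chain.fit_index_hash is not None and idx_hash == chain.fit_index_hash:
            raise HoldoutViolationError(
                "dp_mode requires the chain to be fitted on a holdout disjoint "
                "from the data being perturbed"
            )
        if budget is None:
            budget = PrivacyBudget(epsilon=plan.epsilon, p=p)

    values = np.empty((n, p, m))
    noise_log = []
    rng_c = named_rng(plan.seed, "coupling")
    rng_u = named_rng(plan.seed, "chain-uniforms")
    rng_n = named_rng(plan.seed, "noise")

    for l, nm in enumerate(chain.order):
        if plan.dp_mode:
            noise = make_noise_model("laplace", budget.consume(nm))
        else:
            noise = plan.noise
        G = convolve_uniform_noise(noise)
        e = noise.sample((n, m), rng_n)
        noise_log.append(e.ravel())
        if l == 0:
            spec = schema[nm]
            z = (spec.codes(data[nm]) if spec.is_discrete else data[nm]).to_numpy(dtype=float)
            if plan.share_uniforms:
                u = rank_matched_uniforms(z, rng_c).uniforms[:, None] * np.ones((1, m))
            else:
                u = _rank_matched_matrix(z, m, rng_c)
        else:
            u = rng_u.uniform(size=(n, m))
        v = G.cdf(u + e)
        node = chain.nodes[l]
        for j in range(m):
            if l == 0:
                values[:, 0, j] = node.quantile_given_prefix(None, v[:, j])
            else:
                values[:, l, j] = node.quantile_given_prefix(values[:, :l, j], v[:, j])

    prov = {
        "dp_mode": plan.dp_mode,
        "order": list(chain.order),
        "chain_fit_n": chain.fit_n,
    }
    if budget is not None:
        prov["budget"] = budget.to_dict()
    return PerturbedData(
        values=values,
        ids=np.asarray(data.index),
        columns=list(chain.order),
        plan=plan,
        schema=schema,
        provenance=prov,
        noise_draws=np.concatenate(noise_log),
    )


def perturb_residuals(y, fitted_means, sigma2_hat: float, plan: PerturbationPlan) -> np.ndarray:
    """Perturb regression responses: ``Y*_ij = μ̂(X_i) + ε*_ij``.

    The residuals ``y - μ̂(X)`` are rank-coupled and mapped to the target
    ``N(0, σ̂²)``; the fitted means are added back.  Returns an (n, m)
    array.  ``σ̂² = 0`` is allowed and returns the fitted means themselves.
    """
    y = np.asarray(y, dtype=float).ravel()
    mu = np.asarray(fitted_means, dtype=float).ravel()
    if y.shape != mu.shape:
        raise ValueError("y and fitted_means must have equal length")
    if sigma2_hat < 0:
        raise ValueError("sigma2_hat must be nonnegative")
    if sigma2_hat == 0:
        return np.repeat(mu[:, None], plan.m, axis=1)
    target = ParametricTarget(stats.norm(0.0, float(np.sqrt(sigma2_hat))), name="normal-residual")
    eps = perturb_univariate(y - mu, target, plan).univariate()
    return mu[:, None] + eps


# ---------------------------------------------------------------------------
# ε-DP privatization
# ---------------------------------------------------------------------------


class HoldoutViolationError(RuntimeError):
    """The fixed-once-selected holdout rule was violated."""


class HoldoutLedger:
    """Guards the "holdout is fixed once selected" rule across invocations.

    Keyed by a content hash of the dataset; re-registering the same dataset
    with a different split seed or fraction is an error.  Optionally
    persisted to JSON so the guard survives separate CLI runs.
    """

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self.entries: dict = {}
        if self.path is not None and self.path.exists():
            self.entries = json.loads(self.path.read_text())

    def register(self, content_hash: str, split_seed, holdout_fraction: float) -> None:
        rec = {"split_seed": split_seed, "holdout_fraction": holdout_fraction}
        prev = self.entries.get(content_hash)
        if prev is not None and prev != rec:
            raise HoldoutViolationError(
                f"dataset {content_hash[:12]} already privatized with a different "
                f"holdout split {prev}; the holdout is fixed once selected"
            )
        self.entries[content_hash] = rec
        if self.path is not None:
            self.path.write_text(json.dumps(self.entries, indent=2) + "\n")


def dataset_content_hash(data: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(data, index=False).values.tobytes())
    h.update(",".join(map(str, data.columns)).encode())
    return h.hexdigest()


def privatize(
    data: pd.DataFrame,
    schema: TableSchema,
    epsilon: float,
    holdout_fraction: float = 0.5,
    m: int = 1,
    seed: int | None = None,
    order: list | None = None,
    ledger: HoldoutLedger | None = None,
) -> tuple[PerturbedData, PrivacyBudget]:
    """ε-DP release: split once, fit targets on the holdout, perturb the rest.

    The raw table is split (seeded) into a holdout and a release part; the
    conditional chain is fitted on the holdout only; the release part is
    perturbed with per-variable Laplace(0, p/ε) noise.  The holdout itself
    is never emitted.
    """
    if not (epsilon > 0):
        raise ValueError("epsilon must be positive")
    if not (0 < holdout_fraction < 1):
        raise ValueError("holdout_fraction must lie in (0, 1)")
    schema.validate_frame(data)
    n = len(data)
    n_hold = int(round(holdout_fraction * n))
    if n_hold < 2 or n - n_hold < 1:
        raise ValueError("holdout too small (or release empty); provide more rows")

    content = dataset_content_hash(data)
    if ledger is not None:
        ledger.register(content, seed, holdout_fraction)

    rng = named_rng(seed, "holdout-split")
    perm = rng.permutation(n)
    hold_idx, rel_idx = np.sort(perm[:n_hold]), np.sort(perm[n_hold:])
    holdout, release = data.iloc[hold_idx], data.iloc[rel_idx]

    chain = fit_conditional_chain(holdout, schema, order=order)
    p = len(chain)
    budget = PrivacyBudget(epsilon=epsilon, p=p)
    plan = PerturbationPlan(
        noise=make_noise_model("laplace", p / epsilon),
        m=m,
        seed=seed,
        dp_mode=True,
        epsilon=epsilon,
    )
    out = perturb_multivariate(release, chain, plan, budget=budget)
    out.provenance.update(
        {
            "content_hash": content,
            "holdout_fraction": holdout_fraction,
            "n_holdout": int(n_hold),
            "n_release": int(n - n_hold),
        }
    )
    return out, budget
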
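"""Distribution machinery for distribution-preserving perturbation.

The perturbation map is ``H = R⁻¹(G(·))`` applied to ``U + e`` where
``U ~ Uniform[0,1]`` carries the raw sample's ranks, ``e`` is symmetric
zero-location noise, ``G`` is the exact CDF of ``U + e`` and ``R`` is the
target distribution the perturbed values must follow.  Because
``G(U + e) ~ Uniform[0,1]`` whenever ``U`` is uniform and independent of
``e``, the output follows ``R`` exactly for *any* noise scale — this module
supplies every piece of that pipeline:

* :class:`NoiseModel` — Laplace / Gaussian / Uniform noise ``e``;
* :class:`ConvolvedCDF` — the closed-form CDF ``G`` of ``U + e`` and its
  numerical inverse;
* :class:`TargetDistribution` and its concrete forms — parametric targets,
  the smoothed empirical CDF for tied/discrete numeric data, and discrete
  targets over a fixed integer coding for categorical data;
* :class:`ConditionalChainModel` — per-variable conditional targets
  ``R⁽ˡ⁾`` for the chain-rule multivariate scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .schema import TableSchema

__all__ = [
    "NoiseModel",
    "ConvolvedCDF",
    "TargetDistribution",
    "ParametricTarget",
    "SmoothedEmpiricalCDF",
    "DiscreteTarget",
    "ShiftedTarget",
    "ConditionalChainModel",
    "make_noise_model",
    "convolve_uniform_noise",
    "fit_smoothed_cdf",
    "fit_conditional_chain",
]

NOISE_FAMILIES = ("laplace", "gaussian", "uniform")


# ---------------------------------------------------------------------------
# Noise models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """Symmetric, zero-location additive noise.

    ``scale`` is the Laplace scale *b* for ``laplace`` (variance ``2b²``),
    the standard deviation for ``gaussian``, and the half-width *a* of
    ``Uniform[-a, a]`` for ``uniform``.
    """

    family: str
    scale: float

    def __post_init__(self):
        if self.family not in NOISE_FAMILIES:
            raise ValueError(f"unknown noise family {self.family!r}; expected {NOISE_FAMILIES}")
        if not (self.scale > 0):
            raise ValueError(f"noise scale must be positive, got {self.scale!r}")

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        b = self.scale
        if self.family == "laplace":
            return np.where(x < 0, 0.5 * np.exp(np.minimum(x, 0.0) / b),
                            1.0 - 0.5 * np.exp(-np.maximum(x, 0.0) / b))
        if self.family == "gaussian":
            return stats.norm.cdf(x / b)
        return np.clip((x + b) / (2.0 * b), 0.0, 1.0)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        b = self.scale
        if self.family == "laplace":
            return np.exp(-np.abs(x) / b) / (2.0 * b)
        if self.family == "gaussian":
            return stats.norm.pdf(x / b) / b
        return np.where(np.abs(x) <= b, 1.0 / (2.0 * b), 0.0)

    def quantile(self, u):
        u = np.asarray(u, dtype=float)
        b = self.scale
        if self.family == "laplace":
            return np.where(u < 0.5, b * np.log(2.0 * np.maximum(u, 1e-320)),
                            -b * np.log(2.0 * np.maximum(1.0 - u, 1e-320)))
        if self.family == "gaussian":
            return b * stats.norm.ppf(u)
        return b * (2.0 * u - 1.0)

    def sample(self, size, rng: np.random.Generator):
        if self.family == "laplace":
            return rng.laplace(0.0, self.scale, size)
        if self.family == "gaussian":
            return rng.normal(0.0, self.scale, size)
        return rng.uniform(-self.scale, self.scale, size)

    def cdf_antiderivative(self, x):
        """A(x) = ∫_{-∞}^{x} F_e(v) dv, used to convolve with Uniform[0,1]."""
        x = np.asarray(x, dtype=float)
        b = self.scale
        if self.family == "laplace":
            neg = 0.5 * b * np.exp(np.minimum(x, 0.0) / b)
            pos = np.maximum(x, 0.0) + 0.5 * b * np.exp(-np.maximum(x, 0.0) / b)
            return np.where(x < 0, neg, pos)
        if self.family == "gaussian":
            z = x / b
            return x * stats.norm.cdf(z) + b * stats.norm.pdf(z)
        lo = np.zeros_like(x)
        mid = (x + b) ** 2 / (4.0 * b)
        hi = np.asarray(x, dtype=float)
        return np.where(x <= -b, lo, np.where(x < b, mid, hi))


def make_noise_model(family: str, scale: float) -> NoiseModel:
    """Construct a noise model; see :class:`NoiseModel` for scale semantics."""
    return NoiseModel(family=str(family), scale=float(scale))


# ---------------------------------------------------------------------------
# G — the CDF of U + e
# ---------------------------------------------------------------------------


def _bisect_monotone(f, u, lo, hi, iters: int = 90):
    """Vectorized bisection for a strictly increasing f; f(lo)≤u≤f(hi)."""
    lo = np.array(np.broadcast_to(lo, u.shape), dtype=float)
    hi = np.array(np.broadcast_to(hi, u.shape), dtype=float)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        below = f(mid) < u
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class ConvolvedCDF:
    """CDF ``G`` of ``U + e`` with ``U ~ Uniform[0,1]`` independent of ``e``.

    Since ``F_U`` is the uniform CDF, ``G(t) = A(t) - A(t-1)`` where ``A`` is
    the antiderivative of the noise CDF — closed form for all supported
    families.  ``G`` is continuous, strictly increasing on its support and
    symmetric about ``G(1/2) = 1/2``.  The quantile is obtained by bracketed
    bisection to ~1e-12 absolute accuracy.
    """

    noise: NoiseModel

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        A = self.noise.cdf_antiderivative
        return np.clip(A(t) - A(t - 1.0), 0.0, 1.0)

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        return self.noise.cdf(t) - self.noise.cdf(t - 1.0)

    def quantile(self, u):
        u = np.asarray(u, dtype=float)
        if np.any((u < 0) | (u > 1)):
            raise ValueError("quantile argument must lie in [0, 1]")
        uc = np.clip(u, 1e-15, 1.0 - 1e-15)
        # bracket: U+e lies within [q_e(u/2), 1 + q_e((1+u)/2)]
        lo = self.noise.quantile(uc / 2.0)
        hi = 1.0 + self.noise.quantile(0.5 + uc / 2.0)
        return _bisect_monotone(self.cdf, uc, lo, hi)


def convolve_uniform_noise(noise: NoiseModel) -> ConvolvedCDF:
    """The exact CDF of ``U + e`` for ``U ~ Uniform[0,1]``."""
    return ConvolvedCDF(noise=noise)


# ---------------------------------------------------------------------------
# Target distributions R
# ---------------------------------------------------------------------------


class TargetDistribution:
    """A CDF/quantile pair the perturbed data must follow.

    ``quantile`` implements the generalized inverse
    ``R⁻¹(u) = inf{x : R(x) ≥ u}`` so the inverse-CDF transform is valid for
    continuous, discrete and mixed targets alike.
    """

    support = "continuous"

    def cdf(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def quantile(self, u):  # pragma: no cover - interface
        raise NotImplementedError

    def describe(self) -> dict:
        return {"kind": type(self).__name__, "support": self.support}


@dataclass(frozen=True)
class ParametricTarget(TargetDistribution):
    """Wraps a frozen scipy.stats continuous distribution."""

    dist: object
    name: str = "parametric"

    support = "continuous"

    def cdf(self, x):
        return self.dist.cdf(x)

    def quantile(self, u):
        return self.dist.ppf(u)

    def describe(self) -> dict:
        d = {"kind": "ParametricTarget", "support": self.support, "name": self.name}
        try:
            d["params"] = [float(v) for v in self.dist.args] + [
                float(v) for v in self.dist.kwds.values()
            ]
        except AttributeError:
            pass
        return d


def _smooth_nodes(values: np.ndarray, cum: np.ndarray):
    """Piecewise-linear CDF nodes through the jump points.

    The interpolant passes through every ``(value, cumulative mass)`` pair
    and is anchored at zero half an inter-jump gap below the smallest jump,
    so the CDF is continuous and strictly increasing on its support.
    """
    gap = values[1] - values[0]
    xs = np.concatenate([[values[0] - 0.5 * gap], values])
    cs = np.concatenate([[0.0], cum])
    return xs, cs


@dataclass(frozen=True)
class SmoothedEmpiricalCDF(TargetDistribution):
    """Continuous CDF agreeing with a (weighted) empirical CDF at every jump.

    Between consecutive jump values the CDF is linear; below the smallest
    jump it falls linearly to zero over half the first inter-jump gap.  At
    and above the largest jump it equals one.
    """

    jump_values: np.ndarray
    jump_masses: np.ndarray  # cumulative, ending at 1
    _xs: np.ndarray = field(repr=False, default=None)
    _cs: np.ndarray = field(repr=False, default=None)

    support = "mixed"

    def cdf(self, x):
        return np.interp(np.asarray(x, dtype=float), self._xs, self._cs, left=0.0, right=1.0)

    def quantile(self, u):
        return np.interp(np.asarray(u, dtype=float), self._cs, self._xs)

    def describe(self) -> dict:
        return {
            "kind": "SmoothedEmpiricalCDF",
            "support": self.support,
            "n_jumps": int(len(self.jump_values)),
            "min": float(self.jump_values[0]),
            "max": float(self.jump_values[-1]),
        }


def fit_smoothed_cdf(values, weights=None) -> SmoothedEmpiricalCDF:
    """Fit the smoothed (weighted) empirical CDF of a numeric sample.

    Raises on degenerate samples (fewer than two distinct values), for which
    no strictly increasing continuous interpolant exists.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least 2 observations to fit a smoothed CDF")
    if weights is None:
        weights = np.ones_like(values)
    else:
        weights = np.asarray(weights, dtype=float).ravel()
        if weights.shape != values.shape:
            raise ValueError("weights must match values in length")
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    uniq, start = np.unique(v, return_index=True)
    if uniq.size < 2:
        raise ValueError("degenerate sample: all values identical")
    mass = np.add.reduceat(w, start)
    cum = np.cumsum(mass) / mass.sum()
    cum[-1] = 1.0
    xs, cs = _smooth_nodes(uniq, cum)
    return SmoothedEmpiricalCDF(jump_values=uniq, jump_masses=cum, _xs=xs, _cs=cs)


@dataclass(frozen=True)
class DiscreteTarget(TargetDistribution):
    """Discrete target over an ordered integer coding of categories.

    The quantile is the generalized inverse of the *step* CDF, so draws land
    exactly on category codes and follow the category probabilities exactly.
    ``cdf`` evaluates the smoothed version (continuous, agreeing with the
    step CDF at every code), which is what prefix-conditioning and audits
    use.
    """

    codes: np.ndarray
    probs: np.ndarray
    _cum: np.ndarray = field(repr=False, default=None)
    _xs: np.ndarray = field(repr=False, default=None)
    _cs: np.ndarray = field(repr=False, default=None)

    support = "discrete"

    @classmethod
    def from_probs(cls, codes, probs) -> "DiscreteTarget":
        codes = np.asarray(codes, dtype=float).ravel()
        probs = np.asarray(probs, dtype=float).ravel()
        if codes.size == 0 or codes.shape != probs.shape:
            raise ValueError("codes and probs must be equal-length and non-empty")
        keep = probs > 0
        codes, probs = codes[keep], probs[keep]
        order = np.argsort(codes)
        codes, probs = codes[order], probs[order]
        probs = probs / probs.sum()
        cum = np.cumsum(probs)
        cum[-1] = 1.0
        if codes.size >= 2:
            xs, cs = _smooth_nodes(codes, cum)
        else:  # degenerate one-level target
            xs = np.array([codes[0] - 0.5, codes[0]])
            cs = np.array([0.0, 1.0])
        return cls(codes=codes, probs=probs, _cum=cum, _xs=xs, _cs=cs)

    def cdf(self, x):
        return np.interp(np.asarray(x, dtype=float), self._xs, self._cs, left=0.0, right=1.0)

    def quantile(self, u):
        u = np.asarray(u, dtype=float)
        idx = np.searchsorted(self._cum, u, side="left")
        idx = np.clip(idx, 0, self.codes.size - 1)
        return self.codes[idx]

    def describe(self) -> dict:
        return {
            "kind": "DiscreteTarget",
            "support": self.support,
            "codes": [float(c) for c in self.codes],
            "probs": [float(p) for p in self.probs],
        }


@dataclass(frozen=True)
class ShiftedTarget(TargetDistribution):
    """Location shift of a base target (conditional location models)."""

    base: TargetDistribution
    shift: float

    @property
    def support(self):  # type: ignore[override]
        return self.base.support

    def cdf(self, x):
        return self.base.cdf(np.asarray(x, dtype=float) - self.shift)

    def quantile(self, u):
        return self.shift + self.base.quantile(u)

    def describe(self) -> dict:
        return {"kind": "ShiftedTarget", "shift": float(self.shift), "base": self.base.describe()}


# ---------------------------------------------------------------------------
# Conditional chain model for multivariate perturbation
# ---------------------------------------------------------------------------


class _MarginalNode:
    """Position-1 node: a fixed marginal target."""

    def __init__(self, name, vartype, target):
        self.name, self.vartype, self.target = name, vartype, target

    def conditional_target(self, prefix_row=None) -> TargetDistribution:
        return self.target

    def quantile_given_prefix(self, prefix: np.ndarray, v: np.ndarray) -> np.ndarray:
        return np.asarray(self.target.quantile(v), dtype=float)


class _LinearConditionalNode:
    """Linear location model on the prefix, residual CDF as base target.

    The builder is a pure function of its prefix and fitted parameters;
    prefixes outside the training range extrapolate the location model with
    the residual CDF unchanged.
    """

    def __init__(self, name, vartype, intercept, coef, resid_target):
        self.name, self.vartype = name, vartype
        self.intercept = float(intercept)
        self.coef = np.asarray(coef, dtype=float)
        self.resid_target = resid_target

    def _shift(self, prefix: np.ndarray) -> np.ndarray:
        prefix = np.atleast_2d(np.asarray(prefix, dtype=float))
        return self.intercept + prefix @ self.coef

    def conditional_target(self, prefix_row) -> TargetDistribution:
        return ShiftedTarget(self.resid_target, float(self._shift(prefix_row)[0]))

    def quantile_given_prefix(self, prefix: np.ndarray, v: np.ndarray) -> np.ndarray:
        return self._shift(prefix) + np.asarray(self.resid_target.quantile(v), dtype=float)


class _LogitConditionalNode:
    """Multinomial-logit class probabilities given the prefix.

    Prefix features are standardized with the training moments before the
    fit, purely for optimizer conditioning.
    """

    def __init__(self, name, vartype, model, classes, center=None, scale=None):
        self.name, self.vartype = name, vartype
        self.model = model  # fitted sklearn LogisticRegression, or None if degenerate
        self.classes = np.asarray(classes, dtype=float)
        self.center = center
        self.scale = scale

    def _probs(self, prefix: np.ndarray) -> np.ndarray:
        prefix = np.atleast_2d(np.asarray(prefix, dtype=float))
        if self.model is None:
            return np.ones((prefix.shape[0], 1))
        return self.model.predict_proba((prefix - self.center) / self.scale)

    def conditional_target(self, prefix_row) -> TargetDistribution:
        return DiscreteTarget.from_probs(self.classes, self._probs(prefix_row)[0])

    def quantile_given_prefix(self, prefix: np.ndarray, v: np.ndarray) -> np.ndarray:
        cum = np.cumsum(self._probs(prefix), axis=1)
        cum[:, -1] = 1.0
        idx = (cum >= np.asarray(v, dtype=float)[:, None]).argmax(axis=1)
        return self.classes[idx]


@dataclass
class ConditionalChainModel:
    """Fitted chain of per-variable (conditional) targets ``R⁽ˡ⁾``.

    Position 1 holds a marginal target; every later position maps the
    already-perturbed prefix of the same record to a conditional target via
    a pure builder.
    """

    order: list
    types: list
    nodes: list
    schema: TableSchema | None = None
    fit_n: int = 0
    fit_index_hash: str | None = None  # identifies the rows the chain saw

    def __len__(self):
        return len(self.nodes)

    def conditional_target(self, position: int, prefix_row=None) -> TargetDistribution:
        """Target for the variable at ``position`` (0-based) given a prefix."""
        node = self.nodes[position]
        if position == 0:
            return node.conditional_target()
        return node.conditional_target(prefix_row)


def _encode_columns(df: pd.DataFrame, schema: TableSchema, names) -> np.ndarray:
    cols = []
    for nm in names:
        spec = schema[nm]
        if spec.is_discrete:
            cols.append(spec.codes(df[nm]).to_numpy(dtype=float))
        else:
            cols.append(df[nm].to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def _fit_residual_target(resid: np.ndarray, weights: np.ndarray) -> TargetDistribution:
    try:
        return fit_smoothed_cdf(resid, weights)
    except ValueError:
        # perfectly fitted / degenerate residuals: nearly point-mass normal
        sd = max(float(np.std(resid)), 1e-12)
        return ParametricTarget(stats.norm(0.0, sd), name="normal-residual")


def fit_conditional_chain(
    data: pd.DataFrame,
    schema: TableSchema,
    order: list | None = None,
    marginals: dict | None = None,
) -> ConditionalChainModel:
    """Fit the chain-rule conditional model on a tabular sample.

    Parameters
    ----------
    data
        Complete table; must contain every schema column.  Needs >= 2 rows.
    schema
        Variable types (and the optional weight column, used as fit weights).
    order
        Variable ordering for the chain; defaults to schema order.  The
        first variable is the one whose ranks the perturbation preserves.
    marginals
        Optional ``{column: TargetDistribution}`` overrides for marginal
        targets (e.g. a parametric target for a continuous first variable).
    """
    schema.validate_frame(data)
    if len(data) < 2:
        raise ValueError("need at least 2 rows to fit a conditional chain")
    if order is None:
        order = schema.variable_names
    unknown = [nm for nm in order if nm not in schema.variable_names]
    if unknown:
        raise ValueError(f"order names {unknown} not perturbable schema columns")
    marginals = marginals or {}

    wcol = schema.weight_column
    weights = data[wcol].to_numpy(dtype=float) if wcol else np.ones(len(data))
    types = [schema[nm].type for nm in order]
    nodes = []
    for l, nm in enumerate(order):
        spec = schema[nm]
        if spec.is_discrete:
            y = spec.codes(data[nm]).to_numpy(dtype=float)
        else:
            y = data[nm].to_numpy(dtype=float)
        if l == 0:
            if nm in marginals:
                target = marginals[nm]
            elif spec.is_discrete:
                codes, inv = np.unique(y, return_inverse=True)
                probs = np.bincount(inv, weights=weights)
                target = DiscreteTarget.from_probs(codes, probs)
            else:
                target = fit_smoothed_cdf(y, weights)
            nodes.append(_MarginalNode(nm, spec.type, target))
            continue
        prefix = _encode_columns(data, schema, order[:l])
        if spec.is_discrete:
            classes = np.unique(y)
            if classes.size < 2:
                nodes.append(_LogitConditionalNode(nm, spec.type, None, classes))
            else:
                center = prefix.mean(axis=0)
                scale = prefix.std(axis=0)
                scale[scale == 0] = 1.0
                clf = LogisticRegression(max_iter=1000, C=100.0)
                clf.fit((prefix - center) / scale, y, sample_weight=weights)
                nodes.append(_LogitConditionalNode(nm, spec.type, clf, clf.classes_,
                                                   center=center, scale=scale))
        else:
            X = np.column_stack([np.ones(len(y)), prefix])
            sw = np.sqrt(weights)
            coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
            resid = y - X @ coef
            resid_target = _fit_residual_target(resid, weights)
            nodes.append(_LinearConditionalNode(nm, spec.type, coef[0], coef[1:], resid_target))

    idx_hash = pd.util.hash_pandas_object(data.index).sum()
    return ConditionalChainModel(
        order=list(order), types=types, nodes=nodes, schema=schema, fit_n=len(data),
        fit_index_hash=f"{int(idx_hash) & 0xFFFFFFFFFFFFFFFF:x}",
    )
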
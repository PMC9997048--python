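"""Constrained truncated-L1 (TLP) regression — an L0-surrogate selector.

Minimizes least squares subject to ``Σ_{j≠l} min(|β_j|/τ, 1) ≤ K`` with one
coordinate ``l`` (the coefficient under inference) always unpenalized.  For
small τ the constraint approximates the L0 budget "at most K selected
variables besides l".

Solver: difference-of-convex (DC) iterations warm-started from the L1
(lasso) solution path.  Each DC step linearizes the concave part of the
penalty at the current iterate, which splits coordinates into a "large" set
(|β| > τ, cost saturated at 1) and a "small" set whose weighted-L1 budget
``τ(K - #large)`` shrinks to zero as τ → 0; the inner problem is then least
squares on the large set with the small set at zero.  Iterates are accepted
only when they lower the objective, so the objective path is non-increasing.
On small problems (p ≤ 12 by default) a one-swap local search refines the
selected support, which in practice recovers the exhaustive best-subset
solution.

All inner algebra is Gram-based, so repeated refits with a fixed design and
many response vectors (the Monte-Carlo inference loop) cost O(p²) each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import lars_path_gram

__all__ = ["TLPFit", "TLPWorkspace", "tlp_regression", "choose_k_cv", "default_tau"]

_SWAP_REFINE_MAX_P = 12


def default_tau(n: int, p: int) -> float:
    """Truncation threshold τ = 0.01·√(log p / n)."""
    return 0.01 * np.sqrt(np.log(max(p, 2)) / n)


@dataclass
class TLPFit:
    """Result of a constrained-TLP regression fit."""

    beta: np.ndarray
    active: np.ndarray  # selected penalized coordinates (excl. the free one)
    K: int
    tau: float
    exclude: int | None
    se: float | None  # SE of beta[exclude] from the refitted model
    sigma2: float
    objective: float  # 0.5 * RSS at beta
    objective_path: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True


class TLPWorkspace:
    """Fixed-design engine for repeated TLP fits with varying responses.

    Precomputes the Gram matrix and the residualization of the penalized
    block against the unpenalized coordinate; ``fit_gram`` then needs only
    ``X'y`` and ``y'y``.
    """

    def __init__(self, X: np.ndarray, K: int, tau: float | None = None,
                 exclude: int | None = None, refine: bool | None = None,
                 max_iter: int = 30):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n < 2:
            raise ValueError("need n >= 2")
        n_pen = p - (1 if exclude is not None else 0)
        if not (1 <= K <= n_pen):
            raise ValueError(f"require 1 <= K <= {n_pen} penalized coordinates, got K={K}")
        if exclude is not None and not (0 <= exclude < p):
            raise ValueError("exclude out of range")
        self.n, self.p = n, p
        self.K, self.exclude = K, exclude
        self.tau = default_tau(n, p) if tau is None else float(tau)
        if not (self.tau > 0):
            raise ValueError("tau must be positive")
        self.refine = (p <= _SWAP_REFINE_MAX_P) if refine is None else bool(refine)
        self.max_iter = max_iter
        self.G = X.T @ X
        self.X = X
        self.others = np.array([j for j in range(p) if j != exclude], dtype=int)
        if exclude is not None:
            a = self.G[self.others, exclude]
            s = self.G[exclude, exclude]
            if s <= 0:
                raise ValueError("unpenalized column is identically zero")
            self._a, self._s = a, s
            self.Gr = self.G[np.ix_(self.others, self.others)] - np.outer(a, a) / s
        else:
            self._a = self._s = None
            self.Gr = self.G[np.ix_(self.others, self.others)]

    # -- support algebra ---------------------------------------------------

    def _ols(self, support: np.ndarray, Xy: np.ndarray, yy: float):
        """OLS restricted to ``support`` (full-variable indices)."""
        S = np.asarray(support, dtype=int)
        if S.size == 0:
            return np.empty(0), yy
        GSS = self.G[np.ix_(S, S)]
        try:
            b = np.linalg.solve(GSS, Xy[S])
        except np.linalg.LinAlgError:
            b, *_ = np.linalg.lstsq(GSS, Xy[S], rcond=None)
        rss = max(yy - Xy[S] @ b, 0.0)
        return b, rss

    def _full_support(self, pen_support) -> np.ndarray:
        S = list(pen_support)
        if self.exclude is not None:
            S = [self.exclude] + S
        return np.array(sorted(S), dtype=int)

    def _lasso_candidates(self, Xy: np.ndarray) -> list:
        """Candidate penalized supports from the residualized lasso path."""
        if self.exclude is not None:
            Xry = Xy[self.others] - self._a * (Xy[self.exclude] / self._s)
        else:
            Xry = Xy[self.others]
        cands = []
        try:
            _, _, coefs = lars_path_gram(
                Xy=Xry, Gram=self.Gr, n_samples=self.n, method="lasso",
                max_iter=min(4 * self.K + 10, 2 * self.others.size),
            )
            nnz = (coefs != 0).sum(axis=0)
            # first path point reaching K actives, plus the path end truncated to K
            hit = np.nonzero(nnz == self.K)[0]
            cols = ([hit[0]] if hit.size else []) + [coefs.shape[1] - 1]
            for c in cols:
                b = coefs[:, c]
                idx = np.argsort(-np.abs(b))[: self.K]
                sup = frozenset(self.others[i] for i in idx if b[i] != 0)
                if sup:
                    cands.append(sup)
        except Exception:
            pass
        # marginal screen fallback/extra start
        denom = np.sqrt(np.maximum(np.diag(self.Gr), 1e-300))
        idx = np.argsort(-np.abs(Xry) / denom)[: self.K]
        cands.append(frozenset(self.others[i] for i in idx))
        seen, out = set(), []
        for s in cands:
            if s not in seen:
                seen.add(s)
                out.append(s)
        return out

    def _dc_iterate(self, pen_support: frozenset, Xy: np.ndarray, yy: float):
        """DC descent from a penalized support; returns (support, obj, path)."""
        cur = frozenset(pen_support)
        S = self._full_support(cur)
        b, rss = self._ols(S, Xy, yy)
        obj = 0.5 * rss
        path = [obj]
        for _ in range(self.max_iter):
            beta_map = dict(zip(S, b))
            large = frozenset(j for j in cur if abs(beta_map.get(j, 0.0)) > self.tau)
            if large == cur:
                break
            S_new = self._full_support(large)
            b_new, rss_new = self._ols(S_new, Xy, yy)
            obj_new = 0.5 * rss_new
            if obj_new > obj + 1e-12:  # accept only non-increasing steps
                break
            cur, S, b, obj = large, S_new, b_new, obj_new
            path.append(obj)
        return cur, obj, path

    def _swap_refine(self, pen_support: frozenset, Xy: np.ndarray, yy: float):
        """Best-improvement local search over supports (swaps and pair swaps)."""
        from itertools import combinations

        cur = set(pen_support)
        _, rss = self._ols(self._full_support(cur), Xy, yy)
        obj = 0.5 * rss
        pool = set(int(j) for j in self.others)
        improved = True
        while improved:
            improved = False
            best = (obj, None)
            moves = []
            outside = pool - cur
            if len(cur) < self.K:
                moves += [cur | {k} for k in outside]
            moves += [(cur - {j}) | {k} for j in cur for k in outside]
            moves += [cur - {j} for j in cur if len(cur) > 1 or self.exclude is not None]
            # pair swaps escape the substitution traps single swaps cannot
            moves += [(cur - set(drop)) | set(add)
                      for drop in combinations(sorted(cur), 2)
                      for add in combinations(sorted(outside), 2)]
            for S_new in moves:
                _, rss_new = self._ols(self._full_support(S_new), Xy, yy)
                if 0.5 * rss_new < best[0] - 1e-12:
                    best = (0.5 * rss_new, S_new)
            if best[1] is not None:
                obj, cur = best[0], set(best[1])
                improved = True
        return frozenset(cur), obj

    # -- public fitting ----------------------------------------------------

    def fit_gram(self, Xy: np.ndarray, yy: float) -> TLPFit:
        best_sup, best_obj, best_path = None, np.inf, []
        n_iter = 0
        for start in self._lasso_candidates(Xy):
            sup, obj, path = self._dc_iterate(start, Xy, yy)
            n_iter += len(path)
            if obj < best_obj - 1e-15:
                best_sup, best_obj, best_path = sup, obj, path
        if self.refine:
            best_sup, best_obj = self._swap_refine(best_sup, Xy, yy)
        S = self._full_support(best_sup)
        b, rss = self._ols(S, Xy, yy)
        beta = np.zeros(self.p)
        beta[S] = b
        df = self.n - S.size
        sigma2 = rss / df if df > 0 else np.nan
        se = None
        if self.exclude is not None:
            GSS = self.G[np.ix_(S, S)]
            try:
                Ginv = np.linalg.inv(GSS)
            except np.linalg.LinAlgError:
                Ginv = np.linalg.pinv(GSS)
            pos = int(np.nonzero(S == self.exclude)[0][0])
            var = sigma2 * Ginv[pos, pos]
            se = float(np.sqrt(var)) if np.isfinite(var) and var > 0 else np.nan
        return TLPFit(
            beta=beta,
            active=np.array(sorted(best_sup), dtype=int),
            K=self.K,
            tau=self.tau,
            exclude=self.exclude,
            se=se,
            sigma2=float(sigma2),
            objective=0.5 * rss,
            objective_path=best_path,
            n_iter=n_iter,
            converged=True,
        )

    def fit(self, y: np.ndarray) -> TLPFit:
        y = np.asarray(y, dtype=float).ravel()
        fit = self.fit_gram(self.X.T @ y, float(y @ y))
        # recompute the objective in the data domain for full precision
        r = y - self.X @ fit.beta
        fit.objective = 0.5 * float(r @ r)
        fit.sigma2 = float(r @ r) / max(self.n - fit.active.size -
                                        (1 if self.exclude is not None else 0), 1)
        return fit


def tlp_regression(
    X,
    y,
    K: int,
    tau: float | None = None,
    exclude: int | None = None,
    refine: bool | None = None,
) -> TLPFit:
    """Fit the TLP-constrained regression (see module docstring).

    ``exclude`` is the 0-based coordinate kept unpenalized (always in the
    model); its standard error is computed from the refitted selected
    model's information.
    """
    return TLPWorkspace(np.asarray(X, float), K=K, tau=tau, exclude=exclude,
                        refine=refine).fit(np.asarray(y, float))


def choose_k_cv(
    X,
    y,
    exclude: int | None = None,
    k_grid=None,
    tau: float | None = None,
    n_folds: int = 5,
    seed: int | None = None,
) -> int:
    """Pick the constraint size K by cross-validated prediction error."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    n_pen = p - (1 if exclude is not None else 0)
    if k_grid is None:
        k_grid = range(1, min(10, n_pen, max(n - 2, 1)) + 1)
    k_grid = [k for k in k_grid if 1 <= k <= n_pen]
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), n_folds)
    errs = {k: 0.0 for k in k_grid}
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        for k in k_grid:
            try:
                fit = TLPWorkspace(X[train], K=k, tau=tau, exclude=exclude,
                                   refine=False).fit(y[train])
                r = y[test] - X[test] @ fit.beta
                errs[k] += float(r @ r)
            except (ValueError, np.linalg.LinAlgError):
                errs[k] += np.inf
    return min(k_grid, key=lambda k: (errs[k], k))
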
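# Methods

## The perturbation scheme

Given a raw sample `Z_1, …, Z_n` and a target distribution `R`, each
perturbed value is

    Z*_ij = H(U_i + e_ij),    H = R⁻¹ ∘ G,    i = 1..n, j = 1..m,

where `U_1..U_n` are i.i.d. Uniform[0,1] values *relabeled so that the rank
of U_i equals the rank of Z_i*, `e_ij` is independent symmetric noise, and
`G` is the exact CDF of `U + e`.  Two facts drive everything:

1. **Distribution preservation.** `G(U + e)` is Uniform[0,1] for *any*
   noise scale (probability integral transform of the convolution), so
   `Z*_ij = R⁻¹(G(U_i + e_ij))` follows `R` exactly.  Privacy noise never
   costs distributional fidelity; it only weakens the link to individual
   records.
2. **Identifier preservation.** The rank coupling makes the Spearman
   correlation between `Z` and `Z*` approach 1 as the noise scale shrinks,
   so each perturbed record stays linked to its source record; with large
   noise the link dissolves, which is precisely the privacy mechanism.

`G` is computed in closed form: with `A` the antiderivative of the noise
CDF, `G(t) = A(t) − A(t−1)`.  Laplace, Gaussian and symmetric-uniform noise
all admit elementary `A`.  The quantile of `G` is obtained by bracketed
bisection (90 iterations, ~1e-12 absolute); the convolution itself is exact,
so numerical error stays far below statistical noise.

**Multivariate data** is perturbed through the probability chain rule: the
first variable is rank-coupled as above; each later variable `l` draws
fresh uniforms (no relabeling needed — the identifier already lives in the
first component) and uses the conditional target `R⁽ˡ⁾` given the
*already-perturbed* prefix of the same record and copy.  Within one copy,
records are mutually independent given the fitted targets.

### Targets for mixed data types

- *Parametric targets* wrap frozen scipy distributions.
- *Smoothed empirical CDF* (continuous/empirical columns): piecewise-linear
  interpolation through the (value, cumulative-weight) jump points,
  anchored at zero half the first inter-jump gap below the minimum.  It
  agrees with the (weighted) empirical CDF at every jump value to machine
  precision and is continuous and strictly increasing in between.  No upper
  extension is needed: the CDF equals 1 at the largest jump.
- *Discrete targets* (binary/nominal columns): categories are mapped to a
  fixed integer coding recorded in the schema.  The quantile used for
  generation is the generalized inverse of the **step** CDF, so emitted
  values are exact category codes and the category probabilities are
  preserved exactly; the smoothed piecewise-linear CDF is used wherever a
  continuous evaluation is needed (audits, prefix conditioning).
- *Conditional targets* in the chain: a linear location model on the prefix
  with a smoothed empirical CDF of residuals for numeric columns, and a
  multinomial logit (features standardized internally for optimizer
  conditioning) for categorical columns.  These are deliberately minimal
  models that respect variable type; misspecification here degrades the
  *joint* fidelity of the release, never the marginal of the first
  variable.  Prefixes outside the training range extrapolate the location
  model with the residual CDF unchanged.

### ε-differential privacy mode

`privatize` splits the table once (seeded) into a holdout and a release
part, fits the chain on the holdout only, and perturbs the release part
with per-variable Laplace noise of scale `p/ε` (equal split of the budget
over `p` variables by sequential composition; 17 variables at ε = 1 gives
scale 17 per variable).  The holdout is fixed once selected and never
emitted; a content-hash ledger makes re-splitting the same dataset an
error, also across CLI invocations.  The survey-weight column is used to
weight fits but is not itself perturbed and does not consume budget.  The
package reproduces the construction (noise scale, holdout discipline); it
does not re-derive the privacy proof, and offers no (ε, δ) or Rényi
accounting.

## Monte-Carlo pivotal inference

For a studentized pivot `T = (θ̂ − θ)/se`:

1. Build the plug-in target `R = F(θ̂)`, generate `D` *independent*
   perturbed samples (each with its own fresh rank-coupled uniforms),
   re-estimate on each, and form `T*_d = (θ̂*_d − θ̂)/se*_d`.
2. `B̂ = mean(θ̂*) − θ̂`; corrected estimate `θ̂c = θ̂ + B̂` (the package
   follows this sign convention by default; a `classical` flag gives
   `θ̂ − B̂`).
3. CI: `[θ̂c − q_hi·se, θ̂c − q_lo·se]` with `q` the empirical α/2 and
   1−α/2 quantiles of `T*` (numpy linear-interpolation quantiles, for
   stability at large D).

With fresh uniforms per draw, each perturbed sample is an *exact* i.i.d.
sample from `R`, so for the normal-mean example the conditional law of
`T*` given the data is exactly `t_{n−1}` — the package treats the phrase
"independent perturbed samples" literally rather than reusing one shared
uniform sample across draws, which would make the equivalence only
approximate at noise scale 1/ε.  Estimator failures on perturbed draws are
dropped, topped back up, and counted in the result.

### High-dimensional regression example

`Y = Xβ + N(0, σ²)`, AR(1) predictor correlation.  For a coefficient `β_l`:

- **Selection**: least squares subject to `Σ_{j≠l} min(|β_j|/τ, 1) ≤ K`
  (truncated-L1 surrogate of the L0 budget), coordinate `l` always
  unpenalized.  Defaults: `τ = 0.01·√(log p / n)`; `K` by 5-fold CV on the
  holdout when not supplied.
- **Solver**: difference-of-convex iterations.  The penalized block is
  residualized against column `l` (exactly equivalent to leaving `l`
  unpenalized), the lasso path is computed in Gram mode (LARS) for warm
  starts, and each DC step refits the "large" set (|β| > τ) by OLS — the
  inner weighted-L1 budget `τ(K − #large)` is vanishing at the default τ,
  so small coefficients are set to zero.  Steps are accepted only when the
  objective decreases, making the objective path non-increasing.  On small
  problems (p ≤ 12) a best-improvement local search over supports (single
  and pair swaps) refines the solution; in testing this recovers the
  exhaustive best-subset optimum on every random instance tried (250+).
  The refinement is disabled at larger p, where its cost grows quadratically
  and the lasso-warm-started DC solution is used as-is.
- **SE(β̂_l)**: from the refitted OLS information on the selected support,
  `σ̂²·[(X_S'X_S)⁻¹]_ll` with `σ̂² = RSS/(n − |S|)`.
- **Residual perturbation**: μ̂ and σ̂² are fitted on a holdout with the
  same sparse constrained estimator (constraint size by CV on the holdout),
  not full OLS — sparsity matters: a dense μ̂ would leak per-coordinate
  holdout estimation noise into every perturbed copy and spread the
  corrected estimate beyond what the pivotal draws reflect, costing
  coverage exactly at null coefficients.  Perturbed responses are
  `Y*_ij = μ̂(X_i) + ε*_ij` with the inference-sample residuals
  rank-coupled and mapped to `N(0, σ̂²)` under Laplace(0, 1/ε) noise,
  ε = 0.01.  The TLP fit is repeated on every copy through a fixed-design
  Gram workspace (each refit costs O(p²), ~2 ms at p = 50).

## Synthetic-data generators

- `gen_highdim_regression`: `X` rows i.i.d. `N(0, Σ)` via the Cholesky
  factor of the AR(1) Toeplitz matrix `Σ_jk = ρ^|j−k|`; defaults σ = 0.5,
  ρ = 0.5, β = (1, 1, 1, 0, …) — the study configuration.
- `gen_survey_microdata`: a census-style person table — 17 variables (age
  first, then 15 mixed binary/nominal/empirical demographic covariates and
  a log-normal income) plus an integer person weight.  Planted structure:
  insurance coverage logistic in age (slope 0.4 per decade), income
  increasing in education and concave in age, employment dependent on age.
  It emulates the *types and layout* of real survey microdata, not its
  population margins or design effects; passing audits on it shows the
  machinery preserves joint structure it can represent, not that any real
  survey's conditional dependencies are captured by the linear/logit chain.
- `gen_poisson_glm`: counts `~ Poisson(exp(X_std β))` with covariates drawn
  at a configurable dispersion and standardized inside the link (β scaled
  inversely), so large-dispersion settings remain numerically sound and
  comparisons across dispersion levels stay interpretable.

All generators are pure functions of (config, seed); all randomness in the
package flows from one root seed through named child streams (coupling,
noise, chain uniforms, splits), so stages are independently reproducible.

## Numerical choices and degenerate inputs

- Ties in rank matching are broken uniformly at random under the plan seed.
- Smoothed-CDF fitting rejects samples with fewer than two distinct values;
  degenerate conditional residuals fall back to a near-point-mass normal.
- `G`-quantile bisection brackets via the noise quantile, 90 iterations.
- Empirical quantiles use numpy's linear interpolation convention.
- The DP noise stream is logged on multivariate perturbation so audits can
  test it distributionally against Laplace(0, p/ε).

## Problem sizes used for verification

The package's own experiments run at: D = 1e5 draws for the
pivotal-density check (three sample sizes n ∈ {5, 10, 20}), 1e5 pooled
values per cell for distribution-preservation checks, n = 1000 with 20
replicates per noise scale for the coupling monotonicity check, and 100
replications (of the study's 500) at D = 1000 for the coverage experiment,
whose binomial Monte-Carlo standard error (~2–3 points) is reported
alongside the estimate.

## Known limitations

- Conditional chain models are linear/logit; strongly nonlinear or
  heteroscedastic dependencies between survey variables are smoothed over
  (the marginal of each variable is still preserved through its own target).
- Pure ε-DP by sequential composition only; per-variable budgets are equal.
- The TLP solver is a local method beyond small p; it inherits lasso
  screening behavior at p ≫ 12.
- Coverage of the regression CIs depends on the plug-in σ̂² and on
  selection stability; like the original experiment, mild undercoverage for
  strong-signal coefficients is expected at n = 100, p = 50.
- Non-i.i.d. data (time series, clustered surveys) is out of scope.
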
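# Methods

## Model and estimator

`latdif` fits a mixture 2-PL item response model in which the DIF comparison
groups are latent classes and the anchor set is unknown. The observed-data
likelihood integrates ability out class by class,

    L(Δ) = Π_i Σ_k ν_k ∫ Π_j Bern(Y_ij; expit(a_j θ + d_j + δ_jk)) φ(θ | μ_k, σ_k²) dθ,

with the reference class pinned at `μ_0 = 0, σ_0² = 1` and `δ_j0 = 0`. The
integral is evaluated with per-class Gauss–Hermite quadrature adapted to
`N(μ_k, σ_k²)` (default `Q = 31` nodes; the study runs use `Q = 21`, which
agrees with `Q = 62` to well below 1e-6 on the scenarios used). All
likelihood work is done in log space via `log_expit`/`logsumexp`, so any
finite parameter value yields a finite log-likelihood.

The penalised estimator minimises `−log L(Δ) + λ Σ|δ_jk|` subject to the
simplex constraint on `ν`. DIF items are read off the nonzero pattern; the
final parameter estimate is a constrained maximum-likelihood refit with the
selected zeros pinned, which removes the Lasso shrinkage bias.

## EM algorithm

Each iteration:

1. **E-step** — joint responsibilities `r_ikq` over (class, quadrature node),
   computed in log space.
2. **Class proportions** — closed-form simplex update
   `ν_k ← (1/N) Σ_i P(ξ_i = k | Y_i)`.
3. **M-step** — up to `n_inner = 25` proximal-gradient steps on the
   remaining parameters at fixed responsibilities. Steps are preconditioned
   by a diagonal Fisher-type curvature estimate (per-item Bernoulli
   information, per-class normal information); the proximal operator in this
   metric is coordinate-wise soft-thresholding at `step·λ/W_jk`, so `δ`
   entries are *exactly* zero, never fuzzily small. A backtracking line
   search enforces the weighted quadratic-upper-bound condition, which
   guarantees descent of the surrogate and hence (Jensen) of the penalised
   objective. Without preconditioning the structural parameters move by
   ~1e-3 per iteration and the algorithm stalls far from any optimum.
4. **Re-anchoring** — an exact descent move along the model's scale
   unidentifiability: shifting `μ_k` by `c_k` and `δ_jk` by `−a_j c_k`
   leaves `L` unchanged, so `c_k` is set to the weighted median of
   `δ_jk / a_j` (weights `|a_j|`), the L1-minimising representative, whenever
   that strictly shrinks the penalty.

Convergence is declared when the relative change of the penalised objective
falls below `tol` (default 1e-6) or a stationary point is reached; a
monotonicity safeguard stops the iteration if the quadrature refresh ever
produces a (numerically) increasing objective. Parameters are kept in boxes
(`|d| ≤ 8`, `|δ| ≤ 6`, `|μ_k| ≤ 5`, `σ_k ∈ [0.3, 3]`): without them the
mixture likelihood drifts into degenerate ridges — vanishing-variance point
classes with unbounded DIF offsets — which an independent L-BFGS check
confirms are genuine features of the unbounded likelihood, not optimiser
artifacts.

### Initialisation

The no-DIF mixture likelihood is nearly flat across collapsed and separated
class configurations, and `δ = 0` is a saddle from which symmetric starts
cannot escape. Starts are therefore seeded from the data: a plain 2-PL fit
gives abilities and residuals; k-means on the residual matrix (k-means++,
seeded) clusters respondents whose response patterns deviate *jointly* from
the 2-PL — the latent-DIF signature; cluster shares, ability means and
working-response logit contrasts initialise `ν`, `μ` and `δ`. The best of
`n_starts` such starts (plus one neutral start) by final objective wins.

### The λ path

The grid is built from `λ_max` (smallest λ with an all-zero DIF matrix,
found by a warm-started doubling search) down to `λ_max / 20`, ten points,
and traversed in **ascending** order, warm-started from a fit at the anchor
`λ = N/500`. Direction matters: at small λ the penalty pins the ability
scale at the sparse representative of the scale-shift ridge (DIF-free items
dominate the weighted median), and the support then thins out cleanly as λ
grows. Descending paths inherit the no-DIF fit's shifted scale — the class
mean absorbs the aligned component of the DIF — which activates spurious
entries of the opposite sign that never leave the path. Each support on the
grid is refit at `λ = 0` with zeros pinned and scored by BIC; ties go to the
smallest λ. `K` is selected by comparing the BIC of the selected refit
across candidate `K` (ties to the smaller `K`).

## Synthetic-data generator and study configuration

The generator draws `d_j ~ U(−2, 2)`, `a_j ~ U(0.5, 1.5)`; latent classes
are categorical with the configured proportions and class-conditional normal
abilities (the "second argument" of each normal is a variance). The built-in
grid covers two-group scenarios (J ∈ {25, 50} × N ∈ {1000, 5000} × focal
share ∈ {0.1, 0.2, 0.5}; focal ability N(0.5, 1.5); DIF U(0.5, 1.5) on the
first 40% of items) and three-group scenarios (proportions (0.5, 0.3, 0.2);
abilities N(0.5, 1.5) and N(1, 1.2); DIF U(0.5, 1) and U(1, 1.5) on the last
40% of items). Truth parameters are drawn once per scenario from the
scenario seed and frozen across replicates; responses use a counter-derived
seed stream, so every run is a pure function of (config, seed). The
semi-synthetic speededness scenario (N=2000, J=25) gives a quarter of
examinees guessing-level success (`δ ~ U(−3, −2)`) on the last five items
and a lower mean ability (−0.35), magnitudes consistent with fitted
speededness analyses of real end-of-test data.

Scaled study runs (tests and `scripts/acceptance.py`) use B = 20 replicates
for the two-group cell, B = 10 for the three-group cell (B = 5 in the
acceptance script), with `EMControls(n_starts=3, max_iter=500, tol=1e-6,
Q=21)`. Evaluation metrics: entry-wise TPR/FPR of the selected DIF pattern,
MAP classification error and one-vs-rest Mann–Whitney AUC (under fitted and
true parameters), the known-groups oracle's TPR/FPR, and absolute bias/RMSE
per parameter type, with each item-parameter type averaged over all J items
(so exact zeros on correctly-pinned items enter the DIF row). Label
switching among focal classes is resolved against the generating labels by
the minimum-classification-error permutation before any comparison.

## What the generator does not emulate

Real response data exhibit guessing, local dependence, within-class ability
skew, and missingness mechanisms tied to speededness (omitted rather than
wrong answers). Passing tests demonstrate correct behaviour under the
stated mixture 2-PL generative model only. In real speeded data the class
signal is typically far stronger than this smooth model implies — abrupt
non-completion produces near-deterministic response patterns — so detection
there is easier than in these simulations.

## Known limitations

- **BIC versus the no-DIF mixture at moderate N.** The no-DIF mixture is a
  singular, misspecified competitor whose in-sample optimism substantially
  exceeds the `#params/2` that BIC charges. At N = 1000 with focal shares
  ≤ 0.5 and DIF effects U(0.5, 1.5) aligned with a positive focal-ability
  shift, the marginal-likelihood gain of the true DIF structure over the
  fitted no-DIF mixture (≈ 9–40 nats across truth draws, against a BIC bar
  of ≈ 35) is frequently insufficient, and the selector correctly-by-BIC but
  unhelpfully returns the no-DIF model. The effect disappears at N = 5000
  or when DIF opposes the ability shift (as in speededness). This is a
  property of the estimator, not of the optimiser: the likelihood machinery
  is verified against brute-force integration, and the fitted optima against
  an independent quasi-Newton maximiser.
- **Scale-shift absorption at large λ.** For strongly one-signed DIF the
  global penalised optimum at large λ moves part of the DIF into the class
  mean, zeroing small true effects and activating small opposite-signed
  spurious ones. The ascending path and re-anchoring mitigate but cannot
  remove this: it is the geometry of L1 + a free impact mean.
- Non-uniform DIF (slope effects), ordinal responses, probit links and
  multidimensional abilities are out of scope; the likelihood bounds
  (`σ_k ∈ [0.3, 3]` etc.) embed a mild prior that latent ability classes
  are of comparable dispersion to the reference.
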
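# Methods

## Model

`jointfair` estimates K group-specific logistic regression models jointly.
For groups k = 1, …, K with designs X_k (n_k × p), binary outcomes y_k and
coefficients β_k, the joint objective is

    F(β) = Σ_k (1/n_k) Σ_i [ log(1 + exp(η_ki)) − y_ki η_ki ]
         + λ_F  Σ_{j<k} Σ_{y∈{0,1}} | X̄_jyᵀ β̃_j − X̄_kyᵀ β̃_k |
         + λ_Sim Σ_{j<k} ‖β_j − β_k‖₁
         + Σ_k λ_Sp^k ‖β_k‖₁ ,

with η_ki = b_k + X_ki β_k the linear predictor, β̃_k = (b_k, β_k) the
intercept-augmented block, and X̄_ky the mean feature vector (with a leading
1) over group k's class-y subjects.

* The **1/n_k likelihood weighting** gives small groups the same voice as
  large ones.
* The **fairness penalty** (λ_F) is an equalized-odds surrogate: the exact
  between-group FPR/FNR gaps are non-convex in β, but the absolute gap in
  expected *probabilities* between two groups is at most one quarter of the
  gap in expected *linear predictors* (the sigmoid's derivative is bounded
  by 1/4), so penalizing the class-conditional mean linear predictors
  convexly controls the error-rate gaps.
* The **similarity penalty** (λ_Sim) is a generalized fused lasso on
  pairwise slope differences, shrinking groups toward shared coefficients
  without forcing them equal.
* The **sparsity penalty** (λ_Sp^k) is an ordinary per-group lasso.

Intercepts are never penalized by sparsity or similarity; they do enter the
fairness penalty (they are part of the linear predictor whose group means
the penalty compares). All pairwise penalties enumerate every pair j < k.
A scalar λ_Sp is tied across groups as λ_Sp^k = λ_Sp / √n_k, so sparsity
pressure decreases with group sample size; a length-K vector overrides the
tying.

## Optimization

The fairness + similarity terms equal ‖D β̃‖₁ for a sparse stacked operator
D, whose proximal map has no closed form. We therefore apply Nesterov
smoothing,

    f_μ(β) = max{ αᵀDβ̃ − (μ/2)‖α‖₂² : ‖α‖_∞ ≤ 1 } ,

with maximizer α* = clip(Dβ̃/μ, −1, 1), gradient Dᵀα*, and Lipschitz
constant ‖D‖₂²/μ. The surrogate under-estimates ‖Dβ̃‖₁ by at most μM/2,
where M counts the rows of D that are not identically zero. The smoothed
objective (smooth loss + f_μ + separable L1) is minimized by FISTA-style
accelerated proximal gradient: a gradient step at the extrapolated point,
soft-thresholding with per-coordinate thresholds λ_Sp^k/L (zero on
intercepts), and the standard momentum sequence θ_{t+1} = (1+√(1+4θ_t²))/2.
The fixed step 1/L uses

    L = max_k ‖X̃_k‖₂² / (4 n_k) + ‖D‖₂² / μ ,

combining the logistic-Hessian bound with the smoothing constant; ‖·‖₂ is
computed by power iteration (tolerance 1e-8, deterministic start vector),
with exact SVDs reserved for tests. Momentum restarts whenever the smoothed
objective increases — a standard safeguard that does not affect the O(1/t²)
guarantee. Convergence is declared when the relative change of the smoothed
objective over a 5-iteration window falls below `tol`; the iterate with the
smallest smoothed objective is returned, and the reported final objective is
the exact (unsmoothed) F.

### Choosing μ and the accuracy/conditioning trade-off

Given a target accuracy δ, μ = δ/M makes the smoothing gap at most δ/2, so
the smoothed minimizer is within δ of the exact optimum and the iterates
satisfy F(β^(t)) − F(β**) ≤ δ + 2L‖β^(0)−β*‖₂²/t². The price is
conditioning: L grows as M/δ, so very small δ with sizeable λ_Sim makes the
fixed step tiny and progress slow. Defaults: δ = 1e-4 (high-accuracy
single fits, used by the solver-correctness tests); the benchmark suite
and cross-validation use δ = 0.1 with `max_iter` 600 (fold fits) / 3000
(final fits), which keeps every grid point's fit genuinely converged at the
grid's λ values. The δ = 0.1 surrogate behaves like a Huberized penalty;
the fused/fairness structure is preserved.

Initialization is deterministic and scale-free: zero slopes, intercepts at
each group's logit prevalence.

### Comparator estimators

* **sfm** — one shared coefficient vector under the fairness penalty, with
  an *unweighted* pooled likelihood (the weighted variant is available as an
  ablation flag). Same ASPG machinery with a single block.
* **separate** — K independent lasso logistic fits (mean loss, tied λ_Sp^k).
* **ignorant** — one pooled lasso logistic fit with K−1 reference-coded
  group indicators, penalized like any feature; its λ_Sp is on the raw
  pooled-mean-loss scale (not tied by √n_k).

With λ_F = λ_Sim = 0 the joint model decouples exactly into the separate
fits; with λ_F = 0 the sfm is a pooled lasso. Both reductions are verified
to 1e-4 relative objective against independent solvers.

## Cross-validation

Folds are stratified jointly on group and outcome class, so every training
split retains both classes in every group (required by the fairness penalty)
and every fold supports per-group AUCs; if a group×class cell is smaller
than the fold count, the fold count is reduced with a warning. Selection
criteria: harmonic mean of groupwise AUCs (default — robust to unbalanced
group sizes), arithmetic group mean, overall AUC, negated harmonic mean of
groupwise Brier scores, and group-mean AUC minus its disparity.

By default the criterion is computed once per grid point from the pooled
out-of-fold predictions of each group rather than averaged over per-fold
scores. With an under-represented group of ~50 rows, a per-fold AUC rests
on ~10 held-out rows and is dominated by noise; pooling uses all ~50
out-of-fold predictions. Per-fold averaging is available
(`pool_folds=False`). Ties break toward the smallest λ_F, then λ_Sim, then
λ_Sp. The default grid per active penalty is {0} ∪ logspace(−3, 1, 7);
the benchmark suite uses small explicit grids (see below).

## Synthetic benchmark scenarios

The generators emulate the two-group benchmark design: features iid N(0,1);
outcomes Bernoulli(σ(b_k + Xβ_k)); 40% of coefficients non-zero with value
3; a controllable fraction of the non-zero support shared between groups;
group 1 over-represented (n = 500, target prevalence 50%), group 2
under-represented (n = 200 by default, 30%); test sets of 1000 rows per
group; 20 replicates.

* **Scenario 1** sweeps the shared-support fraction 0–100% (p = 100).
* **Scenario 2** sweeps the under-represented group's n over 50–300.
* **Scenario 3** sweeps p (fixed 40-coordinate support, feasible for
  p ≥ 2·40 − shared; or a support proportional to p).

Design choices:

* Support placement is deterministic (first coordinates, then the next free
  ones), so truth metadata is stable across replicates; exchangeability of
  iid N(0,1) features makes this statistically equivalent to random
  placement.
* "Baseline event prevalence" is interpreted as the *marginal* event rate
  E_X[σ(b + Xβ)], not σ(b) at X = 0. The intercept solving
  E_X[σ(b + Xβ)] = target is found by bisection on a fixed 200,000-draw
  Monte-Carlo sample of Xβ ~ N(0, ‖β‖²); the achieved empirical prevalence
  is within half a percentage point of the target. (For β = 0 the exact
  logit is returned.)
* What the generator does **not** emulate: correlated or non-Gaussian
  features, coefficient heterogeneity beyond support differences,
  covariate shift between groups, and missingness. Passing benchmark tests
  therefore demonstrate the estimator's behavior under the idealized
  design, not on real EHR-like data.

The replicate runner cross-validates each estimator per replicate
(harmonic-AUC criterion for the fairness-aware models, group-mean AUC for
the separate model, overall AUC for the pooled model), fits on the full
training set, and evaluates per-group AUC, FPR/FNR, balanced accuracy,
Brier score, AUC disparity, coefficient MSE and support-recovery rates on
the held-out test sets, reporting medians and IQRs.

### Scaled-down test conditions

The packaged benchmark checks run at p = 50 (20 non-zero coefficients),
20 replicates, with explicit grids λ_F ∈ {0, 0.1},
λ_Sim ∈ {0, 0.1, 0.3, 1}, λ_Sp ∈ {0.25, 0.5, 1} (tied scale) and
{0.005, 0.02, 0.05, 0.1} for the pooled model's raw scale. These are the
package's benchmark presets; the estimators accept arbitrary grids.

## Numerical notes and limitations

* The AUC uses the Mann–Whitney midrank formulation (ties get half credit);
  the Brier score is normalized by n so folds of unequal size are
  comparable.
* The penalty operator is stored dense below 1e5 entries, sparse above;
  matrix-vector products agree to ~1e-12 relative, not bitwise.
* Selection of λ_Sim by cross-validation is reliable when group supports
  are fully shared, but with half-shared supports and a ~50-row group the
  held-out signal is comparable to its noise, and the fused model is chosen
  in roughly half the replicates; the joint model then simply matches the
  separate fits in the remainder.
* Large λ_Sim (≫ 1) with small δ is ill-conditioned for the smoothing
  algorithm: the coefficients stay tied (the penalty's subgradient dominates)
  but the common component converges slowly. The extreme-fusion reduction
  test asserts only the tie, which is the property the penalty enforces.
* K > 2 is supported by every estimator and penalty (all pairs j < k);
  benchmark presets are two-group designs.
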
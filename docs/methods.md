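# Methods

## Model

For standardized features Y (n × p) and intrinsic factors X (n × q) we model
Y | X ~ N(0, Ω(x)⁻¹), with constant diagonal ω_ii and off-diagonal entries
linear in the factors, ω_ij(x) = Σ_l β_ijl x_l. Node-wise (neighborhood)
regression makes estimation tractable: regressing y_i on the composite
regressors x_l ⊙ y_j gives coefficients θ_ijl with
γ_ij(x) = Σ_l θ_ijl x_l = −ω_ij(x)/ω_ii, so nonzero coefficients identify
conditional-dependence edges and their covariate modulation. The model has
no implicit intercept: a homogeneous analysis supplies a constant factor
column, a multi-group analysis supplies indicator columns, and continuous
factors enter as given (centering a factor changes the model space, so
`fit_graph` never standardizes factors unless asked to).

Sparsity: θ_k = b_k s_k with b_k | τ_l ~ N(0, τ_l⁻¹) (one slab precision per
factor), s_k ~ Bernoulli(π_k), π_k ~ Beta(a_π, b_π), τ_l ~ Gamma(a_τ, b_τ).
The noise precision ω_ii carries a flat improper prior, giving a conjugate
Gamma variational posterior with shape n/2 + 1 (the alternative reading — a
flat prior on the variance 1/ω_ii — would shift the shape by 2 and is
indistinguishable in practice at these n).

## Variational inference

We minimize KL(q ‖ posterior) under the factorization
q(b, s) q(ω) q(π) q(τ) with a joint per-coefficient factor q(b_k, s_k).
One CAVI sweep updates, in fixed order: every (b_k, s_k) pair jointly
(slab variance σ_k² = 1/(E[ω]‖z_k‖² + E[τ_l]); slab mean from the partial
residual; inclusion logit = E[log π/(1−π)] + ½(E[log τ_l] + log σ_k²)
+ μ_k²/(2σ_k²)), then q(τ_l) (moments of included coefficients weighted by
α), q(π_k) = Beta(a_π + α_k, b_π + 1 − α_k), and q(ω). The ELBO is evaluated
after each sweep and is non-decreasing (tested to 1e-6); convergence is
declared when |ΔELBO| < tol·(|ELBO| + 1) with tol = 1e-4 and a cap of 1000
sweeps. Sweeps use precomputed Gram matrices and rank-one residual updates,
with an optional numba kernel that mirrors the numpy arithmetic exactly.

**Initialization.** Two deterministic starts are run per node and the
fixed point with the higher ELBO is kept:

* *sparse*: α at the prior inclusion mean a_π/(a_π+b_π), μ = 0;
* *dense*: α = 0.95, μ at the unit-ridge estimate (Z'Z + I)⁻¹Z'y.

The dense start exists because greedy coordinate ascent from the sparse
start sees *marginal* evidence in its first sweep and can permanently adopt
a merely marginally-correlated proxy of a hub node's true neighbor
(explaining-away entrapment); starting from ridge means makes the first
sweep see partial evidence instead. Both runs are deterministic, so the
whole fit is bit-reproducible. In both starts the τ and π factors are
initialized at their coordinate updates given the initial coefficients
rather than at the raw prior values — a vague Gamma(0.005, 0.005) prior has
E[log τ] ≈ −195, which would freeze the fit in an all-spike state — keeping
E[τ] at the prior mean 1 for the sparse start. E[ω] starts at 1 (data are
standardized).

**Defaults.** a_τ = b_τ = 0.005, a_π = 1, b_π = 4 (prior inclusion odds
1:4), Bayesian-FDR level α = 0.01. These are used everywhere, including the
simulation harness; for dense-pathway analyses a_π = b_π = 0.05 raises the
prior inclusion probability to ½.

## Network construction

For an evaluation covariate x (original scale; mapped through any recorded
standardization): PIP(i,j | x) = Σ_l w_l α_l / Σ_l w_l with
w_l = (x_l μ_l)², defined as 0 when all weights vanish (no evidence at that
x — e.g. an indicator covariate that zeroes every active factor). The
partial correlation is ρ̂_ij(x) = Σ_l x_l α_l μ_l: substituting
β̂ = −ω̂_ii θ̂ into −Σ_l x_l E[β s]/ω_ii shows this is −ω̂_ij(x)/ω̂_ii on the
fitted scale, so its sign agrees with the true partial correlation (the
naive −Σ x αμ/E[ω] reading flips the sign). Values can exceed [−1, 1]
because the normalization uses ω_ii only, not √(ω_ii ω_jj); raw values are
reported, with clipping available for display. Undirected estimates average
the two directed estimates (a max rule is available); DAG estimates are
directed and unaveraged. Selection pools all (pair × covariate) records and
keeps the largest PIP-descending prefix whose mean (1 − PIP) ≤ α, so the
posterior-expected FDR of the reported set is ≤ α by construction.

## Simulated worlds

All generators are seeded and bit-reproducible; every stored precision
matrix is symmetric positive definite; Gaussian draws use the Cholesky
factor of the precision.

* **Multi-category** (N = 151, p = 33, 2–3 groups, 2% connectivity; low-dim
  variant n = 100, p = 20, 5%): group 1 is an Erdős–Rényi precision with
  connected weights Uniform(±[0.5, 1]) and unit diagonal, ridge-shifted by
  0.1·I until PD; each later group swaps 3 edges in and 3 out. N splits
  76/75 (or 51/50/50). Group indicators only, no intercept.
* **Continuous** (N = 151, p = 33, q = 2 Uniform(−1, 1) factors): 2% of
  feature pairs carry a ±1 coefficient on one uniformly chosen factor;
  subject precisions Ω_n = I + Σ_l β_l x_nl are redrawn wholesale until PD
  for *every* subject. Joint PD effectively forces the support to be a
  node-disjoint matching (a node with two covariate-driven edges fails PD
  for some subject with overwhelming probability), which is why the density
  is defined per pair rather than per coefficient slot; the redraw cap is
  200,000 (~8,000 expected redraws at p = 33).
* **Homogeneous** (N = 151, p = 33, 2%): one Erdős–Rényi precision,
  i.i.d. samples, intercept-only factor — the positive control.
* **DAG** (p = 50, q = 2, effect 3): continuous factors Uniform(0, 1),
  discrete ones Bernoulli(0.5) (70% continuous when q is large); per factor
  2% of ancestor pairs (j < i) get coefficient 3; node i is drawn around the
  covariate-modulated sum of its *standardized* ancestors with unit noise.
* **Simpson's paradox** (n = 200, 3 nodes, 2 groups): group 1 has
  ω_12 ∈ [0.5, 1], ω_13 ∈ [−1, −0.5]; group 2 reverses the roles; both
  redrawn until PD. Emitted with group indicators and an intercept-only
  variant for the pooled fit.

What the generators do **not** emulate: real RPPA/expression noise and
batch structure, non-Gaussian margins, missing data, unknown group labels,
spatial count noise. A green benchmark therefore certifies structure
recovery under the stated Gaussian worlds, not performance on raw
measurements.

## Evaluation conventions

TPR, FPR, FDR and MCC use the standard formulas with FDR = 0 when nothing
is selected and MCC = 0 when its denominator vanishes. AUC is the
Mann–Whitney rank statistic of PIPs against true edges (ties ½), equal to
the threshold-swept ROC area. Continuous and DAG scenarios are scored per
subject (a subject's true edge set is the support of Σ_l β_ijl x_l) and
averaged; subjects whose true graph is empty — possible with discrete
factors at x = 0, where the PIPs are also identically zero — are skipped,
as are degenerate subjects in AUC. Multi-category scenarios report both
pooled-across-groups metrics (primary) and per-group averages.

## Numerical choices and edge cases

* Standardization uses the sample (n−1) deviation; zero-variance
  non-exempt columns raise a degenerate-input error naming the column.
* A DAG's first node has a valid zero-regressor design; its ELBO is the
  closed-form Gaussian-residual term plus the Gamma entropy of q(ω).
* Non-finite variational updates raise a numerical-failure error carrying
  the coefficient index; non-convergence at max_iter sets a flag instead of
  raising.
* Logistic and digamma evaluations are saturating rather than overflowing;
  α log α terms use the 0·log 0 = 0 convention.
* Ties in the FDR prefix rule resolve by stable descending sort; lowering α
  can only remove edges.
* Tables round-trip at 17 significant digits (`float_precision="round_trip"`
  on read), so write-then-read is bit-lossless.

## Known limitations

Edge strengths are linear in the factors; smooth non-linear modulation
(e.g. Gaussian-process effects) is out of scope. Estimated Ω(x) is
symmetric by averaging but not projected to positive definiteness.
Inference is a mean-field approximation: inclusion probabilities can be
overconfident relative to exact posteriors even though their ranking
matches exhaustive enumeration on small problems (tested to 2^m
configurations, m ≤ 10). Only complete cases are accepted.
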
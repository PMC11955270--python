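# graphreg

Covariate-dependent Gaussian graphical models via spike-and-slab
variational Bayes.

## The problem

Gaussian graphical models (GGMs) infer conditional-dependence networks
between molecular features (genes, proteins) from the zeros of the precision
matrix Ω of a multivariate Gaussian. Standard GGMs assume every sample comes
from one homogeneous population — an assumption that fails badly for tumor
subtypes, continuous dedifferentiation gradients, or spatially resolved
tissue, where conditioning on the wrong population can reverse associations
outright (Simpson's paradox). `graphreg` is for analysts of -omics data who
need **group-, subject- or location-specific networks** with uncertainty
quantification, at variational-Bayes speed rather than MCMC cost.

## The model

Let Y ∈ ℝ^{n×p} be standardized feature measurements and X ∈ ℝ^{n×q}
sample-level *intrinsic factors* (group indicators, continuous indices,
spatial coordinates). The precision matrix is allowed to vary with x:
Y | X ~ N(0, Ω(x)⁻¹) with ω_ii constant and off-diagonals linear in x.
Node-wise regression turns this into p sparse regressions

    y_i = Σ_{j≠i} γ_ij(X) ⊙ y_j + ε_i,
    γ_ij(x) = Σ_{l=1}^{q} θ_ijl x_l = −ω_ij(x)/ω_ii,
    ε_i ~ N(0, 1/ω_ii),

with a spike-and-slab prior on each composite coefficient
θ_ijl = b s, b | τ_l ~ N(0, τ_l⁻¹), s ~ Bernoulli(π), π ~ Beta(a_π, b_π),
τ_l ~ Gamma(a_τ, b_τ), and a flat prior on ω_ii. Inference is
coordinate-ascent mean-field variational Bayes with a joint (b, s) factor
per coefficient; the ELBO is monotone and every fit is deterministic.

Networks are read off at any evaluation covariate x: the edge PIP is a
weighted mean of the per-factor inclusion probabilities with weights
(x_l E[b_ijl])², the partial correlation is the covariate-modulated
coefficient Σ_l x_l E[b_ijl s_ijl], and edges are selected by a Bayesian FDR
rule (largest PIP-ranked set whose mean posterior false-edge probability
stays below α). A DAG mode restricts each node's regressors to its
predecessors under a known ordering. Downstream summaries include
connectivity degrees, pathway connectivity scores, and PIP-weighted regional
summaries for spatial data.

## Worked example

Two tumor groups (n = 151, p = 33) whose true graphs differ by a three-edge
swap; fit with group indicators and build one network per group:

```python
import numpy as np
import graphreg as gr

ds = gr.simulate_multicategory(n=151, p=33, groups=2, conn_prob=0.02, seed=1)
fit = gr.fit_graph(ds.Y, ds.X)                       # p node-wise VB fits
net = gr.build_network(fit, np.eye(2), alpha=0.01,   # one row per group
                       covariate_ids=["group1", "group2"])
sel = net.table[net.table["selected"]]
print(f"selected {len(sel)} of {len(net.table)} edge records "
      f"(PIP threshold {net.threshold:.3f})")
print(sel.sort_values("pip", ascending=False).head(5).to_string(index=False))
res = gr.evaluate_dataset(ds, fit, alpha=0.01)
print(f"MCC={res['mcc']:.3f}  AUC={res['auc']:.3f}  "
      f"TPR={res['tpr']:.3f}  FDR={res['fdr']:.3f}")
```

prints

```
selected 21 of 1056 edge records (PIP threshold 0.887)
  i   j covariate  pip  partial_correlation  selected
V22 V25    group2  1.0             0.449617      True
V12 V25    group2  1.0            -0.651114      True
V13 V22    group1  1.0             0.803124      True
V12 V31    group1  1.0            -0.746560      True
V12 V25    group1  1.0            -0.659241      True
MCC=0.929  AUC=0.999  TPR=0.909  FDR=0.048
```

Each record is one unordered feature pair evaluated at one group's
covariates: `pip` is its posterior inclusion probability there, the signed
`partial_correlation` its conditional association, and `selected` marks the
edges surviving the 1% Bayesian-FDR cutoff. Against the known ground truth
this replicate recovers 90.9% of true edges with 4.8% false discoveries
(MCC 0.93). The same pipeline resolves Simpson's paradox: on
`gr.simpsons_demo(seed=3)` the group-aware fit reports A–B partial
correlations −0.51 and +0.55 in the two groups while the pooled
intercept-only fit collapses to 0.36.

The command line mirrors the library:

```sh
graphreg simulate --scenario multicategory --seed 1 --outdir out/
graphreg fit --features out/features.csv --factors out/factors.csv --outdir out/
graphreg network --fit-file out/graph_fit.json --covariates out/factors.csv --alpha 0.01 --outdir out/
graphreg replicate --scenario homogeneous --reps 50 --outdir out/
```

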
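# cellgp

Gaussian-process latent variable modelling, spatial differential
expression and dynamic eQTL mapping for single-cell transcriptomics.

## The problem

Plate-based single-cell experiments that profile a response — for example
fibroblasts stimulated with a viral mimic and an interferon, sampled at
several time points across many donors — mix the biology of interest with
cell-cycle phase, plate and batch effects, and donor identity.  `cellgp`
is for analysts who want to (1) extract a *target cell state* that is
purged of those confounders, (2) classify genes by how their expression
moves over that state and read off pseudotimes for each response
programme, (3) test whether a donor's genotype shifts a gene's expression
*and whether that shift itself changes along the response* (dynamic
eQTLs), and (4) control FDR hierarchically and colocalize the resulting
signals with GWAS traits — all against donor-resolved genotypes.

## The model

Log-expression of gene *j* across *N* cells follows

```
y_j      ~ N(alpha_j + Z gamma_j,  sigma_j^2 Omega)
alpha_j  ~ N(0,  sigma_j^2 K_theta ∘ K_B ∘ K_X)
gamma_j  ~ N(zeta,  sigma_j^2 Delta)
```

where `K_theta` is a periodic kernel over the cell-cycle angle theta
(period 2π), `K_B` and `K_X` are squared-exponential kernels over
unknown-batch coordinates B and the target cell state X, `∘` is the
entrywise product, Z holds known covariates (donor, plate), and
`Omega = diag(omega_i)` is cell-specific residual variance.  Latents and
hyperparameters are estimated by L-BFGS on a sparse inducing-point lower
bound of the marginal likelihood (exact when inducing points = cells).

On the fitted state, downstream analyses freeze the GPLVM estimates:

- **Spatial DE / pseudotime** — a K-component mixture of GPs
  `y_j ~ N(alpha_j + delta_jk beta_k + Z gamma_j, sigma_j^2 Omega)` with
  `beta_k ~ N(0, K_X)` and loading `delta_jk ~ N(0,1)`; one component is
  pinned at `beta = 0` for pattern-free genes, and the fitted `beta_k`
  curves are the pseudotimes.
- **eQTL mapping** — for variant dosages `g_l`, the alternative model adds
  `beta_jl ∘ g_l` with `beta_jl ~ N(0, delta_g^2 sigma_jl^2 (11' + K_X))`
  (`delta_g = 0.1`), giving a closed-form Bayes factor per gene–variant
  pair and a per-cell posterior effect-size curve; an optional
  context-by-donor GP (scale `delta_dxc`, estimated under the null)
  absorbs donor-specific trajectories.
- **Hierarchical FDR** — variant log BFs in a 1-Mb cis window (MAF >
  0.05) are combined with a softmax prior (exponential TSS-distance decay
  plus annotation log-odds) fitted by empirical-Bayes EM; genes are called
  at local FDR, with 2×2 pseudo-count enrichment statistics.
- **Colocalization** — five hypotheses (no signal / study-1 / study-2 /
  both-distinct / shared variant) scored by regional Bayes factors with
  fixed priors {Π1, Π2, Ψ12} = {0.2, 0.05, 0.01} for GWAS traits
  (Wakefield approximate BFs) or EM-estimated priors for study pairs.

## Worked example

```python
import numpy as np
from cellgp import GPLVM, GplvmConfig, GPMixture, MixtureConfig, EqtlScan
from cellgp.synthetic_data import SimConfig, simulate_dataset, broadcast_dosage

# a small stimulation experiment: 20 donors x 20 cells, 200 genes,
# two response branches, one planted static eQTL per 10 genes
cfg = SimConfig(n_donors=20, cells_per_donor=20, n_genes=200,
                frac_eqtl_static=0.1, seed=0)
Y, Z, genotypes, truth = simulate_dataset(cfg)

fit = GPLVM(Y, Z, GplvmConfig(n_inducing=30, d_X=2, d_B=1, seed=0)).fit()
print(fit.summary())

mix = GPMixture(Y - Y.mean(0), fit.context(),
                config=MixtureConfig(K=3, seed=0)).fit()
print(mix.summary())

scan = EqtlScan(Y - Y.mean(0), fit.context(), gene_ids=list(truth.gene_ids))
gene, variant = truth.eqtl_table.iloc[0][["gene", "variant"]]
g = broadcast_dosage(genotypes[variant].to_numpy(), truth.donor)
res = scan.log_bf(list(truth.gene_ids).index(gene), g, variant)
print(f"{gene} x {variant}: log BF = {res.log_bf:.2f}")
```

prints

```
GPLVM (sparse bound) results
========================================
cells: 400   genes: 200   inducing: 30
d_X: 2   d_B: 1   kernel: product
final bound: -117168.5616   iterations: 83
lengthscales  theta: 8579.172  B: 4.159  X: 1.909
GP amplitude v: 0.5336
variance shares  GP: 0.308  random effect: 0.132  residual: 0.560
wall time: 9.6s
GP mixture results
========================================
components: 3 (component 0 pinned at 0)
weights: 0.495  0.259  0.245
labels:  component-1=45  component-2=43  stationary=112
final log-likelihood: -117613.970 (19 EM iterations)
g0012 x g0012_v0: log BF = 4.83
```

The GP explains ~31% of variance (the planted trajectory and cell-cycle
structure), the mixture recovers the two planted response programmes (45
and 43 genes against 40 planted each, the rest stationary), and the
planted eQTL gets log BF ≈ 4.8 while the same variant against a gene with
no planted effect gives log BF ≈ −0.2.

A `cellgp` command-line tool chains the stages on disk artifacts:
`simulate → qc → fit-latent → classify-genes → map-eqtl → fdr → coloc`
(see `cellgp --help`).

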
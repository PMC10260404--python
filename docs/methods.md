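# Methods

## Model

`cellgp` treats a cells × genes matrix of log-normalised expression
(logCPM; genes mean-centred by default) as J independent draws from a
shared-covariance Gaussian model.  For gene *j*,

    y_j ~ N(Z ζ, σ_j² (K_θ ∘ K_B ∘ K_X + Z Δ Zᵀ + Ω)),

obtained by integrating a baseline GP α_j (cell cycle × unknown batch ×
target state) and a covariate random effect γ_j ~ N(ζ, σ_j²Δ)
analytically.  The periodic kernel over the cell-cycle angle uses the
exp-sine-squared form with the period fixed at 2π; the batch and target
kernels are squared-exponential (ARD optional).  Kernel amplitudes are
identifiable only through their product in the entrywise kernel, so the
implementation carries a single GP amplitude `v_gp` (attached to K_X) and
fixes the θ and B variances at one.  A `linear` kernel mode replaces the
product kernel by X Xᵀ without the cell-cycle factor, for very large
datasets where the full model is too slow; since that covariance is
already low-rank the exact marginal is used there.

### Sparse bound

Only the GP term is approximated.  With inducing inputs u in the joint
latent space and Q = K_nm K_mm⁻¹ K_mn,

    bound_j = log N(y_j | Zζ, σ_j²(Q + A)) − ½ tr(A⁻¹ (K_nn − Q)),

where A = ZΔZᵀ + Ω is the exact integrated noise.  This generalises the
classical inducing-point bound to correlated Gaussian noise; the
gene-specific scale σ_j² cancels in the trace.  The tests verify the two
defining properties directly against the dense marginal: the bound never
exceeds it, and at inducing points = cells the gap is below 10⁻⁶ per
gene.  Jitter of 10⁻⁶ × amplitude is added to K_mm before factorisation
(kept proportional to the amplitude so gradients stay exact).

### Optimisation

All free quantities — ζ, log Δ, log Ω (floored at 10⁻³), log Σ, kernel
log-lengthscales and log-amplitude, the latents (θ wrapped mod 2π, B, X)
and the inducing inputs — are packed into one vector and optimised by
L-BFGS with fully analytic gradients (finite-difference-checked to 10⁻⁴
relative error in the tests).  X and B initialise from principal
components of the covariate-residualised matrix, θ uniformly at random
from the seed, inducing points from k-means in the initial latent space,
lengthscales from the median-distance heuristic.  A short warm-start
stage (50 iterations) updates hyperparameters with latents frozen before
the joint stage; convergence is relative objective change < 10⁻⁶ or
`max_iter` (default 2,000; the bundled analyses use 300, which the
objective traces show is past the knee at these sizes).

## Spatial DE mixture and pseudotime

Conditional on the GPLVM estimates, gene j in component k has marginal
covariance σ_j²(K_θ∘K_B + β_kβ_kᵀ + A): the target-state kernel is
excluded from the baseline and the shared pattern β_k enters as a
rank-one term because its per-gene loading δ_jk ~ N(0,1) integrates
analytically.  Component likelihoods therefore cost one shared
factorisation plus a rank-one Woodbury update (oracle-checked against
dense evaluation).  EM alternates responsibilities with closed-form
weights and a penalised update of each β_k, represented at the GPLVM
inducing points with prior b_k ~ N(0, K_mm) and interpolated to cells by
the GP mean map.  One component is pinned at β = 0 so pattern-free genes
have an explicit home (with K = 3 this reproduces a
primary/secondary/stationary split).  After EM, any free component whose
likelihood column is indistinguishable from the pinned one (mean absolute
log-likelihood difference < 1 nat across genes) is merged into it;
without the merge, near-zero patterns split stationary genes arbitrarily.
Five random restarts are run and the best penalised likelihood kept.
The reported pseudotime is the fitted β_k curve — the penalised-likelihood
(MAP) estimate of the pattern GP, which for this Gaussian model coincides
with the posterior mean/mode of the pattern given the data.

## eQTL Bayes factors

Dosages are donor-level, broadcast to cells.  The alternative covariance
adds δ_g²(11ᵀ + K_X) ∘ (g gᵀ) — a constant (static) effect component plus
a smoothly varying (dynamic) one — with δ_g = 0.1 by default.  The
residual scale σ_jl² is profiled per model (the closed-form MLE of an
overall covariance scale), so the log Bayes factor is a difference of two
profile log-likelihoods.  Each variant costs a rank-(r+1) Woodbury update
of the shared null factorisation, r being the numerical rank of K_X
(eigenvalues above 10⁻¹⁰ of the largest); the dense path is retained as
the test oracle (agreement to 10⁻⁶ in log space).  Monomorphic dosages
return log BF = 0 exactly, with a warning unless the vector is all zero.
Missing genotypes are mean-imputed per variant at VCF reading.

The context-by-donor GP (δ_dxc² K_X masked to donor blocks) can be added
to both null and alternative.  Its scale is estimated once, under the
genotype-free model across all genes, jointly re-profiling the baseline
GP amplitude: a fixed amplitude that misfits the data otherwise leaks
systematically into the donor-context component (observed as an upward
bias of ≈0.1 on null data); with joint profiling the null estimate hits
the zero boundary.  Effect-size curves are the closed-form Gaussian
posterior mean E[β_jl | y_j], reported at every cell.  Called eQTLs are
classified static vs pattern-k by a small mixture whose genetic-prior
kernels are 11ᵀ (static) and β_kβ_kᵀ for each fitted response pattern
(normalised to comparable scale), with EM weights and a 0.9 posterior
threshold.

## Hierarchical FDR and enrichment

Windows hold variants with MAF strictly above 0.05 within ±500 kb of the
TSS (1-based VCF coordinates, strand ignored).  The variant-level prior
is softmax(−λ·|distance| + aᵀ·annotations) within each window; the gene
is an eQTL with scalar prior Π (no gene-level covariates).  EM maximises
Σ_j log((1−Π) + Π Σ_l p_l BF_jl) — vectorised over a flattened variant
array with segment reductions — giving gene posteriors Z_j, within-gene
variant posteriors Z_jl (summing to one) and updates of (Π, λ, a) by a
weighted softmax fit.  Genes are called when Z_j > 1 − q (strict, written
this way so round decimal boundaries behave exactly); lead variants are
the Z_jl argmax with ties broken by TSS proximity then lexicographic id.
Enrichment uses the soft 2×2 pseudo-count table, Woolf log-odds ratio,
variance as the sum of reciprocal cells, and χ² = r²/Var; a Haldane 0.5
is added to all cells only when any cell is below 0.5, and flagged.
Stratified enrichment splits genes into quantile bins of the confounder,
drops degenerate bins (counted), and combines the rest by inverse
variance.

## Colocalization

Per-variant Bayes factors (from the eQTL scan, or Wakefield's
approximation for GWAS summary statistics with default prior variance
W = 0.04) are combined into regional BFs with uniform variant weights by
default (the hierarchical prior can be injected).  RBF_H3 is taken as the
product RBF_H1·RBF_H2 without excluding the same-variant term — the
standard independent-causal-variant approximation, adequate when windows
hold many variants.  Fixed priors {0.2, 0.05, 0.01} (which put exactly
zero prior mass on H3) are used for GWAS traits; for study pairs the
five hypothesis priors are EM-estimated on the probability simplex and
reported as Π1 = p1+p3+p4, Π2 = p2+p3+p4, Ψ12 = p4.  The simplex
parameterisation, rather than the constrained three-parameter map, is
used for estimation because the constraint Ψ12 ≤ Π1Π2 cannot represent
strongly coupled sharing (e.g. 30% shared signals with Π1Π2 ≈ 0.12).

## Synthetic data

The generator emulates a plate-based multi-donor stimulation time course:
five conditions (an unstimulated origin plus two stimulants × two time
points) place each cell on one of two smooth branches (tanh progression
with jitter) in a 2-D latent state; cell-cycle angles are uniform;
donor and plate effects are Gaussian with standard deviations 0.3;
response genes carry signed loadings of 0.6–1.4 × the pattern scale
(default 2, about twice the residual noise sd, so planted structure is
comfortably detectable at desk scale); 30% of genes get a sinusoidal
cell-cycle term (amplitude 0.5); noise is heteroscedastic across cells
(×0.7–1.4) and genes (sd 0.7–1.3).  Genotypes are Binomial(2, MAF) per
donor with MAF ~ U(0.1, 0.5); planted eQTLs add b·g (static) or
b·g·f_branch (dynamic) with |b| ≈ the eQTL scale.  Every component can be
switched off; an ablation mode replaces the parametric patterns with
model-exact GP draws α_j ~ N(0, σ_j² K_X) (used where an estimator, such
as δ_dxc, is only consistent when the generative process matches the
model term-for-term).  Matched GWAS summary statistics come from
single-variant least squares on an independently simulated quantitative
trait (shared / distinct / null causal variant); Bayes-factor windows for
the hierarchical model draw effects from the Wakefield prior so that
posteriors are exactly calibrated by construction.

What the generator does *not* emulate: count-level dropout and
amplification noise (an optional Poisson count emission exists only to
exercise QC filters), linkage disequilibrium beyond independent variants,
and doublets.  Passing tests therefore demonstrate correctness of the
inference machinery under the model's assumptions and robustness to the
mild parametric-vs-GP mismatch of the pattern emission — not robustness
to real scRNA-seq artefacts.

## Problem sizes and numerical choices

The bundled checks use 400 cells × 200 genes (8 donors, 4 plates) for
latent recovery, 60 donors × 20 cells for eQTL power/calibration,
30 donors × 15 cells for donor-context recovery, 2,000 genes × 40
variants for the hierarchical model, and 100-variant regions for
colocalization — sizes at which every planted property is comfortably
identifiable while a full run stays around a minute.  d_X = 2 is used for
the two-branch data (the planted state is two-dimensional); the library
default is d_X = 10.  Degenerate inputs are handled explicitly:
monomorphic variants (BF ≡ 0), empty cis windows (flagged), empty mixture
components (clamped with a warning), boundary prior estimates in the
coloc EM (clamped), all-degenerate enrichment bins (error).

## Known limitations

- The GPLVM objective is non-convex; recovery depends on the PCA
  initialisation, and latent rotations are only identified up to
  orthogonal transforms (recovery is measured after Procrustes
  alignment).
- Per-test residual profiling makes Bayes factors slightly conservative
  rather than exactly calibrated.
- With few donors, static eQTL effects are partially confounded with the
  donor random effect (both are donor-constant); power calculations
  should count donors, not cells.
- Stochastic variational or GPU acceleration is out of scope; the dense
  N×N algebra caps practical problem sizes at a few thousand cells in
  product-kernel mode (the linear mode scales further).
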
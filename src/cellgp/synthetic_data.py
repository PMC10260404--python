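"""Synthetic multi-donor, multi-plate, multi-condition single-cell data.

Emulates a stimulation time-course: cells from several donors are spread
over plates and conditions (an unstimulated state plus two stimulants, each
sampled at an early and a late time point), giving a two-branch response
trajectory from a shared origin.  Expression is generated term-for-term
from the assumptions of the inference models:

    y_ij = loading_j * f_branch(t_i) + a_j sin(theta_i + phase_j)
           + z_i' gamma_j + b_j g_l(i) [* f(t_i)] + eps_ij

with a uniform cell-cycle angle theta, donor/plate random effects gamma_j,
planted static or trajectory-modulated (dynamic) cis-eQTLs, and
heteroscedastic Gaussian noise.  Donor genotypes are Binomial(2, MAF).
Every variance component can be switched off independently.

Also provided: matched GWAS summary statistics (shared / distinct / null
causal variant), Bayes-factor cis windows with a planted TSS-distance
decay for the hierarchical model, and binomial allele-specific expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gplvm import CellStateContext

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_dataset",
    "simulate_summary_stats",
    "simulate_ase",
    "simulate_bf_windows",
    "truth_context",
    "broadcast_dosage",
]

#: binomial ASE success probabilities for genotypes 0/1/2
ASE_P = (0.01, 0.5, 0.99)

DEFAULT_CONDITIONS = ("naive", "stimA-2h", "stimA-6h", "stimB-2h",
                      "stimB-6h")


@dataclass
class SimConfig:
    """Study-design and effect-size knobs of the generator.

    Defaults emulate a desk-scale version of a multi-donor plate-based
    stimulation experiment: 8 donors x 50 cells on 4 plates across five
    conditions, 200 genes of which 20% follow each response branch, with
    response effects of about twice the residual noise so that planted
    structure is comfortably detectable.
    """

    n_donors: int = 8
    cells_per_donor: int = 50
    n_genes: int = 200
    n_plates: int = 4
    conditions: tuple = DEFAULT_CONDITIONS
    frac_pattern1: float = 0.2
    frac_pattern2: float = 0.2
    # eQTL gene fractions (of n_genes); the rest carry no genetic effect
    frac_eqtl_static: float = 0.0
    frac_eqtl_dynamic1: float = 0.0
    frac_eqtl_dynamic2: float = 0.0
    variants_per_gene: int = 1
    pattern_scale: float = 2.0
    eqtl_scale: float = 1.0
    cellcycle_scale: float = 0.5
    frac_cellcycle_genes: float = 0.3
    donor_sd: float = 0.3
    plate_sd: float = 0.3
    noise_sd: float = 1.0
    delta_dxc: float = 0.0
    maf_range: tuple = (0.1, 0.5)
    heteroscedastic: bool = True
    #: when positive, add model-exact baseline GP draws
    #: alpha_j ~ N(0, scale^2 sigma_j^2 K_X) instead of relying solely on
    #: the parametric branch patterns (used for ablation checks where the
    #: generative process must match the inference model term-for-term)
    gp_baseline_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_pattern1 + self.frac_pattern2 > 1:
            raise ValueError("pattern fractions exceed 1")
        if (self.frac_eqtl_static + self.frac_eqtl_dynamic1
                + self.frac_eqtl_dynamic2) > 1:
            raise ValueError("eQTL fractions exceed 1")
        if self.n_donors < 1 or self.cells_per_donor < 1 \
                or self.n_genes < 1:
            raise ValueError("counts must be positive")


@dataclass
class SimTruth:
    """Ground truth paired with a simulated dataset."""

    X: np.ndarray                 # true 2-D latent state per cell
    branch: np.ndarray            # 0 = origin, 1, 2
    t: np.ndarray                 # progression along the branch
    pseudotime1: np.ndarray       # response-1 curve evaluated per cell
    pseudotime2: np.ndarray
    theta: np.ndarray
    donor: np.ndarray
    plate: np.ndarray
    condition: np.ndarray
    gene_labels: np.ndarray       # flat / pattern1 / pattern2
    gene_ids: np.ndarray
    eqtl_table: pd.DataFrame      # gene, variant, pattern, scale
    genotypes: pd.DataFrame       # donors x variants (dosage 0/1/2)
    variant_mafs: pd.Series
    sigma: np.ndarray             # per-gene noise sd
    omega: np.ndarray             # per-cell variance multipliers
    gamma: np.ndarray             # covariate effects (P x J)
    Z: np.ndarray
    design_labels: list
    delta: np.ndarray             # per-column random-effect variances
    delta_dxc: float = 0.0


def _response_curves(t: np.ndarray, branch: np.ndarray):
    """Smooth monotone response profiles for the two branches."""
    f1 = np.where(branch == 1, np.tanh(1.5 * t), 0.0)
    f2 = np.where(branch == 2, np.tanh(1.5 * t), 0.0)
    return f1, f2


def simulate_dataset(config: SimConfig | None = None):
    """Generate (Y, Z, genotypes, truth) for the full pipeline.

    Returns
    -------
    Y : (n_cells, n_genes) log-scale expression
    Z : (n_cells, P) design of donor + plate indicators
    genotypes : DataFrame donors x variants
    truth : SimTruth
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_donors * cfg.cells_per_donor
    j = cfg.n_genes

    donor = np.repeat(np.arange(cfg.n_donors), cfg.cells_per_donor)
    plate = rng.integers(0, cfg.n_plates, size=n)
    condition = np.array([cfg.conditions[i % len(cfg.conditions)]
                          for i in rng.permutation(n)])

    # trajectory: condition -> branch and nominal progression
    branch = np.zeros(n, dtype=int)
    t = np.zeros(n)
    for i, c in enumerate(condition):
        if c == "naive" or c == cfg.conditions[0]:
            branch[i], t[i] = 0, 0.0
        else:
            idx = list(cfg.conditions).index(c)
            branch[i] = 1 if idx in (1, 2) else 2
            t[i] = 0.5 if idx in (1, 3) else 1.0
    t = np.clip(t + rng.uniform(-0.2, 0.2, size=n), 0.0, 1.3)
    t[branch == 0] = 0.0

    # latent 2-D state: two gently curved branches from the origin
    x_true = np.zeros((n, 2))
    m1, m2 = branch == 1, branch == 2
    x_true[m1, 0] = 2.0 * t[m1]
    x_true[m1, 1] = 0.4 * np.sin(2.0 * t[m1])
    x_true[m2, 1] = 2.0 * t[m2]
    x_true[m2, 0] = 0.4 * np.sin(2.0 * t[m2])
    x_true += 0.05 * rng.standard_normal((n, 2))

    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    f1, f2 = _response_curves(t, branch)

    # gene assignment
    n_p1 = int(round(cfg.frac_pattern1 * j))
    n_p2 = int(round(cfg.frac_pattern2 * j))
    gene_labels = np.array(["flat"] * j, dtype=object)
    perm = rng.permutation(j)
    gene_labels[perm[:n_p1]] = "pattern1"
    gene_labels[perm[n_p1:n_p1 + n_p2]] = "pattern2"
    gene_ids = np.array([f"g{k:04d}" for k in range(j)])

    # design: donor + plate indicator blocks
    z_donor = np.eye(cfg.n_donors)[donor]
    z_plate = np.eye(cfg.n_plates)[plate]
    z = np.column_stack([z_donor, z_plate])
    labels = [f"donor_{d}" for d in range(cfg.n_donors)] + \
        [f"plate_{p}" for p in range(cfg.n_plates)]
    delta = np.concatenate([
        np.full(cfg.n_donors, cfg.donor_sd**2),
        np.full(cfg.n_plates, cfg.plate_sd**2)])
    gamma = rng.standard_normal((z.shape[1], j)) * np.sqrt(delta)[:, None]

    sigma = cfg.noise_sd * rng.uniform(0.7, 1.3, size=j)
    omega = rng.uniform(0.7, 1.4, size=n) if cfg.heteroscedastic \
        else np.ones(n)

    y = z @ gamma
    # response patterns: signed loadings bounded away from zero
    loading = (rng.choice([-1.0, 1.0], size=j)
               * rng.uniform(0.6, 1.4, size=j) * cfg.pattern_scale)
    y += np.where(gene_labels == "pattern1", loading, 0.0)[None, :] \
        * f1[:, None]
    y += np.where(gene_labels == "pattern2", loading, 0.0)[None, :] \
        * f2[:, None]
    # cell cycle on a random subset of genes
    cc_genes = rng.random(j) < cfg.frac_cellcycle_genes
    phase = rng.uniform(0, 2 * np.pi, size=j)
    y += cfg.cellcycle_scale * cc_genes[None, :] \
        * np.sin(theta[:, None] + phase[None, :])

    # genotypes: one window of independent variants per gene
    nv = cfg.variants_per_gene
    variant_ids = np.array([f"g{k:04d}_v{l}" for k in range(j)
                            for l in range(nv)])
    mafs = rng.uniform(*cfg.maf_range, size=j * nv)
    geno = rng.binomial(2, mafs[None, :], size=(cfg.n_donors, j * nv))
    genotypes = pd.DataFrame(
        geno, index=[f"donor_{d}" for d in range(cfg.n_donors)],
        columns=variant_ids)
    variant_mafs = pd.Series(mafs, index=variant_ids)

    # planted eQTLs
    n_s = int(round(cfg.frac_eqtl_static * j))
    n_d1 = int(round(cfg.frac_eqtl_dynamic1 * j))
    n_d2 = int(round(cfg.frac_eqtl_dynamic2 * j))
    eperm = rng.permutation(j)
    eqtl_rows = []
    for rank, gi in enumerate(eperm[:n_s + n_d1 + n_d2]):
        pattern = ("static" if rank < n_s
                   else "dynamic1" if rank < n_s + n_d1 else "dynamic2")
        vid = f"g{gi:04d}_v0"
        g_cells = geno[donor, list(variant_ids).index(vid)].astype(float)
        b = cfg.eqtl_scale * rng.choice([-1.0, 1.0]) \
            * rng.uniform(0.8, 1.2)
        if pattern == "static":
            y[:, gi] += b * g_cells
        elif pattern == "dynamic1":
            y[:, gi] += b * g_cells * f1
        else:
            y[:, gi] += b * g_cells * f2
        eqtl_rows.append((gene_ids[gi], vid, pattern, b))
    eqtl_table = pd.DataFrame(
        eqtl_rows, columns=["gene", "variant", "pattern", "scale"])

    # model-exact baseline GP (ablation mode)
    if cfg.gp_baseline_scale > 0:
        from .kernels import KernelSpec, se_kernel
        kx0 = se_kernel(x_true, x_true, KernelSpec(
            "squared_exponential", 1.0, 1.0))
        l0 = np.linalg.cholesky(kx0 + 1e-8 * np.eye(n))
        y += cfg.gp_baseline_scale * sigma[None, :] * (
            l0 @ rng.standard_normal((n, j)))

    # donor-specific response GPs (context-by-donor effect):
    # f_ij ~ N(0, delta_dxc^2 sigma_j^2 K_X o S) with S the donor blocks
    if cfg.delta_dxc > 0:
        from .kernels import KernelSpec, se_kernel
        kx = se_kernel(x_true, x_true, KernelSpec(
            "squared_exponential", 1.0, 1.0))
        kdxc = kx * (donor[:, None] == donor[None, :])
        l_dxc = np.linalg.cholesky(kdxc + 1e-8 * np.eye(n))
        y += cfg.delta_dxc * sigma[None, :] * (
            l_dxc @ rng.standard_normal((n, j)))

    y += sigma[None, :] * np.sqrt(omega)[:, None] \
        * rng.standard_normal((n, j))

    truth = SimTruth(
        X=x_true, branch=branch, t=t, pseudotime1=f1, pseudotime2=f2,
        theta=theta, donor=donor, plate=plate, condition=condition,
        gene_labels=gene_labels, gene_ids=gene_ids, eqtl_table=eqtl_table,
        genotypes=genotypes, variant_mafs=variant_mafs, sigma=sigma,
        omega=omega, gamma=gamma, Z=z, design_labels=labels, delta=delta,
        delta_dxc=cfg.delta_dxc)
    return y, z, genotypes, truth


def assign_coordinates(truth: SimTruth, seed: int = 0,
                       mito_frac: float = 0.02):
    """Invent genomic coordinates for the simulated genes and variants.

    Genes are spaced 2 Mb apart along one chromosome (so cis windows do not
    overlap), each gene's variants fall within +-400 kb of its TSS, and a
    small fraction of genes is placed on the mitochondrial contig for QC
    exercises.  Returns (genes_df, variants_df).
    """
    rng = np.random.default_rng(seed)
    j = len(truth.gene_ids)
    tss = 1_000_000 + 2_000_000 * np.arange(j)
    chrom = np.array(["1"] * j, dtype=object)
    n_mito = int(round(mito_frac * j))
    if n_mito:
        chrom[rng.choice(j, size=n_mito, replace=False)] = "MT"
    genes = pd.DataFrame({"gene": truth.gene_ids, "chrom": chrom,
                          "tss": tss})
    tss_by_gene = dict(zip(truth.gene_ids, tss))
    chrom_by_gene = dict(zip(truth.gene_ids, chrom))
    rows = []
    for vid in truth.genotypes.columns:
        gene = vid.split("_v")[0]
        pos = int(tss_by_gene[gene] + rng.integers(-400_000, 400_001))
        rows.append((vid, chrom_by_gene[gene], max(pos, 1),
                     float(truth.variant_mafs[vid])))
    variants = pd.DataFrame(rows, columns=["variant", "chrom", "pos",
                                           "maf"])
    return genes, variants


def broadcast_dosage(donor_dosages, cell_donors) -> np.ndarray:
    """Broadcast per-donor dosages to per-cell dosages."""
    d = np.asarray(donor_dosages, dtype=float)
    return d[np.asarray(cell_donors)]


def truth_context(truth: SimTruth, ell_x: float = 1.0,
                  v_gp: float = 1.0) -> CellStateContext:
    """Cell-state context built from the generator's ground truth.

    Used to exercise downstream models (mixture, eQTL Bayes factors) in
    isolation from latent-variable estimation.
    """
    n = truth.X.shape[0]
    return CellStateContext(
        Z=truth.Z, zeta=np.zeros(truth.Z.shape[1]), delta=truth.delta,
        omega=truth.omega, theta=truth.theta, B=np.zeros((n, 0)),
        X=truth.X, ell_theta=1.0, ell_B=1.0, ell_X=ell_x, v_gp=v_gp,
        sigma2=truth.sigma**2)


def simulate_summary_stats(truth: SimTruth, gene: str,
                           mode: str = "shared", n_gwas: int = 10_000,
                           effect: float = 0.1, seed: int = 0
                           ) -> pd.DataFrame:
    """GWAS-style per-variant summary statistics for one gene's window.

    A quantitative trait over ``n_gwas`` unrelated individuals is driven by
    the gene's planted causal variant (``shared``), a different variant in
    the window (``distinct``) or nothing (``null``); every variant is then
    tested by single-variant least squares.
    """
    if mode not in {"shared", "distinct", "null"}:
        raise ValueError("mode must be shared / distinct / null")
    rng = np.random.default_rng(seed)
    cols = [v for v in truth.genotypes.columns if v.startswith(
        gene.replace("g", "g", 1) + "_v") or v.split("_v")[0] == gene]
    if not cols:
        raise ValueError(f"no variants simulated for gene {gene}")
    mafs = truth.variant_mafs[cols].to_numpy()
    g = rng.binomial(2, mafs[None, :], size=(n_gwas, len(cols))).astype(
        float)
    trait = rng.standard_normal(n_gwas)
    planted = truth.eqtl_table.set_index("gene")["variant"].to_dict()
    causal = planted.get(gene, cols[0])
    ci = cols.index(causal)
    if mode == "shared":
        trait += effect * g[:, ci]
    elif mode == "distinct":
        ci_alt = (ci + 1) % len(cols)
        trait += effect * g[:, ci_alt]
    beta = np.empty(len(cols))
    se = np.empty(len(cols))
    for l in range(len(cols)):
        x = g[:, l] - g[:, l].mean()
        sxx = float(x @ x)
        if sxx == 0:
            beta[l], se[l] = 0.0, np.inf
            continue
        beta[l] = float(x @ (trait - trait.mean())) / sxx
        resid = (trait - trait.mean()) - beta[l] * x
        se[l] = np.sqrt(float(resid @ resid) / (n_gwas - 2) / sxx)
    return pd.DataFrame({"variant": cols, "beta": beta, "se": se})


def simulate_ase(genotype: int, depth: int, rng=None) -> tuple[int, int]:
    """Allele-specific read counts from a binomial error model.

    alt_count ~ Binomial(depth, p) with p = 0.01 / 0.5 / 0.99 for
    genotypes 0 / 1 / 2.
    """
    if genotype not in (0, 1, 2):
        raise ValueError("genotype must be 0, 1 or 2")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    alt = int(rng.binomial(depth, ASE_P[genotype])) if depth else 0
    return depth - alt, alt


def simulate_bf_windows(n_genes: int = 2000, variants_per_gene: int = 40,
                        pi: float = 0.5, decay: float = 5e-6,
                        window: int = 1_000_000, se: float = 0.05,
                        prior_var: float = 0.04, seed: int = 0):
    """Cis windows of Wakefield log BFs with a planted gene prior and decay.

    Genes are eQTLs with probability ``pi``; for those, the causal variant
    is drawn within the window with probability proportional to
    exp(-decay |distance|), its true effect from N(0, prior_var), and every
    variant's estimate from N(effect, se^2).  Because the Wakefield ABF is
    the exact marginal likelihood ratio of this generative model, posterior
    probabilities computed from these windows are exactly calibrated.

    Returns (windows, truth DataFrame with columns gene, is_eqtl, causal).
    """
    from .coloc import wakefield_abf
    from .hier_fdr import CisWindow

    rng = np.random.default_rng(seed)
    half = window // 2
    windows, rows = [], []
    for gi in range(n_genes):
        pos = np.sort(rng.integers(-half, half + 1,
                                   size=variants_per_gene))
        is_eqtl = rng.random() < pi
        effect = np.zeros(variants_per_gene)
        causal = None
        if is_eqtl:
            w = np.exp(-decay * np.abs(pos))
            ci = rng.choice(variants_per_gene, p=w / w.sum())
            effect[ci] = rng.normal(0.0, np.sqrt(prior_var))
            causal = f"g{gi}_v{ci}"
        beta_hat = rng.normal(effect, se)
        lbf = wakefield_abf(beta_hat, np.full(variants_per_gene, se),
                            prior_var)
        windows.append(CisWindow(
            gene=f"g{gi}", tss=0,
            variant_ids=np.array([f"g{gi}_v{l}"
                                  for l in range(variants_per_gene)]),
            positions=pos, mafs=np.full(variants_per_gene, 0.3),
            log_bf=lbf))
        rows.append((f"g{gi}", is_eqtl, causal))
    truth = pd.DataFrame(rows, columns=["gene", "is_eqtl", "causal"])
    return windows, truth
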
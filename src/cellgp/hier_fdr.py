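"""Hierarchical empirical-Bayes aggregation of eQTL Bayes factors.

Variant-level log Bayes factors within a 1-Mb cis window centred at each
gene's TSS are combined under a two-level model: a gene is an eQTL with
prior probability Pi, and given that, the causal variant within the window
follows a softmax prior combining exponential TSS-distance decay with
additive annotation log-odds,

    p_l  propto  exp(-lambda |d_l| + a' x_l).

The regional Bayes factor is BF_j = sum_l p_l BF_jl; the gene posterior is
Z_j = Pi BF_j / (1 - Pi + Pi BF_j) and the within-gene variant posterior
Z_jl propto p_l BF_jl (summing to one).  (Pi, lambda, a) are estimated by
EM across genes; calling genes at local FDR q keeps those with
1 - Z_j < q.  Enrichment of eQTL posteriors in gene-level annotations uses
the pseudo-count 2x2 table and Woolf log-odds-ratio machinery, optionally
stratified over quantile bins of a confounder with inverse-variance
meta-analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "CisWindow",
    "HierPriors",
    "build_cis_windows",
    "HierarchicalEqtlModel",
    "HierarchicalEqtlResults",
    "EnrichmentResult",
    "enrichment_2x2",
    "stratified_enrichment",
]


@dataclass
class CisWindow:
    """Variants eligible for one gene: ids, positions, MAFs, log BFs."""

    gene: str
    tss: int
    variant_ids: np.ndarray
    positions: np.ndarray
    mafs: np.ndarray
    log_bf: np.ndarray
    annotations: np.ndarray | None = None  # (L, n_annot)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def distances(self) -> np.ndarray:
        return np.abs(self.positions - self.tss)


@dataclass
class HierPriors:
    pi_gene: float = 0.1
    distance_decay: float = 5e-6  # per base
    annotation_logodds: np.ndarray = field(
        default_factory=lambda: np.zeros(0))


def build_cis_windows(genes: pd.DataFrame, variants: pd.DataFrame,
                      log_bf: pd.DataFrame | None = None,
                      maf_min: float = 0.05,
                      window: int = 1_000_000) -> list[CisWindow]:
    """Assign variants to per-gene cis windows.

    A variant qualifies when MAF strictly exceeds ``maf_min`` and
    |pos - TSS| <= window/2, on the same chromosome.

    Parameters
    ----------
    genes : DataFrame with columns gene, chrom, tss
    variants : DataFrame with columns variant, chrom, pos, maf
    log_bf : optional DataFrame with columns gene, variant, log_bf
    """
    half = window // 2
    keep = variants[variants["maf"] > maf_min]
    bf_map = {}
    if log_bf is not None:
        bf_map = {(g, v): b for g, v, b in
                  zip(log_bf["gene"], log_bf["variant"], log_bf["log_bf"])}
    out = []
    for row in genes.itertuples(index=False):
        sub = keep[(keep["chrom"] == row.chrom)
                   & (np.abs(keep["pos"] - row.tss) <= half)]
        if len(sub) == 0:
            warnings.warn(f"gene {row.gene}: no eligible variants in "
                          "cis window", RuntimeWarning)
        lbf = np.array([bf_map.get((row.gene, v), 0.0)
                        for v in sub["variant"]])
        out.append(CisWindow(
            gene=row.gene, tss=int(row.tss),
            variant_ids=sub["variant"].to_numpy(),
            positions=sub["pos"].to_numpy(dtype=int),
            mafs=sub["maf"].to_numpy(dtype=float),
            log_bf=lbf))
    return out


class HierarchicalEqtlModel:
    """Empirical-Bayes model over per-gene cis windows of log BFs.

    ``annotations`` maps each window to an (L_j, n_annot) matrix of binary
    variant annotations (or use CisWindow.annotations).
    """

    def __init__(self, windows: list[CisWindow], n_annotations: int = 0):
        self.windows = [w for w in windows if w.n_variants > 0]
        self.flagged_empty = [w.gene for w in windows if w.n_variants == 0]
        if not self.windows:
            raise ValueError("no non-empty cis windows")
        self.n_annot = n_annotations
        for w in self.windows:
            if w.annotations is None:
                w.annotations = np.zeros((w.n_variants, n_annotations))
        # flattened per-variant arrays with window segment starts, so the
        # EM runs on vectorised segment reductions
        sizes = np.array([w.n_variants for w in self.windows])
        self._starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        self._seg = np.repeat(np.arange(len(self.windows)), sizes)
        self._dist = np.concatenate([w.distances for w in self.windows]
                                    ).astype(float)
        self._lbf = np.concatenate([w.log_bf for w in self.windows])
        self._annot = np.vstack([w.annotations for w in self.windows])
        self._sizes = sizes

    def _seg_logsumexp(self, x: np.ndarray) -> np.ndarray:
        mx = np.maximum.reduceat(x, self._starts)
        s = np.add.reduceat(np.exp(x - mx[self._seg]), self._starts)
        return mx + np.log(s)

    def _variant_logprior(self, w: CisWindow, decay: float,
                          coefs: np.ndarray) -> np.ndarray:
        s = -decay * w.distances
        if coefs.size:
            s = s + w.annotations @ coefs
        return s - logsumexp(s)

    def fit(self, max_iter: int = 200, tol: float = 1e-7,
            priors: HierPriors | None = None) -> "HierarchicalEqtlResults":
        priors = priors or HierPriors(
            annotation_logodds=np.zeros(self.n_annot))
        pi = priors.pi_gene
        decay = priors.distance_decay
        coefs = np.asarray(priors.annotation_logodds, dtype=float)
        trace: list[float] = []
        prev = -np.inf
        z_gene = np.zeros(len(self.windows))
        z_var = [np.full(w.n_variants, 1.0 / w.n_variants)
                 for w in self.windows]
        converged = False
        zv_flat = np.zeros_like(self._lbf)
        for it in range(max_iter):
            # E-step (vectorised over the flattened windows)
            s = -decay * self._dist
            if coefs.size:
                s = s + self._annot @ coefs
            lp = s - self._seg_logsumexp(s)[self._seg]
            lr = lp + self._lbf
            l_regional = self._seg_logsumexp(lr)    # log regional BF
            zv_flat = np.exp(lr - l_regional[self._seg])
            tot = np.logaddexp(np.log1p(-pi), np.log(pi) + l_regional)
            z_gene = np.exp(np.log(pi) + l_regional - tot)
            loglik = float(np.sum(tot))
            trace.append(loglik)
            if loglik - prev < tol * max(1.0, abs(loglik)) and it > 1:
                converged = True
                break
            prev = loglik
            # M-step
            pi = float(np.clip(np.mean(z_gene), 1e-6, 1 - 1e-6))
            decay, coefs = self._mstep_prior(z_gene, zv_flat, decay, coefs)
        z_var = np.split(zv_flat, self._starts[1:])
        if not converged:
            warnings.warn("hierarchical EM reached max_iter without "
                          "convergence; returning best iterate",
                          RuntimeWarning)
        fitted = HierPriors(pi, decay, coefs)
        return HierarchicalEqtlResults(self, fitted, z_gene.copy(),
                                       [z.copy() for z in z_var],
                                       np.asarray(trace))

    def _mstep_prior(self, z_gene, zv_flat, decay0, coefs0):
        """Weighted softmax-prior fit: maximise sum_j Z_j sum_l Z_jl log p_l."""
        n_c = coefs0.size
        zj_flat = z_gene[self._seg]
        w_flat = zj_flat * zv_flat

        def neg(v):
            dec = np.exp(v[0])
            cf = v[1:]
            s = -dec * self._dist
            if n_c:
                s = s + self._annot @ cf
            lse = self._seg_logsumexp(s)
            lp = s - lse[self._seg]
            p = np.exp(lp)
            val = float(w_flat @ lp)
            # features: (-distance, annotations); chain rule for log-decay
            diff = w_flat - zj_flat * p
            grad = np.empty_like(v)
            grad[0] = -float(diff @ self._dist) * dec
            if n_c:
                grad[1:] = diff @ self._annot
            return -val, -grad

        v0 = np.concatenate([[np.log(max(decay0, 1e-12))], coefs0])
        res = minimize(neg, v0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 50})
        return float(np.exp(res.x[0])), res.x[1:].copy()


class HierarchicalEqtlResults:
    """Gene and variant posteriors plus fitted priors."""

    def __init__(self, model, priors: HierPriors, z_gene, z_variant,
                 loglik_trace):
        self.model = model
        self.priors = priors
        self.z_gene = z_gene
        self.z_variant = z_variant
        self.loglik_trace = loglik_trace
        self.genes = [w.gene for w in model.windows]

    def call_eqtls(self, lfdr: float = 0.10) -> list[str]:
        """Genes with local false discovery rate strictly below ``lfdr``.

        The comparison is written as Z_j > 1 - lfdr so the strict boundary
        is exact for round decimal posteriors.
        """
        return [g for g, z in zip(self.genes, self.z_gene)
                if z > 1.0 - lfdr]

    def lead_variant(self, gene: str) -> str:
        """Highest-posterior variant; ties broken by TSS proximity, then id."""
        i = self.genes.index(gene)
        w = self.model.windows[i]
        z = self.z_variant[i]
        if w.n_variants == 0:
            raise ValueError(f"gene {gene}: empty cis window")
        order = sorted(
            range(w.n_variants),
            key=lambda l: (-z[l], w.distances[l], str(w.variant_ids[l])))
        return str(w.variant_ids[order[0]])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, z in zip(self.genes, self.z_gene):
            rows.append((g, z, 1.0 - z, self.lead_variant(g)))
        return pd.DataFrame(
            rows, columns=["gene", "z_gene", "lfdr", "lead_variant"])

    def summary(self) -> str:
        called = self.call_eqtls()
        return "\n".join([
            "Hierarchical eQTL model results",
            "=" * 40,
            f"genes: {len(self.genes)}   "
            f"called at lfdr 0.10: {len(called)}",
            f"Pi (gene prior): {self.priors.pi_gene:.4f}",
            f"distance decay: {self.priors.distance_decay:.3e} per bp "
            f"(x{np.exp(-self.priors.distance_decay * 1e5):.2f} per 100 kb)",
            f"annotation log-odds: {self.priors.annotation_logodds}",
            f"EM iterations: {len(self.loglik_trace)}   final loglik: "
            f"{self.loglik_trace[-1]:.3f}",
        ])


# ---------------------------------------------------------------------------
# enrichment


@dataclass
class EnrichmentResult:
    table: np.ndarray  # [[T00, T01], [T10, T11]]
    log_odds: float
    se: float
    chi2: float
    p_value: float
    corrected: bool = False
    informative: bool = True
    n_bins_used: int = 1
    n_bins_dropped: int = 0


def enrichment_2x2(x, z) -> EnrichmentResult:
    """Soft 2x2 enrichment of posterior Z in annotation X.

    T_kl = sum_j (1-X_j)^(1-k) (1-Z_j)^(1-l) X_j^k Z_j^l; log odds ratio
    r = log(T00 T11 / (T01 T10)) with Var(r) = sum of reciprocal cells
    (Woolf).  A Haldane correction of 0.5 per cell is applied only when any
    cell is below 0.5, and flagged.
    """
    x = np.asarray(x, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if np.any((x < 0) | (x > 1)) or np.any((z < 0) | (z > 1)):
        raise ValueError("X and Z must lie in [0, 1]")
    t = np.array([
        [np.sum((1 - x) * (1 - z)), np.sum((1 - x) * z)],
        [np.sum(x * (1 - z)), np.sum(x * z)],
    ])
    corrected = bool(np.any(t < 0.5))
    tt = t + 0.5 if corrected else t
    r = float(np.log(tt[0, 0] * tt[1, 1] / (tt[0, 1] * tt[1, 0])))
    var = float(np.sum(1.0 / tt))
    chi2 = r * r / var
    p = float(chi2_dist.sf(chi2, df=1))
    informative = not (np.all(x == x[0]) and set(np.unique(x)) <= {0.0, 1.0})
    return EnrichmentResult(t, r, float(np.sqrt(var)), chi2, p,
                            corrected=corrected, informative=informative)


def stratified_enrichment(x, z, confounder, n_bins: int = 100
                          ) -> EnrichmentResult:
    """Confounder-adjusted enrichment via quantile bins + inverse variance.

    Genes are split into ``n_bins`` quantile bins of the confounder; per-bin
    log odds ratios are combined as r = sum(r_b/V_b)/sum(1/V_b),
    V = 1/sum(1/V_b).  Bins whose table has any cell below 0.5 are dropped
    and counted.
    """
    x = np.asarray(x, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    c = np.asarray(confounder, dtype=float).ravel()
    if not np.all(np.isfinite(c)):
        raise ValueError("confounder must be finite")
    bins = pd.qcut(c, q=min(n_bins, len(np.unique(c))), labels=False,
                   duplicates="drop")
    rs, vs = [], []
    dropped = 0
    table = np.zeros((2, 2))
    for b in np.unique(bins):
        m = bins == b
        res = enrichment_2x2(x[m], z[m])
        if res.corrected:
            dropped += 1
            continue
        rs.append(res.log_odds)
        vs.append(res.se**2)
        table += res.table
    if not rs:
        raise ValueError("all bins degenerate; no enrichment estimate")
    w = 1.0 / np.asarray(vs)
    r = float(np.sum(np.asarray(rs) * w) / np.sum(w))
    var = float(1.0 / np.sum(w))
    chi2 = r * r / var
    return EnrichmentResult(table, r, float(np.sqrt(var)), chi2,
                            float(chi2_dist.sf(chi2, df=1)),
                            n_bins_used=len(rs), n_bins_dropped=dropped)
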
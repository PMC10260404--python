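"""Single-cell dynamic eQTL mapping via genotype-by-GP interaction.

For gene j and variant l with per-cell dosage vector g_l (the donor dosage
broadcast to that donor's cells) the alternative model adds a
genotype-modulated GP to the baseline of the latent-variable model:

    y_j ~ N(alpha_j + beta_jl o g_l + Z gamma_j, sigma_jl^2 Omega)
    beta_jl ~ N(0, delta_g^2 sigma_jl^2 (11' + K_X))

so the effect size beta_jl has a constant (static) part and a part that
varies smoothly over the target cell state X (dynamic).  Integrating every
Gaussian term, the null and alternative marginals differ only by the
low-rank addition ``delta_g^2 (11' + K_X) o (g g')`` to the covariance, and
the Bayes factor is the ratio of the two marginals with the residual scale
sigma_jl^2 profiled out per model.  An optional context-by-donor GP
f_ij ~ N(0, delta_dxc^2 sigma^2 K_X), present in both models, absorbs
donor-specific response trajectories; its scale is estimated once under the
null across all genes.

Per-variant work is a rank-(r+1) Woodbury update of one shared null
factorisation (r = numerical rank of K_X); the dense path is kept and used
as the oracle in tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

from .gplvm import CellStateContext

__all__ = [
    "EqtlConfig",
    "EqtlTestResult",
    "EqtlScan",
    "eqtl_bayes_factor",
    "posterior_effect",
    "estimate_delta_dxc",
    "classify_eqtl_dynamics",
]


@dataclass
class EqtlConfig:
    """Scales of the genetic and donor-context variance components."""

    delta_g: float = 0.1
    use_donor_context: bool = False
    delta_dxc: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_g <= 0:
            raise ValueError("delta_g must be positive")
        if self.delta_dxc < 0:
            raise ValueError("delta_dxc must be >= 0")


@dataclass
class EqtlTestResult:
    log_bf: float
    gene: str = ""
    variant: str = ""
    posterior_beta: np.ndarray | None = None
    sigma2_null: float = 0.0
    sigma2_alt: float = 0.0


def _profile_loglik(logdet: float, quad: float, n: int) -> tuple[float, float]:
    """Gaussian log-likelihood with the overall scale profiled out.

    For y ~ N(0, s C) the MLE is s_hat = y'C^-1 y / n; returns (loglik at
    s_hat, s_hat).
    """
    s_hat = max(quad / n, 1e-300)
    ll = -0.5 * (n * np.log(2.0 * np.pi * s_hat) + logdet + n)
    return ll, s_hat


def _donor_block_matrix(donors) -> np.ndarray:
    d = np.asarray(donors)
    return (d[:, None] == d[None, :]).astype(float)


class EqtlScan:
    """Bayes-factor scan of variants against genes on a fixed cell state.

    Precomputes the shared null covariance factorisation and a truncated
    eigenbasis of K_X so each variant costs a low-rank update.

    Parameters
    ----------
    Y : array (n_cells, n_genes)
    context : CellStateContext
    donors : sequence (n_cells,), required when ``config.use_donor_context``
    """

    def __init__(self, Y, context: CellStateContext, donors=None,
                 config: EqtlConfig | None = None, gene_ids=None):
        self.config = config or EqtlConfig()
        self.Y = np.atleast_2d(np.asarray(Y, dtype=float))
        self.context = context
        self.donors = None if donors is None else np.asarray(donors)
        self.gene_ids = (list(gene_ids) if gene_ids is not None
                         else [str(j) for j in range(self.Y.shape[1])])
        n = self.Y.shape[0]

        self.kx = context.K_X()
        c0 = context.K_baseline() + context.A()
        if self.config.use_donor_context:
            if self.donors is None:
                raise ValueError("donor labels required for donor-context "
                                 "effect")
            c0 = c0 + self.config.delta_dxc**2 * (
                self.kx * _donor_block_matrix(self.donors))
        self._c0 = c0
        self._cf0 = cho_factor(c0 + 1e-10 * np.eye(n), lower=True)
        self._logdet0 = 2.0 * np.sum(np.log(np.diag(self._cf0[0])))
        self.R = context.residual_mean(self.Y)
        self._c0inv_r = cho_solve(self._cf0, self.R)
        self._quad0 = np.einsum("nj,nj->j", self.R, self._c0inv_r)

        # truncated eigenbasis of K_X for the per-variant low-rank update
        evals, evecs = np.linalg.eigh(self.kx)
        keep = evals > max(1e-10 * evals.max(), 1e-12)
        self._vx = evecs[:, keep] * np.sqrt(evals[keep])

    # -- core computations --------------------------------------------------
    def _alt_factor(self, g: np.ndarray) -> np.ndarray:
        """U with C_alt = C_null + U U' = C0 + dg^2 (11'+K_X) o (gg')."""
        dg = self.config.delta_g
        return dg * np.column_stack([g, g[:, None] * self._vx])

    def log_bf(self, j: int, g, variant: str = "") -> EqtlTestResult:
        """Log Bayes factor of variant dosages g for gene index j."""
        g = np.asarray(g, dtype=float).ravel()
        n = g.shape[0]
        if g.shape[0] != self.Y.shape[0]:
            raise ValueError("dosage vector does not match cell count")
        r = self.R[:, j]
        ll0, s0 = _profile_loglik(self._logdet0, self._quad0[j], n)
        if np.ptp(g) == 0.0 and not np.any(g):
            # all-zero dosages: the interaction term vanishes identically
            return EqtlTestResult(0.0, self.gene_ids[j], variant,
                                  sigma2_null=s0, sigma2_alt=s0)
        if np.ptp(g) == 0.0:
            warnings.warn("monomorphic variant: log BF set to 0",
                          RuntimeWarning)
            return EqtlTestResult(0.0, self.gene_ids[j], variant,
                                  sigma2_null=s0, sigma2_alt=s0)
        u = self._alt_factor(g)
        c0u = cho_solve(self._cf0, u)
        cap = np.eye(u.shape[1]) + u.T @ c0u
        cap_cf = cho_factor(cap, lower=True)
        logdet1 = self._logdet0 + 2.0 * np.sum(np.log(np.diag(cap_cf[0])))
        w = u.T @ self._c0inv_r[:, j]
        quad1 = self._quad0[j] - float(w @ cho_solve(cap_cf, w))
        ll1, s1 = _profile_loglik(logdet1, quad1, n)
        return EqtlTestResult(ll1 - ll0, self.gene_ids[j], variant,
                              sigma2_null=s0, sigma2_alt=s1)

    def posterior_effect(self, j: int, g) -> np.ndarray:
        """Per-cell posterior mean effect-size curve E[beta_jl | y_j].

        E[beta | y] = delta_g^2 (11' + K_X) D_g C_alt^-1 r / 1, with the
        profiled alternative-scale cancelling.
        """
        g = np.asarray(g, dtype=float).ravel()
        r = self.R[:, j]
        if np.ptp(g) == 0.0 and not np.any(g):
            return np.zeros_like(r)
        u = self._alt_factor(g)
        c0u = cho_solve(self._cf0, u)
        cap = np.eye(u.shape[1]) + u.T @ c0u
        cap_cf = cho_factor(cap, lower=True)
        c0r = self._c0inv_r[:, j]
        c1r = c0r - c0u @ cho_solve(cap_cf, u.T @ c0r)
        dg2 = self.config.delta_g**2
        gc = g * c1r
        return dg2 * (np.sum(gc) + self.kx @ gc)

    def scan(self, dosages: np.ndarray, variant_ids=None,
             genes=None, with_posterior: bool = False):
        """Log BFs for every gene x variant pair.

        dosages: (n_cells, n_variants) per-cell dosage matrix.
        Returns a pandas DataFrame (gene, variant, log_bf).
        """
        import pandas as pd
        dosages = np.atleast_2d(np.asarray(dosages, dtype=float))
        nv = dosages.shape[1]
        variant_ids = (list(variant_ids) if variant_ids is not None
                       else [f"v{i}" for i in range(nv)])
        genes = range(self.Y.shape[1]) if genes is None else genes
        rows = []
        for j in genes:
            for l in range(nv):
                res = self.log_bf(j, dosages[:, l], variant_ids[l])
                rows.append((self.gene_ids[j], res.variant, res.log_bf))
        return pd.DataFrame(rows, columns=["gene", "variant", "log_bf"])


# -- functional wrappers (dense oracle path) --------------------------------


def _dense_cov(context: CellStateContext, config: EqtlConfig, donors,
               g=None) -> np.ndarray:
    c = context.K_baseline() + context.A()
    if config.use_donor_context:
        c = c + config.delta_dxc**2 * (
            context.K_X() * _donor_block_matrix(donors))
    if g is not None:
        gg = np.outer(g, g)
        c = c + config.delta_g**2 * (gg + context.K_X() * gg)
    return c


def eqtl_bayes_factor(y_j, g, context: CellStateContext,
                      config: EqtlConfig | None = None, donors=None,
                      dense: bool = False) -> EqtlTestResult:
    """Log Bayes factor for one gene-variant pair.

    With ``dense=True`` the full covariances are assembled and factorised
    directly (the brute-force oracle); otherwise the low-rank scan path is
    used.
    """
    config = config or EqtlConfig()
    y = np.asarray(y_j, dtype=float).ravel()
    if not dense:
        scan = EqtlScan(y[:, None], context, donors=donors, config=config)
        return scan.log_bf(0, g)
    g = np.asarray(g, dtype=float).ravel()
    n = y.shape[0]
    r = y - context.Z @ context.zeta
    if np.ptp(g) == 0.0:
        if np.any(g):
            warnings.warn("monomorphic variant: log BF set to 0",
                          RuntimeWarning)
        return EqtlTestResult(0.0)
    out = {}
    for label, gv in (("null", None), ("alt", g)):
        c = _dense_cov(context, config, donors, gv)
        cf = cho_factor(c + 1e-10 * np.eye(n), lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        quad = float(r @ cho_solve(cf, r))
        out[label] = _profile_loglik(logdet, quad, n)
    return EqtlTestResult(out["alt"][0] - out["null"][0],
                          sigma2_null=out["null"][1],
                          sigma2_alt=out["alt"][1])


def posterior_effect(y_j, g, context: CellStateContext,
                     config: EqtlConfig | None = None, donors=None,
                     dense: bool = False) -> np.ndarray:
    """Per-cell posterior mean E[beta_jl | y_j] of the eQTL effect curve."""
    config = config or EqtlConfig()
    y = np.asarray(y_j, dtype=float).ravel()
    if not dense:
        scan = EqtlScan(y[:, None], context, donors=donors, config=config)
        return scan.posterior_effect(0, g)
    g = np.asarray(g, dtype=float).ravel()
    n = y.shape[0]
    r = y - context.Z @ context.zeta
    c1 = _dense_cov(context, config, donors, g)
    cf = cho_factor(c1 + 1e-10 * np.eye(n), lower=True)
    c1r = cho_solve(cf, r)
    gc = g * c1r
    dg2 = config.delta_g**2
    return dg2 * (np.sum(gc) + context.K_X() @ gc)


def estimate_delta_dxc(Y, donors, context: CellStateContext,
                       profile_amplitude: bool = True) -> float:
    """Null-model estimate of the context-by-donor scale delta_dxc.

    Maximises the genotype-free profile marginal likelihood summed over all
    genes with the donor-context GP included.  By default the baseline GP
    amplitude is re-profiled jointly (a fixed amplitude that misfits the
    data leaks systematically into the donor-context component); when the
    context comes straight from a GPLVM fit on the same data the amplitude
    barely moves.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    donors = np.asarray(donors)
    if np.unique(donors).size < 2:
        raise ValueError("need at least two donors")
    n = Y.shape[0]
    kx = context.K_X()
    kdxc = kx * _donor_block_matrix(donors)
    kb = context.K_baseline()
    a_mat = context.A()
    r = context.residual_mean(Y)

    def negloglik(scale, delta):
        c = scale * kb + a_mat + delta**2 * kdxc
        cf = cho_factor(c + 1e-10 * np.eye(n), lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        quad = np.einsum("nj,nj->j", r, cho_solve(cf, r))
        return -sum(_profile_loglik(logdet, q, n)[0] for q in quad)

    if profile_amplitude:
        res = minimize(lambda v: negloglik(np.exp(v[0]), np.exp(v[1])),
                       np.log([1.0, 0.3]), method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-6,
                                "maxiter": 200})
        return float(np.exp(res.x[1]))
    res = minimize_scalar(lambda d: negloglik(1.0, d), bounds=(0.0, 2.0),
                          method="bounded", options={"xatol": 1e-3})
    return float(res.x)


def classify_eqtl_dynamics(Y, dosage_by_test, context: CellStateContext,
                           patterns, config: EqtlConfig | None = None,
                           donors=None, threshold: float = 0.9,
                           max_em_iter: int = 100):
    """Classify called eQTLs into static vs spatial effect-size patterns.

    A small GP mixture over the genetic effect: component "static" puts the
    effect prior on the constant kernel 11', and one component per supplied
    pattern curve beta_k puts it on the rank-one kernel beta_k beta_k'
    (effect proportional to that response pattern).  Mixture weights are
    estimated by EM across the tested pairs; a pair is labelled when its
    posterior probability exceeds ``threshold``, else "unclassified".

    Parameters
    ----------
    Y : array (n_cells, n_genes_tested) expression of the called eQTL genes
    dosage_by_test : array (n_cells, n_genes_tested) dosage of each gene's
        lead variant
    patterns : list of per-cell pattern curves (e.g. mixture pseudotimes)

    Returns
    -------
    labels : array of "static" / "pattern-k" / "unclassified"
    posterior : (n_tests, 1 + n_patterns) posterior probabilities
    """
    config = config or EqtlConfig()
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    dosage_by_test = np.atleast_2d(np.asarray(dosage_by_test, dtype=float))
    n, n_tests = Y.shape
    comps = [np.ones(n)]
    for beta in patterns:
        b = np.asarray(beta, dtype=float).ravel()
        nrm = np.linalg.norm(b)
        comps.append(b * (np.sqrt(n) / nrm) if nrm > 0 else b)
    base = context.K_baseline() + context.A()
    if config.use_donor_context:
        base = base + config.delta_dxc**2 * (
            context.K_X() * _donor_block_matrix(donors))
    cf0 = cho_factor(base + 1e-10 * np.eye(n), lower=True)
    logdet0 = 2.0 * np.sum(np.log(np.diag(cf0[0])))
    r_all = context.residual_mean(Y)

    ll = np.empty((n_tests, len(comps)))
    for t in range(n_tests):
        g = dosage_by_test[:, t]
        r = r_all[:, t]
        for c, f in enumerate(comps):
            u = (config.delta_g * f * g)[:, None]
            c0u = cho_solve(cf0, u)
            s = 1.0 + float(u[:, 0] @ c0u[:, 0])
            logdet = logdet0 + np.log(s)
            c0r = cho_solve(cf0, r)
            w = float(u[:, 0] @ c0r)
            quad = float(r @ c0r) - w * w / s
            ll[t, c] = _profile_loglik(logdet, quad, n)[0]

    pi = np.full(len(comps), 1.0 / len(comps))
    for _ in range(max_em_iter):
        lp = ll + np.log(pi)[None, :]
        post = np.exp(lp - logsumexp(lp, axis=1)[:, None])
        new_pi = np.clip(post.mean(axis=0), 1e-8, None)
        new_pi /= new_pi.sum()
        if np.max(np.abs(new_pi - pi)) < 1e-8:
            pi = new_pi
            break
        pi = new_pi
    lp = ll + np.log(pi)[None, :]
    post = np.exp(lp - logsumexp(lp, axis=1)[:, None])
    names = ["static"] + [f"pattern-{k + 1}" for k in range(len(patterns))]
    labels = np.array(
        [names[c] if post[t, (c := int(np.argmax(post[t])))] > threshold
         else "unclassified" for t in range(n_tests)], dtype=object)
    return labels, post
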
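"""Spatial differential expression via a finite mixture of GPs.

Genes are classified into K spatial expression patterns over the target
cell state X.  Conditional on the GPLVM estimates, gene j in component k
follows

    y_j ~ N(alpha_j + delta_jk beta_k + Z gamma_j, sigma_j^2 Omega)
    alpha_j ~ N(0, sigma_j^2 K_theta o K_B)      (target state excluded)
    beta_k ~ N(0, K_X)                            (shared pattern GP)
    delta_jk ~ N(0, 1)                            (per-gene loading)

Integrating alpha_j, gamma_j and delta_jk analytically gives a Gaussian
marginal with covariance ``sigma_j^2 (Sigma0 + beta_k beta_k')`` where
``Sigma0 = K_theta o K_B + Z Delta Z' + Omega`` — the pattern enters as a
rank-one term, so component likelihoods cost a rank-one Woodbury update of
one shared factorisation.  EM alternates responsibilities (E-step) with
closed-form weights and penalised maximum-likelihood pattern updates
(M-step; beta_k is represented at inducing points with its N(0, K_mm)
prior and interpolated to cells through the GP mean map).  One component is
pinned at beta = 0 so pattern-free ("stationary") genes have an explicit
home; with the default K = 3 the remaining two components capture e.g.
primary and secondary response programmes, and their fitted patterns serve
as pseudotimes (per-cell posterior mean of beta_k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.optimize import minimize
from scipy.special import logsumexp

from .gplvm import CellStateContext
from .kernels import KernelSpec, add_jitter, se_kernel

__all__ = [
    "MixtureConfig",
    "GPMixture",
    "GPMixtureResults",
    "gene_marginal_given_component",
]


@dataclass
class MixtureConfig:
    K: int = 3
    max_em_iter: int = 60
    tol: float = 1e-6
    seed: int = 0
    n_restarts: int = 5
    n_inducing: int = 30

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")


def gene_marginal_given_component(y_j, beta, context: CellStateContext,
                                  sigma2_j: float) -> float:
    """Dense log marginal of one gene given a pattern curve beta.

    Closed form: N(y_j | Z zeta, sigma_j^2 (K_theta o K_B + beta beta' +
    Z Delta Z' + Omega)); the loading delta_jk ~ N(0,1) is integrated as the
    rank-one term.  Used directly as the oracle for the Woodbury path.
    """
    y = np.asarray(y_j, dtype=float).ravel()
    beta = np.asarray(beta, dtype=float).ravel()
    cov = context.K_baseline(include_target=False) + np.outer(beta, beta) \
        + context.A()
    c = sigma2_j * cov
    r = y - context.Z @ context.zeta
    cf = cho_factor(c, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    quad = float(r @ cho_solve(cf, r))
    return -0.5 * (y.size * np.log(2.0 * np.pi) + logdet + quad)


class GPMixture:
    """Finite mixture of GPs over the fitted cell state.

    Parameters
    ----------
    Y : array (n_cells, n_genes)
        The expression matrix the GPLVM was fitted to (same centring).
    context : CellStateContext
        Frozen GPLVM estimates (latents and variance parameters).
    sigma2 : array (n_genes,), optional
        Per-gene residual variances; defaults to ``context.sigma2``.
    """

    def __init__(self, Y, context: CellStateContext, sigma2=None,
                 config: MixtureConfig | None = None):
        self.config = config or MixtureConfig()
        self.Y = np.atleast_2d(np.asarray(Y, dtype=float))
        self.context = context
        sigma2 = context.sigma2 if sigma2 is None else sigma2
        if sigma2 is None:
            raise ValueError("sigma2 required (not present in context)")
        self.sigma2 = np.asarray(sigma2, dtype=float)
        if self.sigma2.shape[0] != self.Y.shape[1]:
            raise ValueError("sigma2 must have one entry per gene")

        n = self.Y.shape[0]
        # shared baseline covariance (unit residual scale) and its inverse
        self._sigma0 = context.K_baseline(include_target=False) + context.A()
        self._cf0 = cho_factor(add_jitter(self._sigma0, 1e-10), lower=True)
        self._logdet0 = 2.0 * np.sum(np.log(np.diag(self._cf0[0])))
        self.R = context.residual_mean(self.Y)          # N x J
        self.PR = cho_solve(self._cf0, self.R)          # Sigma0^-1 R
        self._quad0 = np.einsum("nj,nj->j", self.R, self.PR)

        # inducing representation of the pattern GP over X
        xu = context.X_u
        if xu is None or xu.shape[0] == 0 or xu.shape[0] > n:
            rng = np.random.default_rng(self.config.seed)
            take = rng.choice(n, size=min(self.config.n_inducing, n),
                              replace=False)
            xu = context.X[take]
        self._xu = xu
        spec = KernelSpec("squared_exponential", context.ell_X,
                          context.v_gp)
        kmm = add_jitter(se_kernel(xu, xu, spec))
        knm = se_kernel(context.X, xu, spec)
        self._kmm_cf = cho_factor(kmm, lower=True)
        self._kmm = kmm
        self._phi = cho_solve(self._kmm_cf, knm.T).T    # N x M mean map

    # -- likelihood pieces --------------------------------------------------
    def _loglik_matrix(self, betas: np.ndarray) -> np.ndarray:
        """log N(y_j | component k) for all genes x components.

        betas has one row per component (row of zeros for the pinned one).
        """
        n, j = self.Y.shape
        out = np.empty((j, betas.shape[0]))
        base = -0.5 * n * np.log(2.0 * np.pi * self.sigma2)
        for k, beta in enumerate(betas):
            if not np.any(beta):
                logdet = self._logdet0
                quad = self._quad0
            else:
                u = cho_solve(self._cf0, beta)
                s = 1.0 + float(beta @ u)
                logdet = self._logdet0 + np.log(s)
                a = u @ self.R                            # (J,)
                quad = self._quad0 - a * a / s
            out[:, k] = base - 0.5 * logdet - 0.5 * quad / self.sigma2
        return out

    def _mstep_beta(self, w: np.ndarray, b0: np.ndarray) -> np.ndarray:
        """Penalised ML update of one pattern's inducing values b.

        Maximises sum_j w_j log N(y_j | beta(b)) - b' K_mm^-1 b / 2 with
        beta = Phi b; analytic gradient, L-BFGS.
        """
        phi = self._phi
        wsum = float(np.sum(w))
        ws = w / self.sigma2

        def negobj(b):
            beta = phi @ b
            u = cho_solve(self._cf0, beta)
            s = 1.0 + float(beta @ u)
            a = u @ self.R
            val = -0.5 * wsum * np.log(s) + 0.5 * float(ws @ (a * a)) / s
            kb = cho_solve(self._kmm_cf, b)
            val -= 0.5 * float(b @ kb)
            pr_wa = self.PR @ (ws * a)
            grad_beta = (-wsum * u / s
                         + pr_wa / s
                         - float(ws @ (a * a)) * u / s**2)
            grad = phi.T @ grad_beta - kb
            return -val, -grad

        res = minimize(negobj, b0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 60})
        return res.x

    # -- EM -----------------------------------------------------------------
    def fit(self) -> "GPMixtureResults":
        cfg = self.config
        best = None
        for restart in range(cfg.n_restarts):
            out = self._fit_once(cfg.seed + restart)
            if best is None or out[-1][-1] > best[-1][-1]:
                best = out
        pi, b_ind, resp, trace = best
        betas = np.vstack([np.zeros(self.Y.shape[0])]
                          + [self._phi @ b for b in b_ind])
        # merge degenerate components (pattern indistinguishable from the
        # pinned beta = 0 class) into the stationary component, otherwise
        # near-identical likelihoods split pattern-free genes arbitrarily
        ll = self._loglik_matrix(betas)
        pi, resp = pi.copy(), resp.copy()
        for k in range(1, betas.shape[0]):
            if np.mean(np.abs(ll[:, k] - ll[:, 0])) < 1.0:
                betas[k] = 0.0
                resp[:, 0] += resp[:, k]
                resp[:, k] = 0.0
                pi[0] += pi[k]
                pi[k] = 0.0
        return GPMixtureResults(self, pi, betas, b_ind, resp,
                                np.asarray(trace))

    def _fit_once(self, seed: int):
        cfg = self.config
        rng = np.random.default_rng(seed)
        j = self.Y.shape[1]
        m = self._xu.shape[0]
        # responsibilities initialised from a random soft assignment
        resp = rng.dirichlet(np.ones(cfg.K), size=j)
        b_ind = [0.1 * rng.standard_normal(m) for _ in range(cfg.K - 1)]
        pi = np.full(cfg.K, 1.0 / cfg.K)
        trace: list[float] = []
        prev = -np.inf
        for it in range(cfg.max_em_iter):
            # M-step (first iteration uses the initial responsibilities)
            pi = resp.mean(axis=0)
            if np.any(pi < 1e-6):
                warnings.warn("empty mixture component", RuntimeWarning)
                pi = np.clip(pi, 1e-8, None)
                pi /= pi.sum()
            for k in range(1, cfg.K):
                b_ind[k - 1] = self._mstep_beta(resp[:, k], b_ind[k - 1])
            # E-step
            betas = np.vstack([np.zeros(self.Y.shape[0])]
                              + [self._phi @ b for b in b_ind])
            ll = self._loglik_matrix(betas) + np.log(pi)[None, :]
            norm = logsumexp(ll, axis=1)
            resp = np.exp(ll - norm[:, None])
            # penalised objective: mixture log-likelihood + pattern priors
            total = float(np.sum(norm))
            for b in b_ind:
                total -= 0.5 * float(b @ cho_solve(self._kmm_cf, b))
            trace.append(total)
            if total - prev < cfg.tol * max(1.0, abs(total)) and it > 2:
                break
            prev = total
        return pi, b_ind, resp, trace


class GPMixtureResults:
    """Fitted GP mixture: weights, pattern curves, responsibilities."""

    def __init__(self, model: GPMixture, pi, betas, b_inducing,
                 responsibilities, loglik_trace):
        self.model = model
        self.pi = np.asarray(pi)
        #: component pattern curves at cells; row 0 is the pinned beta = 0
        self.betas = np.asarray(betas)
        self.b_inducing = b_inducing
        self.responsibilities = np.asarray(responsibilities)
        self.loglik_trace = np.asarray(loglik_trace)

    @property
    def n_components(self) -> int:
        return self.pi.shape[0]

    def pseudotime(self, k: int) -> np.ndarray:
        """Per-cell posterior-mean pattern curve of component k."""
        if not 0 <= k < self.n_components:
            raise IndexError(f"component {k} out of range")
        return self.betas[k].copy()

    def classify_genes(self, threshold: float = 0.5) -> np.ndarray:
        """Argmax-responsibility labels; 'unassigned' below the threshold.

        Component 0 is the pattern-free (stationary) class.
        """
        arg = np.argmax(self.responsibilities, axis=1)
        top = self.responsibilities[np.arange(arg.size), arg]
        labels = np.array([f"component-{k}" for k in arg], dtype=object)
        labels[arg == 0] = "stationary"
        labels[top <= threshold] = "unassigned"
        return labels

    def delta_posterior_mean(self) -> np.ndarray:
        """Posterior mean loading E[delta_jk | y_j] per gene x component.

        With prior delta ~ N(0, 1) and the rank-one marginalisation,
        E[delta | y] = beta' Sigma0^-1 r / (sigma_j (1 + beta' Sigma0^-1 beta)).
        """
        m = self.model
        out = np.zeros_like(self.responsibilities)
        for k in range(1, self.n_components):
            beta = self.betas[k]
            u = cho_solve(m._cf0, beta)
            s = 1.0 + float(beta @ u)
            out[:, k] = (u @ m.R) / (np.sqrt(m.sigma2) * s)
        return out

    def to_frame(self, gene_ids=None):
        """Gene classification table (responsibilities + label)."""
        import pandas as pd
        j = self.responsibilities.shape[0]
        idx = gene_ids if gene_ids is not None else np.arange(j)
        df = pd.DataFrame(
            self.responsibilities, index=idx,
            columns=[f"resp_{k}" for k in range(self.n_components)])
        df["label"] = self.classify_genes()
        return df

    def summary(self) -> str:
        counts = dict(zip(*np.unique(self.classify_genes(),
                                     return_counts=True)))
        lines = [
            "GP mixture results",
            "=" * 40,
            f"components: {self.n_components} (component 0 pinned at 0)",
            "weights: " + "  ".join(f"{p:.3f}" for p in self.pi),
            "labels:  " + "  ".join(f"{k}={v}" for k, v in counts.items()),
            f"final log-likelihood: {self.loglik_trace[-1]:.3f} "
            f"({len(self.loglik_trace)} EM iterations)",
        ]
        return "\n".join(lines)
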
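"""Confounder-adjusted Gaussian-process latent variable model (GPLVM).

The model for the log-expression vector ``y_j`` of gene ``j`` across ``N``
cells is

    y_j ~ N(alpha_j + Z gamma_j, sigma_j^2 Omega)
    alpha_j ~ N(0, sigma_j^2 K_theta o K_B o K_X)
    gamma_j ~ N(zeta, sigma_j^2 Delta)

where ``o`` is the entrywise product, ``K_theta`` is a periodic kernel over
the cell-cycle angle theta, ``K_B`` and ``K_X`` are squared-exponential
kernels over unknown-batch coordinates B and the target cell state X, ``Z``
is the design matrix of known covariates (donor, plate, condition), and
``Omega = diag(omega_i)`` carries cell-specific residual variance.  Both
``alpha_j`` and ``gamma_j`` integrate out analytically, leaving

    y_j ~ N(Z zeta, sigma_j^2 (K + Z Delta Z' + Omega)),   K = K_theta o K_B o K_X.

Latent variables (theta, B, X), inducing points and hyperparameters are
estimated by maximising a sparse lower bound on the summed log marginal
likelihood: the GP term is approximated through M inducing points
(Q = K_nm K_mm^{-1} K_mn) while the random effect and residual stay exact,

    bound_j = log N(y_j | Z zeta, sigma_j^2 (Q + A)) - tr(A^{-1}(K - Q)) / 2,

with ``A = Z Delta Z' + Omega`` (the gene-specific scale cancels in the
trace).  The bound is exact when the inducing set equals the cells and is
otherwise a lower bound; both properties are exercised in the tests against
the dense marginal.  Optimisation is L-BFGS with analytic gradients.

A ``linear`` kernel mode replaces the product kernel with ``X X'`` (no
cell-cycle term); because that covariance is already low rank the exact
marginal is used directly.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

from .kernels import KernelSpec, linear_kernel, periodic_kernel, se_kernel

__all__ = [
    "GplvmConfig",
    "CellStateContext",
    "GPLVM",
    "GPLVMResults",
    "exact_log_marginal",
    "titsias_bound",
    "titsias_bound_grad",
]


# ---------------------------------------------------------------------------
# configuration and parameter container


@dataclass
class GplvmConfig:
    """Controls for the sparse GPLVM fit.

    n_inducing is the number of inducing points M; d_X and d_B the latent
    dimensionalities of the target state and unknown-batch coordinates.
    """

    n_inducing: int = 100
    d_X: int = 10
    d_B: int = 2
    max_iter: int = 2000
    tol: float = 1e-6
    seed: int = 0
    kernel_mode: str = "product"  # or "linear"
    jitter: float = 1e-6
    center_genes: bool = True
    omega_min: float = 1e-3

    def __post_init__(self) -> None:
        if self.d_X < 1:
            raise ValueError("d_X must be >= 1")
        if self.d_B < 0:
            raise ValueError("d_B must be >= 0")
        if self.kernel_mode not in {"product", "linear"}:
            raise ValueError("kernel_mode must be 'product' or 'linear'")


@dataclass
class GplvmParams:
    """Free parameters and latents of the GPLVM (natural scale).

    Shapes: zeta, delta (P,); omega (N,); sigma2 (J,); theta (N,);
    B (N, d_B); X (N, d_X); *_u the inducing-point counterparts (M rows).
    """

    zeta: np.ndarray
    delta: np.ndarray
    omega: np.ndarray
    sigma2: np.ndarray
    theta: np.ndarray
    B: np.ndarray
    X: np.ndarray
    theta_u: np.ndarray
    B_u: np.ndarray
    X_u: np.ndarray
    ell_theta: float = 1.0
    ell_B: float = 1.0
    ell_X: float = 1.0
    v_gp: float = 1.0
    jitter: float = 1e-6

    @property
    def n_cells(self) -> int:
        return self.theta.shape[0]

    @property
    def n_inducing(self) -> int:
        return self.theta_u.shape[0]

    def kernel_specs(self) -> dict:
        return {
            "theta": KernelSpec("periodic", self.ell_theta, 1.0),
            "B": KernelSpec("squared_exponential", self.ell_B, 1.0),
            "X": KernelSpec("squared_exponential", self.ell_X, self.v_gp),
        }


def _product_kernel(p: GplvmParams, rows, cols) -> np.ndarray:
    """Product kernel between two sets of latent tuples (theta, B, X)."""
    th_a, b_a, x_a = rows
    th_b, b_b, x_b = cols
    specs = p.kernel_specs()
    k = periodic_kernel(th_a, th_b, specs["theta"])
    if b_a.shape[1] > 0:
        k = k * se_kernel(b_a, b_b, specs["B"])
    k = k * se_kernel(x_a, x_b, specs["X"])
    return k


# ---------------------------------------------------------------------------
# context object shared with downstream modules


@dataclass
class CellStateContext:
    """Fitted (or known) cell-state quantities needed downstream.

    Downstream models (spatial DE mixture, eQTL Bayes factors) freeze the
    GPLVM estimates; this object carries exactly those: latents, design,
    random-effect and residual parameters, kernel hyperparameters and the
    inducing set.
    """

    Z: np.ndarray
    zeta: np.ndarray
    delta: np.ndarray
    omega: np.ndarray
    theta: np.ndarray
    B: np.ndarray
    X: np.ndarray
    ell_theta: float = 1.0
    ell_B: float = 1.0
    ell_X: float = 1.0
    v_gp: float = 1.0
    kernel_mode: str = "product"
    theta_u: np.ndarray | None = None
    B_u: np.ndarray | None = None
    X_u: np.ndarray | None = None
    sigma2: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.Z.shape[0]

    def _spec(self, which: str) -> KernelSpec:
        if which == "theta":
            return KernelSpec("periodic", self.ell_theta, 1.0)
        if which == "B":
            return KernelSpec("squared_exponential", self.ell_B, 1.0)
        return KernelSpec("squared_exponential", self.ell_X, self.v_gp)

    def K_theta(self) -> np.ndarray:
        return periodic_kernel(self.theta, self.theta, self._spec("theta"))

    def K_B(self) -> np.ndarray:
        if self.B.shape[1] == 0:
            return np.ones((self.n_cells, self.n_cells))
        return se_kernel(self.B, self.B, self._spec("B"))

    def K_X(self) -> np.ndarray:
        if self.kernel_mode == "linear":
            return linear_kernel(self.X)
        return se_kernel(self.X, self.X, self._spec("X"))

    def K_baseline(self, include_target: bool = True) -> np.ndarray:
        """Covariance of the baseline GP alpha (unit residual scale)."""
        if self.kernel_mode == "linear":
            return self.K_X()
        k = self.K_theta() * self.K_B()
        if include_target:
            k = k * self.K_X()
        return k

    def A(self) -> np.ndarray:
        """Integrated random effect + residual covariance Z Delta Z' + Omega."""
        return (self.Z * self.delta) @ self.Z.T + np.diag(self.omega)

    def residual_mean(self, Y: np.ndarray) -> np.ndarray:
        """Y minus the shared mean Z zeta (cells x genes)."""
        return Y - (self.Z @ self.zeta)[:, None]


# ---------------------------------------------------------------------------
# exact marginal likelihood (dense oracle path)


def exact_log_marginal(y_j, Z, params: GplvmParams | CellStateContext,
                       sigma2_j: float) -> float:
    """Dense log marginal likelihood of one gene.

    log N(y_j | Z zeta, sigma_j^2 (K + Z Delta Z' + Omega)); serves as the
    oracle the sparse bound is checked against.
    """
    y = np.asarray(y_j, dtype=float).ravel()
    n = y.shape[0]
    if isinstance(params, GplvmParams):
        k = _product_kernel(
            params, (params.theta, params.B, params.X),
            (params.theta, params.B, params.X))
        a = (Z * params.delta) @ Z.T + np.diag(params.omega)
        mean = Z @ params.zeta
    else:
        k = params.K_baseline()
        a = params.A()
        mean = Z @ params.zeta
    c = sigma2_j * (k + a)
    r = y - mean
    try:
        cf = cho_factor(c, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - diagnostics
        raise np.linalg.LinAlgError(
            f"covariance not PSD (n={n}, sigma2={sigma2_j:.3g})") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    quad = float(r @ cho_solve(cf, r))
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)


# ---------------------------------------------------------------------------
# sparse bound and analytic gradient

_PARAM_KEYS = (
    "zeta", "log_delta", "log_omega", "log_sigma2",
    "log_ell_theta", "log_ell_B", "log_ell_X", "log_v",
    "theta", "B", "X", "theta_u", "B_u", "X_u",
)


class _Packer:
    """Flattens a named set of arrays into one optimisation vector."""

    def __init__(self, shapes: dict):
        self.shapes = dict(shapes)
        self.slices = {}
        off = 0
        for k, shp in self.shapes.items():
            n = int(np.prod(shp)) if shp else 1
            self.slices[k] = slice(off, off + n)
            off += n
        self.size = off

    def pack(self, d: dict) -> np.ndarray:
        v = np.empty(self.size)
        for k, shp in self.shapes.items():
            v[self.slices[k]] = np.asarray(d[k], dtype=float).ravel()
        return v

    def unpack(self, v: np.ndarray) -> dict:
        out = {}
        for k, shp in self.shapes.items():
            arr = v[self.slices[k]]
            out[k] = arr.reshape(shp) if shp else float(arr[0])
        return out


def _params_to_dict(p: GplvmParams) -> dict:
    return {
        "zeta": p.zeta,
        "log_delta": np.log(p.delta),
        "log_omega": np.log(p.omega),
        "log_sigma2": np.log(p.sigma2),
        "log_ell_theta": np.log(p.ell_theta),
        "log_ell_B": np.log(p.ell_B),
        "log_ell_X": np.log(p.ell_X),
        "log_v": np.log(p.v_gp),
        "theta": p.theta,
        "B": p.B,
        "X": p.X,
        "theta_u": p.theta_u,
        "B_u": p.B_u,
        "X_u": p.X_u,
    }


def _dict_to_params(d: dict, jitter: float) -> GplvmParams:
    return GplvmParams(
        zeta=np.asarray(d["zeta"]),
        delta=np.exp(d["log_delta"]),
        omega=np.exp(d["log_omega"]),
        sigma2=np.exp(d["log_sigma2"]),
        theta=np.asarray(d["theta"]),
        B=np.asarray(d["B"]),
        X=np.asarray(d["X"]),
        theta_u=np.asarray(d["theta_u"]),
        B_u=np.asarray(d["B_u"]),
        X_u=np.asarray(d["X_u"]),
        ell_theta=float(np.exp(d["log_ell_theta"])),
        ell_B=float(np.exp(d["log_ell_B"])),
        ell_X=float(np.exp(d["log_ell_X"])),
        v_gp=float(np.exp(d["log_v"])),
        jitter=jitter,
    )


def _se_cross_terms(xa, xb, ell):
    """Pairwise differences and the SE kernel factor exp(-||d||^2/2l^2)."""
    diff = xa[:, None, :] - xb[None, :, :]
    sq = np.sum(diff * diff, axis=2)
    return diff, np.exp(-0.5 * sq / ell**2), sq


def _bound_core(p: GplvmParams, Y: np.ndarray, Z: np.ndarray,
                want_grad: bool):
    """Value (and gradient dict) of the sparse bound, product-kernel mode."""
    n, j_genes = Y.shape
    m = p.n_inducing
    d_b = p.B.shape[1]

    # --- kernel blocks, keeping per-factor pieces for the chain rule
    dth_nm = p.theta[:, None] - p.theta_u[None, :]
    dth_nn = p.theta[:, None] - p.theta[None, :]
    dth_mm = p.theta_u[:, None] - p.theta_u[None, :]
    st_nm = np.sin(dth_nm / 2.0)
    st_nn = np.sin(dth_nn / 2.0)
    st_mm = np.sin(dth_mm / 2.0)
    kt_nm = np.exp(-2.0 * st_nm**2 / p.ell_theta**2)
    kt_nn = np.exp(-2.0 * st_nn**2 / p.ell_theta**2)
    kt_mm = np.exp(-2.0 * st_mm**2 / p.ell_theta**2)

    dx_nm, kx_nm, sqx_nm = _se_cross_terms(p.X, p.X_u, p.ell_X)
    dx_nn, kx_nn, sqx_nn = _se_cross_terms(p.X, p.X, p.ell_X)
    dx_mm, kx_mm, sqx_mm = _se_cross_terms(p.X_u, p.X_u, p.ell_X)

    if d_b > 0:
        db_nm, kb_nm, sqb_nm = _se_cross_terms(p.B, p.B_u, p.ell_B)
        db_nn, kb_nn, sqb_nn = _se_cross_terms(p.B, p.B, p.ell_B)
        db_mm, kb_mm, sqb_mm = _se_cross_terms(p.B_u, p.B_u, p.ell_B)
    else:
        kb_nm = np.ones((n, m))
        kb_nn = np.ones((n, n))
        kb_mm = np.ones((m, m))

    k_nm = p.v_gp * kt_nm * kb_nm * kx_nm
    k_nn = p.v_gp * kt_nn * kb_nn * kx_nn
    jit = p.jitter * p.v_gp
    k_mm = p.v_gp * kt_mm * kb_mm * kx_mm + jit * np.eye(m)

    # --- Gaussian algebra
    a_mat = (Z * p.delta) @ Z.T + np.diag(p.omega)
    l_mm = cholesky(k_mm, lower=True)
    h = cho_solve((l_mm, True), k_nm.T)            # M x N = Kmm^-1 Kmn
    q = k_nm @ h                                    # Nystrom approx of K
    c = q + a_mat
    l_c = cholesky(c, lower=True)
    r = Y - (Z @ p.zeta)[:, None]
    cir = cho_solve((l_c, True), r)                 # C^-1 R
    quad = np.einsum("nj,nj->j", r, cir)
    logdet_c = 2.0 * np.sum(np.log(np.diag(l_c)))
    l_a = cholesky(a_mat, lower=True)
    ainv = cho_solve((l_a, True), np.eye(n))
    kq = k_nn - q
    trace_term = float(np.sum(ainv * kq))           # tr(A^-1 (K - Q))

    value = (
        -0.5 * n * np.sum(np.log(2.0 * np.pi * p.sigma2))
        - 0.5 * j_genes * logdet_c
        - 0.5 * float(np.sum(quad / p.sigma2))
        - 0.5 * j_genes * trace_term
    )
    if not want_grad:
        return value, None

    # --- coefficient matrices: dF = <E_nm, dKnm> + <E_mm, dKmm> + <E_nn, dKnn>
    #     + <M_A, dA> + mean/scale terms
    cinv = cho_solve((l_c, True), np.eye(n))
    g_mat = -0.5 * j_genes * cinv + 0.5 * (cir / p.sigma2) @ cir.T
    t_mat = ainv @ kq @ ainv
    m_q = g_mat + 0.5 * j_genes * ainv
    m_a = g_mat + 0.5 * j_genes * t_mat
    e_nn = -0.5 * j_genes * ainv
    e_nm = 2.0 * cho_solve((l_mm, True), (m_q @ k_nm).T).T
    e_mm = -(h @ m_q @ h.T)

    grad = {}
    grad["zeta"] = Z.T @ (cir @ (1.0 / p.sigma2))
    grad["log_delta"] = p.delta * np.einsum("np,nm,mp->p", Z, m_a, Z)
    grad["log_omega"] = p.omega * np.diag(m_a)
    grad["log_sigma2"] = -0.5 * n + 0.5 * quad / p.sigma2

    # kernel amplitude: every block (incl. jitter) is linear in v_gp
    grad["log_v"] = (
        np.sum(e_nm * k_nm) + np.sum(e_mm * k_mm) + np.sum(e_nn * k_nn))

    # periodic lengthscale: dK/dlog l = K * 4 sin^2(d/2) / l^2
    lt2 = p.ell_theta**2
    grad["log_ell_theta"] = (
        np.sum(e_nm * k_nm * (4.0 * st_nm**2 / lt2))
        + np.sum(e_mm * (k_mm - jit * np.eye(m)) * (4.0 * st_mm**2 / lt2))
        + np.sum(e_nn * k_nn * (4.0 * st_nn**2 / lt2)))

    # cell-cycle angles: dK[i,j]/dtheta_i = -K sin(theta_i - theta_j)/l^2
    w_nm = e_nm * k_nm
    w_mm = e_mm * (k_mm - jit * np.eye(m))
    w_nn = e_nn * k_nn
    grad["theta"] = (
        -np.sum(w_nm * np.sin(dth_nm), axis=1) / lt2
        - 2.0 * np.sum(w_nn * np.sin(dth_nn), axis=1) / lt2)
    grad["theta_u"] = (
        np.sum(w_nm * np.sin(dth_nm), axis=0) / lt2
        - 2.0 * np.sum(w_mm * np.sin(dth_mm), axis=1) / lt2)

    # SE blocks share the pattern dK[i,j]/dx_i = -K (x_i - x_j)/l^2
    def se_grads(w_nm_, w_mm_, w_nn_, d_nm, d_mm, d_nn, sq_nm, sq_mm, sq_nn,
                 ell):
        l2 = ell**2
        g_rows = (
            -np.einsum("nm,nmd->nd", w_nm_, d_nm) / l2
            - 2.0 * np.einsum("nj,njd->nd", w_nn_, d_nn) / l2)
        g_ind = (
            np.einsum("nm,nmd->md", w_nm_, d_nm) / l2
            - 2.0 * np.einsum("mk,mkd->md", w_mm_, d_mm) / l2)
        g_ell = (
            np.sum(w_nm_ * sq_nm) + np.sum(w_mm_ * sq_mm)
            + np.sum(w_nn_ * sq_nn)) / l2
        return g_rows, g_ind, g_ell

    grad["X"], grad["X_u"], grad["log_ell_X"] = se_grads(
        w_nm, w_mm, w_nn, dx_nm, dx_mm, dx_nn, sqx_nm, sqx_mm, sqx_nn,
        p.ell_X)
    if d_b > 0:
        grad["B"], grad["B_u"], grad["log_ell_B"] = se_grads(
            w_nm, w_mm, w_nn, db_nm, db_mm, db_nn, sqb_nm, sqb_mm, sqb_nn,
            p.ell_B)
    else:
        grad["B"] = np.zeros((n, 0))
        grad["B_u"] = np.zeros((m, 0))
        grad["log_ell_B"] = 0.0
    return value, grad


def _linear_core(p: GplvmParams, Y: np.ndarray, Z: np.ndarray,
                 want_grad: bool):
    """Exact marginal (and gradient) in linear-kernel mode, K = v X X'."""
    n, j_genes = Y.shape
    k_nn = p.v_gp * (p.X @ p.X.T)
    a_mat = (Z * p.delta) @ Z.T + np.diag(p.omega)
    c = k_nn + a_mat
    l_c = cholesky(c, lower=True)
    r = Y - (Z @ p.zeta)[:, None]
    cir = cho_solve((l_c, True), r)
    quad = np.einsum("nj,nj->j", r, cir)
    logdet_c = 2.0 * np.sum(np.log(np.diag(l_c)))
    value = (
        -0.5 * n * np.sum(np.log(2.0 * np.pi * p.sigma2))
        - 0.5 * j_genes * logdet_c
        - 0.5 * float(np.sum(quad / p.sigma2)))
    if not want_grad:
        return value, None
    cinv = cho_solve((l_c, True), np.eye(n))
    g_mat = -0.5 * j_genes * cinv + 0.5 * (cir / p.sigma2) @ cir.T
    grad = {
        "zeta": Z.T @ (cir @ (1.0 / p.sigma2)),
        "log_delta": p.delta * np.einsum("np,nm,mp->p", Z, g_mat, Z),
        "log_omega": p.omega * np.diag(g_mat),
        "log_sigma2": -0.5 * n + 0.5 * quad / p.sigma2,
        "log_v": float(np.sum(g_mat * k_nn)),
        "X": 2.0 * p.v_gp * (g_mat @ p.X),
    }
    return value, grad


def titsias_bound(Y, Z, params: GplvmParams) -> float:
    """Sparse lower bound on the summed log marginal likelihood."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    value, _ = _bound_core(params, Y, np.asarray(Z, dtype=float), False)
    return value


def titsias_bound_grad(Y, Z, params: GplvmParams) -> tuple[float, dict]:
    """Bound value plus gradient dict keyed like the internal packer."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    return _bound_core(params, Y, np.asarray(Z, dtype=float), True)


# ---------------------------------------------------------------------------
# the model / results pair


class GPLVM:
    """Sparse GPLVM over a cells x genes log-expression matrix.

    Parameters
    ----------
    Y : array (n_cells, n_genes)
        Log-normalised expression (e.g. logCPM).  Genes are mean-centred by
        default so the shared mean Z zeta only carries covariate effects.
    design : array (n_cells, P)
        Known-covariate design matrix Z (donor / plate / condition
        indicators and any continuous covariates).
    config : GplvmConfig
    """

    def __init__(self, Y, design, config: GplvmConfig | None = None,
                 design_labels=None):
        self.config = config or GplvmConfig()
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        Z = np.atleast_2d(np.asarray(design, dtype=float))
        if Y.shape[0] != Z.shape[0]:
            raise ValueError("Y and design must have matching cell counts")
        if not np.all(np.isfinite(Y)):
            raise ValueError("Y must be finite")
        if Y.shape[0] < self.config.n_inducing:
            raise ValueError("need at least n_inducing cells")
        self.gene_means = Y.mean(axis=0)
        self.Y = Y - self.gene_means if self.config.center_genes else Y.copy()
        self.Z = Z
        self.design_labels = list(design_labels) if design_labels is not None \
            else [f"z{i}" for i in range(Z.shape[1])]

    # -- initialisation -----------------------------------------------------
    def _initial_params(self) -> GplvmParams:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        n, j = self.Y.shape
        # per-gene OLS on Z gives gamma_j realisations: zeta/Delta moments
        coef, *_ = np.linalg.lstsq(self.Z, self.Y, rcond=None)
        zeta = coef.mean(axis=1)
        delta = np.clip(coef.var(axis=1), 1e-3, None)
        resid = self.Y - self.Z @ coef
        # principal components of the residual for X (first d_X) and B (next)
        u, s, _ = np.linalg.svd(resid, full_matrices=False)
        d_tot = cfg.d_X + cfg.d_B
        pcs = u[:, :d_tot] * s[:d_tot]
        pcs = pcs / np.maximum(pcs.std(axis=0), 1e-9)
        x0 = pcs[:, :cfg.d_X]
        b0 = pcs[:, cfg.d_X:d_tot]
        theta0 = rng.uniform(0.0, 2.0 * np.pi, size=n)
        sigma2 = np.clip(resid.var(axis=0), 1e-6, None)
        if cfg.kernel_mode == "linear":
            return GplvmParams(
                zeta=zeta, delta=delta, omega=np.ones(n), sigma2=sigma2,
                theta=theta0, B=b0, X=x0,
                theta_u=np.zeros(0), B_u=np.zeros((0, cfg.d_B)),
                X_u=np.zeros((0, cfg.d_X)), v_gp=0.5, jitter=cfg.jitter)
        # inducing points: k-means in (X, B, cos/sin theta) space
        from sklearn.cluster import KMeans
        feats = np.column_stack([x0, b0, np.cos(theta0), np.sin(theta0)])
        km = KMeans(n_clusters=cfg.n_inducing, n_init=3,
                    random_state=cfg.seed).fit(feats)
        cent = km.cluster_centers_
        x_u = cent[:, :cfg.d_X]
        b_u = cent[:, cfg.d_X:cfg.d_X + cfg.d_B]
        th_u = np.mod(np.arctan2(cent[:, -1], cent[:, -2]), 2 * np.pi)
        # median-distance lengthscale heuristic
        sub = x0[rng.choice(n, size=min(n, 300), replace=False)]
        d2 = np.sum((sub[:, None] - sub[None, :]) ** 2, axis=2)
        ell_x = float(np.sqrt(np.median(d2[d2 > 0]))) or 1.0
        return GplvmParams(
            zeta=zeta, delta=delta, omega=np.ones(n), sigma2=sigma2,
            theta=theta0, B=b0, X=x0, theta_u=th_u, B_u=b_u, X_u=x_u,
            ell_theta=1.0, ell_B=ell_x, ell_X=ell_x, v_gp=0.5,
            jitter=cfg.jitter)

    # -- fitting ------------------------------------------------------------
    def _shapes(self) -> dict:
        cfg = self.config
        n, j = self.Y.shape
        p_cols = self.Z.shape[1]
        m = 0 if cfg.kernel_mode == "linear" else cfg.n_inducing
        return {
            "zeta": (p_cols,), "log_delta": (p_cols,), "log_omega": (n,),
            "log_sigma2": (j,), "log_ell_theta": (), "log_ell_B": (),
            "log_ell_X": (), "log_v": (),
            "theta": (n,), "B": (n, cfg.d_B), "X": (n, cfg.d_X),
            "theta_u": (m,), "B_u": (m, cfg.d_B), "X_u": (m, cfg.d_X),
        }

    def fit(self, start_params: GplvmParams | None = None,
            maxiter: int | None = None, warm_start_iters: int = 50,
            verbose: bool = False) -> "GPLVMResults":
        """Maximise the sparse bound by L-BFGS with analytic gradients.

        A short warm-start stage optimises hyperparameters with the latents
        frozen at their principal-component initialisation before the joint
        stage releases everything.
        """
        cfg = self.config
        maxiter = cfg.max_iter if maxiter is None else maxiter
        p0 = start_params or self._initial_params()
        packer = _Packer(self._shapes())
        core = _linear_core if cfg.kernel_mode == "linear" else _bound_core
        trace: list[float] = []
        log_omega_min = np.log(cfg.omega_min)

        frozen = {}

        def negobj(v):
            d = packer.unpack(v)
            for k, val in frozen.items():
                d[k] = val
            d["log_omega"] = np.maximum(d["log_omega"], log_omega_min)
            p = _dict_to_params(d, cfg.jitter)
            try:
                val, grad = core(p, self.Y, self.Z, True)
            except np.linalg.LinAlgError:
                return 1e12, np.zeros_like(v)
            g = packer.pack({k: grad.get(k, np.zeros(packer.shapes[k]))
                             for k in packer.shapes})
            for k in frozen:
                g[packer.slices[k]] = 0.0
            if not np.isfinite(val):
                return 1e12, np.zeros_like(v)
            return -val, -g

        v0 = packer.pack(_params_to_dict(p0))
        if warm_start_iters > 0:
            frozen = {k: np.asarray(_params_to_dict(p0)[k])
                      for k in ("theta", "B", "X", "theta_u", "B_u", "X_u")
                      if packer.shapes[k] and np.prod(packer.shapes[k])}
            res0 = minimize(negobj, v0, jac=True, method="L-BFGS-B",
                            options={"maxiter": warm_start_iters})
            v0 = res0.x
            frozen = {}

        def cb(v):
            d = packer.unpack(v)
            d["log_omega"] = np.maximum(d["log_omega"], log_omega_min)
            p = _dict_to_params(d, cfg.jitter)
            try:
                val, _ = core(p, self.Y, self.Z, False)
            except np.linalg.LinAlgError:
                val = -np.inf
            trace.append(val)

        t0 = time.time()
        res = minimize(negobj, v0, jac=True, method="L-BFGS-B",
                       callback=cb,
                       options={"maxiter": maxiter, "ftol": cfg.tol,
                                "gtol": 1e-5})
        d = packer.unpack(res.x)
        d["log_omega"] = np.maximum(d["log_omega"], log_omega_min)
        d["theta"] = np.mod(d["theta"], 2.0 * np.pi)
        if packer.shapes["theta_u"][0]:
            d["theta_u"] = np.mod(d["theta_u"], 2.0 * np.pi)
        params = _dict_to_params(d, cfg.jitter)
        if not np.isfinite(res.fun):
            raise RuntimeError("GPLVM optimisation diverged (non-finite "
                               f"objective); trace={trace[-5:]}")
        return GPLVMResults(self, params, np.asarray(trace), res,
                            time.time() - t0)


class GPLVMResults:
    """Fitted GPLVM: latents, hyperparameters and the bound trace."""

    def __init__(self, model: GPLVM, params: GplvmParams, bound_trace,
                 optres, wall_time):
        self.model = model
        self.params = params
        self.bound_trace = bound_trace
        self.optres = optres
        self.wall_time = wall_time

    @property
    def latent(self) -> np.ndarray:
        """Target cell-state coordinates X (cells x d_X)."""
        return self.params.X.copy()

    def extract_latent(self) -> np.ndarray:
        return self.latent

    @property
    def bound(self) -> float:
        return float(self.bound_trace[-1]) if len(self.bound_trace) else \
            -float(self.optres.fun)

    def context(self) -> CellStateContext:
        p = self.params
        return CellStateContext(
            Z=self.model.Z, zeta=p.zeta, delta=p.delta, omega=p.omega,
            theta=p.theta, B=p.B, X=p.X,
            ell_theta=p.ell_theta, ell_B=p.ell_B, ell_X=p.ell_X,
            v_gp=p.v_gp, kernel_mode=self.model.config.kernel_mode,
            theta_u=p.theta_u, B_u=p.B_u, X_u=p.X_u, sigma2=p.sigma2)

    def variance_decomposition(self) -> dict:
        """Average share of marginal variance from GP / random effect / noise."""
        p = self.params
        gp_var = p.v_gp  # stationary product kernel has diag v_gp
        if self.model.config.kernel_mode == "linear":
            gp_var = float(np.mean(np.sum(p.X**2, axis=1)) * p.v_gp)
        re_var = float(np.mean((self.model.Z**2 * p.delta).sum(axis=1)))
        noise = float(np.mean(p.omega))
        tot = gp_var + re_var + noise
        return {"gp": gp_var / tot, "random_effect": re_var / tot,
                "residual": noise / tot}

    def summary(self) -> str:
        p = self.params
        vd = self.variance_decomposition()
        lines = [
            "GPLVM (sparse bound) results",
            "=" * 40,
            f"cells: {p.n_cells}   genes: {p.sigma2.shape[0]}   "
            f"inducing: {p.n_inducing}",
            f"d_X: {p.X.shape[1]}   d_B: {p.B.shape[1]}   "
            f"kernel: {self.model.config.kernel_mode}",
            f"final bound: {self.bound:.4f}   "
            f"iterations: {len(self.bound_trace)}",
            f"lengthscales  theta: {p.ell_theta:.3f}  B: {p.ell_B:.3f}  "
            f"X: {p.ell_X:.3f}",
            f"GP amplitude v: {p.v_gp:.4f}",
            "variance shares  GP: {gp:.3f}  random effect: "
            "{random_effect:.3f}  residual: {residual:.3f}".format(**vd),
            f"wall time: {self.wall_time:.1f}s",
        ]
        return "\n".join(lines)
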
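"""Covariance kernels for the cell-state Gaussian processes.

Three kernel families drive every GP in the framework: a periodic kernel
over the cell-cycle angle theta (period fixed at 2*pi), squared-exponential
kernels over the unknown-batch coordinates B and the target cell state X,
and a linear kernel X X' used as a cheap reduction for very large datasets.
Composite cell-state covariances are entrywise (Hadamard) products of the
per-coordinate kernels, which preserves symmetry and positive
semi-definiteness (Schur product theorem).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KernelSpec",
    "periodic_kernel",
    "se_kernel",
    "linear_kernel",
    "hadamard_combine",
    "add_jitter",
    "DEFAULT_JITTER",
]

#: relative jitter added to square kernel matrices before factorisation
DEFAULT_JITTER = 1e-6


@dataclass
class KernelSpec:
    """Parameters of one kernel family.

    Parameters
    ----------
    kind : {"periodic", "squared_exponential", "linear"}
    lengthscale : float or array
        Positive lengthscale; an array gives per-dimension (ARD)
        lengthscales for the squared-exponential kernel.
    variance : float
        Positive scale factor (the kernel value at zero lag).
    """

    kind: str
    lengthscale: np.ndarray | float = 1.0
    variance: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in {"periodic", "squared_exponential", "linear"}:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        ls = np.atleast_1d(np.asarray(self.lengthscale, dtype=float))
        if np.any(ls <= 0) or not np.all(np.isfinite(ls)):
            raise ValueError("lengthscale must be positive and finite")
        if self.variance <= 0 or not np.isfinite(self.variance):
            raise ValueError("variance must be positive and finite")


def periodic_kernel(theta_a, theta_b, spec: KernelSpec) -> np.ndarray:
    """Exp-sine-squared kernel over angles, period exactly 2*pi.

    Entry (i, j) is ``variance * exp(-2 sin^2((t_i - t_j)/2) / l^2)``.
    """
    if spec.kind != "periodic":
        raise ValueError("spec.kind must be 'periodic'")
    ta = np.asarray(theta_a, dtype=float).ravel()
    tb = np.asarray(theta_b, dtype=float).ravel()
    if not (np.all(np.isfinite(ta)) and np.all(np.isfinite(tb))):
        raise ValueError("angles must be finite")
    ell = float(np.atleast_1d(spec.lengthscale)[0])
    s = np.sin((ta[:, None] - tb[None, :]) / 2.0)
    return spec.variance * np.exp(-2.0 * s * s / ell**2)


def se_kernel(x_a, x_b, spec: KernelSpec) -> np.ndarray:
    """Squared-exponential (RBF) kernel, optionally ARD.

    Entry (i, j) is ``variance * exp(-sum_d (x_id - x_jd)^2 / (2 l_d^2))``.
    """
    if spec.kind != "squared_exponential":
        raise ValueError("spec.kind must be 'squared_exponential'")
    xa = np.atleast_2d(np.asarray(x_a, dtype=float))
    xb = np.atleast_2d(np.asarray(x_b, dtype=float))
    if xa.shape[1] != xb.shape[1]:
        raise ValueError(
            f"dimension mismatch: {xa.shape[1]} vs {xb.shape[1]} columns"
        )
    ell = np.atleast_1d(np.asarray(spec.lengthscale, dtype=float))
    if ell.size not in (1, xa.shape[1]):
        raise ValueError("lengthscale must be scalar or one per dimension")
    d = (xa[:, None, :] - xb[None, :, :]) / ell
    return spec.variance * np.exp(-0.5 * np.sum(d * d, axis=2))


def linear_kernel(x_a, x_b=None) -> np.ndarray:
    """Linear kernel X_a X_b'; with one argument returns X X'."""
    xa = np.atleast_2d(np.asarray(x_a, dtype=float))
    xb = xa if x_b is None else np.atleast_2d(np.asarray(x_b, dtype=float))
    return xa @ xb.T


def hadamard_combine(kernels) -> np.ndarray:
    """Entrywise product of kernel matrices (PSD-preserving)."""
    mats = [np.asarray(k, dtype=float) for k in kernels]
    if not mats:
        raise ValueError("need at least one kernel matrix")
    shape = mats[0].shape
    for m in mats[1:]:
        if m.shape != shape:
            raise ValueError(f"shape mismatch: {m.shape} vs {shape}")
    out = mats[0].copy()
    for m in mats[1:]:
        out *= m
    return out


def add_jitter(k: np.ndarray, rel: float = DEFAULT_JITTER) -> np.ndarray:
    """Return a copy of a square kernel with ``rel * max(diag)`` on the diagonal."""
    k = np.asarray(k, dtype=float)
    if k.shape[0] != k.shape[1]:
        raise ValueError("jitter applies to square matrices only")
    scale = max(float(np.max(np.diag(k))), 1.0e-12)
    return k + rel * scale * np.eye(k.shape[0])
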
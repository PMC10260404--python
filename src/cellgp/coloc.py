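"""Pairwise colocalization of two association studies over five hypotheses.

For a gene region shared by two studies (eQTL vs eQTL in another tissue, or
eQTL vs GWAS trait) the hypotheses are: H0 no signal in either study; H1 /
H2 a signal in study 1 / 2 only; H3 signals in both with two independent
causal variants; H4 signals in both sharing one causal variant.  Regional
Bayes factors are prior-weighted sums of per-variant Bayes factors,

    RBF_1 = sum_l w_l BF1_l,   RBF_2 = sum_l w_l BF2_l,
    RBF_4 = sum_l w_l BF1_l BF2_l,   RBF_3 = RBF_1 RBF_2,

(the H3 product form keeps the independent-variant approximation), all in
log space.  Posteriors combine the regional BFs with hypothesis priors
derived from {Pi_1, Pi_2, Psi_12}: P(H0)=(1-Pi1)(1-Pi2), P(H1)=Pi1(1-Pi2),
P(H2)=(1-Pi1)Pi2, P(H3)=Pi1 Pi2 - Psi12, P(H4)=Psi12.  GWAS summary
statistics enter as Wakefield approximate Bayes factors.  Across many
regions the five hypothesis priors can be estimated by EM on the
probability simplex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "ColocPriors",
    "ColocResult",
    "wakefield_abf",
    "regional_bfs",
    "coloc_posterior",
    "PairwiseColoc",
    "PairwiseColocResults",
]

#: fixed priors used for eQTL-GWAS colocalization
DEFAULT_GWAS_PRIORS = (0.2, 0.05, 0.01)


@dataclass
class ColocPriors:
    """{Pi1, Pi2, Psi12}: study-1 signal, study-2 signal, colocalization."""

    pi1: float = 0.2
    pi2: float = 0.05
    psi12: float = 0.01

    def hypothesis_priors(self) -> np.ndarray:
        """Prior probabilities of H0..H4."""
        for v in (self.pi1, self.pi2, self.psi12):
            if not 0.0 < v < 1.0:
                raise ValueError("priors must lie in (0, 1)")
        p3 = self.pi1 * self.pi2 - self.psi12
        if p3 < -1e-12:
            raise ValueError(
                f"invalid priors: Psi12={self.psi12} exceeds "
                f"Pi1*Pi2={self.pi1 * self.pi2}")
        return np.array([
            (1 - self.pi1) * (1 - self.pi2),
            self.pi1 * (1 - self.pi2),
            (1 - self.pi1) * self.pi2,
            max(p3, 0.0),
            self.psi12,
        ])


@dataclass
class ColocResult:
    log_rbf: np.ndarray       # regional log BFs of H1..H4 (H0 = 0)
    posterior: np.ndarray     # P(H0..H4 | data)

    @property
    def p_h4(self) -> float:
        return float(self.posterior[4])


def wakefield_abf(beta, se, prior_var: float = 0.04) -> np.ndarray:
    """Log approximate Bayes factor from an effect estimate and its SE.

    log ABF = 0.5 log(se^2/(se^2+W)) + z^2 W / (2 (se^2+W)) with
    z = beta/se and W the prior variance of the true effect; oriented so
    positive values favour association.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if prior_var < 0:
        raise ValueError("prior variance must be >= 0")
    z2 = (beta / se) ** 2
    s2 = se**2
    return 0.5 * np.log(s2 / (s2 + prior_var)) \
        + 0.5 * z2 * prior_var / (s2 + prior_var)


def regional_bfs(log_bf1, log_bf2, log_weights=None) -> np.ndarray:
    """Regional log Bayes factors [H1, H2, H3, H4] from per-variant log BFs.

    ``log_weights`` is the within-window variant prior (log scale, summing
    to one); uniform by default.
    """
    b1 = np.asarray(log_bf1, dtype=float).ravel()
    b2 = np.asarray(log_bf2, dtype=float).ravel()
    if b1.shape != b2.shape:
        raise ValueError("studies must share the variant index")
    n = b1.size
    if log_weights is None:
        lw = np.full(n, -np.log(n))
    else:
        lw = np.asarray(log_weights, dtype=float).ravel()
        if lw.shape != b1.shape:
            raise ValueError("weights must match the variant index")
        tot = logsumexp(lw)
        if abs(tot) > 1e-6:
            raise ValueError("weights must sum to 1 within 1e-6")
        lw = lw - tot
    lh1 = logsumexp(lw + b1)
    lh2 = logsumexp(lw + b2)
    lh4 = logsumexp(lw + b1 + b2)
    return np.array([lh1, lh2, lh1 + lh2, lh4])


def coloc_posterior(log_rbf, priors: ColocPriors | None = None
                    ) -> ColocResult:
    """Posterior over H0..H4 given regional log BFs [H1..H4]."""
    priors = priors or ColocPriors(*DEFAULT_GWAS_PRIORS)
    log_rbf = np.asarray(log_rbf, dtype=float).ravel()
    if log_rbf.shape != (4,):
        raise ValueError("expected four regional log BFs (H1..H4)")
    hp = priors.hypothesis_priors()
    with np.errstate(divide="ignore"):
        lp = np.log(hp) + np.concatenate([[0.0], log_rbf])
    post = np.exp(lp - logsumexp(lp))
    return ColocResult(log_rbf.copy(), post)


class PairwiseColoc:
    """EM estimation of hypothesis priors across many paired regions.

    Each region contributes regional log BFs [H1..H4]; the EM maximises
    sum_r log sum_h p_h RBF_rh over the prior vector p on the 5-simplex and
    reports the implied {Pi1, Pi2, Psi12} (Pi1 = p1+p3+p4, Pi2 = p2+p3+p4,
    Psi12 = p4).
    """

    def __init__(self, log_rbf_regions):
        lr = np.atleast_2d(np.asarray(log_rbf_regions, dtype=float))
        if lr.shape[1] != 4:
            raise ValueError("each region needs four regional log BFs")
        if lr.shape[0] < 2:
            raise ValueError("need at least two regions")
        if lr.shape[0] < 50:
            warnings.warn("fewer than 50 regions: prior estimates will be "
                          "noisy", RuntimeWarning)
        # prepend H0 (log RBF = 0)
        self.log_rbf = np.column_stack([np.zeros(lr.shape[0]), lr])

    def fit(self, max_iter: int = 500, tol: float = 1e-9
            ) -> "PairwiseColocResults":
        p = np.full(5, 0.2)
        trace: list[float] = []
        prev = -np.inf
        for _ in range(max_iter):
            lp = self.log_rbf + np.log(p)[None, :]
            norm = logsumexp(lp, axis=1)
            post = np.exp(lp - norm[:, None])
            ll = float(np.sum(norm))
            trace.append(ll)
            if ll - prev < tol * max(1.0, abs(ll)):
                break
            prev = ll
            p = post.mean(axis=0)
            if np.any(p < 1e-10):
                warnings.warn("prior component at boundary; clamped",
                              RuntimeWarning)
                p = np.clip(p, 1e-10, None)
                p /= p.sum()
        return PairwiseColocResults(p, post, np.asarray(trace))


class PairwiseColocResults:
    def __init__(self, prior_vector, posteriors, loglik_trace):
        self.prior_vector = np.asarray(prior_vector)
        self.posteriors = np.asarray(posteriors)
        self.loglik_trace = np.asarray(loglik_trace)

    @property
    def priors(self) -> ColocPriors:
        p = self.prior_vector
        return ColocPriors(pi1=float(p[1] + p[3] + p[4]),
                           pi2=float(p[2] + p[3] + p[4]),
                           psi12=float(p[4]))

    def summary(self) -> str:
        p = self.prior_vector
        pr = self.priors
        return "\n".join([
            "Pairwise colocalization priors (EM)",
            "=" * 40,
            "P(H0..H4): " + "  ".join(f"{v:.4f}" for v in p),
            f"Pi1={pr.pi1:.4f}  Pi2={pr.pi2:.4f}  Psi12={pr.psi12:.4f}",
            f"EM iterations: {len(self.loglik_trace)}   final loglik: "
            f"{self.loglik_trace[-1]:.3f}",
        ])
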
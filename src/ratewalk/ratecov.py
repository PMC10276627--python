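"""Closed-form moments of log branchwise rates under the log-normal
approximation to geometric Brownian rate evolution.

The log trait-evolution rate follows a Brownian path with drift `trend`
(per unit time) and infinitesimal variance `rate_variance`. The branchwise
rate is the time-average of the rate along a branch; on the log scale its
distribution is approximated as MVN(beta, rate_variance * D), where beta
captures the deterministic trend and D the shared Brownian history of
branch pairs (a branch counts as ancestral to itself, so a root branch of
length t has variance t/3 — the variance of the time-average of a standard
Brownian path).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from .treedata import Phylogeny


@dataclass
class RateProcessParams:
    """Parameters of the rate-evolution process.

    ln_root_rate : log trait-evolution rate at the root, ln(sigma0^2).
    trend : drift of the log rate per unit time (negative = early burst).
    rate_variance : diffusion rate of the log rate per unit time (>= 0).
    tip_error_variance : variance of a single raw measurement (trait units^2).
    """

    ln_root_rate: float = 0.0
    trend: float = 0.0
    rate_variance: float = 0.0
    tip_error_variance: float = 0.0

    def __post_init__(self):
        if self.rate_variance < 0:
            raise ValueError("rate_variance must be >= 0")
        if self.tip_error_variance < 0:
            raise ValueError("tip_error_variance must be >= 0")

    @property
    def rate_sd(self) -> float:
        return float(np.sqrt(self.rate_variance))


@dataclass
class BranchRates:
    """Log branchwise rates plus the latent standard-normal vector that
    generated them (one entry per non-pseudo branch, rate-index order)."""

    ln_rates: np.ndarray
    z: np.ndarray | None = None

    @property
    def rates(self) -> np.ndarray:
        return np.exp(self.ln_rates)


def _log_mean_exp_ratio(a: np.ndarray) -> np.ndarray:
    """f(a) = log((exp(a) - 1) / a), the log of the time-average of
    exp(trend * time) over a branch, in branch-local units a = trend * t.
    Series for small |a| keeps the function second-order continuous at 0."""
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    small = np.abs(a) < 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        out[~small] = np.log(np.abs(np.expm1(a[~small]) / a[~small]))
    out[small] = a[small] / 2.0 + a[small] ** 2 / 24.0
    return out


def _dlog_mean_exp_ratio(a: np.ndarray) -> np.ndarray:
    """Derivative of f(a): exp(a)/(exp(a)-1) - 1/a, with small-|a| series."""
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    small = np.abs(a) < 1e-5
    ab = a[~small]
    with np.errstate(divide="ignore", over="ignore"):
        out[~small] = 1.0 / (-np.expm1(-ab)) - 1.0 / ab
    out[small] = 0.5 + a[small] / 12.0
    return out


def compute_beta(phylo: Phylogeny, ln_root_rate: float, trend: float) -> np.ndarray:
    """Expected log branchwise rates (length = non-pseudo branch count).

    beta_k = ln_root_rate + log of the time-average of exp(trend * tau)
    over [tau1_k, tau2_k]; for a zero-length branch this is the point value
    ln_root_rate + trend * tau1_k.
    """
    nodes = phylo.rate_nodes
    tau1 = phylo.tau1[nodes]
    t = phylo.t[nodes]
    return ln_root_rate + trend * tau1 + _log_mean_exp_ratio(trend * t)


def dbeta_dtrend(phylo: Phylogeny, trend: float) -> np.ndarray:
    """d beta / d trend at the given trend (same length/order as beta)."""
    nodes = phylo.rate_nodes
    tau1 = phylo.tau1[nodes]
    t = phylo.t[nodes]
    return tau1 + t * _dlog_mean_exp_ratio(trend * t)


def compute_D(phylo: Phylogeny) -> np.ndarray:
    """Covariance structure of log branchwise rates per unit rate variance.

    D_ij = sum of branch lengths over branches ancestral to both i and j
    (each branch ancestral to itself), corrected for within-branch
    averaging: minus 2 t_i / 3 on the diagonal, minus t_i / 2 (resp.
    t_j / 2) when i is ancestral to j (resp. j to i). Symmetric PSD;
    linear in branch lengths.
    """
    M = phylo.ancestor_matrix()  # M[k, i]: k on root path of i
    nodes = phylo.rate_nodes
    Mr = M[:, nodes].astype(float)  # all branches k x rate branches i
    t_all = phylo.t.copy()
    D = (Mr * t_all[:, None]).T @ Mr  # sum_k t_k [k anc i][k anc j]
    # corrections
    t = phylo.t[nodes]
    e = len(nodes)
    A = M[np.ix_(nodes, nodes)]  # A[i, j]: i ancestral-or-equal to j
    off = np.where(A & ~np.eye(e, dtype=bool), t[:, None] / 2.0, 0.0)
    D -= off + off.T
    D[np.diag_indices(e)] -= 2.0 * t / 3.0
    return D


def cholesky_D(D: np.ndarray, jitter: float = 1e-10, tries: int = 3) -> np.ndarray:
    """Lower Cholesky factor of D, adding jitter * max(diag) to the diagonal
    on failure (up to `tries` retries, escalating tenfold). Zero-length
    branches can make D rank-deficient in pathological inputs."""
    scale = max(np.max(np.diag(D)), 1.0)
    eps = 0.0
    for k in range(tries + 1):
        try:
            return np.linalg.cholesky(D + eps * np.eye(len(D)))
        except np.linalg.LinAlgError:
            eps = jitter * scale * (10.0 ** k)
    raise np.linalg.LinAlgError(
        "D is not positive semidefinite even after jitter; malformed tree?")


def uncentered_to_rates(z: np.ndarray, params: RateProcessParams,
                        beta: np.ndarray, L: np.ndarray) -> BranchRates:
    """Map latent standard-normal z to log branchwise rates:
    ln_rates = rate_sd * L @ z + beta, with L the lower Cholesky factor of D."""
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != L.shape[0] or len(beta) != L.shape[0]:
        raise ValueError("dimension mismatch between z, beta, and L")
    return BranchRates(ln_rates=params.rate_sd * (z @ L.T) + beta, z=z)


def rate_field_logdensity(ln_rates: np.ndarray, beta: np.ndarray,
                          D: np.ndarray, rate_variance: float) -> float:
    """MVN log density of log branchwise rates with mean beta and covariance
    rate_variance * D (the rate-process factor of the joint posterior)."""
    r = np.asarray(ln_rates) - beta
    e = len(beta)
    if rate_variance == 0.0:
        return 0.0 if np.allclose(r, 0.0) else -np.inf
    L = cholesky_D(D)
    u = solve_triangular(L, r, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L))) + e * np.log(rate_variance)
    return float(-0.5 * (e * np.log(2 * np.pi) + logdet + u @ u / rate_variance))
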
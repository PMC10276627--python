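"""Likelihood of tip trait data conditional on branchwise rates.

The workhorse is Felsenstein's pruning algorithm for quantitative traits
with the root trait value marginalized (contrast / REML likelihood, i.e. an
improper flat prior on the root state). Replicate measurements and
measurement error enter through the tip initialization: a tip with m raw
measurements contributes its mean with variance sigma_y^2 / m plus the
density of its m - 1 within-tip contrasts; a tip with no measurements is
"data-deficient" (undefined expectation, infinite variance) and has no
effect on the likelihood.

A reverse-mode gradient through the pruning recursion is implemented by
hand so the posterior can be explored with Hamiltonian Monte Carlo; both
passes are jitted with numba when available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .treedata import Phylogeny, TraitData
from .ratecov import BranchRates

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

_LOG2PI = math.log(2.0 * math.pi)


# ----------------------------------------------------------------------
def tip_init(y_i, sigma_y2_i: float, m_i: int | None = None):
    """Initialize one tip for pruning.

    Returns (expectation, variance, partial_loglik). For m >= 1 the
    expectation is the measurement mean and the variance sigma_y2 / m; the
    partial log-likelihood is the sum of within-tip contrast densities
    N(y_{k+1} - mean(y_{1:k}); 0, sigma_y2 (k+1)/k) (zero for m <= 1).
    A tip with m = 0 is data-deficient: (nan, inf, 0.0).
    """
    y = np.atleast_1d(np.asarray(y_i, dtype=float))
    m = len(y) if m_i is None else int(m_i)
    if m == 0:
        return (np.nan, np.inf, 0.0)
    if m == 1:
        return (float(y[0]), float(sigma_y2_i), 0.0)
    ll = 0.0
    for k in range(1, m):
        c = y[k] - y[:k].mean()
        var = sigma_y2_i * (k + 1) / k
        if var == 0.0:
            if c != 0.0:
                warnings.warn("replicate measurements differ but tip error "
                              "variance is 0; likelihood is -inf")
                return (float(y.mean()), 0.0, -np.inf)
            continue  # identical replicates, zero-variance point mass
        ll += -0.5 * (_LOG2PI + math.log(var)) - c * c / (2.0 * var)
    return (float(y.mean()), float(sigma_y2_i / m), float(ll))


# ----------------------------------------------------------------------
@njit(cache=True)
def _prune_core(post, left, right, bv, x, v, defc, floor,
                gx, gv, gbv):  # pragma: no cover - jitted
    """Forward + reverse pruning. x, v, defc hold tip initializations on
    entry and are overwritten at internal nodes; bv[node] is the branch
    variance contribution rate*t above the node. Outputs: contrast
    log-likelihood; gbv[node] = d ll / d bv[node]; gv[tip] = d ll / d v0."""
    npost = post.shape[0]
    n = x.shape[0]
    ba_s = np.zeros(n)
    bb_s = np.zeros(n)
    clamped = np.zeros(n, dtype=np.uint8)
    ll = 0.0
    for idx in range(npost):
        f = post[idx]
        a = left[f]
        b = right[f]
        if defc[a] == 1 and defc[b] == 1:
            defc[f] = 1
            continue
        ba = v[a] + bv[a]
        bb = v[b] + bv[b]
        if defc[a] == 1:
            x[f] = x[b]
            v[f] = bb
            defc[f] = 0
            continue
        if defc[b] == 1:
            x[f] = x[a]
            v[f] = ba
            defc[f] = 0
            continue
        defc[f] = 0
        s = ba + bb
        if s < floor:
            ba = 0.5 * floor
            bb = 0.5 * floor
            s = floor
            clamped[f] = 1
        ba_s[f] = ba
        bb_s[f] = bb
        d = x[a] - x[b]
        ll += -0.5 * (1.8378770664093453 + np.log(s)) - d * d / (2.0 * s)
        x[f] = (bb * x[a] + ba * x[b]) / s
        v[f] = ba * bb / s

    for idx in range(npost - 1, -1, -1):
        f = post[idx]
        a = left[f]
        b = right[f]
        if defc[a] == 1 and defc[b] == 1:
            continue
        gxf = gx[f]
        gvf = gv[f]
        if defc[a] == 1:
            gx[b] += gxf
            gv[b] += gvf
            gbv[b] += gvf
            continue
        if defc[b] == 1:
            gx[a] += gxf
            gv[a] += gvf
            gbv[a] += gvf
            continue
        ba = ba_s[f]
        bb = bb_s[f]
        s = ba + bb
        d = x[a] - x[b]
        gs_ll = -0.5 / s + d * d / (2.0 * s * s)
        gd = -d / s
        g_xa = gxf * bb / s + gd
        g_xb = gxf * ba / s - gd
        gx[a] += g_xa
        gx[b] += g_xb
        if clamped[f] == 0:
            s2 = s * s
            g_ba = gxf * bb * (x[b] - x[a]) / s2 + gvf * bb * bb / s2 + gs_ll
            g_bb = gxf * ba * (x[a] - x[b]) / s2 + gvf * ba * ba / s2 + gs_ll
            gv[a] += g_ba
            gv[b] += g_bb
            gbv[a] += g_ba
            gbv[b] += g_bb
    return ll


# ----------------------------------------------------------------------
@dataclass
class _WithinTip:
    """Aggregated within-tip contrast pieces for free-error tips:
    ll(sy2) = const - 0.5 K ln(sy2) - ss / (2 sy2)."""
    K: float
    const: float
    ss: float

    def loglik(self, sy2: float) -> float:
        if self.K == 0:
            return self.const
        if sy2 <= 0.0:
            return self.const if self.ss == 0.0 else -np.inf
        return self.const - 0.5 * self.K * math.log(sy2) - self.ss / (2.0 * sy2)

    def dloglik(self, sy2: float) -> float:
        if self.K == 0 or sy2 <= 0.0:
            return 0.0
        return -0.5 * self.K / sy2 + self.ss / (2.0 * sy2 * sy2)


class PruneContext:
    """Precomputed pruning arrays for one (phylogeny, trait data) pair.

    Call :meth:`loglik` with per-branch rates (rate-index order) and a free
    tip-error variance; it returns the log likelihood and, optionally, its
    gradient with respect to the log branchwise rates and the error
    variance.
    """

    def __init__(self, phylo: Phylogeny, traits: TraitData,
                 rel_floor: float = 1e-12):
        if traits.labels != list(phylo.tip_labels):
            raise ValueError("trait data not aligned to tree tips")
        self.phylo = phylo
        self.traits = traits
        n = phylo.n_nodes
        self.x0 = np.zeros(n)
        self.defc0 = np.ones(n, dtype=np.uint8)  # internal nodes overwritten
        self.v0_fixed = np.zeros(n)      # variance independent of free sy2
        self.v0_scale = np.zeros(n)      # coefficient on free sy2
        self.sy2_weight = np.zeros(n)    # d v0 / d sy2 per tip (= v0_scale)
        K = 0.0
        const = 0.0
        ss = 0.0
        self.fixed_within_ll = 0.0
        for ti, node in enumerate(phylo.tip_ids):
            m = int(traits.m[ti])
            if m == 0:
                continue
            y = traits.y[ti]
            fv = traits.fixed_var[ti]
            self.defc0[node] = 0
            self.x0[node] = y.mean()
            if np.isfinite(fv):
                self.v0_fixed[node] = fv / m
                _, _, ll = tip_init(y, fv, m)
                self.fixed_within_ll += ll
            else:
                self.v0_scale[node] = 1.0 / m
                for k in range(1, m):
                    c = y[k] - y[:k].mean()
                    K += 1.0
                    const += -0.5 * (_LOG2PI + math.log((k + 1) / k))
                    ss += c * c * k / (k + 1)
        if (self.defc0[phylo.tip_ids] == 1).all():
            raise ValueError("no trait information: all tips are data-deficient")
        self.within = _WithinTip(K, const, ss)
        self.floor = rel_floor * max(traits.sigma_raw2, 1.0)
        self._post = phylo.postorder
        self._left = phylo.left
        self._right = phylo.right
        self._t = phylo.t
        self._rate_index = phylo.rate_index

    def loglik(self, ln_rates: np.ndarray, sigma_y2: float = 0.0,
               grad: bool = False):
        """Log P(y | tree, branchwise rates, tip error variance).

        With grad=True returns (ll, d ll / d ln_rates, d ll / d sigma_y2).
        """
        phylo = self.phylo
        n = phylo.n_nodes
        rates_node = np.zeros(n)
        sel = phylo.rate_nodes
        with np.errstate(over="ignore"):  # inf rate -> -inf loglik, rejected
            rates_node[sel] = np.exp(np.asarray(ln_rates, dtype=float))
        bv = rates_node * self._t
        x = self.x0.copy()
        v = self.v0_fixed + self.v0_scale * sigma_y2
        defc = self.defc0.copy()
        gx = np.zeros(n)
        gv = np.zeros(n)
        gbv = np.zeros(n)
        ll = _prune_core(self._post, self._left, self._right, bv, x, v, defc,
                         self.floor, gx, gv, gbv)
        ll += self.within.loglik(sigma_y2) + self.fixed_within_ll
        if not grad:
            return float(ll)
        g_lnr = gbv[sel] * self._t[sel] * rates_node[sel]
        g_sy2 = float(gv @ self.v0_scale) + self.within.dloglik(sigma_y2)
        return float(ll), g_lnr, g_sy2


def prune_loglik(phylo: Phylogeny, trait_data: TraitData,
                 branch_rates: BranchRates, sigma_y2: float = 0.0) -> float:
    """Convenience wrapper: contrast (REML) log likelihood of the trait data."""
    ctx = PruneContext(phylo, trait_data)
    return ctx.loglik(branch_rates.ln_rates, sigma_y2)


# ----------------------------------------------------------------------
@dataclass
class TraitCov:
    """Dense tip-trait covariance C (observed-tip order = tree tip order)
    and root-mean vector alpha; mainly a reference object for testing."""
    C: np.ndarray
    alpha: np.ndarray


def build_C(phylo: Phylogeny, branch_rates: BranchRates,
            root_value: float = 0.0) -> TraitCov:
    """Dense n x n trait covariance: C_ij = sum over branches ancestral to
    both tips i and j of rate_k * t_k. Constant rates r give r times the
    shared-path-length matrix ("squashing and stretching" of branch
    lengths)."""
    M = phylo.ancestor_matrix()
    tips = phylo.tip_ids
    rates_node = np.zeros(phylo.n_nodes)
    rates_node[phylo.rate_nodes] = branch_rates.rates
    w = rates_node * phylo.t
    Mt = M[:, tips].astype(float)
    C = (Mt * w[:, None]).T @ Mt
    alpha = np.full(phylo.n_tips, float(root_value))
    return TraitCov(C=C, alpha=alpha)


def dense_reml_loglik(phylo: Phylogeny, trait_data: TraitData,
                      branch_rates: BranchRates, sigma_y2: float = 0.0) -> float:
    """Reference likelihood: generalized-least-squares REML on the dense
    MVN of tip means (root marginalized), plus within-tip contrast terms.
    O(n^3); used to cross-check the pruning implementation."""
    obs = np.nonzero(trait_data.m > 0)[0]
    if len(obs) == 0:
        raise ValueError("no trait information")
    cov = build_C(phylo, branch_rates).C[np.ix_(obs, obs)]
    mvar = np.array([
        (trait_data.fixed_var[i] if np.isfinite(trait_data.fixed_var[i])
         else sigma_y2) / trait_data.m[i] for i in obs])
    V = cov + np.diag(mvar)
    ybar = trait_data.tip_means()[obs]
    k = len(obs)
    within = 0.0
    for i in obs:
        fv = trait_data.fixed_var[i]
        s2 = fv if np.isfinite(fv) else sigma_y2
        within += tip_init(trait_data.y[i], s2)[2]
    if k == 1:
        return float(within)
    Vi = np.linalg.inv(V)
    one = np.ones(k)
    denom = one @ Vi @ one
    alpha_hat = (one @ Vi @ ybar) / denom
    r = ybar - alpha_hat
    sign, logdet = np.linalg.slogdet(V)
    ll = -0.5 * ((k - 1) * _LOG2PI + logdet + math.log(denom) + r @ Vi @ r)
    return float(ll + within)
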
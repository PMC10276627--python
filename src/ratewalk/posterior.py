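"""Joint log posterior in unconstrained coordinates, with gradient.

Sampled coordinates (unconstrained model):

    q = [ trend, ln_root_rate, ln(rate_sd), (ln(tip_error_var)), z_1..z_e' ]

Rate variance is parameterized through its square root (``rate_sd``,
sampled on the log scale); branchwise log rates are never sampled directly
but reconstructed from the latent standard-normal vector z via
``ln_rates = rate_sd * L z + beta`` (uncentered parameterization, L the
Cholesky factor of D). Half-Cauchy priors on the rate variance and tip
error variance pick up the appropriate log-scale Jacobians. The root trait
value is marginalized analytically inside the pruning likelihood and is
not a coordinate.

The constrained variant fixes rate variance at 0 (``ln_rates = beta``
exactly); with a negative/zero/positive trend it is precisely the
conventional early-burst / Brownian-motion / late-burst model.
"""

from __future__ import annotations

import math

import numpy as np

from .treedata import Phylogeny, TraitData
from .priors import PriorSpec, half_cauchy_logpdf
from .ratecov import compute_beta, dbeta_dtrend, compute_D, cholesky_D
from .traitlik import PruneContext

_LOG2PI = math.log(2.0 * math.pi)


class Model:
    """Posterior density of the rate-evolution model.

    Parameters
    ----------
    phylo, trait_data : the comparative data. ``trait_data=None`` gives the
        prior-only model (useful for validating the sampler).
    priors : a :class:`PriorSpec`.
    constrained : fix rate variance to 0 (conventional EB/BM/LB model).
    tip_error : "free" to estimate a shared tip error variance, or a fixed
        non-negative float (0.0 = error-free measurements). Per-tip fixed
        variances in the trait table are always honored.
    """

    def __init__(self, phylo: Phylogeny, trait_data: TraitData | None,
                 priors: PriorSpec, constrained: bool = False,
                 tip_error: float | str = 0.0):
        self.phylo = phylo
        self.trait_data = trait_data
        self.priors = priors
        self.constrained = constrained
        self.free_tip_error = tip_error == "free"
        self.fixed_tip_error = 0.0 if self.free_tip_error else float(tip_error)
        self.e = phylo.n_rate_branches
        self.ctx = PruneContext(phylo, trait_data) if trait_data is not None else None
        if not constrained:
            self.D = compute_D(phylo)
            self.L = cholesky_D(self.D)
        names = ["trend", "ln_root_rate"]
        if not constrained:
            names.append("ln_rate_sd")
        if self.free_tip_error:
            names.append("ln_tip_error_variance")
        self.scalar_names = names
        self.dim = len(names) + (0 if constrained else self.e)

    # -- packing ------------------------------------------------------
    def unpack(self, q: np.ndarray) -> dict:
        q = np.asarray(q, dtype=float)
        i = 0
        out = {"trend": q[0], "ln_root_rate": q[1]}
        i = 2
        if not self.constrained:
            out["ln_rate_sd"] = q[i]
            i += 1
        if self.free_tip_error:
            out["ln_tip_error_variance"] = q[i]
            i += 1
        out["z"] = q[i:] if not self.constrained else np.zeros(0)
        return out

    def ln_rates_of(self, q: np.ndarray) -> np.ndarray:
        p = self.unpack(q)
        beta = compute_beta(self.phylo, p["ln_root_rate"], p["trend"])
        if self.constrained:
            return beta
        return math.exp(p["ln_rate_sd"]) * (self.L @ p["z"]) + beta

    def initial_q(self, jitter: float = 0.0, rng=None) -> np.ndarray:
        """Start at the Brownian-motion backbone: z = 0, trend = 0, root
        rate at its prior location, small rate variance."""
        q = np.zeros(self.dim)
        q[1] = self.priors.root_rate_loc
        i = 2
        if not self.constrained:
            q[i] = 0.5 * math.log(0.1 * self.priors.rate_variance_scale)
            i += 1
        if self.free_tip_error:
            q[i] = math.log(0.1 * self.priors.tip_error_scale)
            i += 1
        if jitter and rng is not None:
            q = q + jitter * rng.standard_normal(self.dim)
        return q

    # -- density ------------------------------------------------------
    def logp_grad(self, q: np.ndarray):
        """Joint log density (trait likelihood + latent-z density + priors
        with change-of-variable Jacobians) and its gradient."""
        q = np.asarray(q, dtype=float)
        pr = self.priors
        g = np.zeros_like(q)
        p = self.unpack(q)
        mu, r0 = p["trend"], p["ln_root_rate"]
        i_u = 2
        logp = 0.0

        # priors on trend and root rate
        logp += -0.5 * (mu / pr.trend_sd) ** 2 - math.log(pr.trend_sd) - 0.5 * _LOG2PI
        g[0] += -mu / pr.trend_sd ** 2
        d_r0 = r0 - pr.root_rate_loc
        logp += (-0.5 * (d_r0 / pr.root_rate_scale) ** 2
                 - math.log(pr.root_rate_scale) - 0.5 * _LOG2PI)
        g[1] += -d_r0 / pr.root_rate_scale ** 2

        sd = 0.0
        if not self.constrained:
            u = p["ln_rate_sd"]
            sd = math.exp(u)
            x = sd * sd  # rate variance
            s = pr.rate_variance_scale
            logp += half_cauchy_logpdf(x, s) + math.log(2.0) + 2.0 * u
            g[i_u] += 2.0 - 4.0 * x * x / (s * s + x * x)
            z = p["z"]
            logp += -0.5 * float(z @ z) - 0.5 * len(z) * _LOG2PI
            g[-len(z):] += -z

        i_w = i_u + (0 if self.constrained else 1)
        if self.free_tip_error:
            w = p["ln_tip_error_variance"]
            sy2 = math.exp(w)
            s = pr.tip_error_scale
            logp += half_cauchy_logpdf(sy2, s) + w
            g[i_w] += 1.0 - 2.0 * sy2 * sy2 / (s * s + sy2 * sy2)
        else:
            sy2 = self.fixed_tip_error

        if self.ctx is not None:
            beta = compute_beta(self.phylo, r0, mu)
            if self.constrained:
                ln_rates = beta
            else:
                ln_rates = sd * (self.L @ p["z"]) + beta
            ll, g_lnr, g_sy2 = self.ctx.loglik(ln_rates, sy2, grad=True)
            logp += ll
            g[0] += float(g_lnr @ dbeta_dtrend(self.phylo, mu))
            g[1] += float(np.sum(g_lnr))
            if not self.constrained:
                g[i_u] += float((ln_rates - beta) @ g_lnr)
                g[-self.e:] += sd * (self.L.T @ g_lnr)
            if self.free_tip_error:
                g[i_w] += g_sy2 * sy2
        return float(logp), g

    def logp(self, q: np.ndarray) -> float:
        return self.logp_grad(q)[0]

    def components(self, q: np.ndarray) -> dict:
        """The three additive pieces of the log posterior, computed
        independently: trait likelihood, latent-z (rate-field) density,
        and priors + Jacobians."""
        p = self.unpack(q)
        mu, r0 = p["trend"], p["ln_root_rate"]
        pr = self.priors
        trait = 0.0
        if self.ctx is not None:
            sy2 = (math.exp(p["ln_tip_error_variance"])
                   if self.free_tip_error else self.fixed_tip_error)
            trait = self.ctx.loglik(self.ln_rates_of(q), sy2)
        zterm = 0.0
        if not self.constrained:
            z = p["z"]
            zterm = -0.5 * float(z @ z) - 0.5 * len(z) * _LOG2PI
        total, _ = self.logp_grad(q)
        return {"trait": trait, "rate_field": zterm,
                "priors": total - trait - zterm, "total": total}


def log_posterior(z, params, phylo, trait_data, priors, **kw) -> float:
    """Functional wrapper: log posterior at latent vector z with process
    parameters `params` (a RateProcessParams)."""
    m = Model(phylo, trait_data, priors, **kw)
    q = np.zeros(m.dim)
    q[0] = params.trend
    q[1] = params.ln_root_rate
    i = 2
    if not m.constrained:
        q[i] = 0.5 * math.log(params.rate_variance)
        i += 1
    if m.free_tip_error:
        q[i] = math.log(params.tip_error_variance)
        i += 1
    if not m.constrained:
        q[i:] = z
    return m.logp(q)


def constrained_log_posterior(params, phylo, trait_data, priors, **kw) -> float:
    """Log posterior of the rate-variance-0 (EB/BM/LB) model."""
    return log_posterior(np.zeros(0), params, phylo, trait_data, priors,
                         constrained=True, **kw)
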
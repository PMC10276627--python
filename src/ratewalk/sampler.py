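"""Gradient-based MCMC: multinomial NUTS with warmup adaptation.

The no-U-turn sampler follows the multinomial scheme used by modern
probabilistic-programming backends: doubling trajectory expansion,
multinomial sampling of the proposal within each trajectory weighted by
the local density, generalized U-turn termination, dual-averaging step
size adaptation toward a target acceptance statistic, and a diagonal mass
matrix estimated during expanding warmup windows. Divergences are flagged
when the Hamiltonian error along a trajectory exceeds 1000 nats.

The model supplies a joint log density and gradient (see
:mod:`ratewalk.posterior`); nothing here is specific to phylogenetics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .posterior import Model
from .ratecov import compute_beta

__all__ = ["SamplerConfig", "PosteriorSamples", "nuts_sample", "fit",
           "diagnostics"]


@dataclass
class SamplerConfig:
    chains: int = 4
    iterations: int = 3000       # total per chain, including warmup
    warmup: int = 1500
    seed: int = 0
    target_accept: float = 0.9   # divergence-averse default
    max_treedepth: int = 10
    init_jitter: float = 0.1
    rhat_max: float = 1.05
    ess_min: float = 400.0


# ----------------------------------------------------------------------
# NUTS core
# ----------------------------------------------------------------------
class _Tree:
    __slots__ = ("q_m", "p_m", "g_m", "q_p", "p_p", "g_p", "q_prop",
                 "lp_prop", "g_prop", "lw", "rho", "diverged", "turning",
                 "alpha", "n_alpha")

    def __init__(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)


def _leapfrog(logp_grad, q, p, g, eps, minv):
    p = p + 0.5 * eps * g
    q = q + eps * minv * p
    lp, g = logp_grad(q)
    p = p + 0.5 * eps * g
    return q, p, g, lp


def _uturn(minv, rho, p_m, p_p):
    return (np.dot(minv * rho, p_m) <= 0.0) or (np.dot(minv * rho, p_p) <= 0.0)


def _build_tree(logp_grad, q, p, g, depth, direction, eps, minv, e0, rng):
    if depth == 0:
        q1, p1, g1, lp1 = _leapfrog(logp_grad, q, p, g, direction * eps, minv)
        energy = -lp1 + 0.5 * np.dot(minv * p1, p1)
        lw = e0 - energy
        diverged = (not np.isfinite(lw)) or (energy - e0 > 1000.0)
        alpha = 0.0 if not np.isfinite(lw) else min(1.0, math.exp(min(0.0, lw)))
        return _Tree(q_m=q1, p_m=p1, g_m=g1, q_p=q1, p_p=p1, g_p=g1,
                     q_prop=q1, lp_prop=lp1, g_prop=g1,
                     lw=(-np.inf if diverged else lw), rho=p1.copy(),
                     diverged=diverged, turning=False, alpha=alpha, n_alpha=1)
    first = _build_tree(logp_grad, q, p, g, depth - 1, direction, eps, minv,
                        e0, rng)
    if first.diverged or first.turning:
        return first
    if direction == 1:
        second = _build_tree(logp_grad, first.q_p, first.p_p, first.g_p,
                             depth - 1, direction, eps, minv, e0, rng)
        first.q_p, first.p_p, first.g_p = second.q_p, second.p_p, second.g_p
    else:
        second = _build_tree(logp_grad, first.q_m, first.p_m, first.g_m,
                             depth - 1, direction, eps, minv, e0, rng)
        first.q_m, first.p_m, first.g_m = second.q_m, second.p_m, second.g_m
    first.alpha += second.alpha
    first.n_alpha += second.n_alpha
    if second.diverged or second.turning:
        # an invalid subtree poisons the whole doubling; its states are
        # never sampled from
        first.diverged = first.diverged or second.diverged
        first.turning = first.turning or second.turning
        return first
    lw_tot = np.logaddexp(first.lw, second.lw)
    if math.log(rng.random() + 1e-300) < second.lw - lw_tot:
        first.q_prop, first.lp_prop, first.g_prop = (
            second.q_prop, second.lp_prop, second.g_prop)
    first.lw = lw_tot
    first.rho = first.rho + second.rho
    first.turning = second.turning or _uturn(minv, first.rho, first.p_m,
                                             first.p_p)
    return first


def _nuts_step(logp_grad, q, lp, g, eps, minv, max_depth, rng):
    d = len(q)
    p0 = rng.standard_normal(d) / np.sqrt(minv)
    e0 = -lp + 0.5 * np.dot(minv * p0, p0)
    q_m = q_p = q
    p_m = p_p = p0
    g_m = g_p = g
    rho = p0.copy()
    lw_tot = 0.0
    q_cur, lp_cur, g_cur = q, lp, g
    alpha_sum, n_alpha = 0.0, 0
    diverged = False
    depth = 0
    while depth < max_depth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(logp_grad, q_p, p_p, g_p, depth, 1, eps, minv,
                              e0, rng)
            q_p, p_p, g_p = sub.q_p, sub.p_p, sub.g_p
        else:
            sub = _build_tree(logp_grad, q_m, p_m, g_m, depth, -1, eps, minv,
                              e0, rng)
            q_m, p_m, g_m = sub.q_m, sub.p_m, sub.g_m
        alpha_sum += sub.alpha
        n_alpha += sub.n_alpha
        if sub.diverged or sub.turning:
            diverged = diverged or sub.diverged
            break
        # biased progressive sampling favors the new subtree
        if math.log(rng.random() + 1e-300) < sub.lw - lw_tot:
            q_cur, lp_cur, g_cur = sub.q_prop, sub.lp_prop, sub.g_prop
        lw_tot = np.logaddexp(lw_tot, sub.lw)
        rho = rho + sub.rho
        if _uturn(minv, rho, p_m, p_p):
            break
        depth += 1
    accept_stat = alpha_sum / max(n_alpha, 1)
    return q_cur, lp_cur, g_cur, accept_stat, diverged


def _find_eps(logp_grad, q, lp, g, minv, rng):
    eps = 1.0
    d = len(q)
    p0 = rng.standard_normal(d) / np.sqrt(minv)
    e0 = -lp + 0.5 * np.dot(minv * p0, p0)

    def log_ratio(eps):
        q1, p1, g1, lp1 = _leapfrog(logp_grad, q, p0, g, eps, minv)
        e1 = -lp1 + 0.5 * np.dot(minv * p1, p1)
        return e0 - e1 if np.isfinite(lp1) else -np.inf

    r = log_ratio(eps)
    direction = 1 if r > math.log(0.5) else -1
    for _ in range(60):
        eps *= 2.0 ** direction
        r = log_ratio(eps)
        if (direction == 1 and r <= math.log(0.5)) or \
           (direction == -1 and r >= math.log(0.5)):
            break
    return eps


def _warmup_windows(warmup: int):
    """(step-size-only init, list of slow-window end indices, start of the
    terminal step-size-only buffer). Slow windows double in size."""
    init = max(1, min(75, int(0.15 * warmup)))
    term = max(1, min(50, int(0.10 * warmup)))
    slow = warmup - init - term
    ends = []
    pos = init
    w = max(5, min(25, slow))
    while slow > 0:
        if 2 * w > slow:
            w = slow
        pos += w
        ends.append(pos)
        slow -= w
        w *= 2
    return init, ends, warmup - term


def nuts_sample(logp_grad, q0, *, n_iter: int, n_warmup: int, seed: int,
                target_accept: float = 0.9, max_treedepth: int = 10):
    """Run one NUTS chain; returns (draws, divergence count, info dict).

    `draws` has shape (n_iter - n_warmup, dim); divergences are counted
    post-warmup only (warmup divergences are reported in `info`).
    """
    rng = np.random.default_rng(seed)
    q = np.asarray(q0, dtype=float).copy()
    lp, g = logp_grad(q)
    if not np.isfinite(lp):
        raise ValueError("log posterior not finite at the initial point")
    d = len(q)
    minv = np.ones(d)
    eps = _find_eps(logp_grad, q, lp, g, minv, rng)

    # dual averaging state
    mu_da = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    init, slow_ends, term_start = _warmup_windows(n_warmup)
    welford_n, welford_m, welford_s = 0, np.zeros(d), np.zeros(d)

    keep = np.empty((n_iter - n_warmup, d))
    n_div = 0
    n_div_warm = 0
    for it in range(n_iter):
        q, lp, g, astat, div = _nuts_step(logp_grad, q, lp, g, eps, minv,
                                          max_treedepth, rng)
        if it < n_warmup:
            n_div_warm += int(div)
            da_count += 1
            frac = 1.0 / (da_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - astat)
            log_eps = mu_da - math.sqrt(da_count) / gamma * h_bar
            w = da_count ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = math.exp(log_eps)
            if init <= it < term_start:
                welford_n += 1
                delta = q - welford_m
                welford_m += delta / welford_n
                welford_s += delta * (q - welford_m)
                if slow_ends and it == slow_ends[0] - 1:
                    slow_ends.pop(0)
                    if welford_n > 1:
                        var = welford_s / (welford_n - 1)
                        minv = (welford_n / (welford_n + 5.0)) * var \
                            + 1e-3 * (5.0 / (welford_n + 5.0))
                        minv = np.maximum(minv, 1e-10)
                    welford_n, welford_m[:], welford_s[:] = 0, 0.0, 0.0
                    eps = _find_eps(logp_grad, q, lp, g, minv, rng)
                    mu_da = math.log(10.0 * eps)
                    log_eps_bar, h_bar, da_count = math.log(eps), 0.0, 0
            if it == n_warmup - 1:
                eps = math.exp(log_eps_bar)
        else:
            n_div += int(div)
            keep[it - n_warmup] = q
    info = {"step_size": eps, "inv_mass": minv,
            "warmup_divergences": n_div_warm}
    return keep, n_div, info


# ----------------------------------------------------------------------
# chain management
# ----------------------------------------------------------------------
@dataclass
class PosteriorSamples:
    """Post-warmup draws for all parameters across chains.

    `draws` maps parameter name to an array of shape (chains, draws) for
    scalars or (chains, draws, k) for vectors. Derived quantities
    (rate_variance, ln_rates, ...) are deterministic transforms of the
    stored primitives.
    """

    draws: dict
    divergences: np.ndarray
    config: SamplerConfig
    model: Model | None = None
    info: list = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def stacked(self, name: str) -> np.ndarray:
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    def quantiles(self, name: str, qs=(0.025, 0.5, 0.975)) -> np.ndarray:
        return np.quantile(self.stacked(name), qs, axis=0)


def _derive(model: Model, draws: dict) -> dict:
    """Attach deterministic transforms of the primitive draws."""
    out = dict(draws)
    if "ln_rate_sd" in draws:
        out["rate_sd"] = np.exp(draws["ln_rate_sd"])
        out["rate_variance"] = np.exp(2.0 * draws["ln_rate_sd"])
    else:
        shape = draws["trend"].shape
        out["rate_sd"] = np.zeros(shape)
        out["rate_variance"] = np.zeros(shape)
    if "ln_tip_error_variance" in draws:
        out["tip_error_variance"] = np.exp(draws["ln_tip_error_variance"])
    ch, nd = draws["trend"].shape
    e = model.e
    ln_rates = np.empty((ch, nd, e))
    for c in range(ch):
        beta = _beta_draws(model, draws["trend"][c], draws["ln_root_rate"][c])
        if model.constrained:
            ln_rates[c] = beta
        else:
            ln_rates[c] = beta + out["rate_sd"][c][:, None] * \
                (draws["z"][c] @ model.L.T)
    out["ln_rates"] = ln_rates
    return out


def _beta_draws(model: Model, trend: np.ndarray, r0: np.ndarray) -> np.ndarray:
    """beta for each draw; (draws, e)."""
    nodes = model.phylo.rate_nodes
    tau1 = model.phylo.tau1[nodes]
    t = model.phylo.t[nodes]
    from .ratecov import _log_mean_exp_ratio
    return (r0[:, None] + trend[:, None] * tau1[None, :]
            + _log_mean_exp_ratio(trend[:, None] * t[None, :]))


def fit(phylo, trait_data, priors, config: SamplerConfig | None = None,
        constrained: bool = False, tip_error: float | str = 0.0,
        model: Model | None = None) -> PosteriorSamples:
    """Sample the posterior of the rate-evolution model.

    Runs `config.chains` NUTS chains with deterministically derived
    per-chain seeds, pools post-warmup draws, attaches derived branchwise
    rates, and warns (never silently fails) if split-R̂ or effective sample
    sizes indicate the chains should be lengthened.
    """
    config = config or SamplerConfig()
    if model is None:
        model = Model(phylo, trait_data, priors, constrained=constrained,
                      tip_error=tip_error)
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chain_draws = []
    divs = []
    infos = []
    n_keep = config.iterations - config.warmup
    if n_keep <= 0:
        raise ValueError("iterations must exceed warmup")
    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        q0 = model.initial_q(jitter=config.init_jitter, rng=rng)
        draws, ndiv, info = nuts_sample(
            model.logp_grad, q0, n_iter=config.iterations,
            n_warmup=config.warmup, seed=ss.spawn(1)[0],
            target_accept=config.target_accept,
            max_treedepth=config.max_treedepth)
        chain_draws.append(draws)
        divs.append(ndiv)
        infos.append(info)
    arr = np.stack(chain_draws)  # (chains, draws, dim)
    named = {}
    for i, name in enumerate(model.scalar_names):
        named[name] = arr[:, :, i]
    if not model.constrained:
        named["z"] = arr[:, :, len(model.scalar_names):]
    samples = PosteriorSamples(draws=_derive(model, named),
                               divergences=np.array(divs), config=config,
                               model=model, info=infos)
    if config.chains >= 2:
        rep = diagnostics(samples)
        bad = rep[(rep["rhat"] > config.rhat_max)
                  | (rep["ess"] < min(config.ess_min, 100))]
        if len(bad):
            warnings.warn(
                "convergence diagnostics flagged parameters "
                f"{list(bad.index)}: max R-hat "
                f"{np.nanmax(rep['rhat']):.3f}, min ESS "
                f"{np.nanmin(rep['ess']):.0f}; lengthen the chains",
                stacklevel=2)
    return samples


def diagnostics(samples: PosteriorSamples, rhat_max: float | None = None,
                ess_min: float | None = None) -> pd.DataFrame:
    """Per-parameter rank-normalized split R-hat, bulk ESS, and pass/fail
    flags; vector parameters report their worst entry. Requires >= 2
    chains for R-hat (flagged NaN otherwise)."""
    import arviz as az
    cfg = samples.config
    rhat_max = rhat_max if rhat_max is not None else cfg.rhat_max
    ess_min = ess_min if ess_min is not None else cfg.ess_min
    rows = {}
    single = samples.n_chains < 2
    for name, a in samples.draws.items():
        if name == "z":
            continue
        if np.ptp(a) == 0.0:
            continue  # constant derived quantity (e.g. constrained model)
        dataset = az.convert_to_dataset(a if a.ndim == 3 else a[:, :, None])
        ess = float(np.nanmin(az.ess(dataset)["x"].values))
        if single:
            rhat = np.nan
        else:
            rhat = float(np.nanmax(az.rhat(dataset)["x"].values))
        rows[name] = {"rhat": rhat, "ess": ess,
                      "rhat_ok": bool(rhat <= rhat_max) if not single else False,
                      "ess_ok": bool(ess >= ess_min)}
    rep = pd.DataFrame(rows).T
    rep.attrs["divergences"] = int(samples.divergences.sum())
    rep.attrs["single_chain"] = single
    return rep
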
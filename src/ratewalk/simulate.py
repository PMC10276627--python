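"""Synthetic data generation under the rate-evolution model.

Provides pure-birth (Yule) trees rescaled to height 1, rate evolution both
as fine-grained geometric Brownian motion (the "truth" the log-normal
approximation targets) and as exact draws from the approximation itself,
Brownian trait evolution conditional on branchwise rates, and the
full simulation-study grid: rate variance in {0, 3, 6} x trend in
{-4, 0, 4} x tree sizes {50, 100, 200} x 10 replicates (270 cells), with
a trait and log rate of 0 at the root and one error-free observation per
tip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .treedata import Phylogeny, TraitData, _Node, trait_data_from_dict
from .ratecov import (RateProcessParams, BranchRates, compute_beta,
                      compute_D, cholesky_D, uncentered_to_rates)


def sim_tree(n_tips: int, seed=None) -> Phylogeny:
    """Pure-birth (Yule) tree conditioned on `n_tips` extant tips, rescaled
    to height exactly 1.

    Lineages split after exponential waiting times (total rate k per unit
    time for k lineages; the birth rate is irrelevant after rescaling and
    fixed at 1); once n lineages exist the process runs for one further
    Exp(n) waiting time before the present is set.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    t = 0.0
    root = _Node(length=0.0)
    first, second = _Node(), _Node()
    root.children = [first, second]
    active = [(first, 0.0), (second, 0.0)]
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = rng.integers(k)
        node, birth = active.pop(i)
        node.length = t - birth
        a, b = _Node(), _Node()
        node.children = [a, b]
        active.extend([(a, t), (b, t)])
    t += rng.exponential(1.0 / n_tips)
    for i, (node, birth) in enumerate(active):
        node.length = t - birth
        node.label = f"t{i + 1}"
    phy = Phylogeny(root)
    return phy.rescaled(1.0)


@dataclass
class GBMRates(BranchRates):
    """Branchwise rates from a fine-grained GBM path: `ln_rates` is the log
    of the arithmetic time-average of the rate along each branch;
    `ln_geometric` the time-average of the log rate."""
    ln_geometric: np.ndarray | None = None


def sim_rates_gbm(phylo: Phylogeny, params: RateProcessParams,
                  n_steps_per_branch: int = 50, seed=None) -> GBMRates:
    """Simulate the log rate as a discretized Brownian path with drift
    `trend` and variance rate `rate_variance` along every branch;
    branch averages are computed by the trapezoid rule on the rate
    (arithmetic) and the log rate (geometric)."""
    if n_steps_per_branch < 20:
        raise ValueError("use at least 20 steps per branch")
    rng = np.random.default_rng(seed)
    n = phylo.n_nodes
    end_val = np.empty(n)
    end_val[0] = params.ln_root_rate
    e = phylo.n_rate_branches
    ln_arith = np.zeros(e)
    ln_geo = np.zeros(e)
    sd = np.sqrt(params.rate_variance)
    for node in range(1, n):
        par = int(phylo.parent[node])
        v0 = end_val[par]
        t = phylo.t[node]
        if t == 0.0:
            end_val[node] = v0
            ri = phylo.rate_index[node]
            if ri >= 0:
                ln_arith[ri] = v0
                ln_geo[ri] = v0
            continue
        dt = t / n_steps_per_branch
        incr = rng.normal(params.trend * dt, sd * np.sqrt(dt),
                          n_steps_per_branch)
        path = v0 + np.concatenate([[0.0], np.cumsum(incr)])
        end_val[node] = path[-1]
        ri = phylo.rate_index[node]
        if ri >= 0:
            w = np.full(len(path), 1.0 / n_steps_per_branch)
            w[0] = w[-1] = 0.5 / n_steps_per_branch  # trapezoid weights
            ln_arith[ri] = np.log(w @ np.exp(path))
            ln_geo[ri] = w @ path
    return GBMRates(ln_rates=ln_arith, z=None, ln_geometric=ln_geo)


def sim_rates_approx(phylo: Phylogeny, params: RateProcessParams,
                     seed=None, L: np.ndarray | None = None) -> BranchRates:
    """Exact draw from the log-normal approximation: z ~ N(0, I),
    ln_rates = rate_sd * L z + beta."""
    rng = np.random.default_rng(seed)
    if L is None:
        L = cholesky_D(compute_D(phylo))
    z = rng.standard_normal(phylo.n_rate_branches)
    beta = compute_beta(phylo, params.ln_root_rate, params.trend)
    return uncentered_to_rates(z, params, beta, L)


def sim_traits(phylo: Phylogeny, branch_rates: BranchRates,
               root_value: float = 0.0, sigma_y2: float = 0.0,
               m_per_tip: int = 1, seed=None) -> TraitData:
    """Evolve the trait down the tree (Brownian increments with variance
    rate_k * t_k per branch), then attach `m_per_tip` observations per tip
    with measurement variance `sigma_y2` (0 noise, m = 1 reproduces the
    error-free design)."""
    rng = np.random.default_rng(seed)
    n = phylo.n_nodes
    val = np.empty(n)
    val[0] = root_value
    rates_node = np.zeros(n)
    rates_node[phylo.rate_nodes] = branch_rates.rates
    for node in range(1, n):
        par = int(phylo.parent[node])
        var = rates_node[node] * phylo.t[node]
        val[node] = val[par] + (rng.normal(0.0, np.sqrt(var)) if var > 0 else 0.0)
    values = {}
    for ti, node in enumerate(phylo.tip_ids):
        obs = val[node] + (rng.normal(0.0, np.sqrt(sigma_y2), m_per_tip)
                           if sigma_y2 > 0 else np.zeros(m_per_tip))
        values[phylo.tip_labels[ti]] = obs
    return trait_data_from_dict(values, phylo)


@dataclass
class SimStudyConfig:
    rate_variances: tuple = (0.0, 3.0, 6.0)
    trends: tuple = (-4.0, 0.0, 4.0)
    tip_counts: tuple = (50, 100, 200)
    n_reps: int = 10
    seed: int = 0
    use_gbm: bool = False          # fine-grained GBM truth instead of the
    gbm_steps: int = 50            # log-normal approximation
    sigma_y2: float = 0.0
    m_per_tip: int = 1


@dataclass
class SimCell:
    """One simulated dataset plus its generating truth."""
    tree: Phylogeny
    traits: TraitData
    params: RateProcessParams
    true_rates: BranchRates
    n_tips: int
    replicate: int
    seed: object = field(repr=False, default=None)


def sim_study_grid(config: SimStudyConfig | None = None) -> list[SimCell]:
    """Reproducible grid of (tree, traits, truth) cells; the default
    configuration yields the full 270-cell study design."""
    config = config or SimStudyConfig()
    combos = [(rv, mu, nt, rep)
              for nt in config.tip_counts
              for rv in config.rate_variances
              for mu in config.trends
              for rep in range(config.n_reps)]
    seeds = np.random.SeedSequence(config.seed).spawn(len(combos))
    cells = []
    for (rv, mu, nt, rep), ss in zip(combos, seeds):
        s_tree, s_rate, s_trait = ss.spawn(3)
        tree = sim_tree(nt, s_tree)
        params = RateProcessParams(ln_root_rate=0.0, trend=mu,
                                   rate_variance=rv,
                                   tip_error_variance=config.sigma_y2)
        if config.use_gbm:
            rates = sim_rates_gbm(tree, params, config.gbm_steps, s_rate)
        else:
            rates = sim_rates_approx(tree, params, s_rate)
        traits = sim_traits(tree, rates, root_value=0.0,
                            sigma_y2=config.sigma_y2,
                            m_per_tip=config.m_per_tip, seed=s_trait)
        cells.append(SimCell(tree=tree, traits=traits, params=params,
                             true_rates=rates, n_tips=nt, replicate=rep,
                             seed=ss))
    return cells
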
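import warnings

import numpy as np
import pytest

from ratewalk import SamplerConfig, default_priors, fit
from ratewalk.ratecov import RateProcessParams
from ratewalk.simulate import sim_tree, sim_rates_approx, sim_traits


def make_dataset(n_tips, rate_variance, trend, seed):
    """One simulation-study cell: Yule tree at height 1, rates from the
    log-normal rate process, one error-free observation per tip, trait and
    log rate 0 at the root."""
    ss = np.random.SeedSequence(seed).spawn(3)
    tree = sim_tree(n_tips, ss[0])
    params = RateProcessParams(ln_root_rate=0.0, trend=trend,
                               rate_variance=rate_variance)
    rates = sim_rates_approx(tree, params, ss[1])
    traits = sim_traits(tree, rates, root_value=0.0, seed=ss[2])
    return tree, traits, params, rates


def short_fit(tree, traits, seed, iterations=800, warmup=400, chains=2):
    priors = default_priors(tree, traits)
    cfg = SamplerConfig(chains=chains, iterations=iterations, warmup=warmup,
                        seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short chains; ESS warnings expected
        return fit(tree, traits, priors, cfg, tip_error=0.0)


#: heterogeneous-rate study scenarios: (rate variance, trend)
HET_SCENARIOS = [(3.0, -4.0), (3.0, 0.0), (3.0, 4.0),
                 (6.0, -4.0), (6.0, 0.0), (6.0, 4.0)]


@pytest.fixture(scope="session")
def calib_fits():
    """Replicate fits on 50-tip trees spanning the heterogeneous-rate
    scenarios (rate variance in {3, 6} x trend in {-4, 0, 4}), for
    coverage and shrinkage checks."""
    out = []
    reps = HET_SCENARIOS + HET_SCENARIOS[:4]  # 10 fits, all scenarios
    for k, (rv, mu) in enumerate(reps):
        tree, traits, params, rates = make_dataset(50, rv, mu, 1000 + k)
        samples = short_fit(tree, traits, seed=500 + k)
        out.append((tree, params, rates, samples))
    return out


@pytest.fixture(scope="session")
def null_fits():
    """Fits to Brownian-motion data (rate variance 0, no trend)."""
    out = []
    for rep in range(4):
        tree, traits, params, rates = make_dataset(32, 0.0, 0.0, 2000 + rep)
        samples = short_fit(tree, traits, seed=700 + rep)
        out.append((tree, params, rates, samples))
    return out
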
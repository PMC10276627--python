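"""Conventional early/late-burst model versus the rate-evolution model.

With rate variance constrained to 0 the model collapses to the classic
exponential-rate-change family (negative trend = early burst, zero =
Brownian motion, positive = late burst). This script simulates an early
burst contaminated by rate noise and compares the trend inference of the
constrained and unconstrained fits: the unconstrained model typically
detects the decline with more posterior mass below 0, because anomalous
lineages no longer mislead the trend estimate.
"""

import numpy as np

from ratewalk import SamplerConfig, default_priors, fit
from ratewalk.ratecov import RateProcessParams
from ratewalk.simulate import sim_tree, sim_rates_approx, sim_traits

tree = sim_tree(50, seed=31)
truth = RateProcessParams(ln_root_rate=0.0, trend=-4.0, rate_variance=3.0)
rates = sim_rates_approx(tree, truth, seed=32)
traits = sim_traits(tree, rates, root_value=0.0, seed=33)
priors = default_priors(tree, traits)

for constrained in (True, False):
    label = "constrained (EB/LB)" if constrained else "unconstrained"
    cfg = SamplerConfig(chains=2, iterations=1200, warmup=600, seed=4)
    s = fit(tree, traits, priors, cfg, constrained=constrained,
            tip_error=0.0)
    tr = s.stacked("trend")
    lo, hi = np.quantile(tr, [0.025, 0.975])
    print(f"{label:22s} trend median {np.median(tr):6.2f} "
          f"95% CI ({lo:6.2f}, {hi:6.2f})  PP(trend>0) {np.mean(tr > 0):.3f}")
print("\ntruth: trend -4 with rate variance 3 "
      "(a noisy early burst; lower PP(trend>0) = clearer detection)")
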
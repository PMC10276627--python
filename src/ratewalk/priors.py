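"""Default priors for the rate-evolution process.

All defaults scale with the tree height T and the pooled variance of the
raw trait measurements sigma_raw^2, so that the same settings are sensibly
weak across timescales and trait scales:

* trend           ~ Normal(0, (10/T)^2) — a trend of 10/T corresponds to an
                    e^10 ~ 20,000-fold rate change over the tree's timespan.
* rate variance   ~ Half-Cauchy(scale 5/T).
* ln(root rate)   ~ Normal(ln(sigma_raw^2 / T), 10^2), i.e. a log-normal
                    prior on the root rate roughly centered on rates that
                    could produce the observed trait spread without
                    heterogeneity.
* tip error var.  ~ Half-Cauchy(scale sigma_raw^2 / 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .treedata import Phylogeny, TraitData


def half_cauchy_logpdf(x: float, scale: float) -> float:
    """log of 2 / (pi s (1 + (x/s)^2)) for x >= 0."""
    if x < 0:
        return -np.inf
    return math.log(2.0 / (math.pi * scale)) - math.log1p((x / scale) ** 2)


def half_cauchy_pdf0(scale: float) -> float:
    """Half-Cauchy density at 0 in closed form (used by the Savage-Dickey
    ratio): 2 / (pi s)."""
    return 2.0 / (math.pi * scale)


@dataclass
class PriorSpec:
    trend_sd: float
    rate_variance_scale: float
    root_rate_loc: float
    root_rate_scale: float
    tip_error_scale: float

    def __post_init__(self):
        for name in ("trend_sd", "rate_variance_scale", "root_rate_scale",
                     "tip_error_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def default_priors(phylo: Phylogeny, trait_data: TraitData,
                   **overrides) -> PriorSpec:
    """The four default priors with T- and sigma_raw^2-scaling; any field
    of :class:`PriorSpec` can be overridden by keyword.

    Raises if all measurements are identical (sigma_raw^2 = 0) and no
    explicit root-rate prior location is supplied, since the default
    location would be undefined.
    """
    T = phylo.T
    s2 = trait_data.sigma_raw2
    if s2 <= 0 and not {"root_rate_loc", "tip_error_scale"} <= overrides.keys():
        raise ValueError(
            "sigma_raw^2 = 0 (all measurements identical); supply explicit "
            "root_rate_loc and tip_error_scale priors")
    defaults = dict(
        trend_sd=10.0 / T,
        rate_variance_scale=5.0 / T,
        root_rate_loc=math.log(s2 / T) if s2 > 0 else 0.0,
        root_rate_scale=10.0,
        tip_error_scale=s2 / 2.0 if s2 > 0 else 1.0,
    )
    defaults.update(overrides)
    return PriorSpec(**defaults)
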
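import warnings

import numpy as np
import pytest

from ratewalk import (SamplerConfig, default_priors, trend_test, sd_ratio,
                      detrend, branch_anomaly_test, fold_change_summary,
                      eval_metrics, trait_data_from_dict)
from ratewalk.posterior import Model
from ratewalk.priors import PriorSpec, half_cauchy_pdf0
from ratewalk.sampler import PosteriorSamples
from ratewalk.simulate import sim_tree
from ratewalk.ratecov import compute_beta


def make_samples(tree=None, **arrays):
    """PosteriorSamples stub with hand-built draws (single chain)."""
    model = None
    if tree is not None:
        td = trait_data_from_dict(
            {lab: float(i) for i, lab in enumerate(tree.tip_labels)}, tree)
        model = Model(tree, None, default_priors(tree, td))
    draws = {k: np.asarray(v)[None, ...] for k, v in arrays.items()}
    return PosteriorSamples(draws=draws, divergences=np.zeros(1, dtype=int),
                            config=SamplerConfig(chains=1), model=model)


class TestTrendTest:
    def test_all_negative_draws(self):
        s = make_samples(trend=-np.abs(np.random.default_rng(0).normal(size=500)))
        out = trend_test(s)
        assert out["pp_increase"] == 0.0
        assert out["call"] == "decreasing"

    def test_symmetric_draws_no_call(self):
        x = np.random.default_rng(1).normal(size=2000)
        out = trend_test(make_samples(trend=x))
        assert out["pp_increase"] == pytest.approx(0.5, abs=0.05)
        assert out["call"] == "no call"

    def test_all_positive_draws(self):
        out = trend_test(make_samples(trend=np.linspace(0.1, 2, 100)))
        assert out["call"] == "increasing"


class TestSdRatio:
    PRIORS = PriorSpec(trend_sd=10, rate_variance_scale=5.0,
                       root_rate_loc=0, root_rate_scale=10,
                       tip_error_scale=0.5)

    def test_posterior_equal_prior_gives_ratio_one(self):
        # draws straight from the half-Cauchy prior: density ratio at 0 ~ 1
        rng = np.random.default_rng(0)
        draws = np.abs(5.0 * rng.standard_cauchy(20_000))
        out = sd_ratio(draws, self.PRIORS)
        assert out["ratio"] == pytest.approx(1.0, abs=0.2)
        assert not out["significant_rate_variance"]

    def test_posterior_away_from_zero_gives_small_ratio(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(4.0, 0.3, 5000)
        out = sd_ratio(draws, self.PRIORS)
        assert out["ratio"] < 0.05
        assert out["significant_rate_variance"]

    def test_prior_density_closed_form(self):
        out = sd_ratio(np.abs(np.random.default_rng(2).normal(2, 1, 2000)),
                       self.PRIORS)
        assert out["prior_density_0"] == pytest.approx(2 / (np.pi * 5.0))
        assert half_cauchy_pdf0(5.0) == pytest.approx(2 / (np.pi * 5.0))

    def test_few_draws_warns(self):
        with pytest.warns(UserWarning, match="draws"):
            sd_ratio(np.abs(np.random.default_rng(3).normal(1, 1, 200)),
                     self.PRIORS)


@pytest.fixture(scope="module")
def tree():
    return sim_tree(10, 21)


class TestDetrend:
    def _samples(self, tree, trend, ln_rates, r0=0.0):
        n = len(trend)
        return make_samples(
            tree, trend=np.asarray(trend, dtype=float),
            ln_root_rate=np.full(n, r0),
            rate_sd=np.ones(n), ln_rates=np.asarray(ln_rates))

    def test_zero_trend_detrended_equals_ln_rates(self, tree):
        rng = np.random.default_rng(0)
        lnr = rng.normal(0, 1, (40, tree.n_rate_branches))
        s = self._samples(tree, np.zeros(40), lnr)
        dev = detrend(s)
        assert np.allclose(dev.detrended, lnr)

    def test_constant_rate_draw_has_zero_deviations(self, tree):
        lnr = np.full((5, tree.n_rate_branches), -0.3)
        s = self._samples(tree, np.zeros(5), lnr)
        dev = detrend(s)
        assert np.allclose(dev.deviations, 0.0, atol=1e-12)
        assert np.allclose(dev.background, -0.3)

    def test_weighted_mean_deviation_is_zero_per_draw(self, tree):
        rng = np.random.default_rng(4)
        n = 30
        lnr = rng.normal(0, 2, (n, tree.n_rate_branches))
        s = self._samples(tree, rng.normal(0, 1, n), lnr, r0=0.5)
        dev = detrend(s)
        assert np.allclose(dev.deviations @ dev.weights, 0.0, atol=1e-10)

    def test_detrending_removes_time_component_only(self, tree):
        # beta minus the root-rate level is subtracted: a pure-trend draw
        # detrends to a constant
        mu = -3.0
        r0 = 0.7
        beta = compute_beta(tree, r0, mu)
        s = self._samples(tree, [mu], beta[None, :], r0=r0)
        dev = detrend(s)
        assert np.allclose(dev.detrended, r0)

    def test_subset_background(self, tree):
        rng = np.random.default_rng(5)
        lnr = rng.normal(0, 1, (20, tree.n_rate_branches))
        s = self._samples(tree, np.zeros(20), lnr)
        idx = np.array([0, 2, 5])
        dev = detrend(s, subset=idx)
        t = tree.t[tree.rate_nodes]
        w = t[idx] / t[idx].sum()
        assert np.allclose(dev.background, lnr[:, idx] @ w)

    def test_arithmetic_mean_variant(self, tree):
        rng = np.random.default_rng(6)
        lnr = rng.normal(0, 1, (10, tree.n_rate_branches))
        s = self._samples(tree, np.zeros(10), lnr)
        dev = detrend(s, mean="arithmetic")
        t = tree.t[tree.rate_nodes]
        w = t / t.sum()
        assert np.allclose(dev.background, np.log(np.exp(lnr) @ w))
        # arithmetic background dominates the geometric one (Jensen)
        assert np.all(dev.background >= detrend(s).background - 1e-12)


class TestAnomalyCalls:
    def test_thresholds(self):
        tree = sim_tree(4, 3)
        rng = np.random.default_rng(7)
        e = tree.n_rate_branches
        n = 400
        lnr = rng.normal(0, 0.05, (n, e))
        lnr[:, 0] += 10.0   # always fastest
        lnr[:, 1] -= 10.0   # always slowest
        s = make_samples(tree, trend=np.zeros(n),
                         ln_root_rate=np.zeros(n), rate_sd=np.ones(n),
                         ln_rates=lnr)
        calls = branch_anomaly_test(detrend(s))
        assert calls["call"][0] == "fast"
        assert calls["call"][1] == "slow"


class TestFoldChange:
    def test_zero_rate_sd_is_point_mass(self):
        mu = np.full(3000, -0.3)
        s = make_samples(trend=mu, rate_sd=np.zeros(3000),
                         rate_variance=np.zeros(3000))
        out = fold_change_summary(s, seed=1)
        assert np.allclose(out["fold_change_draws"], np.exp(-0.3))
        assert out["median_fold_change"] == pytest.approx(np.exp(-0.3))

    def test_lognormal_identities(self):
        rng = np.random.default_rng(2)
        mu = rng.normal(-0.1, 0.02, 20_000)
        sd = np.full_like(mu, 0.6)
        s = make_samples(trend=mu, rate_sd=sd, rate_variance=sd ** 2)
        out = fold_change_summary(s, seed=3)
        fc = out["fold_change_draws"]
        assert np.median(fc) == pytest.approx(np.exp(-0.1), rel=0.05)
        assert fc.mean() == pytest.approx(np.exp(-0.1 + 0.36 / 2), rel=0.05)
        assert out["mean_rate_trend_median"] == pytest.approx(-0.1 + 0.18,
                                                              abs=0.01)


class TestEvalMetrics:
    def test_point_mass_posterior(self):
        s = make_samples(trend=np.full(100, 1.5))
        m = eval_metrics(s, {"trend": 1.5})
        assert m.loc["trend", "mae"] == 0.0
        assert m.loc["trend", "breadth"] == 0.0
        assert m.loc["trend", "coverage"] == 1.0

    def test_standard_normal_around_truth(self):
        rng = np.random.default_rng(8)
        draws = rng.normal(2.0, 1.0, 100_000)
        m = eval_metrics(make_samples(trend=draws), {"trend": 2.0})
        assert m.loc["trend", "mae"] == pytest.approx(0.674, abs=0.02)
        assert m.loc["trend", "breadth"] == pytest.approx(3.92, abs=0.05)
        assert m.loc["trend", "coverage"] == 1.0

    def test_branchwise_averaging(self):
        rng = np.random.default_rng(9)
        lnr = rng.normal(0, 1, (5000, 3)) + np.array([0.0, 5.0, 0.0])
        s = make_samples(ln_rates=lnr)
        m = eval_metrics(s, {"ln_rates": np.zeros(3)})
        assert m.loc["ln_rates", "coverage"] == pytest.approx(2 / 3)
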
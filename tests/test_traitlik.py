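import numpy as np
import pytest
from scipy.stats import norm

from ratewalk import (read_tree, trait_data_from_dict, tip_init,
                      prune_loglik, build_C, dense_reml_loglik, PruneContext)
from ratewalk.ratecov import BranchRates
from ratewalk.simulate import sim_tree


def random_dataset(rng, n_tips, missing=0.0, replicates=False, fixed=0.0):
    phy = sim_tree(n_tips, rng)
    vals, fv = {}, {}
    for lab in phy.tip_labels:
        u = rng.random()
        if u < missing:
            continue
        m = int(rng.integers(1, 4)) if replicates else 1
        vals[lab] = rng.normal(0, 1, m)
        if rng.random() < fixed:
            fv[lab] = float(rng.uniform(0.05, 0.5))
    td = trait_data_from_dict(vals, phy, fv)
    lnr = rng.normal(0, 1.5, phy.n_rate_branches)
    return phy, td, BranchRates(lnr)


class TestTipInit:
    def test_single_measurement(self):
        x, v, ll = tip_init([2.7], 0.4)
        assert (x, v, ll) == (2.7, 0.4, 0.0)

    def test_missing_is_data_deficient(self):
        x, v, ll = tip_init([], 0.4)
        assert np.isnan(x) and np.isinf(v) and ll == 0.0

    def test_two_measurements_contrast_density(self):
        # contrast y2 - y1 has variance 2 sigma_y^2: (4 pi)^(-1/2) e^(-1/4)
        _, v, ll = tip_init([0.0, 1.0], 1.0)
        assert np.exp(ll) == pytest.approx((4 * np.pi) ** -0.5 * np.exp(-0.25))
        assert v == pytest.approx(0.5)

    def test_contrast_oracle_general(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 5)
        s2 = 0.3
        _, _, ll = tip_init(y, s2)
        want = sum(norm.logpdf(y[k] - y[:k].mean(), 0,
                               np.sqrt(s2 * (k + 1) / k))
                   for k in range(1, len(y)))
        assert ll == pytest.approx(want, abs=1e-12)

    def test_zero_variance_conflicting_replicates(self):
        with pytest.warns(UserWarning, match="tip error"):
            _, _, ll = tip_init([0.0, 1.0], 0.0)
        assert ll == -np.inf


class TestPruneLoglik:
    def test_two_tip_closed_form(self):
        phy = read_tree("(A:1,B:1);")
        td = trait_data_from_dict({"A": 0.3, "B": 1.1}, phy)
        r = np.log(np.array([0.8, 0.8]))
        ll = prune_loglik(phy, td, BranchRates(r))
        assert ll == pytest.approx(norm.logpdf(0.3 - 1.1, 0, np.sqrt(1.6)))

    @pytest.mark.parametrize("n_tips,missing,replicates,fixed,sy2", [
        (4, 0.0, False, 0.0, 0.0),
        (8, 0.0, False, 0.0, 0.3),
        (10, 0.2, True, 0.0, 0.2),
        (10, 0.1, True, 0.3, 0.15),
        (6, 0.4, False, 0.0, 0.0),
    ])
    def test_matches_dense_mvn_oracle(self, n_tips, missing, replicates,
                                      fixed, sy2):
        rng = np.random.default_rng(n_tips * 7 + int(missing * 10))
        for _ in range(4):
            phy, td, br = random_dataset(rng, n_tips, missing, replicates,
                                         fixed)
            if td.n_observed == 0:
                continue
            assert prune_loglik(phy, td, br, sy2) == pytest.approx(
                dense_reml_loglik(phy, td, br, sy2), abs=1e-8)

    def test_deficient_tip_has_no_effect(self):
        rng = np.random.default_rng(17)
        phy = sim_tree(6, rng)
        lnr = rng.normal(0, 1, phy.n_rate_branches)
        vals = {lab: float(rng.normal()) for lab in phy.tip_labels}
        full = trait_data_from_dict(vals, phy)
        drop = dict(vals)
        drop.pop(phy.tip_labels[2])
        part = trait_data_from_dict(drop, phy)
        # compare against the likelihood on the pruned-down dense oracle
        lp_full_missing = prune_loglik(phy, part, BranchRates(lnr))
        ld = dense_reml_loglik(phy, part, BranchRates(lnr))
        assert lp_full_missing == pytest.approx(ld, abs=1e-8)
        assert lp_full_missing != pytest.approx(
            prune_loglik(phy, full, BranchRates(lnr)))

    def test_tip_order_invariance(self):
        # same topology written with children rotated
        a = read_tree("((A:1,B:2):0.5,(C:0.7,D:0.7):1.2);")
        b = read_tree("((D:0.7,C:0.7):1.2,(B:2,A:1):0.5);")
        vals = {"A": 0.1, "B": -0.4, "C": 1.0, "D": 0.3}
        rate_by_label = {"A": 0.2, "B": -0.1, "C": 0.5, "D": -0.3}

        def ll(phy):
            lnr = np.zeros(phy.n_rate_branches)
            for lab, i in zip(phy.tip_labels, phy.tip_ids):
                lnr[phy.rate_index[i]] = rate_by_label[lab]
            return prune_loglik(phy, trait_data_from_dict(vals, phy),
                                BranchRates(lnr))

        assert ll(a) == pytest.approx(ll(b), abs=1e-12)

    def test_all_missing_rejected(self):
        phy = read_tree("(A:1,B:1);")
        td = trait_data_from_dict({}, phy)
        with pytest.raises(ValueError, match="no trait information"):
            prune_loglik(phy, td, BranchRates(np.zeros(2)))

    def test_zero_error_limit_equals_no_error_likelihood(self):
        rng = np.random.default_rng(3)
        phy, td, br = random_dataset(rng, 7)
        l0 = prune_loglik(phy, td, br, 0.0)
        leps = prune_loglik(phy, td, br, 1e-12)
        assert leps == pytest.approx(l0, abs=1e-6)


class TestBuildC:
    def test_constant_rates_scale_path_lengths(self):
        phy = sim_tree(8, 2)  # ultrametric, height 1
        r = 1.7
        C = build_C(phy, BranchRates(np.full(phy.n_rate_branches,
                                             np.log(r)))).C
        assert np.allclose(np.diag(C), r * 1.0)
        # off-diagonals equal r x mrca depth
        tips = phy.tip_ids
        i, j = 0, 1
        mrca = phy.mrca(int(tips[i]), int(tips[j]))
        assert C[i, j] == pytest.approx(r * phy.tau2[mrca])

    def test_two_tip_diagonal(self):
        phy = read_tree("(A:1,B:1);")
        C = build_C(phy, BranchRates(np.log([2.0, 3.0]))).C
        assert np.allclose(C, [[2, 0], [0, 3]])

    def test_path_sum_oracle(self):
        rng = np.random.default_rng(6)
        phy = sim_tree(6, rng)
        br = BranchRates(rng.normal(0, 1, phy.n_rate_branches))
        C = build_C(phy, br).C
        rates_node = np.zeros(phy.n_nodes)
        rates_node[phy.rate_nodes] = br.rates
        for i, ti in enumerate(phy.tip_ids):
            for j, tj in enumerate(phy.tip_ids):
                want = sum(rates_node[k] * phy.t[k] for k in
                           phy.shared_ancestral_branches(int(ti), int(tj)))
                assert C[i, j] == pytest.approx(want)


class TestGradient:
    def test_matches_finite_differences(self):
        rng = np.random.default_rng(12)
        phy, td, br = random_dataset(rng, 9, missing=0.1, replicates=True)
        ctx = PruneContext(phy, td)
        sy2 = 0.25
        ll, g, gs = ctx.loglik(br.ln_rates, sy2, grad=True)
        eps = 1e-6
        for i in range(len(g)):
            lp = br.ln_rates.copy(); lp[i] += eps
            lm = br.ln_rates.copy(); lm[i] -= eps
            fd = (ctx.loglik(lp, sy2) - ctx.loglik(lm, sy2)) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)
        fd_s = (ctx.loglik(br.ln_rates, sy2 + eps)
                - ctx.loglik(br.ln_rates, sy2 - eps)) / (2 * eps)
        assert gs == pytest.approx(fd_s, rel=1e-5)
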
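import math

import numpy as np
import pytest
from scipy.stats import chi2

from sbias import (Chronogram, SignalEngine, blomberg_k, k_permutation_test,
                   lambda_loglik, lambda_lrt, pagel_lambda_ml, phylo_mean,
                   read_newick, signal_tests, simulate_pure_birth,
                   simulate_trait, vcv)

from conftest import make_balanced


def pic_contrast_variance(tree: Chronogram, x: np.ndarray) -> float:
    """Independent oracle: variance of standardized Felsenstein contrasts.

    Classic pruning recursion on a binary tree; equals the GLS mean-squared
    error (x - a1)' C^-1 (x - a1) / (n-1) exactly.
    """
    vals = {int(t): x[i] for i, t in enumerate(tree.tips)}
    lens = {}
    for v in tree.tips:
        v = int(v)
        lens[v] = tree.age[tree.parent[v]] - tree.age[v]
    contrasts = []
    for v in tree.postorder():
        v = int(v)
        kids = tree.children[v]
        if not kids:
            continue
        l, r = kids
        contrasts.append((vals[l] - vals[r]) / math.sqrt(lens[l] + lens[r]))
        vals[v] = ((vals[l] / lens[l] + vals[r] / lens[r])
                   / (1.0 / lens[l] + 1.0 / lens[r]))
        bl = (tree.age[tree.parent[v]] - tree.age[v]
              if v != tree.root else 0.0)
        lens[v] = bl + lens[l] * lens[r] / (lens[l] + lens[r])
    n = tree.n_tips
    return float(np.sum(np.square(contrasts)) / (n - 1))


def gls_mse(tree, x):
    C = vcv(tree)
    a = phylo_mean(x, C)
    r = x - a
    return float(r @ np.linalg.solve(C, r) / (len(x) - 1))


class TestPhyloMean:
    def test_identity_vcv_gives_arithmetic_mean(self):
        x = np.array([1.0, 4.0, -2.0])
        assert phylo_mean(x, np.eye(3)) == pytest.approx(x.mean())

    def test_constant_trait(self, three_tip):
        C = vcv(three_tip)
        assert phylo_mean(np.full(3, 3.7), C) == pytest.approx(3.7)

    def test_three_tip_brute_force(self, three_tip):
        C = vcv(three_tip)
        x = np.array([1.0, 2.0, 3.0])
        Ci = np.linalg.inv(C)
        expect = (np.ones(3) @ Ci @ x) / (np.ones(3) @ Ci @ np.ones(3))
        assert phylo_mean(x, C) == pytest.approx(expect, rel=1e-12)


class TestBlombergK:
    def test_star_tree_k_is_one(self, star5):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=5)
            assert blomberg_k(x, star5) == pytest.approx(1.0, abs=1e-12)

    def test_constant_trait_rejected(self, three_tip):
        with pytest.raises(ValueError):
            blomberg_k(np.ones(3), three_tip)

    def test_invariance_to_shift_and_scale(self):
        t = simulate_pure_birth(40, 1.0, seed=1)
        x = simulate_trait(t, 0.8, seed=2).values
        k0 = blomberg_k(x, t)
        assert blomberg_k(3.0 * x + 11.0, t) == pytest.approx(k0, rel=1e-9)

    def test_permuted_traits_lower_k_on_deep_balanced_tree(self):
        tree = make_balanced(6)
        rng = np.random.default_rng(3)
        wins = 0
        for _ in range(200):
            x = simulate_trait(tree, 1.0, rng=rng).values
            k_obs = blomberg_k(x, tree)
            k_perm = blomberg_k(rng.permutation(x), tree)
            wins += k_perm < k_obs
        assert wins >= 190  # >= 95% of trials

    def test_works_on_polytomic_trees(self):
        t = read_newick("((A:1,B:1,C:1):1,D:2,E:2);")
        x = np.array([0.1, 0.2, -0.3, 1.0, -1.2])
        assert np.isfinite(blomberg_k(x, t))

    def test_mse_equals_contrast_variance_identity(self):
        # the polytomy-safe VCV route reproduces Felsenstein contrasts
        rng = np.random.default_rng(4)
        for seed in range(50):
            t = simulate_pure_birth(10, 1.0, seed=seed)
            x = rng.normal(size=10)
            assert gls_mse(t, x) == pytest.approx(
                pic_contrast_variance(t, x), rel=1e-8)


class TestKPermutationTest:
    def test_minimum_p_is_one_over_nperm_plus_one(self):
        # strong signal on a deep balanced tree: no permutation beats it
        tree = make_balanced(5)
        x = simulate_trait(tree, 1.0, seed=10).values
        p = k_permutation_test(x, tree, n_perm=999, seed=0)
        assert p >= 1.0 / 1000
        # and the bound is attained for a clean strong-signal trait
        strong = np.repeat([0.0, 10.0], 16) + 0.01 * np.arange(32)
        p2 = k_permutation_test(strong, tree, n_perm=999, seed=0)
        assert p2 == pytest.approx(1.0 / 1000)

    def test_nperm_validation(self, star5):
        with pytest.raises(ValueError):
            k_permutation_test(np.arange(5.0), star5, n_perm=0)

    def test_power_under_strong_signal(self):
        # lambda_sim = 0.9 on 200-tip chronograms: p <= 0.05 almost always
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            t = simulate_pure_birth(200, 1.0, seed=seed)
            x = simulate_trait(t, 0.9, seed=5000 + seed)
            p = k_permutation_test(x, t, n_perm=999, seed=seed)
            hits += p <= 0.05
        assert hits > 0.95 * n_rep

    def test_k_statistic_variant_agrees_in_direction(self):
        t = simulate_pure_birth(60, 1.0, seed=8)
        x = simulate_trait(t, 0.9, seed=9)
        p_mse = k_permutation_test(x, t, n_perm=499, seed=1, stat="mse")
        p_k = k_permutation_test(x, t, n_perm=499, seed=1, stat="k")
        assert p_mse <= 0.05 and p_k <= 0.05


class TestLambdaLoglik:
    def test_lambda_zero_matches_iid_normal_closed_form(self):
        t = simulate_pure_birth(25, 1.0, seed=11)
        x = simulate_trait(t, 0.3, seed=12).values
        n, H = len(x), t.height
        # C_0 = H I: MLE mean = x-bar, sigma2_hat = ss / (n H)
        ss = np.sum((x - x.mean()) ** 2)
        sig2 = ss / (n * H)
        expect = -0.5 * (n * np.log(2 * np.pi * sig2) + n * np.log(H) + n)
        assert lambda_loglik(x, t, 0.0) == pytest.approx(expect, rel=1e-10)

    def test_three_tip_brute_force(self, three_tip):
        x = np.array([0.5, 1.5, -0.7])
        lam = 0.6
        C = vcv(three_tip)
        Cl = lam * C
        np.fill_diagonal(Cl, np.diag(C))
        Ci = np.linalg.inv(Cl)
        one = np.ones(3)
        a = (one @ Ci @ x) / (one @ Ci @ one)
        r = x - a
        sig2 = r @ Ci @ r / 3
        expect = -0.5 * (3 * np.log(2 * np.pi * sig2)
                         + np.log(np.linalg.det(Cl)) + 3)
        assert lambda_loglik(x, three_tip, lam) == pytest.approx(
            expect, rel=1e-10)

    def test_continuous_in_lambda(self):
        # jumps must shrink in proportion to the grid spacing (a genuine
        # discontinuity would leave them constant under refinement)
        t = simulate_pure_birth(30, 1.0, seed=13)
        eng = SignalEngine(t)
        y = eng.project(simulate_trait(t, 0.7, seed=14).values)
        def max_jump(h):
            grid = np.arange(0.0, 1.0 + h / 2, h)
            ll = np.array([eng._loglik(y, g) for g in grid])
            assert np.all(np.isfinite(ll))
            return np.max(np.abs(np.diff(ll)))
        assert max_jump(5e-4) < 0.6 * max_jump(1e-3)
        assert max_jump(1e-3) < 2.0  # and no jump is large at 1e-3 spacing


class TestPagelLambdaML:
    def test_permuted_traits_estimate_near_zero(self):
        rng = np.random.default_rng(15)
        lams = []
        for seed in range(200):
            t = simulate_pure_birth(200, 1.0, seed=seed)
            x = simulate_trait(t, 0.9, seed=6000 + seed)
            lam, _ = pagel_lambda_ml(rng.permutation(x.values), t)
            lams.append(lam)
        assert np.mean(lams) < 0.1

    def test_invariant_to_branch_scaling(self):
        t = simulate_pure_birth(50, 1.0, seed=16)
        x = simulate_trait(t, 0.6, seed=17).values
        scaled = Chronogram(t.parent, t.age * 10.0, t.labels)
        lam1, _ = pagel_lambda_ml(x, t)
        lam2, _ = pagel_lambda_ml(x, scaled)
        assert lam2 == pytest.approx(lam1, abs=1e-6)

    def test_boundary_estimates_are_exact(self):
        # independent trait -> lambda-hat exactly 0
        t = simulate_pure_birth(50, 1.0, seed=18)
        rng = np.random.default_rng(19)
        hit0 = False
        for _ in range(10):
            lam, _ = pagel_lambda_ml(rng.normal(size=50), t)
            if lam == 0.0:
                hit0 = True
        assert hit0

    def test_lnl_hat_at_least_lnl0(self):
        t = simulate_pure_birth(30, 1.0, seed=20)
        for seed in range(10):
            x = simulate_trait(t, 0.5, seed=seed).values
            lam, lnl = pagel_lambda_ml(x, t)
            assert lnl >= lambda_loglik(x, t, 0.0) - 1e-9


class TestLambdaLRT:
    def test_p_is_one_when_lambda_zero(self):
        t = simulate_pure_birth(40, 1.0, seed=21)
        rng = np.random.default_rng(22)
        seen = False
        for _ in range(10):
            x = rng.normal(size=40)
            lam, lnl = pagel_lambda_ml(x, t)
            if lam == 0.0:
                assert lambda_lrt(x, t) == pytest.approx(1.0)
                seen = True
        assert seen

    def test_chi2_mapping(self):
        # D = 3.841 maps to p ~ 0.05 for one degree of freedom
        assert chi2.sf(3.841, 1) == pytest.approx(0.05, abs=1e-3)
        t = simulate_pure_birth(60, 1.0, seed=23)
        x = simulate_trait(t, 0.8, seed=24).values
        lam, lnl = pagel_lambda_ml(x, t)
        lnl0 = lambda_loglik(x, t, 0.0)
        assert lambda_lrt(x, t) == pytest.approx(
            chi2.sf(2 * (lnl - lnl0), 1), rel=1e-9)

    def test_near_nominal_size_under_no_signal(self):
        # boundary-at-zero makes the LRT conservative-to-nominal
        rej = 0
        n_rep = 500
        for seed in range(n_rep):
            t = simulate_pure_birth(50, 1.0, seed=seed)
            x = simulate_trait(t, 0.0, seed=7000 + seed)
            rej += lambda_lrt(x.values, t) <= 0.05
        assert rej / n_rep <= 0.07


class TestSignalTests:
    def test_full_battery_consistency(self):
        t = simulate_pure_birth(50, 1.0, seed=25)
        x = simulate_trait(t, 0.7, seed=26)
        res = signal_tests(x, t, n_perm=199, seed=0,
                           metadata={"tree_id": 0})
        assert res.K == pytest.approx(blomberg_k(x, t), rel=1e-12)
        lam, lnl = pagel_lambda_ml(x, t)
        assert res.lambda_hat == pytest.approx(lam)
        assert res.lnL_hat == pytest.approx(lnl)
        assert res.n_perm == 199
        assert res.metadata["tree_id"] == 0
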
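"""BM/OU likelihoods, AICc, and the stepwise regime search."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import multivariate_normal

import phyloconv as pc
from phyloconv.regime_models import (
    ModelError,
    RegimePainting,
    TreeLikelihoodContext,
    count_convergence,
)


class TestAicc:
    def test_closed_form_example(self):
        assert pc.aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7)

    def test_zero_parameters(self):
        assert pc.aicc(0.0, 0, 10) == pytest.approx(0.0)

    def test_matches_independent_formula_on_random_inputs(self, rng):
        for _ in range(50):
            logL = float(rng.normal(scale=50))
            k = int(rng.integers(0, 8))
            n = int(rng.integers(k + 2, 60))
            expected = -2 * logL + 2 * k + (2 * k * (k + 1)) / (n - k - 1)
            assert pc.aicc(logL, k, n) == pytest.approx(expected, rel=1e-12)

    def test_undefined_below_minimum_sample(self):
        with pytest.raises(ModelError):
            pc.aicc(0.0, 3, 4)


class TestBmFit:
    def test_two_tip_closed_form(self, cherry):
        root, s2, logL, _ = pc.bm_fit(np.array([0.0, 2.0]), cherry)
        assert root == pytest.approx(1.0)
        assert s2 == pytest.approx(1.0)

    def test_constant_trait_degenerate(self, balanced_four):
        with pytest.raises(ModelError, match="degenerate"):
            pc.bm_fit(np.full(4, 3.3), balanced_four)

    def test_loglik_matches_direct_gaussian_density(self):
        tree = pc.read_newick("(((A:2,B:2):3,(C:4,D:4):1):5,(E:6,F:6):4);")
        y = pc.simulate_bm(tree, 0.3, seed=22)[:, 0]
        root, s2, logL, _ = pc.bm_fit(y, tree)
        C = pc.phylo_cov(tree).matrix
        direct = multivariate_normal(mean=np.full(6, root), cov=s2 * C).logpdf(y)
        assert logL == pytest.approx(direct, abs=1e-8)


def _oracle_hansen(tree, painting, alpha, y):
    """Brute-force Hansen model: enumerate lineage segments, build E[y]
    design and V entry by entry from the transition formulas."""
    labels = painting.regime_labels()
    lab_i = {l: i for i, l in enumerate(labels)}
    n, T = tree.n_tips, tree.depth
    W = np.zeros((n, len(labels)))
    for tipnode, lab in zip(tree.tips, tree.tip_labels):
        i = tree.tip_index(lab)
        v = tipnode
        while v != tree.root:
            p = int(tree.parent[v])
            t0, t1 = tree.depths[p], tree.depths[v]
            W[i, lab_i[painting.branch_regimes[v]]] += math.exp(
                -alpha * (T - t1)
            ) - math.exp(-alpha * (T - t0))
            v = p
        W[i, lab_i[painting.root_regime]] += math.exp(-alpha * T)
    S = pc.phylo_cov(tree).matrix
    D = pc.patristic(tree)
    V0 = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            V0[i, j] = (
                math.exp(-alpha * D[i, j])
                * (1 - math.exp(-2 * alpha * S[i, j]))
                / (2 * alpha)
            )
    cho = cho_factor(V0, lower=True)
    theta = np.linalg.solve(W.T @ cho_solve(cho, W), W.T @ cho_solve(cho, y))
    r = y - W @ theta
    s2 = float(r @ cho_solve(cho, r)) / n
    logL = (
        -n / 2 * math.log(2 * math.pi)
        - n / 2 * math.log(s2)
        - float(np.sum(np.log(np.diag(cho[0]))))
        - n / 2
    )
    return logL, dict(zip(labels, theta)), W


class TestHansenLoglik:
    def test_bm_limit(self, balanced_four):
        y = np.array([0.1, 0.3, -0.2, 0.5])
        single = RegimePainting.from_shifts(balanced_four, {})
        logL_ou, _, _ = pc.hansen_loglik(y, balanced_four, single, 1e-8)
        _, _, logL_bm, _ = pc.bm_fit(y, balanced_four)
        assert logL_ou == pytest.approx(logL_bm, abs=1e-4)

    @pytest.mark.parametrize("alpha", [0.3, 1.0, 4.0])
    def test_brute_force_oracle(self, alpha):
        tree = pc.read_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        # shift on the (A,B) stem and on C's terminal branch: identifiable
        # (shifting BOTH root-child stems would make the design collinear)
        painting = RegimePainting.from_shifts(tree, {1: "b", 5: "c"})
        y = np.array([0.3, -0.1, 1.2, 0.8])
        logL, s2, theta = pc.hansen_loglik(y, tree, painting, alpha)
        o_logL, o_theta, _ = _oracle_hansen(tree, painting, alpha, y)
        assert logL == pytest.approx(o_logL, abs=1e-8)
        for lab, val in o_theta.items():
            assert theta[lab] == pytest.approx(val, abs=1e-8)

    def test_white_noise_limit_theta_near_regime_means(self):
        tree = pc.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        painting = RegimePainting.from_shifts(tree, {1: "b"})
        y = np.array([1.0, 1.2, -0.6, -0.4])
        _, _, theta = pc.hansen_loglik(y, tree, painting, 1e3 / tree.depth)
        means = {"b": np.mean([1.0, 1.2]), "a": np.mean([-0.6, -0.4])}
        for lab, m in means.items():
            assert theta[lab] == pytest.approx(m, rel=1e-3)

    def test_non_ultrametric_rejected(self):
        tree = pc.read_newick("((A:1,B:1):1,C:5);")
        painting = RegimePainting.from_shifts(tree, {})
        with pytest.raises(ModelError, match="ultrametric"):
            pc.hansen_loglik(np.array([0.0, 1.0, 2.0]), tree, painting, 1.0)

    @pytest.mark.parametrize("alpha", [1e-6, 0.05, 1.0, 20.0])
    def test_design_rows_sum_to_one_and_cov_pd(self, alpha, random_tree):
        ctx = TreeLikelihoodContext(random_tree)
        painting = pc.paint_random_shifts(random_tree, 3, 1, seed=4)
        from phyloconv.regime_models import _painting_arrays

        idx, root_idx, labels = _painting_arrays(random_tree, painting)
        W = ctx.design_weights(idx, root_idx, len(labels), alpha)
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-12)
        V0 = ctx.ou_cov_unit(alpha)
        np.testing.assert_allclose(V0, V0.T, atol=1e-12)
        assert np.linalg.eigvalsh(V0).min() > 0


class TestHansenFit:
    def test_half_life_identity(self):
        tree = pc.simulate_tree(12, 36.0, seed=31)
        painting = pc.paint_random_shifts(tree, 1, 0, seed=32)
        Y = pc.simulate_hansen(tree, painting, 0.5, 0.05,
                               {l: i for i, l in enumerate(painting.regime_labels())},
                               seed=33)
        fit = pc.hansen_fit(Y, tree, painting)
        np.testing.assert_allclose(fit.half_life * fit.alpha, np.log(2), rtol=1e-12)

    def test_single_regime_equals_ou1(self, random_tree):
        Y = pc.simulate_bm(random_tree, 0.1, seed=41)
        empty = RegimePainting.from_shifts(random_tree, {})
        fit = pc.hansen_fit(Y, random_tree, empty)
        assert fit.n_regimes == 1
        # parameter count is 3 per trait (alpha, sigma2, one optimum)
        assert fit.aicc == pytest.approx(
            sum(pc.aicc(ll, 3, random_tree.n_tips) for ll in fit.loglik)
        )

    def test_parameter_recovery_two_regimes(self):
        # strong-signal recovery: alpha = 3, sigma2 = 0.05, optima at +-1
        tree = pc.simulate_tree(64, 2.0, seed=51)
        painting = pc.paint_random_shifts(tree, 1, 0, seed=52)
        theta = {"a": -1.0, "b": 1.0}
        alphas, th_err = [], []
        for rep in range(20):
            Y = pc.simulate_hansen(tree, painting, 3.0, 0.05, theta, seed=100 + rep)
            fit = pc.hansen_fit(Y, tree, painting)
            alphas.append(fit.alpha[0])
            th_err.append(
                max(abs(fit.theta.loc[l, "trait1"] - theta[l]) for l in ("a", "b"))
            )
        assert 1.5 <= np.median(alphas) <= 6.0
        assert np.median(th_err) <= 0.25


class TestCountConvergence:
    def test_no_shifts(self, random_tree):
        counts = count_convergence(
            random_tree, RegimePainting.from_shifts(random_tree, {})
        )
        assert counts["n_shifts"] == 0
        assert counts["convergence_fraction"] == 0.0

    def test_disjoint_singleton_regimes_not_convergent(self, random_tree):
        painting = pc.paint_random_shifts(random_tree, 3, 0, seed=61)
        counts = count_convergence(random_tree, painting)
        assert counts["n_shifts"] == 3
        assert counts["n_convergent_regimes"] == 0
        assert counts["convergence_fraction"] == 0.0

    def test_convergent_pair_bookkeeping(self, random_tree):
        painting = pc.paint_random_shifts(random_tree, 2, 1, seed=62)
        counts = count_convergence(random_tree, painting)
        assert counts["n_shifts"] == 2
        assert counts["n_convergent_regimes"] == 1
        assert counts["convergence_fraction"] == 1.0


class TestSurface:
    def test_forward_history_strictly_decreasing(self):
        ds = pc.make_convergence_dataset(5, n_tips=20)
        painting, history = pc.surface_forward(ds.traits, ds.tree)
        aiccs = [h["aicc"] for h in history]
        assert all(b < a for a, b in zip(aiccs, aiccs[1:]))

    def test_bm_data_never_fails(self):
        tree = pc.simulate_tree(16, 36.0, seed=71)
        Y = pc.simulate_bm(tree, np.diag([0.02, 0.02]), seed=72)
        res = pc.surface(Y, tree)
        assert res.n_shifts >= 0
        assert 0.0 <= res.convergence_fraction <= 1.0

    def test_backward_aicc_not_above_forward(self):
        ds = pc.make_convergence_dataset(6, n_tips=20)
        res = pc.surface(ds.traits, ds.tree)
        fwd_final = res.forward_history[-1]["aicc"]
        assert res.fit.aicc <= fwd_final + 1e-9
        bw = [h["aicc"] for h in res.backward_history]
        assert all(b <= a + 1e-9 for a, b in zip(bw, bw[1:]))

    def test_forward_discovers_planted_shift_branches(self):
        # strong planted shifts: the forward phase should place a shift on
        # each planted branch or an immediate neighbour
        n_rep, hits = 10, 0
        for seed in range(n_rep):
            ds = pc.make_convergence_dataset(seed)
            tree = ds.tree
            painting, _ = pc.surface_forward(ds.traits, tree)
            found = painting.shifts(tree)

            def nb(v):
                s = {v, int(tree.parent[v])}
                s.update(tree.children[v])
                return s

            hits += all(
                any(f in nb(t) for f in found) for t in ds.painting.shifts(tree)
            )
        assert hits >= int(0.8 * n_rep)

    def test_backward_collapses_planted_convergent_pair(self):
        # given exactly the two planted shifts (initially distinct
        # regimes), the backward phase should merge them into one
        n_rep, merges = 20, 0
        for seed in range(n_rep):
            ds = pc.make_convergence_dataset(seed)
            tree = ds.tree
            a, b = sorted(ds.painting.shifts(tree))
            start = RegimePainting.from_shifts(tree, {a: "b", b: "c"})
            res = pc.surface_backward(ds.traits, tree, start)
            merges += (
                res.painting.branch_regimes[a] == res.painting.branch_regimes[b]
            )
        assert merges >= int(0.8 * n_rep)

    def test_multipeak_beats_simpler_models_on_planted_data(self):
        ds = pc.make_convergence_dataset(7, n_tips=24)
        res = pc.surface(ds.traits, ds.tree)
        if res.n_shifts > 0:
            assert res.fit.aicc <= res.fit_ou1.aicc + 1e-9
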
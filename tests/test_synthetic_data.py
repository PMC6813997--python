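"""Generators: trees, paintings, trait evolution, landmarks, ecology."""
import numpy as np
import pytest

import phyloconv as pc
from phyloconv.regime_models import (
    RegimePainting,
    TreeLikelihoodContext,
    _painting_arrays,
    count_convergence,
    hansen_loglik,
)
from phyloconv.synthetic_data import default_scheme


class TestSimulateTree:
    def test_two_tip_cherry(self):
        t = pc.simulate_tree(2, 5.0, seed=1)
        assert t.n_tips == 2
        np.testing.assert_allclose(sorted(t.blen[1:]), [5.0, 5.0], atol=1e-9)

    def test_study_scale_contract(self):
        t = pc.simulate_tree(48, 36.0, seed=2)
        assert t.n_tips == 48
        d = t.depths[list(t.tips)]
        assert abs(d - 36.0).max() < 1e-9

    def test_bit_reproducible(self):
        a = pc.simulate_tree(16, 36.0, seed=3)
        b = pc.simulate_tree(16, 36.0, seed=3)
        assert a.to_newick() == b.to_newick()

    def test_imbalance_consistent_with_yule(self):
        # independent oracle: Yule topologies via uniform pick-a-tip-to-split
        def colless(tree):
            sizes = {}
            tot = 0
            for v in tree.postorder():
                if not tree.children[v]:
                    sizes[v] = 1
                else:
                    kids = [sizes[c] for c in tree.children[v]]
                    sizes[v] = sum(kids)
                    if len(kids) == 2:
                        tot += abs(kids[0] - kids[1])
            return tot

        def oracle_colless(n, rng):
            # grow: each split chooses a uniformly random current tip
            sizes = [1, 1]
            children = {0: [], 1: []}
            parent = {}
            nxt = 2
            tips = [0, 1]
            while len(tips) < n:
                pick = tips.pop(int(rng.integers(len(tips))))
                a, b = nxt, nxt + 1
                nxt += 2
                children[pick] = [a, b]
                children[a] = children[b] = []
                tips.extend([a, b])
            # postorder sizes / colless
            def walk(v):
                if not children[v]:
                    return 1, 0
                (sa, ca), (sb, cb) = walk(children[v][0]), walk(children[v][1])
                return sa + sb, ca + cb + abs(sa - sb)
            tot = 0
            for r in (0, 1):
                _, c = walk(r)
                tot += c
            s0, _ = walk(0)
            s1, _ = walk(1)
            return tot + abs(s0 - s1)

        rng = np.random.default_rng(0)
        oracle = np.array([oracle_colless(32, rng) for _ in range(200)])
        observed = np.mean(
            [colless(pc.simulate_tree(32, 36.0, seed=5000 + i)) for i in range(100)]
        )
        lo, hi = np.percentile(oracle, [1, 99])
        assert lo - 5 <= observed <= hi + 5


class TestPaintRandomShifts:
    def test_zero_shifts_single_regime(self, random_tree):
        p = pc.paint_random_shifts(random_tree, 0, 0, seed=1)
        assert p.regime_labels() == ("a",)

    def test_convergent_pair_bookkeeping(self, random_tree):
        p = pc.paint_random_shifts(random_tree, 2, 1, seed=2)
        c = count_convergence(random_tree, p)
        assert c["n_shifts"] == 2
        assert c["n_convergent_regimes"] == 1
        assert c["convergence_fraction"] == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_painting_invariants_hold(self, seed):
        tree = pc.simulate_tree(24, 36.0, seed=100 + seed)
        p = pc.paint_random_shifts(tree, 3, 1, seed=seed)
        p.validate(tree)
        shifts = p.shifts(tree)
        assert len(shifts) == 3
        for v, lab in shifts.items():
            parent = int(tree.parent[v])
            parent_reg = p.root_regime if parent == tree.root else p.branch_regimes[parent]
            assert lab != parent_reg


class TestSimulateBm:
    def test_cherry_moments(self):
        t = pc.read_newick("(A:1,B:1);")
        sims = np.array(
            [pc.simulate_bm(t, 1.0, seed=1000 + i)[:, 0] for i in range(1000)]
        )
        var = sims.var(axis=0, ddof=1)
        corr = np.corrcoef(sims[:, 0], sims[:, 1])[0, 1]
        assert 0.9 <= var[0] <= 1.1 and 0.9 <= var[1] <= 1.1
        assert abs(corr) < 0.1

    def test_covariance_matches_tree_structure(self):
        t = pc.read_newick("((A:1,B:1):1,C:2);")
        R = np.array([[0.5, 0.2], [0.2, 0.4]])
        rng = np.random.default_rng(7)
        sims = np.stack([pc.simulate_bm(t, R, rng=rng) for _ in range(2000)])
        C = pc.phylo_cov(t).matrix
        # E[y_ia y_jb] = C_ij * R_ab
        for i in range(3):
            for j in range(3):
                emp = np.mean(sims[:, i, 0] * sims[:, j, 0])
                assert emp == pytest.approx(C[i, j] * R[0, 0], abs=0.12)
        emp_cross = np.mean(sims[:, 0, 0] * sims[:, 0, 1])
        assert emp_cross == pytest.approx(C[0, 0] * R[0, 1], abs=0.12)

    def test_non_psd_rate_rejected(self, random_tree):
        with pytest.raises(ValueError, match="semidefinite"):
            pc.simulate_bm(random_tree, np.array([[1.0, 2.0], [2.0, 1.0]]), seed=1)


class TestSimulateHansen:
    def test_zero_diffusion_deterministic_mean_path(self):
        tree = pc.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        painting = RegimePainting.from_shifts(tree, {1: "b"})
        alpha = 0.8
        Y = pc.simulate_hansen(tree, painting, alpha, 0.0, {"a": 0.0, "b": 2.0}, seed=1)
        # deterministic OU mean along each lineage
        import math

        def mean_tip(path_regimes_lengths):
            x = 0.0
            for reg, t in path_regimes_lengths:
                th = 2.0 if reg == "b" else 0.0
                x = th + (x - th) * math.exp(-alpha * t)
            return x

        a_expect = mean_tip([("b", 1.0), ("b", 1.0)])
        c_expect = mean_tip([("a", 1.0), ("a", 1.0)])
        assert Y[tree.tip_index("A"), 0] == pytest.approx(a_expect, abs=1e-12)
        assert Y[tree.tip_index("C"), 0] == pytest.approx(c_expect, abs=1e-12)

    def test_strong_pull_tips_near_optima(self):
        tree = pc.simulate_tree(24, 36.0, seed=21)
        painting = pc.paint_random_shifts(tree, 1, 0, seed=22)
        theta = {"a": -1.0, "b": 1.0}
        alpha, s2 = 0.5, 0.05  # alpha*T = 18, stationary sd ~ 0.22
        stat_sd = np.sqrt(s2 / (2 * alpha))
        hits = 0
        reps = 50
        for i in range(reps):
            Y = pc.simulate_hansen(tree, painting, alpha, s2, theta, seed=500 + i)
            ok = True
            for v, lab in zip(tree.tips, tree.tip_labels):
                mu = theta[painting.branch_regimes[v]]
                # only tips that spent long in their regime are near theta
            means = {}
            for reg in ("a", "b"):
                rows = [
                    tree.tip_index(lab)
                    for v, lab in zip(tree.tips, tree.tip_labels)
                    if painting.branch_regimes[v] == reg
                ]
                if rows:
                    means[reg] = Y[rows, 0].mean()
            hits += all(abs(means[r] - theta[r]) <= 3 * stat_sd for r in means)
        assert hits >= int(0.8 * reps)

    def test_tip_covariance_matches_analytic_ou(self):
        tree = pc.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        painting = RegimePainting.from_shifts(tree, {})
        alpha, s2 = 0.7, 1.0
        rng = np.random.default_rng(9)
        sims = np.stack(
            [
                pc.simulate_hansen(tree, painting, alpha, s2, {"a": 0.0}, rng=rng)[:, 0]
                for _ in range(4000)
            ]
        )
        ctx = TreeLikelihoodContext(tree)
        V = s2 * ctx.ou_cov_unit(alpha)
        emp = np.cov(sims.T)
        np.testing.assert_allclose(emp, V, rtol=0.12, atol=0.02)

    def test_likelihood_peaks_near_true_parameters(self):
        tree = pc.simulate_tree(24, 36.0, seed=31)
        painting = pc.paint_random_shifts(tree, 1, 0, seed=32)
        theta = {"a": 0.0, "b": 1.0}
        alpha = 0.3
        better = 0
        for i in range(40):
            y = pc.simulate_hansen(tree, painting, alpha, 0.02, theta, seed=700 + i)[:, 0]
            ll_true, _, _ = hansen_loglik(y, tree, painting, alpha)
            ll_off, _, _ = hansen_loglik(y, tree, painting, alpha * 20)
            better += ll_true > ll_off
        assert better >= 32  # true alpha usually beats a 20x perturbation

    def test_missing_regime_optimum_reported(self, random_tree):
        painting = pc.paint_random_shifts(random_tree, 1, 0, seed=41)
        with pytest.raises(ValueError, match="b"):
            pc.simulate_hansen(random_tree, painting, 1.0, 0.1, {"a": 0.0}, seed=1)


class TestSimulateLandmarks:
    def test_count_contract(self):
        scheme = default_scheme(3, 5)
        lm = pc.simulate_landmarks(4, scheme, seed=1)
        assert lm.n_landmarks == scheme.n_landmarks

    def test_noise_free_single_group_aligns_exactly(self):
        lm = pc.simulate_landmarks(5, default_scheme(), noise_sd=0.0, seed=2)
        aligned = pc.gpa(lm)
        from phyloconv.morphometrics import procrustes_distance

        for i in range(1, 5):
            assert procrustes_distance(aligned.coords[0], aligned.coords[i]) <= 1e-9

    def test_group_deformations_separate_in_pc1(self):
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            groups = [0] * 5 + [1] * 5
            lm = pc.simulate_landmarks(
                10, default_scheme(), groups=groups, deformation_scale=0.2,
                noise_sd=0.01, seed=900 + seed,
            )
            space = pc.shape_pca(pc.gpa(lm))
            s1 = space.scores[:5, 0]
            s2 = space.scores[5:, 0]
            # separation: group means further apart than within-group spread
            sep = abs(s1.mean() - s2.mean()) > (s1.std() + s2.std())
            wins += sep
        assert wins >= 9

    def test_reproducible(self):
        a = pc.simulate_landmarks(3, default_scheme(), seed=5)
        b = pc.simulate_landmarks(3, default_scheme(), seed=5)
        np.testing.assert_array_equal(a.coords, b.coords)


class TestSimulateEcology:
    def test_strength_one_deterministic_per_regime(self, random_tree):
        painting = pc.paint_random_shifts(random_tree, 2, 0, seed=51)
        eco = pc.simulate_ecology(random_tree, painting, strength=1.0, seed=52)
        tip_reg = {
            lab: painting.branch_regimes[v]
            for v, lab in zip(random_tree.tips, random_tree.tip_labels)
        }
        for reg in set(tip_reg.values()):
            members = [s for s, r in tip_reg.items() if r == reg]
            habs = {eco.data.loc[s, "habitat"] for s in members}
            assert len(habs) == 1

    def test_strength_zero_independent(self, random_tree):
        painting = pc.paint_random_shifts(random_tree, 2, 0, seed=53)
        eco = pc.simulate_ecology(random_tree, painting, strength=0.0, seed=54)
        assert set(eco.species) == set(random_tree.tip_labels)

    def test_strong_association_detected_by_chi_square(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            tree = pc.simulate_tree(32, 36.0, seed=6000 + seed)
            painting = pc.paint_random_shifts(tree, 2, 1, seed=seed)
            eco = pc.simulate_ecology(tree, painting, strength=0.9, seed=7000 + seed)
            membership = {
                lab: painting.branch_regimes[v]
                for v, lab in zip(tree.tips, tree.tip_labels)
            }
            results = pc.chi_square_tests(membership, eco, "b")
            hab = [r for r in results if r.factor == "habitat" and not r.skipped]
            if hab and min(h.p_raw for h in hab) <= 0.05:
                hits += 1
        assert hits >= 16


class TestDataset:
    def test_reproducible_and_serialisable(self, tmp_path):
        a = pc.make_convergence_dataset(11, n_tips=16, with_ecology=True)
        b = pc.make_convergence_dataset(11, n_tips=16, with_ecology=True)
        assert a.tree.to_newick() == b.tree.to_newick()
        assert (a.traits.values == b.traits.values).all()
        assert a.painting.branch_regimes == b.painting.branch_regimes

        from phyloconv.synthetic_data import save_dataset

        save_dataset(a, tmp_path / "ds")
        assert (tmp_path / "ds" / "tree.nwk").exists()
        assert (tmp_path / "ds" / "traits.csv").exists()
        assert (tmp_path / "ds" / "ecology.csv").exists()
        assert (tmp_path / "ds" / "provenance.json").exists()
        back = pc.read_newick((tmp_path / "ds" / "tree.nwk").read_text())
        assert back.tip_labels == a.tree.tip_labels
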
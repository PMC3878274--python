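import numpy as np
import pytest

import riskevo as rv
from riskevo.trees import TreeError, pl_objective


def clade_length_map(tree):
    sets = tree.clade_tipsets()
    return {sets[v]: tree.branch_lengths[v] for v in range(tree.n_nodes) if v != tree.root}


class TestNewickIO:
    def test_two_tip_depths(self):
        t = rv.parse_newick("(A:1,B:1):0;")
        d = t.node_depths()
        assert {t.labels[i]: d[i] for i in t.tip_indices()} == {"A": 1.0, "B": 1.0}
        assert t.is_ultrametric()

    def test_three_tip_depths(self):
        t = rv.parse_newick("((A:1,B:1):1,C:2):0;")
        d = t.node_depths()
        assert all(d[i] == 2.0 for i in t.tip_indices())

    def test_missing_length_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="missing"):
            t = rv.parse_newick("(A:1,B);")
        assert 0.0 in [t.branch_lengths[i] for i in t.tip_indices()]

    def test_duplicate_tips_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            rv.parse_newick("(A:1,A:1);")

    def test_malformed_rejected(self):
        with pytest.raises(TreeError, match="parse"):
            rv.parse_newick("((A:1,B:1;")

    def test_write_contains_labels_and_zero_lengths(self):
        t = rv.parse_newick("(A:1,B:0):0;")
        s = rv.write_newick(t)
        assert "A:1" in s and "B:0" in s

    def test_labels_with_spaces_round_trip(self):
        t = rv.parse_newick("('Genus species':1,B:1);")
        s = rv.write_newick(t)
        back = rv.parse_newick(s)
        assert set(back.tip_labels) == {"Genus species", "B"}

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_identity_on_random_trees(self, seed):
        tree = rv.simulate_yule(rv.SimConfig(n_tips=5 + seed * 4, seed=seed))
        back = rv.parse_newick(rv.write_newick(tree))
        a, b = clade_length_map(tree), clade_length_map(back)
        assert set(a) == set(b)
        for s in a:
            assert a[s] == pytest.approx(b[s], rel=1e-9)

    def test_nexus_translate_table(self, tmp_path):
        nex = (
            "#NEXUS\nBEGIN TAXA;\nDIMENSIONS NTAX=3;\nTAXLABELS A B C;\nEND;\n"
            "BEGIN TREES;\nTRANSLATE 1 A, 2 B, 3 C;\n"
            "TREE t1 = ((1:1,2:1):1,3:2);\nTREE t2 = ((1:1,3:1):1,2:2);\nEND;\n"
        )
        p = tmp_path / "trees.nex"
        p.write_text(nex)
        ts = rv.read_trees(p, schema="nexus")
        assert len(ts) == 2
        assert set(ts[0].tip_labels) == {"A", "B", "C"}


class TestDepthsAndTimes:
    def test_depths_monotone_along_paths(self):
        tree = rv.simulate_yule(rv.SimConfig(n_tips=20, seed=3))
        d = tree.node_depths()
        for v in range(tree.n_nodes):
            if v != tree.root:
                assert d[v] >= d[tree.parent[v]]

    def test_unequal_tips_not_ultrametric(self):
        t = rv.parse_newick("((A:1,B:2):1,C:3);")
        assert not t.is_ultrametric(1e-9)

    def test_relative_times_bounds(self):
        tree = rv.simulate_yule(rv.SimConfig(n_tips=16, seed=4))
        rel = tree.relative_times()
        assert rel[tree.root] == 0.0
        assert all(rel[i] == 1.0 for i in tree.tip_indices())
        t = rv.parse_newick("((A:0.5,B:0.5):0.5,C:1);")
        internal = [v for v in t.internal_indices() if v != t.root]
        assert t.relative_times()[internal[0]] == pytest.approx(0.5)

    def test_relative_times_require_ultrametric(self):
        with pytest.raises(TreeError, match="ultrametric"):
            rv.parse_newick("((A:1,B:2):1,C:3);").relative_times()


class TestConsensus:
    def test_identity_on_copies(self):
        tree = rv.simulate_yule(rv.SimConfig(n_tips=10, seed=5))
        cons = rv.consensus_tree(rv.TreeSet([tree, tree.copy(), tree.copy()]))
        a, b = clade_length_map(tree), clade_length_map(cons)
        assert set(a) == set(b)
        for s in a:
            assert a[s] == pytest.approx(b[s], abs=1e-12)

    def test_majority_topology(self):
        t1 = rv.parse_newick("((A:1,B:1):1,C:2);")
        t2 = rv.parse_newick("((A:1,B:1):1,C:2);")
        t3 = rv.parse_newick("((A:1,C:1):1,B:2);")
        cons = rv.consensus_tree(rv.TreeSet([t1, t2, t3]))
        assert frozenset({"A", "B"}) in clade_length_map(cons)
        assert frozenset({"A", "C"}) not in clade_length_map(cons)

    def test_lengths_averaged_over_trees_containing_clade(self):
        t1 = rv.parse_newick("((A:1,B:1):1,C:2);")
        t2 = rv.parse_newick("((A:1,B:1):3,C:4);")
        cons = rv.consensus_tree(rv.TreeSet([t1, t2]))
        assert clade_length_map(cons)[frozenset({"A", "B"})] == pytest.approx(2.0)

    def test_consensus_clades_have_majority_support(self):
        rng = np.random.default_rng(0)
        trees = [rv.simulate_yule(rv.SimConfig(n_tips=8, seed=int(s)))
                 for s in rng.integers(0, 1000, size=7)]
        for t in trees[1:]:  # same label set by construction (t001..t008)
            assert set(t.tip_labels) == set(trees[0].tip_labels)
        cons = rv.consensus_tree(rv.TreeSet(trees))
        all_sets = [set(t.clade_tipsets().values()) for t in trees]
        for s in cons.clade_tipsets().values():
            if len(s) in (1, cons.n_tips):
                continue
            freq = sum(s in group for group in all_sets) / len(trees)
            assert freq > 0.5

    def test_mismatched_labels_listed(self):
        t1 = rv.parse_newick("(A:1,B:1);")
        t2 = rv.parse_newick("(A:1,C:1);")
        with pytest.raises(TreeError, match="C"):
            rv.TreeSet([t1, t2])

    def test_empty_set_rejected(self):
        with pytest.raises(TreeError, match="non-empty"):
            rv.TreeSet([])


class TestDating:
    def test_ultrametric_input_preserves_relative_depths(self):
        tree = rv.simulate_yule(rv.SimConfig(n_tips=10, seed=7))
        dated = rv.date_tree_pl(tree, rv.DatingConfig(root_age=1.0))
        d0, d1 = tree.node_depths(), dated.node_depths()
        for v in range(tree.n_nodes):
            assert d1[v] == pytest.approx(d0[v], abs=5e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_output_ultrametric_under_rate_noise(self, seed):
        tree = rv.simulate_yule(rv.SimConfig(n_tips=12, seed=seed))
        noisy = tree.copy()
        rng = np.random.default_rng(seed)
        mask = np.arange(tree.n_nodes) != tree.root
        noisy.branch_lengths[mask] *= rng.lognormal(0.0, 0.4, mask.sum())
        dated = rv.date_tree_pl(noisy)
        assert dated.is_ultrametric(1e-5)
        assert dated.max_depth() == pytest.approx(1.0, abs=1e-6)

    def test_objective_matches_grid_search_oracle(self):
        # 3-tip caterpillar with unequal tip path lengths: one free internal
        # age; for each age on a fine grid the optimal rates are solved in
        # closed form (the data term is quadratic in each rate).
        tree = rv.parse_newick("((A:1,B:2):1,C:4);")
        cfg = rv.DatingConfig(smoothing=1.0, root_age=1.0)
        dated = rv.date_tree_pl(tree, cfg)
        ages = cfg.root_age - dated.node_depths()
        from scipy.optimize import minimize

        def best_at_age(a):
            def f(r):
                ag = {tree.root: 1.0}
                inner = [v for v in tree.internal_indices() if v != tree.root][0]
                ag[inner] = a
                for v in tree.tip_indices():
                    ag[v] = 0.0
                ages_vec = np.array([ag[v] for v in range(tree.n_nodes)])
                return pl_objective(tree, ages_vec, np.abs(r), cfg.smoothing)
            res = minimize(f, np.ones(tree.n_nodes), method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            return res.fun

        grid_best = min(best_at_age(a) for a in np.linspace(0.02, 0.98, 97))
        inner = [v for v in tree.internal_indices() if v != tree.root][0]
        ours = best_at_age(ages[inner])
        assert ours <= grid_best + 1e-4

    def test_rejects_negative_lengths_at_construction(self):
        with pytest.raises(TreeError, match=">= 0"):
            rv.Phylogeny([-1, 0, 0], [0.0, -1.0, 1.0], [None, "A", "B"])
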
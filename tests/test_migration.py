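import math

import numpy as np
import pytest

from organrep import (
    LineageTree,
    SequenceRecord,
    SimulationConfig,
    ValidationError,
    filter_trees_input,
    parsimony_reconstruct,
    reorder_polytomies,
    simulate_lineage_trees,
    sp_statistic,
    sp_test,
    uniform_migration_matrix,
)
from conftest import brute_force_parsimony, random_yule_tree


def cherry_with_outgroup(org_a="spleen", org_b="BM", org_c="spleen"):
    #    root
    #    /  \
    #  (A,B) C
    parent = [-1, 0, 0, 1, 1]
    length = [0.0, 1.0, 2.0, 1.0, 1.0]
    names = [None, None, "C", "A", "B"]
    organs = [None, None, org_c, org_a, org_b]
    return LineageTree(parent, length, names, organs)


def seqs(n, organ, count=5, prefix="s"):
    return [
        SequenceRecord(f"{prefix}{i}", organ, "IGHV1-1", "IGHJ1", "CARDYW", count=count)
        for i in range(n)
    ]


class TestFilterTreesInput:
    def test_large_clone_downsampled_to_cap(self):
        clones = {"c1": seqs(75, "BM") + seqs(75, "spleen", prefix="t")}
        out, report = filter_trees_input(clones, seed=0)
        assert len(out["c1"]) == 100
        assert report["downsampled_clones"] == 1

    def test_small_clone_removed(self):
        clones = {"c1": seqs(3, "BM") + seqs(3, "spleen", prefix="t") + seqs(3, "aLN-L", prefix="u")}
        out, report = filter_trees_input(clones)
        assert out == {} and report["removed_small_clones"] == 1

    def test_single_organ_clone_removed(self):
        clones = {"c1": seqs(50, "spleen")}
        out, report = filter_trees_input(clones)
        assert out == {} and report["removed_single_organ_clones"] == 1

    def test_low_read_sequences_discarded_first(self):
        low = seqs(30, "BM", count=2)
        keep = seqs(8, "BM", prefix="k") + seqs(8, "spleen", prefix="q")
        out, report = filter_trees_input({"c1": low + keep})
        assert report["dropped_low_read_sequences"] == 30
        assert len(out["c1"]) == 16

    def test_read_filter_can_be_disabled(self):
        clones = {"c1": seqs(8, "BM", count=1) + seqs(8, "spleen", count=1, prefix="t")}
        out, _ = filter_trees_input(clones, min_reads=None)
        assert len(out["c1"]) == 16


class TestParsimonyReconstruct:
    def test_uniform_tips_need_no_changes(self):
        tree = cherry_with_outgroup("BM", "BM", "BM")
        res = parsimony_reconstruct(tree)
        assert res.n_changes == 0
        assert set(res.node_labels) == {"BM"}

    def test_cherry_with_outgroup(self):
        tree = cherry_with_outgroup("spleen", "BM", "spleen")
        res = parsimony_reconstruct(tree)
        assert res.n_changes == 1
        assert res.node_labels[0] == "spleen"  # root
        assert res.transition_counts.loc["spleen", "BM"] == 1

    def test_matches_brute_force_on_random_trees(self, rng):
        organs = ["BM", "aLN-L", "spleen"]
        for _ in range(25):
            tree = random_yule_tree(rng, int(rng.integers(3, 8)), organs)
            res = parsimony_reconstruct(tree, organs=organs)
            assert res.n_changes == brute_force_parsimony(tree, organs)
            # reconstruction realizes exactly the minimum number of changes
            assert res.transition_counts.values.sum() == res.n_changes

    def test_average_strategy_conserves_change_count(self, rng):
        organs = ["BM", "spleen"]
        for _ in range(10):
            tree = random_yule_tree(rng, 6, organs)
            avg = parsimony_reconstruct(tree, organs=organs, strategy="average")
            assert math.isclose(avg.transition_counts.values.sum(), avg.n_changes)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValidationError):
            parsimony_reconstruct(cherry_with_outgroup(), strategy="bogus")


class TestReorderPolytomies:
    def test_no_zero_length_branches_is_identity(self, rng):
        tree = random_yule_tree(rng, 6, ["BM", "spleen"])
        assert reorder_polytomies(tree) is tree

    def test_zero_length_cluster_can_save_a_change(self):
        # ((A:BM, B:spleen):0, (C:BM, D:spleen):0) under a root: 2 changes;
        # regrouping same-organ tips across the zero-length edge saves one.
        parent = [-1, 0, 0, 1, 1, 2, 2]
        length = [0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0]
        names = [None, None, None, "A", "B", "C", "D"]
        organs = [None, None, None, "BM", "spleen", "BM", "spleen"]
        tree = LineageTree(parent, length, names, organs)
        before = parsimony_reconstruct(tree).n_changes
        after = parsimony_reconstruct(reorder_polytomies(tree)).n_changes
        assert before == 2 and after < before

    def test_never_increases_changes_and_is_idempotent(self, rng):
        for _ in range(10):
            tree = random_yule_tree(rng, 8, ["BM", "spleen", "aLN-L"])
            # zero out some internal branch lengths
            for v in range(tree.n_nodes):
                if tree.children[v] and tree.parent[v] >= 0 and rng.random() < 0.6:
                    tree.length[v] = 0.0
            tree = LineageTree(tree.parent, tree.length, tree.names, tree.organs)
            once = reorder_polytomies(tree)
            twice = reorder_polytomies(once)
            assert (
                parsimony_reconstruct(once).n_changes
                <= parsimony_reconstruct(tree).n_changes
            )
            assert once.to_newick() == twice.to_newick()


class TestSPStatistic:
    def test_forced_direction(self):
        trees = [cherry_with_outgroup("spleen", "BM", "spleen") for _ in range(3)]
        sp = sp_statistic(trees)
        assert sp.loc["spleen", "BM"] == 1.0
        assert np.nansum(sp.values) == 1.0

    def test_balanced_two_changes(self):
        a = cherry_with_outgroup("spleen", "BM", "spleen")
        b = cherry_with_outgroup("BM", "spleen", "BM")
        sp = sp_statistic([a, b])
        assert sp.loc["spleen", "BM"] == 0.5
        assert sp.loc["BM", "spleen"] == 0.5

    def test_no_transitions_warns_and_is_nan(self):
        with pytest.warns(UserWarning):
            sp = sp_statistic([cherry_with_outgroup("BM", "BM", "BM")])
        assert sp.isna().all().all()


class TestSPTest:
    def make_trees(self, seed=5, n=6):
        organs = ("BM", "LN", "spleen")
        cfg = SimulationConfig(
            organs=organs,
            migration_matrix=uniform_migration_matrix(organs),
            founder_organ="spleen",
            n_trees=n,
            tree_size_mean=14,
            tree_size_min=8,
            seed=seed,
        )
        return [t for t in simulate_lineage_trees(cfg) if len(t.organ_set) >= 2]

    def test_seed_reproducibility(self):
        trees = self.make_trees()
        a = sp_test(trees, replicates=50, seed=1)
        b = sp_test(trees, replicates=50, seed=1)
        assert a.p_values.equals(b.p_values)
        assert np.array_equal(a.deltas, b.deltas)

    def test_observed_sp_sums_to_one(self):
        trees = self.make_trees()
        res = sp_test(trees, replicates=10, seed=1)
        assert math.isclose(np.nansum(res.observed.values), 1.0, abs_tol=1e-9)

    def test_p_values_in_unit_interval(self):
        res = sp_test(self.make_trees(), replicates=50, seed=2)
        off_diag = res.p_values.values[~np.eye(3, dtype=bool)]
        assert ((off_diag >= 0) & (off_diag <= 1)).all()

    def test_single_organ_dataset_is_degenerate(self):
        trees = [cherry_with_outgroup("BM", "BM", "BM")]
        with pytest.warns(UserWarning):
            res = sp_test(trees, replicates=10, seed=0)
        assert res.p_values.isna().all().all()

    def test_among_trees_mode_is_symmetric(self):
        trees = self.make_trees(n=8)
        res = sp_test(trees, replicates=50, mode="among_trees", seed=3)
        p = res.p_values.values
        assert np.allclose(p, p.T, equal_nan=True)
        obs = res.observed.values
        assert np.allclose(obs, obs.T, equal_nan=True)
        # unordered pairs sum to 1 over the upper triangle
        assert math.isclose(np.nansum(np.triu(obs, 1)), 1.0, abs_tol=1e-9)

    def test_invalid_arguments_rejected(self):
        trees = self.make_trees()
        with pytest.raises(ValidationError):
            sp_test(trees, replicates=0)
        with pytest.raises(ValidationError):
            sp_test(trees, tip_change_ratio_cap=0.0)
        with pytest.raises(ValidationError):
            sp_test(trees, mode="sideways")

    def test_downsampling_cap_engages(self):
        # a large tree with a single change has tip/change ratio >> 2
        organs = ("BM", "spleen")
        cfg = SimulationConfig(
            organs=organs,
            migration_matrix=np.array([[1.0, 0.0], [0.4, 0.6]]),
            founder_organ="spleen",
            n_trees=4,
            tree_size_mean=40,
            tree_size_min=30,
            seed=9,
        )
        trees = [t for t in simulate_lineage_trees(cfg) if len(t.organ_set) >= 2]
        res = sp_test(trees, replicates=20, tip_change_ratio_cap=2.0, seed=4)
        off_diag = res.p_values.values[~np.eye(2, dtype=bool)]
        assert np.isfinite(off_diag).all()
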
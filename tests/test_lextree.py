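"""Lexical tree: construction, node scores, antichain selection, permutation."""

import numpy as np
import pytest
from scipy import stats as sps

from mtassoc.genotypes import CASE, CONTROL, MISSING_ALLELE
from mtassoc.lextree import (
    HaplotypeTree,
    NodeStat,
    TreeNode,
    build_tree,
    max_weight_antichain,
    node_statistics,
    node_table,
    permutation_test,
    run_tree_test,
    to_newick,
    tree_statistic,
)
from mtassoc.simulate import null_config, simulate_cohort

from conftest import complete_cohort, make_table


class TestBuildTree:
    def test_single_snp_splits_root(self):
        g = make_table([[0], [1], [0], [1], [1]], [CASE] * 3 + [CONTROL] * 2)
        tree = build_tree(g)
        assert len(tree.nodes) == 3
        root, wild, mutant = tree.nodes
        assert root.size == 5 and root.parent_id == -1
        assert wild.branch == 0 and wild.size == 2
        assert mutant.branch == 1 and mutant.size == 3

    def test_hand_enumerated_three_snp_tree(self):
        """3 SNPs with MAFs 0.4/0.3/0.1 over 10 individuals: the full
        split sequence was enumerated by hand.

        Splits: s1 -> {wild 6 | mutant 4}; s2 splits both branches
        ({4|2} and {3|1}); s3 splits only the s1-wild/s2-wild leaf
        ({3|1}). Five leaves = five distinct haplotypes.
        """
        haplotypes = [
            (0, 0, 0), (0, 0, 0), (0, 0, 0),
            (0, 1, 0), (0, 1, 0),
            (0, 0, 1),
            (1, 0, 0), (1, 0, 0), (1, 1, 0), (1, 0, 0),
        ]
        g = make_table(
            list(haplotypes), [CASE] * 5 + [CONTROL] * 5, positions=[100, 200, 300]
        )
        tree = build_tree(g)
        # (parent, branch, members) in creation order, root first
        expected = [
            (-1, None, {0, 1, 2, 3, 4, 5, 6, 7, 8, 9}),
            (0, 0, {0, 1, 2, 3, 4, 5}),
            (0, 1, {6, 7, 8, 9}),
            (1, 0, {0, 1, 2, 5}),
            (1, 1, {3, 4}),
            (2, 0, {6, 7, 9}),
            (2, 1, {8}),
            (3, 0, {0, 1, 2}),
            (3, 1, {5}),
        ]
        assert len(tree.nodes) == len(expected)
        for node, (parent, branch, members) in zip(tree.nodes, expected):
            assert node.parent_id == parent
            assert node.branch == branch
            assert set(node.members) == members
        leaves = {frozenset(tree.nodes[i].members) for i in tree.leaf_ids()}
        assert leaves == {
            frozenset(s) for s in [{3, 4}, {6, 7, 9}, {8}, {0, 1, 2}, {5}]
        }

    def test_monomorphic_snp_contributes_no_node(self):
        g = make_table([[0, 0], [1, 0], [1, 0]], [CASE, CASE, CONTROL])
        tree = build_tree(g)
        assert len(tree.nodes) == 3  # only the polymorphic SNP splits

    def test_missing_data_rejected(self):
        g = make_table([[0], [MISSING_ALLELE]], [CASE, CONTROL])
        with pytest.raises(ValueError, match="complete"):
            build_tree(g)

    def test_count_conservation(self):
        g = simulate_cohort(null_config(100, 100, seed=21))
        tree = build_tree(g)
        children = {}
        for node in tree.nodes:
            if node.parent_id != -1:
                children.setdefault(node.parent_id, []).append(node)
        assert tree.nodes[0].size == 200
        for pid, kids in children.items():
            assert sum(k.size for k in kids) == tree.nodes[pid].size
            combined = np.sort(np.concatenate([k.members for k in kids]))
            assert np.array_equal(combined, np.sort(tree.nodes[pid].members))


class TestNodeStatistics:
    def test_closed_form_chi_square(self):
        """Node splitting 50 individuals off a 100-cohort with table
        (10, 40, 40, 10) scores chi-square 36 exactly."""
        pheno = np.array([CASE] * 50 + [CONTROL] * 50)
        members = np.concatenate([np.arange(10), 50 + np.arange(40)])
        tree = _tree_with_single_node(100, members, pheno)
        (stat,) = node_statistics(tree)
        assert stat.table == (10, 40, 40, 10)
        assert stat.statistic == pytest.approx(36.0)
        assert stat.direction == "protective"

    def test_balanced_node_scores_zero(self):
        pheno = np.array([CASE] * 50 + [CONTROL] * 50)
        members = np.concatenate([np.arange(20), 50 + np.arange(20)])
        tree = _tree_with_single_node(100, members, pheno)
        (stat,) = node_statistics(tree)
        assert stat.statistic == 0.0 and stat.direction == "none"

    def test_root_not_scored(self):
        g = make_table([[0], [1], [0], [1]], [CASE, CASE, CONTROL, CONTROL])
        stats = node_statistics(build_tree(g))
        assert all(s.node_id != 0 for s in stats)

    def test_all_one_class_rejected(self):
        g = make_table([[0], [1]], [CASE, CASE])
        with pytest.raises(ValueError, match="cases and controls"):
            node_statistics(build_tree(g))

    def test_matches_scipy_oracle(self):
        g = simulate_cohort(null_config(150, 150, seed=33))
        tree = build_tree(g)
        for stat in node_statistics(tree):
            a, b, c, d = stat.table
            oracle = sps.chi2_contingency(
                [[a, b], [c, d]], correction=False
            ).statistic
            assert stat.statistic == pytest.approx(oracle, rel=1e-10)


def _tree_with_single_node(n, members, pheno):
    import pandas as pd

    root = TreeNode(0, -1, None, None, np.arange(n), 0)
    members = np.asarray(members)
    rest = np.setdiff1d(np.arange(n), members)
    in_node = TreeNode(1, 0, 0, 1, members, 1)
    meta = pd.DataFrame(
        {"id": ["s"], "position": [100], "ref_allele": ["A"], "alt_allele": ["G"]}
    )
    return HaplotypeTree(
        nodes=[root, in_node],
        snp_order=np.array([0]),
        phenotype=pheno,
        snp_meta=meta,
    )


class TestTreeStatistic:
    def _chain_tree(self):
        """root -> a -> (b, c): a is b's and c's parent."""
        nodes = [
            TreeNode(0, -1, None, None, np.arange(10), 0),
            TreeNode(1, 0, 0, 1, np.arange(6), 1),
            TreeNode(2, 1, 1, 0, np.arange(3), 2),
            TreeNode(3, 1, 1, 1, np.arange(3, 6), 2),
        ]
        import pandas as pd

        meta = pd.DataFrame(
            {
                "id": ["s1", "s2"],
                "position": [100, 200],
                "ref_allele": ["A", "A"],
                "alt_allele": ["G", "G"],
            }
        )
        return HaplotypeTree(
            nodes=nodes,
            snp_order=np.array([0, 1]),
            phenotype=np.array([CASE] * 5 + [CONTROL] * 5),
            snp_meta=meta,
        )

    def test_ancestor_excluded(self):
        tree = self._chain_tree()
        stats = [
            NodeStat(1, 5.0, "risk", (0, 0, 0, 0)),
            NodeStat(2, 3.0, "risk", (0, 0, 0, 0)),
        ]
        result = tree_statistic(stats, tree)
        assert result.selected_ids == [1]
        assert result.S == 5.0

    def test_siblings_all_selected(self):
        tree = self._chain_tree()
        stats = [
            NodeStat(2, 3.0, "risk", (0, 0, 0, 0)),
            NodeStat(3, 4.0, "risk", (0, 0, 0, 0)),
        ]
        result = tree_statistic(stats, tree)
        assert set(result.selected_ids) == {2, 3}
        assert result.S == 7.0

    def test_empty_stats_degenerate(self):
        tree = self._chain_tree()
        result = tree_statistic([], tree)
        assert result.S == 0.0 and result.selected_nodes == []

    def test_greedy_matches_independent_bruteforce(self):
        """On random trees of <= 12 nodes, the greedy rule agrees with an
        independently coded reference and always yields an antichain."""
        rng = np.random.default_rng(99)
        for _ in range(50):
            tree, stats = _random_tree(rng, max_nodes=12)
            result = tree_statistic(stats, tree)
            ref_ids, ref_s = _bruteforce_greedy(tree, stats, k=5)
            assert result.selected_ids == ref_ids
            assert result.S == pytest.approx(ref_s)
            for x in result.selected_ids:
                for y in result.selected_ids:
                    if x != y:
                        assert not tree.is_ancestor(x, y)

    def test_greedy_never_beats_exact_antichain(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            tree, stats = _random_tree(rng, max_nodes=10)
            greedy = tree_statistic(stats, tree)
            exact = max_weight_antichain(stats, tree)
            assert greedy.S <= exact.S + 1e-12


def _random_tree(rng, max_nodes=12):
    import pandas as pd

    n_nodes = int(rng.integers(2, max_nodes + 1))
    nodes = [TreeNode(0, -1, None, None, np.arange(4), 0)]
    for i in range(1, n_nodes):
        parent = int(rng.integers(0, i))
        nodes.append(
            TreeNode(i, parent, 0, 1, np.arange(1), nodes[parent].depth + 1)
        )
    meta = pd.DataFrame(
        {"id": ["s"], "position": [100], "ref_allele": ["A"], "alt_allele": ["G"]}
    )
    tree = HaplotypeTree(
        nodes=nodes,
        snp_order=np.array([0]),
        phenotype=np.array([CASE, CASE, CONTROL, CONTROL]),
        snp_meta=meta,
    )
    stats = [
        NodeStat(i, float(np.round(rng.random() * 10, 6)), "risk", (0, 0, 0, 0))
        for i in range(1, n_nodes)
    ]
    return tree, stats


def _bruteforce_greedy(tree, stats, k=5):
    """Reference greedy: explicit parent-chain walks, no bitmasks."""

    def ancestors(v):
        out = set()
        p = tree.nodes[v].parent_id
        while p != -1:
            out.add(p)
            p = tree.nodes[p].parent_id
        return out

    ranked = sorted(
        stats, key=lambda s: (-s.statistic, tree.nodes[s.node_id].depth, s.node_id)
    )
    chosen = []
    for s in ranked:
        ok = True
        for c in chosen:
            if s.node_id in ancestors(c.node_id) or c.node_id in ancestors(s.node_id):
                ok = False
                break
        if ok:
            chosen.append(s)
        if len(chosen) == k:
            break
    return [c.node_id for c in chosen], sum(c.statistic for c in chosen)


class TestPermutationTest:
    def test_perfectly_balanced_cohort_gives_p_one(self):
        g = complete_cohort(n_per_hap=6)
        tree = build_tree(g)
        result = permutation_test(tree, n_perm=99, seed=1)
        assert result.S == 0.0
        assert result.p_perm == 1.0

    def test_seed_determinism(self):
        g = simulate_cohort(null_config(100, 100, seed=12))
        tree = build_tree(g)
        r1 = permutation_test(tree, n_perm=199, seed=5)
        r2 = permutation_test(tree, n_perm=199, seed=5)
        assert r1.p_perm == r2.p_perm and r1.S == r2.S

    def test_p_floor_is_one_over_nperm_plus_one(self):
        g = simulate_cohort(null_config(100, 100, seed=12))
        tree = build_tree(g)
        r = permutation_test(tree, n_perm=49, seed=3)
        assert r.p_perm >= 1 / 50

    def test_observed_statistic_preserved(self):
        g = simulate_cohort(null_config(100, 100, seed=13))
        tree = build_tree(g)
        obs = tree_statistic(node_statistics(tree), tree)
        r = permutation_test(tree, n_perm=49, seed=3)
        assert r.S == pytest.approx(obs.S)
        assert r.selected_ids == obs.selected_ids


class TestRunTreeTest:
    def test_relabelled_control_duplicates_not_significant(self):
        """Duplicating a control cohort and relabelling one copy as cases
        balances every node exactly: the whole-tree p is 1."""
        g = simulate_cohort(null_config(60, 60, seed=44))
        doubled = make_table(
            np.vstack([g.alleles, g.alleles]),
            np.concatenate([np.full(120, CASE), np.full(120, CONTROL)]),
            positions=list(g.snp_meta["position"]),
        )
        report, result = run_tree_test(doubled, n_perm=99, seed=2)
        assert result.S == pytest.approx(0.0)
        assert result.p_perm == 1.0

    def test_seed_reproducibility(self):
        g = simulate_cohort(null_config(80, 80, seed=17))
        _, r1 = run_tree_test(g, n_perm=99, seed=9)
        _, r2 = run_tree_test(g, n_perm=99, seed=9)
        assert r1.p_perm == r2.p_perm

    def test_ledger_matches_final_table(self):
        g = simulate_cohort(null_config(80, 80, seed=18))
        report, _ = run_tree_test(g, n_perm=49, seed=1)
        assert g.n_samples - report.individuals_removed == report.final_n


class TestExports:
    def test_node_table_and_newick(self):
        g = simulate_cohort(null_config(30, 30, seed=2))
        tree = build_tree(g)
        stats = node_statistics(tree)
        result = tree_statistic(stats, tree)
        df = node_table(tree, stats, result)
        assert len(df) == len(tree.nodes)
        assert df["selected"].sum() == len(result.selected_ids)
        assert (df["n_cases"] + df["n_controls"] == df["n"]).all()
        nwk = to_newick(tree)
        assert nwk.endswith(";") and nwk.count("(") == nwk.count(")")
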
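"""Lexical haplotype-tree association test with a permutation null.

The tree is built over complete (missing-free) haploid genotypes by
considering SNPs in decreasing minor-allele-frequency order: starting
from a root holding every individual, each current leaf splits into a
wild-type (reference-allele) left child and a mutant right child
whenever both classes are non-empty; otherwise the leaf's haplotype
prefix simply extends. Leaves end up in bijection with the distinct
haplotypes.

Every non-root node is scored by the Pearson chi-square (1 df, no
continuity correction) of its in-node/out-of-node x case/control 2x2
table. The whole-tree statistic S is the sum of the five largest node
statistics among nodes that are mutually neither ancestors nor
descendants (a greedy antichain selection), and its significance is
assessed by uniformly permuting the case/control labels with the tree
topology held fixed. The permutation p-value uses the add-one
estimator (1 + #{S_perm >= S_obs}) / (1 + n_perm), which never
reports zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mtassoc.genotypes import ALT, MISSING_ALLELE, REF, GenotypeTable
from mtassoc.qc import QcReport, QcThresholds, lextree_qc
from mtassoc.stats2x2 import chi2_2x2


@dataclass
class TreeNode:
    """One node of the lexical tree.

    ``snp_col`` is the genotype-matrix column whose split created the
    node (None for the root); ``branch`` is 0 for the wild-type
    (reference) left branch, 1 for the mutant right branch.
    """

    node_id: int
    parent_id: int  # -1 for root
    snp_col: int | None
    branch: int | None
    members: np.ndarray  # individual row indices
    depth: int

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeTree:
    nodes: list  # TreeNode, ids equal list positions; ancestors have smaller ids
    snp_order: np.ndarray  # genotype columns by decreasing MAF (ties: position)
    phenotype: np.ndarray  # PLINK-coded phenotypes, aligned with member indices
    snp_meta: pd.DataFrame
    root_id: int = 0

    @property
    def n_samples(self) -> int:
        return self.nodes[self.root_id].size

    def is_ancestor(self, a: int, b: int) -> bool:
        """True if node a is a strict ancestor of node b."""
        p = self.nodes[b].parent_id
        while p != -1:
            if p == a:
                return True
            p = self.nodes[p].parent_id
        return False

    def ancestor_masks(self) -> list:
        """Per node, a bitmask (int) of its strict ancestors' ids."""
        masks = [0] * len(self.nodes)
        for node in self.nodes:
            if node.parent_id != -1:
                masks[node.node_id] = masks[node.parent_id] | (1 << node.parent_id)
        return masks

    def leaf_ids(self) -> list:
        has_child = set()
        for node in self.nodes:
            if node.parent_id != -1:
                has_child.add(node.parent_id)
        return [n.node_id for n in self.nodes if n.node_id not in has_child]

    def prefix(self, node_id: int) -> list:
        """(snp id, allele) pairs on the path from the root to the node."""
        out = []
        node = self.nodes[node_id]
        while node.parent_id != -1:
            snp_id = self.snp_meta.iloc[node.snp_col]["id"]
            allele = (
                self.snp_meta.iloc[node.snp_col]["ref_allele"]
                if node.branch == 0
                else self.snp_meta.iloc[node.snp_col]["alt_allele"]
            )
            out.append((snp_id, allele))
            node = self.nodes[node.parent_id]
        return list(reversed(out))


@dataclass
class NodeStat:
    """Association evidence at one tree node."""

    node_id: int
    statistic: float
    direction: str  # "risk" | "protective" | "none"
    table: tuple  # (cases_in, cases_out, controls_in, controls_out)


@dataclass
class TreeTestResult:
    selected_nodes: list  # <=5 NodeStat forming an antichain
    S: float
    n_perm: int = 0
    p_perm: float | None = None

    @property
    def selected_ids(self) -> list:
        return [s.node_id for s in self.selected_nodes]


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------


def build_tree(g: GenotypeTable) -> HaplotypeTree:
    """Build the lexical tree over a complete genotype table.

    SNPs are processed in decreasing MAF order (ties broken by
    ascending rCRS position); nodes are created only at genuine splits,
    so single-child chain extensions never appear and every node's
    member set is distinct.
    """
    if (g.alleles == MISSING_ALLELE).any():
        raise ValueError("lexical tree requires complete data (run lextree_qc first)")
    maf = g.maf()
    positions = g.snp_meta["position"].to_numpy()
    snp_order = np.lexsort((positions, -np.nan_to_num(maf, nan=0.0)))

    root = TreeNode(0, -1, None, None, np.arange(g.n_samples), 0)
    nodes = [root]
    leaves = [root]
    for col in snp_order:
        column = g.alleles[:, col]
        new_leaves = []
        for leaf in leaves:
            calls = column[leaf.members]
            wild = leaf.members[calls == REF]
            mutant = leaf.members[calls == ALT]
            if len(wild) and len(mutant):
                left = TreeNode(len(nodes), leaf.node_id, int(col), 0, wild, leaf.depth + 1)
                nodes.append(left)
                right = TreeNode(len(nodes), leaf.node_id, int(col), 1, mutant, leaf.depth + 1)
                nodes.append(right)
                new_leaves.extend([left, right])
            else:
                new_leaves.append(leaf)  # prefix extends, no node created
        leaves = new_leaves
    return HaplotypeTree(
        nodes=nodes,
        snp_order=snp_order,
        phenotype=g.phenotype.copy(),
        snp_meta=g.snp_meta.copy(),
    )


# ---------------------------------------------------------------------------
# node statistics
# ---------------------------------------------------------------------------


def _node_tables(tree: HaplotypeTree, case_indicator: np.ndarray):
    """Per non-root node: (cases_in, cases_out, controls_in, controls_out)."""
    total_cases = int(case_indicator.sum())
    total = len(case_indicator)
    ids, a, s = [], [], []
    for node in tree.nodes:
        if node.parent_id == -1:
            continue
        ids.append(node.node_id)
        a.append(int(case_indicator[node.members].sum()))
        s.append(node.size)
    a = np.array(a, dtype=float)
    s = np.array(s, dtype=float)
    cases_in = a
    cases_out = total_cases - a
    controls_in = s - a
    controls_out = (total - total_cases) - controls_in
    return ids, cases_in, cases_out, controls_in, controls_out


def node_statistics(tree: HaplotypeTree, phenotype: np.ndarray | None = None) -> list:
    """Score every non-root node against the case/control labels.

    Returns one :class:`NodeStat` per node, with the Pearson chi-square
    of the node-vs-rest 2x2 table and the direction of effect (risk if
    the node is case-enriched). The root partitions nothing and is
    excluded; a cohort with no cases or no controls is rejected.
    """
    pheno = tree.phenotype if phenotype is None else np.asarray(phenotype)
    case = pheno == 2
    control = pheno == 1
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError("node statistics need both cases and controls")
    ids, ci, co, ki, ko = _node_tables(tree, case)
    stat = chi2_2x2(ci, co, ki, ko)
    cross = ci * ko - co * ki
    out = []
    for idx, node_id in enumerate(ids):
        direction = "risk" if cross[idx] > 0 else ("protective" if cross[idx] < 0 else "none")
        out.append(
            NodeStat(
                node_id=node_id,
                statistic=float(stat[idx]),
                direction=direction,
                table=(int(ci[idx]), int(co[idx]), int(ki[idx]), int(ko[idx])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# whole-tree statistic
# ---------------------------------------------------------------------------


def _greedy_select(order, anc_masks, k: int):
    """Greedy antichain pick over candidate node ids in the given order."""
    selected = []
    blocked = 0  # bitmask of every node comparable to an accepted one
    for node_id in map(int, order):
        if (blocked >> node_id) & 1:
            continue
        selected.append(node_id)
        if len(selected) == k:
            break
        blocked |= anc_masks[node_id] | (1 << node_id)
        # also block descendants: any node whose ancestor set contains node_id
        for other_id, mask in enumerate(anc_masks):
            if (mask >> node_id) & 1:
                blocked |= 1 << other_id
    return selected


def tree_statistic(stats: list, tree: HaplotypeTree, k: int = 5) -> TreeTestResult:
    """Whole-tree statistic: sum of the k largest mutually non-nested
    node statistics, selected greedily.

    Nodes are visited in decreasing-statistic order (ties broken by
    shallower depth, then node id) and accepted only if neither an
    ancestor nor a descendant of an already-accepted node. An empty
    statistic list yields S = 0 (a degenerate tree with no splits).
    """
    if not stats:
        return TreeTestResult(selected_nodes=[], S=0.0)
    by_id = {s.node_id: s for s in stats}
    ids = np.array([s.node_id for s in stats])
    values = np.array([s.statistic for s in stats])
    depths = np.array([tree.nodes[s.node_id].depth for s in stats])
    order = ids[np.lexsort((ids, depths, -values))]
    anc_masks = tree.ancestor_masks()
    chosen = _greedy_select(order, anc_masks, k)
    selected = [by_id[i] for i in chosen]
    return TreeTestResult(selected_nodes=selected, S=float(sum(s.statistic for s in selected)))


def max_weight_antichain(stats: list, tree: HaplotypeTree, k: int = 5) -> TreeTestResult:
    """Exact maximum-weight antichain of size <= k (sensitivity-analysis
    alternative to the literal greedy rule). Exponential in the number of
    scored nodes; intended for small trees."""
    from itertools import combinations

    anc_masks = tree.ancestor_masks()
    best: tuple = (-1.0, [])
    items = sorted(stats, key=lambda s: -s.statistic)
    for r in range(1, min(k, len(items)) + 1):
        for combo in combinations(items, r):
            ok = True
            for x in combo:
                for y in combo:
                    if x is not y and (
                        (anc_masks[y.node_id] >> x.node_id) & 1
                        or (anc_masks[x.node_id] >> y.node_id) & 1
                    ):
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                total = sum(s.statistic for s in combo)
                if total > best[0]:
                    best = (total, list(combo))
    return TreeTestResult(selected_nodes=best[1], S=max(best[0], 0.0))


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


def permutation_test(
    tree: HaplotypeTree,
    n_perm: int,
    seed: int,
    k: int = 5,
    batch_size: int = 256,
) -> TreeTestResult:
    """Assess the whole-tree statistic by case/control label permutation.

    The tree topology and node memberships stay fixed; only the labels
    are shuffled uniformly. Per permutation the node 2x2 counts are
    recomputed from memberships and the greedy top-k antichain sum is
    re-derived. p = (1 + #{S_perm >= S_obs}) / (1 + n_perm);
    deterministic given the seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs_stats = node_statistics(tree)
    observed = tree_statistic(obs_stats, tree, k=k)
    s_obs = observed.S

    case = (tree.phenotype == 2).astype(np.float64)
    n = len(case)
    total_cases = case.sum()
    total_controls = n - total_cases

    scored = [node for node in tree.nodes if node.parent_id != -1]
    if not scored:
        return TreeTestResult(
            selected_nodes=[], S=0.0, n_perm=n_perm, p_perm=1.0
        )
    member = np.zeros((len(scored), n), dtype=np.float64)
    sizes = np.empty(len(scored))
    ids = np.array([node.node_id for node in scored])
    depths = np.array([node.depth for node in scored])
    for row, node in enumerate(scored):
        member[row, node.members] = 1.0
        sizes[row] = node.size
    anc_masks = tree.ancestor_masks()

    denom = (
        sizes[:, None]
        * (n - sizes)[:, None]
        * total_cases
        * total_controls
    )
    rng = np.random.default_rng(seed)
    idx = {nid: r for r, nid in enumerate(ids)}
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(batch_size, n_perm - done)
        labels = np.empty((n, b))
        for j in range(b):
            labels[:, j] = rng.permutation(case)
        cases_in = member @ labels  # (nodes, b)
        controls_in = sizes[:, None] - cases_in
        cases_out = total_cases - cases_in
        controls_out = total_controls - controls_in
        num = n * (cases_in * controls_out - cases_out * controls_in) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            stats = np.where(denom > 0, num / denom, 0.0)
        for j in range(b):
            col = stats[:, j]
            order = ids[np.lexsort((ids, depths, -col))]
            chosen = _greedy_select(order, anc_masks, k)
            s_perm = sum(col[idx[c]] for c in chosen)
            if s_perm >= s_obs:
                exceed += 1
        done += b
    p = (1 + exceed) / (1 + n_perm)
    return TreeTestResult(
        selected_nodes=observed.selected_nodes,
        S=s_obs,
        n_perm=n_perm,
        p_perm=p,
    )


# ---------------------------------------------------------------------------
# end-to-end driver and exports
# ---------------------------------------------------------------------------


def run_tree_test(
    g: GenotypeTable,
    t: QcThresholds | None = None,
    n_perm: int = 999,
    seed: int = 0,
    k: int = 5,
):
    """QC cascade -> tree build -> node scores -> permutation p-value.

    Returns ``(QcReport, TreeTestResult)`` mirroring the study's
    per-cohort report row (removed by QC, rare haplotypes removed,
    final sample size, whole-tree p-value).
    """
    clean, report = lextree_qc(g, t=t)
    if clean.n_samples == 0:
        raise ValueError("no individuals left after lexical-tree QC")
    tree = build_tree(clean)
    result = permutation_test(tree, n_perm=n_perm, seed=seed, k=k)
    return report, result


def node_table(tree: HaplotypeTree, stats: list, result: TreeTestResult | None = None) -> pd.DataFrame:
    """Per-node TSV-ready table: id, parent, defining prefix, counts,
    statistic, direction, selected flag."""
    selected = set(result.selected_ids) if result is not None else set()
    by_id = {s.node_id: s for s in stats}
    rows = []
    for node in tree.nodes:
        st = by_id.get(node.node_id)
        prefix = ";".join(f"{sid}:{allele}" for sid, allele in tree.prefix(node.node_id))
        cases = int((tree.phenotype[node.members] == 2).sum())
        rows.append(
            {
                "node_id": node.node_id,
                "parent_id": node.parent_id,
                "prefix": prefix or ".",
                "n": node.size,
                "n_cases": cases,
                "n_controls": node.size - cases,
                "statistic": st.statistic if st else np.nan,
                "direction": st.direction if st else ".",
                "selected": node.node_id in selected,
            }
        )
    return pd.DataFrame(rows)


def to_newick(tree: HaplotypeTree) -> str:
    """Skeletal Newick export with node labels ``id_cases/controls``."""

    children: dict = {}
    for node in tree.nodes:
        if node.parent_id != -1:
            children.setdefault(node.parent_id, []).append(node.node_id)

    def label(node_id: int) -> str:
        node = tree.nodes[node_id]
        cases = int((tree.phenotype[node.members] == 2).sum())
        return f"n{node_id}_{cases}/{node.size - cases}"

    def render(node_id: int) -> str:
        kids = children.get(node_id, [])
        if not kids:
            return label(node_id)
        inner = ",".join(render(c) for c in kids)
        return f"({inner}){label(node_id)}"

    return render(tree.root_id) + ";"
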
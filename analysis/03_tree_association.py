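#!/usr/bin/env python
"""Lexical haplotype-tree association on the simulated cohorts: QC, tree
build, node scores, whole-tree statistic and permutation p-values, with
per-node tables and skeletal Newick exports.

Found: the null cohort's whole-tree p is unremarkable while the planted
cohort rejects decisively, with the planted lineage among the five
selected non-nested nodes.
"""

from pathlib import Path

from mtassoc.lextree import (
    build_tree,
    node_statistics,
    node_table,
    permutation_test,
    to_newick,
)
from mtassoc.qc import lextree_qc
from mtassoc.simulate import null_config, planted_config, simulate_cohort

OUT = Path("results/tree")
SEED = 3
N_PERM = 9999


def run(label, cfg):
    g = simulate_cohort(cfg)
    clean, report = lextree_qc(g)
    tree = build_tree(clean)
    stats = node_statistics(tree)
    result = permutation_test(tree, n_perm=N_PERM, seed=SEED)
    df = node_table(tree, stats, result)
    df.to_csv(OUT / f"{label}_nodes.tsv", sep="\t", index=False)
    (OUT / f"{label}_tree.nwk").write_text(to_newick(tree) + "\n")
    report.to_tsv(OUT / f"{label}_qc.tsv")
    rare = report.stage("rare_haplotypes")[1]
    print(
        f"{label}: removed by QC {report.individuals_removed - rare}, "
        f"rare haplotypes removed {rare}, sample size {report.final_n}, "
        f"S = {result.S:.2f}, whole-tree p = {result.p_perm:.4g} "
        f"({result.n_perm} permutations)"
    )
    return result


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    run("null", null_config(500, 500, seed=SEED))
    run("planted", planted_config(500, 500, seed=SEED + 1))


if __name__ == "__main__":
    main()
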
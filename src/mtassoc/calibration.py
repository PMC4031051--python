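"""Simulation-based operating characteristics of the whole-tree test.

These runners measure, under the synthetic cohort model, the properties
a permutation test must have: correct size (rejection rate at the
nominal level, uniform p-values) when no clade carries a disease
effect, and power plus clade recovery when one does. They also verify
the retrospective sampler against its closed-form enrichment law. The
same routines back the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from mtassoc.lextree import build_tree, permutation_test
from mtassoc.simulate import (
    PLANTED_CLADE_POSITION,
    CladeDef,
    SimulationConfig,
    null_config,
    planted_config,
    simulate_cohort,
)


def _child_seeds(seed: int, n: int, stream: int) -> np.ndarray:
    rng = np.random.default_rng([seed, stream])
    return rng.integers(0, 2**31 - 1, size=n)


def null_calibration(
    n_replicates: int = 500,
    n_cases: int = 200,
    n_controls: int = 200,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Size of the whole-tree test under the null (all clade ORs = 1).

    Simulates complete-data cohorts with haplogroup structure but no
    disease effect, runs the permutation test on each, and summarises
    the p-value distribution: empirical rejection rate at ``alpha`` and
    a Kolmogorov-Smirnov uniformity p-value.
    """
    sim_seeds = _child_seeds(seed, n_replicates, stream=1)
    perm_seeds = _child_seeds(seed, n_replicates, stream=2)
    p_values = np.empty(n_replicates)
    for i in range(n_replicates):
        g = simulate_cohort(null_config(n_cases, n_controls, seed=int(sim_seeds[i])))
        tree = build_tree(g)
        p_values[i] = permutation_test(tree, n_perm=n_perm, seed=int(perm_seeds[i])).p_perm
    return {
        "p_values": p_values,
        "rejection_rate": float((p_values <= alpha).mean()),
        "ks_p": float(stats.kstest(p_values, "uniform").pvalue),
    }


def planted_recovery(
    n_replicates: int = 200,
    n_cases: int = 500,
    n_controls: int = 500,
    clade_frequency: float = 0.15,
    odds_ratio: float = 3.0,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Power and clade recovery with one planted risk clade.

    A replicate counts as *recovered* when some selected node's members
    are all carriers of the planted clade — the test not only rejects
    but points at the planted lineage (or a sub-lineage of it).
    """
    sim_seeds = _child_seeds(seed, n_replicates, stream=3)
    perm_seeds = _child_seeds(seed, n_replicates, stream=4)
    rejected = np.zeros(n_replicates, dtype=bool)
    recovered = np.zeros(n_replicates, dtype=bool)
    p_values = np.empty(n_replicates)
    for i in range(n_replicates):
        cfg = planted_config(
            n_cases,
            n_controls,
            seed=int(sim_seeds[i]),
            clade_frequency=clade_frequency,
            odds_ratio=odds_ratio,
        )
        g = simulate_cohort(cfg)
        tree = build_tree(g)
        result = permutation_test(tree, n_perm=n_perm, seed=int(perm_seeds[i]))
        p_values[i] = result.p_perm
        rejected[i] = result.p_perm < alpha
        (col,) = np.flatnonzero(
            tree.snp_meta["position"].to_numpy() == PLANTED_CLADE_POSITION
        )
        carriers = set(np.flatnonzero(g.alleles[:, col] == 1))
        recovered[i] = any(
            set(tree.nodes[s.node_id].members) <= carriers
            for s in result.selected_nodes
        )
    return {
        "p_values": p_values,
        "rejection_rate": float(rejected.mean()),
        "recovery_rate": float(recovered.mean()),
    }


def clade_frequency_law(
    clade_frequency: float = 0.2,
    odds_ratio: float = 2.0,
    baseline_odds: float = 0.01,
    n_cases: int = 10_000,
    seed: int = 0,
) -> dict:
    """Retrospective enrichment of a planted clade among cases.

    For a rare disease the case-carrier frequency converges to
    fR/(1 - f + fR); the sampler's observed frequency is returned with
    the closed-form expectation and its Monte-Carlo standard error.
    """
    f, R = clade_frequency, odds_ratio
    clades = [CladeDef("X", None, frozenset({(5000, "T")}), f, R)]
    cfg = SimulationConfig(
        clades=clades,
        n_cases=n_cases,
        n_controls=max(1000, n_cases // 10),
        n_neutral_snps=2,
        baseline_odds=baseline_odds,
        seed=seed,
    )
    g = simulate_cohort(cfg)
    (col,) = np.flatnonzero(g.snp_meta["position"].to_numpy() == 5000)
    observed = float((g.alleles[g.is_case, col] == 1).mean())
    expected = f * R / (1 - f + f * R)
    se = float(np.sqrt(expected * (1 - expected) / n_cases))
    return {"observed": observed, "expected": expected, "se": se, "n_cases": n_cases}
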
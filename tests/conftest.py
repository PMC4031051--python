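"""Shared fixtures: hand-crafted cohorts with fully enumerated QC outcomes."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mtassoc.genotypes import (
    ALT,
    CASE,
    CONTROL,
    MISSING_ALLELE,
    MISSING_PHENOTYPE,
    REF,
    GenotypeTable,
)


def make_table(
    alleles,
    phenotype,
    positions=None,
    ref="A",
    alt="G",
    sample_ids=None,
    platform="test",
) -> GenotypeTable:
    """Build a GenotypeTable from a plain allele matrix (0/1/-1)."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n, m = alleles.shape
    if positions is None:
        positions = list(range(100, 100 + 10 * m, 10))
    refs = [ref] * m if isinstance(ref, str) else list(ref)
    alts = [alt] * m if isinstance(alt, str) else list(alt)
    snp_meta = pd.DataFrame(
        {
            "id": [f"mt{p}" for p in positions],
            "position": positions,
            "ref_allele": refs,
            "alt_allele": alts,
        }
    )
    return GenotypeTable(
        sample_ids=sample_ids or [f"I{i:03d}" for i in range(n)],
        phenotype=np.asarray(phenotype),
        alleles=alleles,
        snp_meta=snp_meta,
        platform=platform,
    )


def lexical_qc_fixture():
    """30 individuals x 14 SNPs with every lexical-QC stage's removal designed.

    Expected behaviour with QcThresholds(worst_individual_fraction=0.1):

    - phenotype pruning: individual 29 (phenotype -9) -> 29 left
    - stage 1: SNP 0 (2 missing calls, call rate 27/29 < 0.95) and SNP 1
      (monomorphic, MAF 0 < 0.005) removed -> SNPs 2..13 left
    - stage 2: floor(0.1 * 29) = 2 worst individuals: 27 (3 missing) and
      28 (2 missing) -> 27 individuals left
    - stage 3: floor(12 / 2) = 6 SNPs; SNPs 2..8 each have one missing
      call among the survivors, so the six lowest positions of that
      group (SNPs 2..7) are cut -> SNPs 8..13 left
    - stage 4: individual 26 (missing at SNP 8) removed -> 26 left
    - stage 5: haplotype C (alt at SNP 9; individuals 20-23; count 4 < 5)
      and haplotype D (alt at SNP 10; individuals 24-25; cases only)
      removed -> final 20 individuals x 6 SNPs
    """
    n, m = 30, 14
    alleles = np.zeros((n, m), dtype=np.int8)

    # stage-1 fodder: SNP0 loses 2 calls; SNP1 stays monomorphic (all REF)
    alleles[18, 0] = MISSING_ALLELE
    alleles[19, 0] = MISSING_ALLELE
    # stage-2 fodder: individuals 27 and 28 with the most missing sites
    alleles[27, [9, 10, 11]] = MISSING_ALLELE
    alleles[28, [12, 13]] = MISSING_ALLELE
    # stage-3/4 fodder: SNPs 2..8 each get one missing call; individual 26
    # holds the one at SNP 8, the sole survivor of that group
    for ind, snp in zip(range(20, 27), range(2, 9)):
        alleles[ind, snp] = MISSING_ALLELE

    # keep every SNP 2..13 polymorphic (MAF >= 0.005 at stage 1)
    alleles[0, 2:8] = ALT            # SNPs 2..7 (removed later at stage 3)
    alleles[12:20, 8] = ALT          # haplotype B carriers
    alleles[20:24, 9] = ALT          # haplotype C carriers (count 4)
    alleles[24:26, 10] = ALT         # haplotype D carriers (cases only)
    alleles[28, 11] = ALT
    alleles[27, 12] = ALT
    alleles[26, 13] = ALT

    phenotype = np.full(n, CONTROL)
    cases = [0, 1, 2, 3, 4, 5, 12, 13, 14, 15, 20, 21, 24, 25]
    phenotype[cases] = CASE
    phenotype[29] = MISSING_PHENOTYPE

    positions = list(range(100, 100 + 10 * m, 10))
    g = make_table(alleles, phenotype, positions=positions)
    expected = {
        "missing_phenotype": (1, 0),
        "snp_callrate_maf": (0, 2),
        "worst_individuals": (2, 0),
        "worst_snps": (0, 6),
        "any_missing_individuals": (1, 0),
        "rare_haplotypes": (6, 0),
        "final_n": 20,
        "final_m": 6,
        "final_positions": positions[8:14],
        "final_sample_ids": [f"I{i:03d}" for i in range(20)],
    }
    return g, expected


def primary_qc_fixture():
    """30 individuals x 21 SNPs with every primary-QC stage designed.

    Expected with default thresholds:

    - stage 1: individual 29 (phenotype -9) removed
    - stage 2: SNP at position 100 (4/29 missing = 13.8% > 10%) removed
    - stage 3: individual 5 (3/20 = 15% missing of remaining SNPs) removed
    - stage 4: individual 7 (non-European: alt at m.8701) removed
    - stage 5: position 1500 (its only alt carrier was individual 7) and
      the three now-monomorphic diagnostic SNPs, all MAF 0 < 1e-5, removed
    -> final 27 individuals x 16 SNPs
    """
    positions = (
        list(range(100, 1600, 100)) + [8540, 8701, 10873] + [16000, 16100, 16200]
    )
    n, m = 30, len(positions)
    assert m == 21
    alleles = np.zeros((n, m), dtype=np.int8)
    col = {p: j for j, p in enumerate(positions)}

    alleles[0:4, col[100]] = MISSING_ALLELE          # SNP missingness 4/29
    alleles[5, [col[200], col[300], col[400]]] = MISSING_ALLELE  # ind 15%
    alleles[7, col[8701]] = ALT                      # non-European lineage
    alleles[7, col[1500]] = ALT                      # sole carrier at 1500
    # keep all other non-diagnostic SNPs polymorphic via individual 10
    for p in positions:
        if p not in (1500, 8540, 8701, 10873):
            alleles[10, col[p]] = ALT

    phenotype = np.full(n, CONTROL)
    phenotype[:14] = CASE
    phenotype[29] = MISSING_PHENOTYPE

    # diagnostic SNPs: reference allele IS the European base
    from mtassoc.genotypes import EUROPEAN_DIAGNOSTIC_ALLELES

    refs = [EUROPEAN_DIAGNOSTIC_ALLELES.get(p, "A") for p in positions]
    g = make_table(alleles, phenotype, positions=positions, ref=refs, alt="G")
    expected = {
        "missing_phenotype": (1, 0),
        "snp_missingness": (0, 1),
        "individual_missingness": (1, 0),
        "non_european": (1, 0),
        "maf": (0, 4),
        "final_n": 27,
        "final_m": 16,
        "removed_individuals": ["I029", "I005", "I007"],
        "removed_positions": [100, 1500, 8540, 8701, 10873],
    }
    return g, expected


@pytest.fixture
def lexical_fixture():
    return lexical_qc_fixture()


@pytest.fixture
def primary_fixture():
    return primary_qc_fixture()


def complete_cohort(n_per_hap=6, seed=0):
    """Small complete-data cohort: 4 haplotypes x n_per_hap copies each,
    phenotypes balanced within haplotype (every node statistic is 0)."""
    haps = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 1]], dtype=np.int8
    )
    alleles = np.repeat(haps, n_per_hap, axis=0)
    phenotype = np.tile(
        np.array([CASE] * (n_per_hap // 2) + [CONTROL] * (n_per_hap - n_per_hap // 2)),
        4,
    )
    return make_table(alleles, phenotype)
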
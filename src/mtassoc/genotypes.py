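"""Core genotype container for haploid mtDNA case-control cohorts.

Genotypes are binary haploid calls (reference vs alternate allele) over
sites on the revised Cambridge Reference Sequence (rCRS, NC_012920;
1-based positions 1..16,569). Phenotypes use the PLINK pedigree
convention: 1 = control, 2 = case, -9 = missing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

# phenotype codes (PLINK pedigree convention)
CONTROL = 1
CASE = 2
MISSING_PHENOTYPE = -9

# allele codes in the genotype matrix
REF = 0
ALT = 1
MISSING_ALLELE = -1

MT_LENGTH = 16569

#: Macrohaplogroup-N diagnostic alleles used to recognise European mtDNA
#: lineages: an individual is treated as European-lineage when it carries
#: all of m.8701A, m.8540T and m.10873T (at the testable positions).
EUROPEAN_DIAGNOSTIC_ALLELES = {8701: "A", 8540: "T", 10873: "T"}

SNP_META_COLUMNS = ("id", "position", "ref_allele", "alt_allele")


@dataclass
class GenotypeTable:
    """n individuals x m mtDNA SNPs of binary haploid calls.

    Attributes
    ----------
    sample_ids
        Per-individual identifiers, length n.
    phenotype
        Integer array of length n with codes 1 (control), 2 (case),
        -9 (missing).
    alleles
        (n, m) int8 matrix: 0 = reference allele, 1 = alternate allele,
        -1 = missing call.
    snp_meta
        DataFrame with columns ``id``, ``position`` (1-based rCRS),
        ``ref_allele``, ``alt_allele``; one row per SNP, aligned with the
        columns of ``alleles``.
    platform
        Free-text genotyping platform label.
    """

    sample_ids: list[str]
    phenotype: np.ndarray
    alleles: np.ndarray
    snp_meta: pd.DataFrame
    platform: str = ""

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("allele matrix must be 2-dimensional")
        n, m = self.alleles.shape
        if len(self.sample_ids) != n or len(self.phenotype) != n:
            raise ValueError("sample_ids/phenotype length mismatch with allele matrix")
        if len(self.snp_meta) != m:
            raise ValueError("snp_meta rows must match allele matrix columns")
        missing_cols = set(SNP_META_COLUMNS) - set(self.snp_meta.columns)
        if missing_cols:
            raise ValueError(f"snp_meta missing columns: {sorted(missing_cols)}")
        pos = self.snp_meta["position"].to_numpy()
        if m and (pos.min() < 1 or pos.max() > MT_LENGTH):
            raise ValueError("SNP positions must lie in [1, 16569]")
        bad = set(np.unique(self.phenotype)) - {CONTROL, CASE, MISSING_PHENOTYPE}
        if bad:
            raise ValueError(f"invalid phenotype codes: {sorted(bad)}")

    # ---- basic shape ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    # ---- phenotype masks ------------------------------------------------
    @property
    def is_case(self) -> np.ndarray:
        return self.phenotype == CASE

    @property
    def is_control(self) -> np.ndarray:
        return self.phenotype == CONTROL

    @property
    def phenotype_missing(self) -> np.ndarray:
        return self.phenotype == MISSING_PHENOTYPE

    # ---- per-SNP / per-sample summaries ---------------------------------
    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP over non-missing calls.

        Monomorphic-for-missing columns (no calls at all) yield NaN.
        """
        called = self.alleles != MISSING_ALLELE
        n_called = called.sum(axis=0)
        n_alt = (self.alleles == ALT).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, n_alt / np.maximum(n_called, 1), np.nan)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP in [0, 0.5], NaN if uncalled."""
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def snp_missing_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_snps)
        return (self.alleles == MISSING_ALLELE).mean(axis=0)

    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - self.snp_missing_rate()

    def sample_missing_rate(self) -> np.ndarray:
        if self.n_snps == 0:
            return np.zeros(self.n_samples)
        return (self.alleles == MISSING_ALLELE).mean(axis=1)

    # ---- subsetting ------------------------------------------------------
    def subset(
        self,
        samples: np.ndarray | None = None,
        snps: np.ndarray | None = None,
    ) -> "GenotypeTable":
        """Return a new table restricted to the given sample/SNP selectors.

        Selectors may be boolean masks or integer index arrays.
        """
        s_idx = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        if s_idx.dtype == bool:
            s_idx = np.flatnonzero(s_idx)
        m_idx = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if m_idx.dtype == bool:
            m_idx = np.flatnonzero(m_idx)
        return GenotypeTable(
            sample_ids=[self.sample_ids[i] for i in s_idx],
            phenotype=self.phenotype[s_idx].copy(),
            alleles=self.alleles[np.ix_(s_idx, m_idx)].copy(),
            snp_meta=self.snp_meta.iloc[m_idx].reset_index(drop=True).copy(),
            platform=self.platform,
        )

    def copy(self) -> "GenotypeTable":
        return replace(
            self,
            sample_ids=list(self.sample_ids),
            phenotype=self.phenotype.copy(),
            alleles=self.alleles.copy(),
            snp_meta=self.snp_meta.copy(),
        )

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.phenotype, other.phenotype)
            and np.array_equal(self.alleles, other.alleles)
            and self.snp_meta.reset_index(drop=True).equals(
                other.snp_meta.reset_index(drop=True)
            )
        )
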
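"""Ordered quality-control cascades for haploid mtDNA case-control data.

Two cascades are provided. The primary-association cascade prunes
missing phenotypes, poorly genotyped SNPs and individuals, non-European
lineages, and low-MAF SNPs. The stricter lexical-tree cascade removes,
in order: SNPs with call rate < 95% or MAF < 0.5%; the 2% of
individuals with the most missing sites; the bottom 50% of SNPs with
the most missing samples; individuals with any remaining missing data;
and finally individuals whose full haplotype is absent from controls or
carried fewer than 5 times. Control-cohort merging and the
differential-missingness filter complete the QC surface.

Every cascade returns a :class:`QcReport`, an ordered ledger of
removals whose totals reconcile with the output table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mtassoc.genotypes import (
    ALT,
    EUROPEAN_DIAGNOSTIC_ALLELES,
    MISSING_ALLELE,
    MISSING_PHENOTYPE,
    REF,
    GenotypeTable,
)
from mtassoc.stats2x2 import chi2_2x2_p


@dataclass
class QcThresholds:
    """Threshold set for both cascades (defaults are the study values)."""

    snp_call_rate_min: float = 0.95       # lexical stage 1
    lextree_maf_min: float = 0.005        # lexical stage 1
    primary_maf_min: float = 1e-5         # primary stage 5
    snp_missing_max: float = 0.1          # primary stage 2
    individual_missing_max: float = 0.1   # primary stage 3
    worst_individual_fraction: float = 0.02  # lexical stage 2
    worst_snp_fraction: float = 0.50      # lexical stage 3
    rare_haplotype_min_count: int = 5     # lexical stage 5
    diff_missing_p: float = 1e-4
    control_discordance_p: float = 0.05

    def __post_init__(self):
        for name in (
            "snp_call_rate_min",
            "lextree_maf_min",
            "primary_maf_min",
            "snp_missing_max",
            "individual_missing_max",
            "worst_individual_fraction",
            "worst_snp_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.rare_haplotype_min_count < 0:
            raise ValueError("rare_haplotype_min_count must be >= 0")
        for name in ("diff_missing_p", "control_discordance_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class QcReport:
    """Ordered removal ledger: one row per cascade stage."""

    stages: list = field(default_factory=list)  # (name, individuals_removed, snps_removed)
    final_n: int = 0
    final_m: int = 0

    def add(self, name: str, individuals_removed: int, snps_removed: int) -> None:
        self.stages.append((name, int(individuals_removed), int(snps_removed)))

    @property
    def individuals_removed(self) -> int:
        return sum(s[1] for s in self.stages)

    @property
    def snps_removed(self) -> int:
        return sum(s[2] for s in self.stages)

    def stage(self, name: str):
        for s in self.stages:
            if s[0] == name:
                return s
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["stage", "individuals_removed", "snps_removed"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK text input
# ---------------------------------------------------------------------------


def load_plink(path_prefix, allele_map: dict | None = None) -> GenotypeTable:
    """Read a PED/MAP pair into a haploid :class:`GenotypeTable`.

    mtDNA calls written as homozygous diploid genotypes are collapsed to
    haploid; heterozygous calls are impossible for haploid mtDNA and are
    set missing (and counted). Allele polarity comes from
    ``allele_map`` (snp id -> (ref, alt)) when supplied, otherwise the
    first-seen allele per SNP becomes the reference.

    Raises
    ------
    ValueError
        On PED/MAP row-length mismatch or a SNP with more than two
        observed alleles (the offending SNP id is named).
    """
    prefix = str(path_prefix)
    snps = []
    with open(prefix + ".map") as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"malformed MAP line: {line!r}")
            snps.append((parts[1], int(parts[3])))
    m = len(snps)

    sample_ids: list[str] = []
    phenotypes: list[int] = []
    rows: list[np.ndarray] = []
    het_count = 0
    # observed alleles per SNP, in order of first appearance
    observed: list[list[str]] = [[] for _ in range(m)]

    with open(prefix + ".ped") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"PED row for {parts[0] if parts else '?'} has "
                    f"{len(parts)} fields, expected {6 + 2 * m}"
                )
            sample_ids.append(parts[1])
            pheno = int(parts[5])
            phenotypes.append(MISSING_PHENOTYPE if pheno in (0, MISSING_PHENOTYPE) else pheno)
            calls = np.empty(m, dtype=object)
            for j in range(m):
                a, b = parts[6 + 2 * j], parts[7 + 2 * j]
                if a == "0" or b == "0":
                    calls[j] = None
                elif a != b:
                    het_count += 1  # heterozygous mtDNA call: artefact
                    calls[j] = None
                else:
                    calls[j] = a.upper()
                    if calls[j] not in observed[j]:
                        observed[j].append(calls[j])
            rows.append(calls)

    ref_alleles, alt_alleles = [], []
    for j, (snp_id, _) in enumerate(snps):
        obs = observed[j]
        if allele_map is not None and snp_id in allele_map:
            ref, alt = allele_map[snp_id]
            extra = set(obs) - {ref.upper(), alt.upper()}
            if extra:
                raise ValueError(f"SNP {snp_id}: alleles {sorted(extra)} not in allele map")
            ref, alt = ref.upper(), alt.upper()
        else:
            if len(obs) > 2:
                raise ValueError(f"SNP {snp_id} is not biallelic: {sorted(obs)}")
            ref = obs[0] if obs else "N"
            alt = obs[1] if len(obs) > 1 else "N"
        ref_alleles.append(ref)
        alt_alleles.append(alt)

    n = len(sample_ids)
    alleles = np.full((n, m), MISSING_ALLELE, dtype=np.int8)
    for i, calls in enumerate(rows):
        for j in range(m):
            c = calls[j]
            if c is None:
                continue
            alleles[i, j] = REF if c == ref_alleles[j] else ALT

    snp_meta = pd.DataFrame(
        {
            "id": [s for s, _ in snps],
            "position": [p for _, p in snps],
            "ref_allele": ref_alleles,
            "alt_allele": alt_alleles,
        }
    )
    g = GenotypeTable(
        sample_ids=sample_ids,
        phenotype=np.array(phenotypes),
        alleles=alleles,
        snp_meta=snp_meta,
    )
    if het_count:
        warnings.warn(
            f"{het_count} heterozygous mtDNA calls set missing", stacklevel=2
        )
    return g


# ---------------------------------------------------------------------------
# primary-association cascade
# ---------------------------------------------------------------------------


def primary_qc(
    g: GenotypeTable, t: QcThresholds | None = None
) -> tuple[GenotypeTable, QcReport]:
    """Primary-association QC, stages applied strictly in order.

    1. drop individuals with missing phenotypes;
    2. drop SNPs with missingness > ``snp_missing_max``;
    3. drop individuals with missingness > ``individual_missing_max``;
    4. drop non-European lineages (diagnostic-triplet rule);
    5. drop SNPs with MAF < ``primary_maf_min``.

    Stops early (with the partial ledger) if a stage empties the table.
    """
    t = t or QcThresholds()
    report = QcReport()
    cur = g

    def empty() -> bool:
        return cur.n_samples == 0 or cur.n_snps == 0

    keep = ~cur.phenotype_missing
    report.add("missing_phenotype", (~keep).sum(), 0)
    cur = cur.subset(samples=keep)
    if not empty():
        keep_snp = cur.snp_missing_rate() <= t.snp_missing_max
        report.add("snp_missingness", 0, (~keep_snp).sum())
        cur = cur.subset(snps=keep_snp)
    if not empty():
        keep = cur.sample_missing_rate() <= t.individual_missing_max
        report.add("individual_missingness", (~keep).sum(), 0)
        cur = cur.subset(samples=keep)
    if not empty():
        cur, removed_ids = filter_non_european(cur)
        report.add("non_european", len(removed_ids), 0)
    if not empty():
        keep_snp = cur.maf() >= t.primary_maf_min
        report.add("maf", 0, (~keep_snp).sum())
        cur = cur.subset(snps=keep_snp)
    report.final_n = cur.n_samples
    report.final_m = cur.n_snps
    return cur, report


def filter_non_european(g: GenotypeTable) -> tuple[GenotypeTable, list]:
    """Remove individuals not carrying the European-lineage diagnostic
    alleles (m.8701A, m.8540T, m.10873T) at every testable position.

    Missing calls at a diagnostic position are treated as compatible
    (the individual is retained). If none of the three positions is
    genotyped, the table is returned unchanged with a warning.
    """
    positions = g.snp_meta["position"].to_numpy()
    non_eur = np.zeros(g.n_samples, dtype=bool)
    testable = 0
    for pos, eur_base in EUROPEAN_DIAGNOSTIC_ALLELES.items():
        (cols,) = np.nonzero(positions == pos)
        for j in cols:
            testable += 1
            ref = g.snp_meta.iloc[j]["ref_allele"]
            alt = g.snp_meta.iloc[j]["alt_allele"]
            col = g.alleles[:, j]
            if ref == eur_base:
                non_eur |= col == ALT
            elif alt == eur_base:
                non_eur |= col == REF
            else:
                # neither recorded allele is the European base:
                # every non-missing carrier fails the rule
                non_eur |= col != MISSING_ALLELE
    if testable == 0:
        warnings.warn(
            "none of the European diagnostic positions (8701, 8540, 10873) "
            "is genotyped; non-European filter is a no-op",
            stacklevel=2,
        )
        return g, []
    removed_ids = [g.sample_ids[i] for i in np.flatnonzero(non_eur)]
    return g.subset(samples=~non_eur), removed_ids


# ---------------------------------------------------------------------------
# lexical-tree cascade
# ---------------------------------------------------------------------------


def lextree_qc(
    g: GenotypeTable,
    controls_mask: np.ndarray | None = None,
    t: QcThresholds | None = None,
) -> tuple[GenotypeTable, QcReport]:
    """Stricter ordered cascade feeding the lexical haplotype tree.

    Individuals with missing phenotypes are pruned first (they cannot
    be classed as case or control), then the five stages run strictly
    in order (see module docstring). Ties in the stage-2 and stage-3
    rank cuts are broken by sample input order and ascending rCRS
    position respectively, making the 2% and 50% cuts deterministic.
    The output contains no missing genotypes and every retained
    haplotype has count >= ``rare_haplotype_min_count`` and at least
    one control carrier.
    """
    t = t or QcThresholds()
    report = QcReport()
    cur = g

    keep = ~cur.phenotype_missing
    report.add("missing_phenotype", (~keep).sum(), 0)
    cur = cur.subset(samples=keep)
    if controls_mask is None:
        controls = cur.is_control
    else:
        controls = np.asarray(controls_mask)[keep]

    # stage 1: SNP call rate < 95% or MAF < 0.5%
    drop = (cur.snp_call_rate() < t.snp_call_rate_min) | (
        np.nan_to_num(cur.maf(), nan=0.0) < t.lextree_maf_min
    )
    report.add("snp_callrate_maf", 0, drop.sum())
    cur = cur.subset(snps=~drop)

    # stage 2: the 2% of individuals with the most missing sites
    # (only individuals that actually have missing sites are eligible)
    miss_count = (cur.alleles == MISSING_ALLELE).sum(axis=1)
    k = int(np.floor(t.worst_individual_fraction * cur.n_samples))
    order = np.lexsort((np.arange(cur.n_samples), -miss_count))
    worst = [i for i in order[:k] if miss_count[i] > 0]
    keep = np.ones(cur.n_samples, dtype=bool)
    keep[worst] = False
    report.add("worst_individuals", len(worst), 0)
    cur = cur.subset(samples=keep)
    controls = controls[keep]

    # stage 3: bottom 50% of SNPs with the most missing samples
    # (rank by missing count descending, position ascending; remove the
    # top half of that ranking, rounding the count down)
    miss_count = (cur.alleles == MISSING_ALLELE).sum(axis=0)
    k = int(np.floor(t.worst_snp_fraction * cur.n_snps))
    order = np.lexsort((cur.snp_meta["position"].to_numpy(), -miss_count))
    keep_snp = np.ones(cur.n_snps, dtype=bool)
    keep_snp[order[:k]] = False
    report.add("worst_snps", 0, k)
    cur = cur.subset(snps=keep_snp)

    # stage 4: individuals with any missing data on the remaining SNPs
    any_missing = (cur.alleles == MISSING_ALLELE).any(axis=1)
    report.add("any_missing_individuals", any_missing.sum(), 0)
    cur = cur.subset(samples=~any_missing)
    controls = controls[~any_missing]

    # stage 5: haplotypes absent from controls or with frequency < 5
    if cur.n_samples:
        hap_codes = _haplotype_codes(cur.alleles)
        uniq, inv, counts = np.unique(hap_codes, return_inverse=True, return_counts=True)
        control_counts = np.bincount(inv[controls], minlength=len(uniq))
        bad_hap = (counts < t.rare_haplotype_min_count) | (control_counts == 0)
        drop_ind = bad_hap[inv]
    else:
        drop_ind = np.zeros(0, dtype=bool)
    report.add("rare_haplotypes", drop_ind.sum(), 0)
    cur = cur.subset(samples=~drop_ind)

    report.final_n = cur.n_samples
    report.final_m = cur.n_snps
    if cur.n_snps == 0:
        raise ValueError("lexical-tree QC removed every SNP; nothing to analyse")
    return cur, report


def _haplotype_codes(alleles: np.ndarray) -> np.ndarray:
    """Encode complete binary haplotypes as hashable row keys."""
    if (alleles == MISSING_ALLELE).any():
        raise ValueError("haplotype coding requires complete data")
    packed = np.packbits(alleles.astype(bool), axis=1)
    return np.array([row.tobytes() for row in packed])


# ---------------------------------------------------------------------------
# control merging and differential missingness
# ---------------------------------------------------------------------------


def merge_controls(
    c1: GenotypeTable, c2: GenotypeTable, t: QcThresholds | None = None
) -> tuple[GenotypeTable, QcReport]:
    """Merge two control cohorts, dropping allele-frequency-discordant SNPs.

    SNPs are matched on rCRS position (the intersection is taken and
    the difference logged). Each shared SNP's haploid allele counts in
    the two cohorts form a 2x2 table; SNPs with chi-square
    P < ``control_discordance_p`` are removed before concatenation.
    """
    t = t or QcThresholds()
    report = QcReport()
    pos1 = c1.snp_meta["position"].to_numpy()
    pos2 = c2.snp_meta["position"].to_numpy()
    shared, i1, i2 = np.intersect1d(pos1, pos2, return_indices=True)
    if shared.size == 0:
        raise ValueError("control cohorts share no SNP positions")
    report.add("not_shared", 0, (len(pos1) - len(shared)) + (len(pos2) - len(shared)))
    a = c1.subset(snps=i1)
    b = c2.subset(snps=i2)

    # harmonise polarity where ref/alt are swapped between cohorts
    swap = (a.snp_meta["ref_allele"].to_numpy() == b.snp_meta["alt_allele"].to_numpy()) & (
        a.snp_meta["alt_allele"].to_numpy() == b.snp_meta["ref_allele"].to_numpy()
    )
    if swap.any():
        cols = np.flatnonzero(swap)
        sub = b.alleles[:, cols]
        flipped = np.where(sub == MISSING_ALLELE, MISSING_ALLELE, 1 - sub)
        b.alleles[:, cols] = flipped
        b.snp_meta.loc[cols, ["ref_allele", "alt_allele"]] = a.snp_meta.loc[
            cols, ["ref_allele", "alt_allele"]
        ].to_numpy()

    alt1 = (a.alleles == ALT).sum(axis=0)
    ref1 = (a.alleles == REF).sum(axis=0)
    alt2 = (b.alleles == ALT).sum(axis=0)
    ref2 = (b.alleles == REF).sum(axis=0)
    _, p = chi2_2x2_p(alt1, ref1, alt2, ref2)
    discordant = p < t.control_discordance_p
    report.add("control_discordance", 0, discordant.sum())
    a = a.subset(snps=~discordant)
    b = b.subset(snps=~discordant)

    merged = GenotypeTable(
        sample_ids=list(a.sample_ids) + list(b.sample_ids),
        phenotype=np.concatenate([a.phenotype, b.phenotype]),
        alleles=np.vstack([a.alleles, b.alleles]),
        snp_meta=a.snp_meta.copy(),
        platform=a.platform or b.platform,
    )
    report.final_n = merged.n_samples
    report.final_m = merged.n_snps
    return merged, report


def differential_missingness(
    cases: GenotypeTable, controls: GenotypeTable, t: QcThresholds | None = None
) -> tuple[list, list]:
    """Flag SNPs whose missingness differs between cases and controls.

    For each shared SNP (matched on position) the 2x2 table
    missing/called x case/control is tested by Pearson chi-square; SNPs
    with P < ``diff_missing_p`` are removed. A SNP with no missing
    calls anywhere has statistic 0 and is kept. Returns
    ``(kept_snp_ids, removed_snp_ids)``.
    """
    t = t or QcThresholds()
    pos1 = cases.snp_meta["position"].to_numpy()
    pos2 = controls.snp_meta["position"].to_numpy()
    shared, i1, i2 = np.intersect1d(pos1, pos2, return_indices=True)
    miss_ca = (cases.alleles[:, i1] == MISSING_ALLELE).sum(axis=0)
    call_ca = cases.n_samples - miss_ca
    miss_co = (controls.alleles[:, i2] == MISSING_ALLELE).sum(axis=0)
    call_co = controls.n_samples - miss_co
    _, p = chi2_2x2_p(miss_ca, call_ca, miss_co, call_co)
    ids = cases.snp_meta["id"].to_numpy()[i1]
    removed = p < t.diff_missing_p
    return list(ids[~removed]), list(ids[removed])
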
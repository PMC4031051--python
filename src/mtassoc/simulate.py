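"""Synthetic haplogroup-structured mtDNA case-control cohorts and panels.

The generator emulates the statistical structure a haploid case-control
association analysis assumes: nested clades ("haplogroups") defined by
shared variants, clade frequencies, planted disease odds ratios acting
multiplicatively on the odds scale, neutral SNPs at random minor-allele
frequencies, per-call and per-individual missingness, and missing
phenotypes coded -9. Sampling is retrospective: individuals are drawn
from the population model and labelled case with probability
sigmoid(log(baseline_odds) + sum of log clade odds ratios), and draws
continue until the case and control quotas are both met — matching
case-control ascertainment. No coalescent or mutation-process realism is
attempted; mtDNA recombination is absent by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mtassoc.genotypes import (
    ALT,
    CASE,
    CONTROL,
    EUROPEAN_DIAGNOSTIC_ALLELES,
    MISSING_ALLELE,
    MISSING_PHENOTYPE,
    MT_LENGTH,
    REF,
    GenotypeTable,
)

BASES = "ACGT"


class SimulationError(RuntimeError):
    """Raised when the retrospective sampler cannot meet its quotas."""


def reference_base(position: int, exclude: str | None = None) -> str:
    """Deterministic rCRS-like reference base for a position.

    The European diagnostic positions carry their European-lineage
    alleles (m.8701A, m.8540T, m.10873T); other positions get a fixed
    pseudo-random base. ``exclude`` forces a base different from a
    planned alternate allele.
    """
    if position in EUROPEAN_DIAGNOSTIC_ALLELES:
        base = EUROPEAN_DIAGNOSTIC_ALLELES[position]
    else:
        base = BASES[(position * 7919 + 3) % 4]
    if exclude is not None and base == exclude.upper():
        base = BASES[(BASES.index(base) + 1) % 4]
    return base


@dataclass(frozen=True)
class CladeDef:
    """A maternally inherited clade (haplogroup) in the disease model.

    ``defining_variants`` is a set of (1-based rCRS position, alternate
    base) pairs carried by every member of the clade; they must be
    disjoint from the defining variants of all ancestor clades.
    ``frequency`` is the clade's frequency conditional on membership in
    its parent (the shortfall from 1 across siblings is the parent
    background). ``odds_ratio`` multiplies the disease odds of carriers.
    """

    name: str
    parent: str | None
    defining_variants: frozenset
    frequency: float
    odds_ratio: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"clade {self.name}: frequency outside [0,1]")
        if self.odds_ratio <= 0:
            raise ValueError(f"clade {self.name}: odds_ratio must be > 0")
        for pos, allele in self.defining_variants:
            if not 1 <= pos <= MT_LENGTH:
                raise ValueError(f"clade {self.name}: position {pos} outside rCRS")
            if allele.upper() not in BASES:
                raise ValueError(f"clade {self.name}: bad allele {allele!r}")


@dataclass
class SimulationConfig:
    """Full recipe for one synthetic case-control cohort."""

    clades: list = field(default_factory=list)
    n_cases: int = 500
    n_controls: int = 500
    n_neutral_snps: int = 8
    neutral_maf_range: tuple = (0.01, 0.45)
    snp_missing_rate: float = 0.0
    individual_missing_rate: float = 0.0
    phenotype_missing_rate: float = 0.0
    baseline_odds: float = 0.05
    seed: int = 0
    draw_cap_factor: int = 1000
    platform: str = "synthetic"

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        for name in ("snp_missing_rate", "individual_missing_rate", "phenotype_missing_rate"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        lo, hi = self.neutral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("neutral_maf_range must satisfy 0 < low <= high <= 0.5")
        if self.baseline_odds <= 0:
            raise ValueError("baseline_odds must be > 0")
        _validate_clades(self.clades)


def _validate_clades(clades) -> None:
    names = [c.name for c in clades]
    if len(set(names)) != len(names):
        raise ValueError("clade names must be unique")
    by_name = {c.name: c for c in clades}
    # sibling frequencies sum to <= 1 at each level
    groups: dict = {}
    for c in clades:
        if c.parent is not None and c.parent not in by_name:
            raise ValueError(f"clade {c.name}: unknown parent {c.parent}")
        groups.setdefault(c.parent, []).append(c)
    for parent, sibs in groups.items():
        tot = sum(c.frequency for c in sibs)
        if tot > 1.0 + 1e-12:
            raise ValueError(
                f"sibling frequencies under parent {parent!r} sum to {tot} > 1"
            )
    # defining variants disjoint from ancestors'; all positions distinct
    seen_positions: dict = {}
    for c in clades:
        anc_vars = set()
        p = c.parent
        while p is not None:
            anc_vars |= set(by_name[p].defining_variants)
            p = by_name[p].parent
        if set(c.defining_variants) & anc_vars:
            raise ValueError(f"clade {c.name}: defining variants overlap an ancestor's")
        for pos, _ in c.defining_variants:
            if pos in seen_positions and seen_positions[pos] != c.name:
                raise ValueError(f"position {pos} defined by more than one clade")
            seen_positions[pos] = c.name


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _clade_children(clades):
    kids: dict = {}
    for i, c in enumerate(clades):
        kids.setdefault(c.parent, []).append(i)
    return kids


def _draw_lineages(clades, n: int, rng: np.random.Generator) -> np.ndarray:
    """Assign each of n individuals a clade lineage, returned as an
    (n, n_clades) boolean membership matrix."""
    member = np.zeros((n, len(clades)), dtype=bool)
    kids = _clade_children(clades)

    def assign(parent_name, rows):
        child_idx = kids.get(parent_name, [])
        if not child_idx or rows.size == 0:
            return
        freqs = np.array([clades[i].frequency for i in child_idx])
        probs = np.concatenate([freqs, [max(0.0, 1.0 - freqs.sum())]])
        probs = probs / probs.sum()
        choice = rng.choice(len(probs), size=rows.size, p=probs)
        for j, ci in enumerate(child_idx):
            sel = rows[choice == j]
            member[sel, ci] = True
            assign(clades[ci].name, sel)

    assign(None, np.arange(n))
    return member


def _case_probability(clades, member: np.ndarray, baseline_odds: float) -> np.ndarray:
    log_or = np.array([math.log(c.odds_ratio) for c in clades])
    logit = math.log(baseline_odds) + member @ log_or
    return 1.0 / (1.0 + np.exp(-logit))


def _snp_layout(config: SimulationConfig, rng: np.random.Generator):
    """Fixed SNP positions/alleles for a cohort: clade-defining variants
    plus neutral SNPs at distinct random positions, sorted by position."""
    clade_snps = {}  # position -> (alt, clade indices carrying it)
    for ci, c in enumerate(config.clades):
        for pos, alt in sorted(c.defining_variants):
            clade_snps[pos] = (alt.upper(), ci)
    taken = set(clade_snps) | set(EUROPEAN_DIAGNOSTIC_ALLELES)
    free = np.setdiff1d(np.arange(1, MT_LENGTH + 1), np.fromiter(taken, int))
    neutral_pos = np.sort(rng.choice(free, size=config.n_neutral_snps, replace=False))
    lo, hi = config.neutral_maf_range
    neutral_maf = rng.uniform(lo, hi, size=config.n_neutral_snps)

    rows = []
    for pos, (alt, ci) in clade_snps.items():
        rows.append((pos, reference_base(pos, exclude=alt), alt, ci, np.nan))
    for pos, maf in zip(neutral_pos, neutral_maf):
        ref = reference_base(int(pos))
        alt = BASES[(BASES.index(ref) + 1) % 4]
        rows.append((int(pos), ref, alt, -1, float(maf)))
    rows.sort(key=lambda r: r[0])
    return rows


def simulate_cohort(config: SimulationConfig) -> GenotypeTable:
    """Draw a case-control cohort under the clade disease model.

    Individuals are sampled (clade lineage by frequency, neutral alleles
    at their MAFs) and labelled case with probability
    ``sigmoid(log(baseline_odds) + sum log OR)``; sampling continues
    until exactly ``n_cases`` cases and ``n_controls`` controls accrue,
    then missingness is applied. Deterministic given ``config.seed``.

    Raises
    ------
    SimulationError
        If the quotas are not met within
        ``draw_cap_factor * (n_cases + n_controls)`` draws.
    """
    rng = np.random.default_rng(config.seed)
    layout = _snp_layout(config, rng)
    n_total = config.n_cases + config.n_controls
    draw_cap = config.draw_cap_factor * n_total

    kept_member: list = []
    kept_case: list = []
    n_case_kept = 0
    n_ctrl_kept = 0
    drawn = 0
    batch = max(1024, n_total)
    while n_case_kept < config.n_cases or n_ctrl_kept < config.n_controls:
        if drawn >= draw_cap:
            raise SimulationError(
                f"case/control quotas not met after {drawn} draws "
                f"({n_case_kept}/{config.n_cases} cases, "
                f"{n_ctrl_kept}/{config.n_controls} controls); "
                "check baseline_odds and clade odds ratios"
            )
        b = min(batch, draw_cap - drawn)
        member = _draw_lineages(config.clades, b, rng)
        p_case = _case_probability(config.clades, member, config.baseline_odds)
        is_case = rng.random(b) < p_case
        drawn += b
        for i in range(b):
            if is_case[i] and n_case_kept < config.n_cases:
                kept_member.append(member[i])
                kept_case.append(True)
                n_case_kept += 1
            elif not is_case[i] and n_ctrl_kept < config.n_controls:
                kept_member.append(member[i])
                kept_case.append(False)
                n_ctrl_kept += 1

    member = np.array(kept_member, dtype=bool)
    is_case = np.array(kept_case, dtype=bool)

    # genotype matrix in position order
    n = n_total
    m = len(layout)
    alleles = np.zeros((n, m), dtype=np.int8)
    for j, (pos, ref, alt, ci, maf) in enumerate(layout):
        if ci >= 0:
            alleles[:, j] = np.where(member[:, ci], ALT, REF)
        else:
            alleles[:, j] = np.where(rng.random(n) < maf, ALT, REF)

    phenotype = np.where(is_case, CASE, CONTROL)
    snp_meta = pd.DataFrame(
        {
            "id": [f"mt{pos}" for pos, *_ in layout],
            "position": [pos for pos, *_ in layout],
            "ref_allele": [ref for _, ref, *_ in layout],
            "alt_allele": [alt for _, _, alt, *_ in layout],
        }
    )
    g = GenotypeTable(
        sample_ids=[f"S{i:05d}" for i in range(n)],
        phenotype=phenotype,
        alleles=alleles,
        snp_meta=snp_meta,
        platform=config.platform,
    )
    return apply_missingness(g, config)


def apply_missingness(
    g: GenotypeTable, config: SimulationConfig, return_counts: bool = False
):
    """Mask genotype calls and phenotypes at the configured rates.

    Each call is set missing independently with probability
    ``1 - (1 - snp_missing_rate) * (1 - individual_missing_rate)``;
    phenotypes are set to -9 with probability
    ``phenotype_missing_rate``. Deterministic given ``config.seed``
    (an independent stream from the cohort draw).
    """
    out = g.copy()
    n_geno_masked = 0
    n_pheno_masked = 0
    call_rate = 1.0 - (1.0 - config.snp_missing_rate) * (
        1.0 - config.individual_missing_rate
    )
    if call_rate > 0 or config.phenotype_missing_rate > 0:
        rng = np.random.default_rng([config.seed, 0x5EED])
        if call_rate > 0:
            mask = rng.random(out.alleles.shape) < call_rate
            n_geno_masked = int(mask.sum())
            out.alleles[mask] = MISSING_ALLELE
        if config.phenotype_missing_rate > 0:
            pmask = rng.random(out.n_samples) < config.phenotype_missing_rate
            n_pheno_masked = int(pmask.sum())
            out.phenotype[pmask] = MISSING_PHENOTYPE
    if return_counts:
        return out, {"genotypes_masked": n_geno_masked, "phenotypes_masked": n_pheno_masked}
    return out


# ---------------------------------------------------------------------------
# sequence panel simulation
# ---------------------------------------------------------------------------


def simulate_panel(
    n_sequences: int,
    clades,
    length: int,
    seed: int,
    truncated_fraction: float = 0.0,
    non_european_fraction: float = 0.0,
    private_mutation_rate: float = 0.0,
    reference: str | None = None,
):
    """Generate an aligned mtDNA-like sequence panel with known structure.

    Sequences derive from a reference string by applying clade-defining
    substitutions (clades drawn by frequency as in the cohort model),
    plus a Poisson(``private_mutation_rate``) number of private
    substitutions per sequence at random positions, giving the panel a
    rare-variant tail. A ``truncated_fraction`` of sequences is
    shortened below 16,500 bp to exercise the panel length filter, and
    a ``non_european_fraction`` is given non-European alleles at the
    diagnostic triplet positions.
    """
    from mtassoc.panel import SequencePanel

    if length < 1:
        raise ValueError("length must be >= 1")
    _validate_clades(clades)
    for c in clades:
        for pos, _ in c.defining_variants:
            if pos > length:
                raise ValueError(
                    f"clade {c.name}: position {pos} beyond sequence length {length}"
                )
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = "".join(reference_base(p) for p in range(1, length + 1))
    elif len(reference) != length:
        raise ValueError("reference length mismatch")

    member = _draw_lineages(list(clades), n_sequences, rng)
    ref_arr = np.frombuffer(reference.encode(), dtype="S1")
    records = []
    is_non_eur = rng.random(n_sequences) < non_european_fraction
    is_trunc = rng.random(n_sequences) < truncated_fraction
    for i in range(n_sequences):
        seq = ref_arr.copy()
        for ci, c in enumerate(clades):
            if member[i, ci]:
                for pos, alt in c.defining_variants:
                    seq[pos - 1] = alt.upper().encode()
        if private_mutation_rate > 0:
            diag = set(EUROPEAN_DIAGNOSTIC_ALLELES)
            for pos in rng.integers(1, length + 1, size=rng.poisson(private_mutation_rate)):
                if int(pos) in diag:
                    continue
                cur = seq[pos - 1].decode()
                seq[pos - 1] = BASES[(BASES.index(cur) + 1) % 4].encode()
        if is_non_eur[i]:
            for pos, eur in EUROPEAN_DIAGNOSTIC_ALLELES.items():
                if pos <= length:
                    alt = BASES[(BASES.index(eur) + 1) % 4]
                    seq[pos - 1] = alt.encode()
        s = seq.tobytes().decode()
        if is_trunc[i]:
            cut = int(rng.integers(length // 2, min(16500, length)))
            s = s[:cut]
        records.append((f"seq{i:05d}", s))
    return SequencePanel(records=records, reference=reference)


# ---------------------------------------------------------------------------
# PLINK text output
# ---------------------------------------------------------------------------


def write_plink(g: GenotypeTable, path_prefix) -> None:
    """Write a PED/MAP pair (PLINK text format).

    mtDNA is written as chromosome code 26; haploid calls are emitted as
    homozygous diploid genotypes; missing calls as "0 0"; missing
    phenotypes as -9. Round-trips losslessly through
    :func:`mtassoc.qc.load_plink` when the table's allele map is passed.
    """
    prefix = str(path_prefix)
    meta = g.snp_meta
    with open(prefix + ".map", "w") as fh:
        for _, row in meta.iterrows():
            fh.write(f"26\t{row['id']}\t0\t{row['position']}\n")
    ref = meta["ref_allele"].to_numpy()
    alt = meta["alt_allele"].to_numpy()
    with open(prefix + ".ped", "w") as fh:
        for i, sid in enumerate(g.sample_ids):
            calls = g.alleles[i]
            bases = np.where(calls == ALT, alt, ref)
            bases = np.where(calls == MISSING_ALLELE, "0", bases)
            geno = " ".join(f"{b} {b}" for b in bases)
            pheno = int(g.phenotype[i])
            fh.write(f"{sid} {sid} 0 0 0 {pheno} {geno}\n")


# ---------------------------------------------------------------------------
# canonical study configurations
# ---------------------------------------------------------------------------


def default_background_clades():
    """Neutral European-style clade structure: H, J, U with nested U5.

    Defining variants sit at the classic marker positions (m.7028,
    m.4216, m.12308, m.3197); all odds ratios are 1.
    """
    return [
        CladeDef("H", None, frozenset({(7028, "T")}), 0.45, 1.0),
        CladeDef("J", None, frozenset({(4216, "C")}), 0.10, 1.0),
        CladeDef("U", None, frozenset({(12308, "G")}), 0.20, 1.0),
        CladeDef("U5", "U", frozenset({(3197, "C")}), 0.40, 1.0),
    ]


PLANTED_CLADE_POSITION = 15218


def null_config(n_cases: int, n_controls: int, seed: int) -> SimulationConfig:
    """Cohort with haplogroup structure but no disease effect (all OR = 1);
    complete data (no missingness); 12 SNPs in total."""
    return SimulationConfig(
        clades=default_background_clades(),
        n_cases=n_cases,
        n_controls=n_controls,
        n_neutral_snps=8,
        baseline_odds=0.05,
        seed=seed,
    )


def planted_config(
    n_cases: int,
    n_controls: int,
    seed: int,
    clade_frequency: float = 0.15,
    odds_ratio: float = 3.0,
) -> SimulationConfig:
    """Null background plus one planted risk clade (defining variant at
    m.15218); 12 SNPs in total."""
    clades = default_background_clades() + [
        CladeDef(
            "RISK",
            None,
            frozenset({(PLANTED_CLADE_POSITION, "G")}),
            clade_frequency,
            odds_ratio,
        )
    ]
    return SimulationConfig(
        clades=clades,
        n_cases=n_cases,
        n_controls=n_controls,
        n_neutral_snps=7,
        baseline_odds=0.05,
        seed=seed,
    )
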
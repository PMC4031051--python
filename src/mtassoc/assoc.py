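"""Haploid single-variant association, risk-direction tallying, and
case-control power for a haploid locus.

Each individual contributes one allele (mtDNA is effectively haploid),
so the allelic test is the Pearson chi-square of the per-individual
allele x case/control 2x2 table — deliberately not the diploid
allele-doubling of general-purpose GWAS tools. Odds ratios use the
Haldane-Anscombe 0.5 correction only when a cell is zero.

The power computation follows the classic case-control genetic power
model: disease prevalence K and a per-allele relative risk R fix the
carrier/non-carrier penetrances, which give the expected risk-allele
frequencies in cases and controls; power is then the upper tail of a
noncentral chi-square (1 df) at the central 1 - alpha quantile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from mtassoc.genotypes import ALT, REF, GenotypeTable
from mtassoc.stats2x2 import chi2_2x2, chi2_2x2_p


@dataclass
class AssocResult:
    """Single-SNP haploid association result."""

    snp_id: str
    position: int
    counts: tuple  # (cases_alt, cases_ref, controls_alt, controls_ref)
    chi2: float
    p: float
    odds_ratio: float
    direction: str  # "risk" | "protective" | "none"
    significant: bool = False
    monomorphic: bool = False
    haldane_corrected: bool = False


def allelic_test(g: GenotypeTable, alpha: float = 0.05) -> list:
    """Per-SNP haploid allelic chi-square over a case-control table.

    Individuals with missing phenotypes are ignored; per SNP only
    non-missing calls count. Monomorphic SNPs are emitted with a null
    statistic (chi2 = 0, p = 1, OR = NaN) and flagged. SNPs with
    p < ``alpha`` are flagged significant.
    """
    case = g.is_case
    control = g.is_control
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError("allelic test needs both cases and controls")
    out = []
    is_alt = g.alleles == ALT
    is_ref = g.alleles == REF
    ca_alt = is_alt[case].sum(axis=0)
    ca_ref = is_ref[case].sum(axis=0)
    co_alt = is_alt[control].sum(axis=0)
    co_ref = is_ref[control].sum(axis=0)
    for j in range(g.n_snps):
        a, b, c, d = int(ca_alt[j]), int(ca_ref[j]), int(co_alt[j]), int(co_ref[j])
        meta = g.snp_meta.iloc[j]
        monomorphic = (a + c == 0) or (b + d == 0)
        if monomorphic:
            out.append(
                AssocResult(
                    snp_id=meta["id"],
                    position=int(meta["position"]),
                    counts=(a, b, c, d),
                    chi2=0.0,
                    p=1.0,
                    odds_ratio=float("nan"),
                    direction="none",
                    monomorphic=True,
                )
            )
            continue
        stat, p = chi2_2x2_p(a, b, c, d)
        haldane = 0 in (a, b, c, d)
        if haldane:
            aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            aa, bb, cc, dd = a, b, c, d
        odds_ratio = (aa * dd) / (bb * cc)
        direction = (
            "risk" if odds_ratio > 1 else ("protective" if odds_ratio < 1 else "none")
        )
        out.append(
            AssocResult(
                snp_id=meta["id"],
                position=int(meta["position"]),
                counts=(a, b, c, d),
                chi2=float(stat),
                p=float(p),
                odds_ratio=float(odds_ratio),
                direction=direction,
                significant=bool(p < alpha),
                haldane_corrected=haldane,
            )
        )
    return out


def assoc_table(results: list):
    """Association results as a TSV-ready DataFrame (id, position,
    case/control MAF, chi2, P, OR, direction)."""
    import pandas as pd

    rows = []
    for r in results:
        a, b, c, d = r.counts
        rows.append(
            {
                "snp_id": r.snp_id,
                "position": r.position,
                "case_maf": min(a / (a + b), b / (a + b)) if a + b else float("nan"),
                "control_maf": min(c / (c + d), d / (c + d)) if c + d else float("nan"),
                "chi2": r.chi2,
                "p": r.p,
                "odds_ratio": r.odds_ratio,
                "direction": r.direction,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)


def bonferroni_alpha(n_tests: int, family_alpha: float = 0.05) -> float:
    """Per-test significance level controlling the family-wise error."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests


def risk_direction_tally(results: list, p_threshold: float = 0.05):
    """Count risk vs protective alleles among significant SNPs.

    Among results with ``p < p_threshold`` and a finite, non-unit odds
    ratio, counts OR > 1 (risk) vs OR < 1 (protective) and tests the
    imbalance against a fair coin with a two-sided exact binomial test.
    Returns ``(n_risk, n_protective, binomial_p)``; the p-value is None
    when nothing is significant.
    """
    sig = [
        r
        for r in results
        if r.p < p_threshold and math.isfinite(r.odds_ratio) and r.odds_ratio != 1.0
    ]
    n_risk = sum(1 for r in sig if r.odds_ratio > 1)
    n_protective = len(sig) - n_risk
    if not sig:
        return 0, 0, None
    p = stats.binomtest(n_risk, n_risk + n_protective, 0.5).pvalue
    return n_risk, n_protective, float(p)


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------


@dataclass
class PowerParams:
    """Inputs of the haploid case-control power computation.

    ``prevalence`` is the population disease prevalence K;
    ``risk_allele_freq`` the population frequency p of the risk allele;
    ``effect_size`` the per-allele relative risk R (carrier penetrance
    over non-carrier penetrance).
    """

    prevalence: float
    risk_allele_freq: float
    effect_size: float
    alpha: float
    n_cases: int
    n_controls: int

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if not 0 < self.risk_allele_freq <= 0.5:
            raise ValueError("risk_allele_freq must lie in (0, 0.5]")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("sample sizes must be >= 1")


def penetrances(params: PowerParams) -> tuple:
    """Solve K = p K1 + (1-p) K0 with K1/K0 = R for (K0, K1)."""
    p, K, R = params.risk_allele_freq, params.prevalence, params.effect_size
    K0 = K / (p * R + (1 - p))
    K1 = R * K0
    if K1 > 1:
        raise ValueError(
            f"implied carrier penetrance {K1:.3f} > 1: prevalence and "
            "effect size are inconsistent"
        )
    return K0, K1


def expected_allele_freqs(params: PowerParams) -> tuple:
    """(case, control) risk-allele frequencies under the penetrance model."""
    p, K = params.risk_allele_freq, params.prevalence
    K0, K1 = penetrances(params)
    p_case = p * K1 / K
    p_control = p * (1 - K1) / (1 - K)
    return p_case, p_control


def power_calc(params: PowerParams) -> float:
    """Analytic power of the haploid allelic test.

    Noncentrality: lambda = (p_case - p_control)^2 /
    [pbar (1 - pbar) (1/n_cases + 1/n_controls)] with pbar the
    sample-size-weighted mean frequency; power is the upper tail of
    the noncentral chi-square (1 df, lambda) beyond the central
    1 - alpha quantile. With R = 1 this returns alpha exactly.
    """
    p_case, p_control = expected_allele_freqs(params)
    n1, n2 = params.n_cases, params.n_controls
    pbar = (n1 * p_case + n2 * p_control) / (n1 + n2)
    lam = (p_case - p_control) ** 2 / (pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    crit = stats.chi2.ppf(1 - params.alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=lam))


def power_simulation(params: PowerParams, n_reps: int = 10_000, seed: int = 0) -> float:
    """Empirical power by retrospective simulation.

    Draws case and control allele counts binomially at the model's
    expected case/control frequencies, applies the haploid allelic
    chi-square, and reports the rejection fraction at ``alpha``.
    """
    p_case, p_control = expected_allele_freqs(params)
    rng = np.random.default_rng(seed)
    a = rng.binomial(params.n_cases, p_case, size=n_reps)
    c = rng.binomial(params.n_controls, p_control, size=n_reps)
    stat = chi2_2x2(a, params.n_cases - a, c, params.n_controls - c)
    crit = stats.chi2.ppf(1 - params.alpha, df=1)
    return float((stat > crit).mean())
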
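# Methods

## The lexical haplotype tree

The tree test targets a specific feature of mtDNA: absence of
intermolecular recombination means variants co-segregate along
maternal lineages, so disease signal carried by a clade is spread over
all of the clade's defining variants and diluted in per-SNP tests. The
lexical tree recovers the clade structure from the genotypes alone,
without reference to haplogroup nomenclature.

Construction: all individuals start at the root; SNPs are taken in
decreasing minor-allele-frequency order (ties broken by ascending rCRS
position, for determinism); at each SNP every current leaf is split
into a reference-allele ("wild-type") left child and a derived-allele
right child. A split is made only when both classes are non-empty —
otherwise the leaf's haplotype prefix extends without creating a node.
Consequences: leaves are in bijection with distinct haplotypes,
single-child chains never exist (each scored node is a distinct
partition; nothing is double-counted in the tree statistic), and a
monomorphic SNP contributes no node. The tree requires complete data;
the lexical QC cascade guarantees this.

Node score: Pearson chi-square (1 df, no continuity correction) of the
node-vs-rest × case/control 2×2 table. The statistic on 2×2 tables is
defined as 0 whenever a margin is zero, which keeps degenerate nodes
from generating NaNs. The choice of chi-square is a design decision —
any statistic on the node 2×2 table would fit this slot, and
`node_statistics` is the single place to swap one in; chi-square is
the natural match for the haploid allelic test used elsewhere in the
pipeline.

Whole-tree statistic: the sum of the five largest node statistics over
nodes that are mutually neither ancestors nor descendants, selected
greedily — visit nodes in decreasing-statistic order (ties: shallower
depth, then node id) and accept a node only if it is incomparable with
everything accepted so far. The greedy rule is the construction
implemented deliberately, not an optimisation; an exact maximum-weight
antichain (`max_weight_antichain`, exponential, for small trees) is
available for sensitivity analysis, and the greedy value can only be
≤ the exact optimum (tested).

Permutation null: case/control labels are permuted uniformly with tree
topology and memberships fixed; all node counts are recomputed per
permutation (vectorised as a membership-matrix product). The p-value
uses the add-one estimator (1 + #{S_perm ≥ S_obs})/(1 + n_perm), which
never reports 0 and is valid for finite permutation counts; its floor
is 1/(n_perm + 1). With every node balanced (S_obs = 0) every
permutation ties, so p = 1 by construction.

Caveat on exchangeability: the rare-haplotype QC stage consults the
observed control labels (haplotypes absent from controls are removed),
so the label-permutation null runs on a table that was filtered using
the labels. The effect is small at the default threshold — the
calibration runs below show nominal size — but it is the reason the
calibration harness simulates complete-data cohorts and permutes
without refiltering.

## QC cascades

Two cascades, both returning an ordered removal ledger whose row sums
reconcile exactly with the output table (tested).

Primary cascade (feeding single-variant association), in order:
missing phenotypes (code -9); SNPs with missingness > 0.1; individuals
with missingness > 0.1; non-European lineages; SNPs with MAF < 1e-5.
The two 0.1 thresholds follow standard array-QC practice; the source
description of these cutoffs is garbled in places, and "remove SNPs
with missingness above 0.1, then individuals above 0.1" is the reading
adopted here.

Lexical cascade, strictly in order: (1) SNPs with call rate < 0.95 or
MAF < 0.005; (2) the 2% of individuals with the most missing sites;
(3) the bottom 50% of SNPs with the most missing samples; (4)
individuals with any remaining missing call; (5) individuals whose
complete haplotype is carried fewer than 5 times or by no control.
Decisions inside this cascade:

- Stage 2 removes at most the number of individuals that actually have
  missing sites, so complete data lose nobody; stage 3 cuts
  ⌊m/2⌋ SNPs unconditionally (ranking by missing count descending).
  Ties in both rank cuts are broken deterministically (sample input
  order; ascending rCRS position).
- Individuals with missing phenotypes are pruned before stage 1: the
  rare-haplotype rule needs every retained individual classed as case
  or control.
- "Call rate" denominators are taken post-phenotype-pruning; whether
  the original pipeline used pre- or post-pruning denominators is not
  determinable, and the difference only matters when phenotype
  missingness is correlated with genotype missingness.
- The European filter keeps an individual only if it carries the
  macrohaplogroup-N diagnostic allele at every *testable* position of
  the triplet m.8701A, m.8540T, m.10873T; a missing call at a
  diagnostic position is treated as compatible (retained), and if none
  of the three positions is genotyped the filter is a warned no-op.
  Whether the triplet defines the kept or the removed class is
  genuinely ambiguous in the source description; keep-if-all-present
  (the N-lineage pattern) is implemented and flagged to the user.

Control merging matches SNPs on rCRS position, harmonises swapped
ref/alt polarity, removes SNPs whose haploid allele counts differ
between the two control sets at chi-square P < 0.05, and concatenates.
Differential missingness tests each SNP's missing/called × case/control
table and removes SNPs at P < 1e-4; a SNP with no missing calls has
statistic 0 by the margin rule and is kept.

## Haploid association and power

Each individual contributes one allele — mtDNA is haploid — so the
allelic test is the chi-square of per-individual allele counts, not
the diploid allele-doubling of general-purpose tools (a deliberate,
documented divergence). Odds ratios apply the Haldane–Anscombe +0.5
correction only when a cell is zero. Monomorphic SNPs are emitted with
a null statistic and a flag rather than dropped silently. The
risk-direction tally counts OR > 1 vs OR < 1 among significant SNPs
and tests the imbalance with a two-sided exact binomial test; on the
published tally of 61 risk vs 38 protective this gives p ≈ 0.027, not
the "< 0.001" printed alongside those counts — no standard test on
those counts produces that bound, so the package reports the exact
binomial value and notes the discrepancy rather than matching it.

Power: prevalence K and per-allele relative risk R fix the penetrances
through K = p·K1 + (1−p)·K0, K1 = R·K0 (rejecting K1 > 1 as
inconsistent); expected case/control allele frequencies follow by
Bayes; the noncentrality is λ = (p_case − p_control)² /
[p̄(1−p̄)(1/n_cases + 1/n_controls)] with p̄ the size-weighted mean,
and power is the upper tail of the noncentral chi-square (1 df) beyond
the central 1−α quantile. R = 1 returns α exactly; the computation is
verified against a 10⁴-replicate retrospective simulation (agreement
within 0.02 at the K = 0.01, p = 0.2, R = 2, 500+500 fixture). Note
that at a risk-allele frequency of 0.01 and R = 1.2 this model yields
only percent-level power at realistic cohort sizes under any
Bonferroni α in the 13–126-test range; published >80% claims at those
nominal inputs are not reproducible from this (or any allelic
noncentral-chi-square) computation, and the package makes no attempt
to match them.

## Panel curation

Sequences must arrive pre-aligned to the reference length (alignment
is a routine external step, out of scope); the simulator produces such
panels directly. Filters run in order — carriers of listed pathogenic
variants, then non-European lineages by the same diagnostic-triplet
rule as the genotype QC, then sequences shorter than 16,500 bp — so a
sequence failing several rules is counted once, in the first category.
Filtering is idempotent and the ledger conserves the input count
(tested). Variant calling is positional: per site the alternate allele
is the most frequent non-reference base, sites with two or more
distinct non-reference bases are flagged multi-allelic and excluded
from the biallelic table, N/gap are missing, and MAF is computed over
non-missing calls. The MAF spectrum is the fraction of variants
strictly above a threshold (default 0.01), the quantity that bounds
what an imputation panel restricted to common variants can capture.

## The synthetic-data generator

The study this package operationalises analysed access-controlled
genotype cohorts; no generative model exists to copy, so the simulator
is a stand-in built to exercise the statistical structure the analysis
assumes, and every choice below is the package's own:

- **Clades**: a tree of `CladeDef`s, each with defining variants,
  a frequency conditional on its parent, and a disease odds ratio.
  The default background emulates four European-style lineages — H
  (0.45), J (0.10), U (0.20) with nested U5 (0.40 of U) — with
  defining variants at the classic marker positions m.7028, m.4216,
  m.12308, m.3197 and all odds ratios 1. The planted-effect
  configuration adds one risk clade (frequency 0.15, OR 3, marker at
  m.15218).
- **Disease model**: logistic on clade membership; an individual's
  case probability is sigmoid(log(baseline_odds) + Σ log OR over its
  lineage). Sampling is retrospective: draws continue until the case
  and control quotas are met (capped at 1000× the total, then aborts
  with a diagnostic), matching case-control ascertainment. For a rare
  disease the case-carrier frequency of a planted clade converges to
  fR/(1−f+fR), which the tests verify within 3 SE at 10⁴ cases.
- **Neutral SNPs** at distinct random positions with MAFs uniform on
  (0.01, 0.45); default cohorts carry 12 SNPs in total, the scale of
  the per-platform mtDNA content of genotyping arrays.
- **Missingness**: each call is masked independently at a combined
  per-SNP/per-individual rate; phenotypes are set to -9 at their own
  rate. Calibration and planted-effect runs use complete data so the
  tree machinery is measured in isolation from QC.
- **Sequence panels**: clade substitutions applied to a fixed
  pseudo-reference (European diagnostic alleles at the triplet
  positions, deterministic bases elsewhere), optional private
  mutations (Poisson per sequence) for a rare-variant tail, optional
  truncation and non-European fractions to exercise the filters.

What the simulator does **not** reproduce: coalescent genealogies,
recurrent/back mutation, linkage to nuclear background, platform
intensity artefacts, or population stratification beyond the planted
clade structure. Passing calibration on these cohorts therefore shows
the test has correct size and power *given* haplogroup-structured
binary haplotypes — it does not validate robustness to artefacts the
simulator cannot produce.

## Operating characteristics (computed by the tests and
`scripts/acceptance.py`)

- Size: 500 null cohorts (200+200, 12 SNPs) × 999 permutations;
  empirical rejection at α = 0.05 must fall in the exact-binomial 99%
  interval [0.027, 0.079] and the p-values must pass a KS uniformity
  check at the 1% level.
- Power/recovery: 200 planted-clade cohorts (500+500, f = 0.15,
  OR = 3) × 999 permutations; the test must reject and select a node
  lying inside the planted lineage in ≥ 75% of replicates (pilot runs
  gave ~85–92%; the 75% bar was fixed from those pilots).
- Oracle equivalences: the closed-form 2×2 chi-square against an
  independent library implementation to 1e-10 relative on 1,000 random
  tables; greedy antichain selection against an independently coded
  reference on 200 random trees of ≤ 12 nodes; chi-square/Fisher
  p-value ordering (Spearman 1.0) on 50 tables sharing all margins —
  margins are pinned in that fixture because across free margins the
  two tests' orderings can legitimately invert.
- Problem sizes throughout (cohort sizes, permutation counts,
  replicate counts) are chosen so the full suite completes in a few
  minutes on a single core while keeping Monte-Carlo error well inside
  the asserted tolerances.

## Known limitations

- The permutation loop is pure numpy/Python; 10⁶-permutation runs on
  large cohorts (the scale used for the published per-cohort
  p-values) take hours, not minutes. The estimator and seeds make
  longer runs a parameter change, not a code change.
- Only biallelic SNPs are supported; multi-allelic mtDNA sites must be
  excluded upstream (the panel module flags them).
- The European-lineage filter is a coarse three-site rule, not a
  haplogroup caller; fine-grained lineage assignment is out of scope.
- PLINK binary (BED/BIM/FAM) input is not supported; text PED/MAP
  only.
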
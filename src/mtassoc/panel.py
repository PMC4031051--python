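"""Reference-panel curation for aligned mtDNA sequence sets.

Mirrors the sequence-filtering rules of an imputation-panel build:
sequences carrying listed pathogenic variants are removed first, then
non-European lineages (the m.8701A/m.8540T/m.10873T diagnostic-triplet
rule, shared with the genotype QC), then truncated sequences shorter
than 16,500 bp. Variant calling is positional comparison against the
reference (sequences must be pre-aligned to reference length; the
alignment step itself is delegated to standard tools and out of scope
here). The MAF spectrum summarises what fraction of panel variation an
imputation built on common variants would capture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mtassoc.genotypes import EUROPEAN_DIAGNOSTIC_ALLELES

VALID_BASES = frozenset("ACGTN-")
MISSING_BASES = frozenset("N-")


@dataclass
class SequencePanel:
    """Aligned sequence set plus reference and pathogenic exclusion list."""

    records: list  # (id, sequence) pairs, uppercase
    reference: str
    exclusion_variants: set = field(default_factory=set)  # {(position, allele)}

    def __post_init__(self):
        self.reference = self.reference.upper()
        self.records = [(rid, seq.upper()) for rid, seq in self.records]
        for rid, seq in self.records:
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"sequence {rid}: invalid bases {sorted(bad)}")
        self.exclusion_variants = {
            (int(pos), allele.upper()) for pos, allele in self.exclusion_variants
        }

    @property
    def n_sequences(self) -> int:
        return len(self.records)


def read_fasta_panel(path, reference: str, exclusion_variants=()) -> SequencePanel:
    """Load an aligned FASTA into a :class:`SequencePanel`."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    return SequencePanel(
        records=records, reference=reference, exclusion_variants=set(exclusion_variants)
    )


def write_fasta_panel(panel: SequencePanel, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in panel.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_exclusion_list(path) -> set:
    """Two-column TSV (position, allele) -> exclusion-variant set."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return {(int(row[0]), str(row[1]).upper()) for _, row in df.iterrows()}


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def _carries(seq: str, position: int, allele: str) -> bool:
    return len(seq) >= position and seq[position - 1] == allele


def _is_non_european(seq: str) -> bool:
    """Fails the diagnostic-triplet rule: any testable diagnostic
    position carries a non-European base (N/- are not diagnostic)."""
    for pos, eur in EUROPEAN_DIAGNOSTIC_ALLELES.items():
        if len(seq) >= pos:
            base = seq[pos - 1]
            if base not in MISSING_BASES and base != eur:
                return True
    return False


def filter_sequences(
    panel: SequencePanel, min_length: int = 16500
) -> tuple[SequencePanel, dict]:
    """Apply the panel curation rules in order.

    Removal order: (1) sequences carrying any listed pathogenic
    variant; (2) non-European lineages by the diagnostic-triplet rule;
    (3) truncated sequences shorter than ``min_length``. Returns the
    retained panel and a ledger of per-category removal counts.
    """
    if not panel.reference:
        raise ValueError("panel reference must be set before filtering")
    ledger = {"pathogenic": 0, "non_european": 0, "truncated": 0, "retained": 0}
    kept = []
    for rid, seq in panel.records:
        if any(_carries(seq, pos, allele) for pos, allele in panel.exclusion_variants):
            ledger["pathogenic"] += 1
        elif _is_non_european(seq):
            ledger["non_european"] += 1
        elif len(seq) < min_length:
            ledger["truncated"] += 1
        else:
            kept.append((rid, seq))
    ledger["retained"] = len(kept)
    return (
        SequencePanel(
            records=kept,
            reference=panel.reference,
            exclusion_variants=panel.exclusion_variants,
        ),
        ledger,
    )


# ---------------------------------------------------------------------------
# variant calling and the MAF spectrum
# ---------------------------------------------------------------------------


def call_variants(panel: SequencePanel) -> pd.DataFrame:
    """Biallelic variant table by positional comparison to the reference.

    Every sequence must equal the reference length (run
    :func:`filter_sequences` first). Per position the alternate allele
    is the most frequent non-reference base; positions with more than
    two observed bases are flagged multi-allelic and excluded from the
    biallelic table (listed in ``df.attrs['multiallelic']``). N and
    gap characters are treated as missing; MAF is computed over
    non-missing calls.
    """
    L = len(panel.reference)
    for rid, seq in panel.records:
        if len(seq) != L:
            raise ValueError(f"sequence {rid}: length {len(seq)} != reference {L}")
    if not panel.records:
        df = pd.DataFrame(
            columns=["position", "ref_allele", "alt_allele", "alt_count", "maf"]
        )
        df.attrs["multiallelic"] = []
        return df

    mat = np.frombuffer(
        "".join(seq for _, seq in panel.records).encode(), dtype="S1"
    ).reshape(panel.n_sequences, L)
    ref = np.frombuffer(panel.reference.encode(), dtype="S1")
    rows = []
    multiallelic = []
    base_codes = [b"A", b"C", b"G", b"T"]
    counts = np.stack([(mat == b).sum(axis=0) for b in base_codes])  # (4, L)
    called = counts.sum(axis=0)
    ref_idx = np.array(
        [base_codes.index(b) if b in base_codes else -1 for b in ref]
    )
    # only positions where some called base differs from the reference
    nonref_total = np.array(
        [called[j] - (counts[ref_idx[j], j] if ref_idx[j] >= 0 else 0) for j in range(L)]
    )
    for j in np.flatnonzero(nonref_total > 0):
        nonref = sorted(
            (
                (int(counts[k, j]), base_codes[k].decode())
                for k in range(4)
                if k != ref_idx[j] and counts[k, j] > 0
            ),
            reverse=True,
        )
        if len(nonref) > 1:
            multiallelic.append(int(j) + 1)
            continue
        alt_count, alt = nonref[0]
        n_called = int(called[j])
        f = alt_count / n_called
        rows.append(
            {
                "position": int(j) + 1,
                "ref_allele": ref[j].decode(),
                "alt_allele": alt,
                "alt_count": int(alt_count),
                "maf": float(min(f, 1 - f)),
            }
        )
    df = pd.DataFrame(rows, columns=["position", "ref_allele", "alt_allele", "alt_count", "maf"])
    df.attrs["multiallelic"] = multiallelic
    return df


def maf_spectrum(variant_table: pd.DataFrame, threshold: float = 0.01) -> float:
    """Fraction of variants with MAF strictly above ``threshold``."""
    if len(variant_table) == 0:
        raise ValueError("variant table is empty")
    return float((variant_table["maf"] > threshold).mean())


def maf_histogram(variant_table: pd.DataFrame, bins: int = 50) -> pd.DataFrame:
    """Binned MAF spectrum, TSV-ready (bin_low, bin_high, count)."""
    counts, edges = np.histogram(variant_table["maf"], bins=bins, range=(0, 0.5))
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )
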
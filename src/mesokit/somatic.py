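"""Per-sample variant-derived features.

TERT-promoter hotspot calling from base pileups, tumour mutation burden,
neoantigen and expressed-mutation filtering, and the telomere-motif
content ratio.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "TERT_PROMOTER_SITES",
    "PileupCounts",
    "TertCall",
    "NeoantigenRecord",
    "call_tert_promoter",
    "mutation_burden",
    "filter_neoantigens",
    "expressed_mutations",
    "count_motif_runs",
    "telomere_motif_ratio",
    "read_pileup_tsv",
    "read_neoantigen_tsv",
]

# Assessed TERT promoter hotspots (GRCh37 chr5), with the expected
# reference and alternate base of each recurrent substitution.  Only the
# listed alternate base counts toward the mutant allele fraction.
TERT_PROMOTER_SITES: dict[tuple[str, int], tuple[str, str]] = {
    ("chr5", 1_295_161): ("T", "G"),   # c.-57  T>G
    ("chr5", 1_295_228): ("G", "A"),   # c.-124 G>A
    ("chr5", 1_295_242): ("G", "A"),   # c.-138 G>A
    ("chr5", 1_295_243): ("G", "A"),   # c.-139 G>A
    ("chr5", 1_295_250): ("G", "A"),   # c.-146 G>A
}

_BASES = ("A", "C", "G", "T")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class PileupCounts:
    """Per-position base counts from a pileup."""

    chrom: str
    pos: int
    ref_base: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.ref_base not in _BASES:
            raise ValueError(f"invalid reference base {self.ref_base!r}")
        for b in _BASES:
            if self.counts.get(b, 0) < 0:
                raise ValueError("pileup counts must be non-negative")

    @property
    def depth(self) -> int:
        return sum(self.counts.get(b, 0) for b in _BASES)


@dataclass(frozen=True)
class TertCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float | None          # None when the position had zero depth
    called: bool
    assessable: bool


def call_tert_promoter(
    pileups, maf_min: float = 0.10, sites=None
) -> list[TertCall]:
    """Call hotspot promoter mutations from pileups.

    A site is called when the count of the expected alternate base divided
    by total depth strictly exceeds ``maf_min``.  Pileups at positions not
    in the assessed site list are ignored with a warning; a zero-depth
    pileup at an assessed site is reported as unassessable rather than
    wild-type.
    """
    sites = TERT_PROMOTER_SITES if sites is None else sites
    calls: list[TertCall] = []
    for p in pileups:
        key = (p.chrom, p.pos)
        if key not in sites:
            warnings.warn(
                f"pileup at {p.chrom}:{p.pos} is not an assessed promoter "
                "position; ignored",
                stacklevel=2,
            )
            continue
        ref, alt = sites[key]
        depth = p.depth
        if depth == 0:
            calls.append(TertCall(p.chrom, p.pos, ref, alt, None, False, False))
            continue
        maf = p.counts.get(alt, 0) / depth
        calls.append(TertCall(p.chrom, p.pos, ref, alt, maf, maf > maf_min, True))
    return calls


def mutation_burden(
    snv_count: int,
    dnp_count: int = 0,
    tnp_count: int = 0,
    indel_count: int = 0,
    genome_mb: float = 2800.0,
) -> float:
    """Somatic variant load per megabase (SNV + DNP + TNP + indel)."""
    counts = (snv_count, dnp_count, tnp_count, indel_count)
    if any(c < 0 for c in counts):
        raise ValueError("variant counts must be non-negative")
    if genome_mb <= 0:
        raise ValueError("genome_mb must be positive")
    return sum(counts) / genome_mb


@dataclass(frozen=True)
class NeoantigenRecord:
    """A predicted epitope with binding affinity and RNA read support."""

    mutation_id: str
    peptide: str
    ic50_nM: float
    rna_ref_reads: int
    rna_alt_reads: int

    def __post_init__(self) -> None:
        if self.rna_ref_reads < 0 or self.rna_alt_reads < 0:
            raise ValueError("RNA read counts must be non-negative")


def filter_neoantigens(records, ic50_max: float = 500.0) -> list[NeoantigenRecord]:
    """Retain epitopes with binding IC50 <= ``ic50_max`` nM (inclusive).
    Records with non-positive IC50 are rejected with a warning."""
    kept = []
    for r in records:
        if r.ic50_nM <= 0:
            warnings.warn(
                f"record {r.mutation_id}: non-positive IC50 {r.ic50_nM}; dropped",
                stacklevel=2,
            )
            continue
        if r.ic50_nM <= ic50_max:
            kept.append(r)
    return kept


def expressed_mutations(records, min_alt_reads: int = 10) -> list[NeoantigenRecord]:
    """Retain records with at least ``min_alt_reads`` RNA reads supporting
    the mutant allele (inclusive)."""
    return [r for r in records if r.rna_alt_reads >= min_alt_reads]


def count_motif_runs(seq: str, motif: str = "TTAGGG", min_repeats: int = 2) -> int:
    """Count runs of >= ``min_repeats`` consecutive motif copies on both
    strands of ``seq`` (each maximal run counts once)."""
    if min_repeats < 1:
        raise ValueError("min_repeats must be >= 1")
    seq = seq.upper()
    rc = "".join(_COMP[b] for b in reversed(motif.upper()))
    n = 0
    for m in (motif.upper(), rc):
        pat = re.compile(f"(?:{m}){{{min_repeats},}}")
        n += len(pat.findall(seq))
    return n


def telomere_motif_ratio(
    tumour_reads,
    normal_reads,
    tumour_bases: int,
    normal_bases: int,
    motif: str = "TTAGGG",
    min_repeats: int = 2,
) -> float:
    """Tumour/normal ratio of telomere-motif run rates per sequenced base."""
    if tumour_bases <= 0 or normal_bases <= 0:
        raise ValueError("base counts must be positive")
    t = sum(count_motif_runs(r, motif, min_repeats) for r in tumour_reads)
    n = sum(count_motif_runs(r, motif, min_repeats) for r in normal_reads)
    normal_rate = n / normal_bases
    if normal_rate == 0:
        raise ZeroDivisionError("normal sample has no telomere motif runs")
    return (t / tumour_bases) / normal_rate


def read_pileup_tsv(path) -> pd.DataFrame:
    """Read a pileup TSV (sample, chrom, pos, ref, A, C, G, T)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    needed = {"sample", "chrom", "pos", "ref", "A", "C", "G", "T"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"pileup table {path} missing columns: {sorted(missing)}")
    return df


def pileups_for_sample(df: pd.DataFrame, sample: str) -> list[PileupCounts]:
    sub = df[df["sample"] == sample]
    return [
        PileupCounts(
            str(r.chrom),
            int(r.pos),
            str(r.ref),
            {"A": int(r.A), "C": int(r.C), "G": int(r.G), "T": int(r.T)},
        )
        for r in sub.itertuples()
    ]


def read_neoantigen_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"sample", "mutation_id", "peptide", "ic50_nM", "rna_ref_reads", "rna_alt_reads"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"neoantigen table {path} missing columns: {sorted(missing)}")
    return df


def neoantigens_for_sample(df: pd.DataFrame, sample: str) -> list[NeoantigenRecord]:
    sub = df[df["sample"] == sample]
    return [
        NeoantigenRecord(
            str(r.mutation_id),
            str(r.peptide),
            float(r.ic50_nM),
            int(r.rna_ref_reads),
            int(r.rna_alt_reads),
        )
        for r in sub.itertuples()
    ]
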
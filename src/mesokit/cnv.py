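"""Allele-specific copy-number profiles and genome-state classification rules.

The data model mirrors ASCAT-style output: per-sample segment tables with
integer major/minor allele copy number, 1-based inclusive coordinates.
On top of it sit the cohort classification rules used throughout the
package: length-weighted ploidy, whole-genome-doubling (WGD) calling,
loss-of-heterozygosity (LOH) and copy-number-alteration fractions,
near-haploidization flagging and extreme copy-number events.

A tumour is called whole-genome doubled when its length-weighted ploidy
exceeds 2.7 AND more than half of the covered genome sits at total copy
number 3–6 with both alleles present (heterozygous gain) — both
inequalities strict.  An alternative, stricter preset based on overall CNA
burden is provided as :func:`call_wgd_cna_preset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome import GenomeSpec

__all__ = [
    "AlleleSpecificSegment",
    "CopyNumberProfile",
    "ploidy",
    "fraction_cn_range_het",
    "call_wgd",
    "call_wgd_cna_preset",
    "loh_fraction",
    "flag_near_haploidization",
    "extreme_cn_events",
    "cna_fraction",
    "read_segments_tsv",
    "write_segments_tsv",
]

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "major_cn", "minor_cn"]


@dataclass(frozen=True)
class AlleleSpecificSegment:
    """One allele-specific segment, 1-based inclusive (ASCAT convention)."""

    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"segment end {self.end} < start {self.start}")
        if self.minor_cn < 0 or self.major_cn < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.major_cn < self.minor_cn:
            raise ValueError(
                f"major_cn {self.major_cn} < minor_cn {self.minor_cn}"
            )

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_loh(self) -> bool:
        """LOH: minor allele lost but at least one copy retained."""
        return self.minor_cn == 0 and self.total_cn >= 1

    @property
    def is_imbalanced(self) -> bool:
        return self.major_cn != self.minor_cn

    @property
    def state(self) -> tuple[int, int]:
        return (self.major_cn, self.minor_cn)


@dataclass(frozen=True)
class CopyNumberProfile:
    """Ordered, non-overlapping allele-specific segments for one sample."""

    sample: str
    genome: GenomeSpec
    segments: tuple[AlleleSpecificSegment, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        order = {name: i for i, name in enumerate(self.genome.names)}
        for seg in self.segments:
            if seg.chrom not in order:
                raise ValueError(f"segment on unknown chromosome {seg.chrom!r}")
            if seg.end > self.genome[seg.chrom].length:
                raise ValueError(
                    f"segment {seg.chrom}:{seg.start}-{seg.end} exceeds "
                    f"chromosome length {self.genome[seg.chrom].length}"
                )
        segs = sorted(self.segments, key=lambda s: (order[s.chrom], s.start))
        for a, b in zip(segs, segs[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                raise ValueError(
                    f"overlapping segments on {a.chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        object.__setattr__(self, "segments", tuple(segs))

    @property
    def covered_length(self) -> int:
        return sum(s.length for s in self.segments)

    def by_chromosome(self, chrom: str) -> list[AlleleSpecificSegment]:
        return [s for s in self.segments if s.chrom == chrom]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (self.sample, s.chrom, s.start, s.end, s.major_cn, s.minor_cn)
                for s in self.segments
            ],
            columns=SEGMENT_COLUMNS,
        )


def _denominator(profile: CopyNumberProfile, over: str) -> int:
    if over == "covered":
        return profile.covered_length
    if over == "genome":
        return profile.genome.total_length_bp
    raise ValueError(f"unknown denominator {over!r}; use 'covered' or 'genome'")


def ploidy(profile: CopyNumberProfile) -> float:
    """Length-weighted mean total copy number over the covered genome."""
    if not profile.segments:
        raise ValueError(f"sample {profile.sample}: empty copy-number profile")
    num = sum(s.length * s.total_cn for s in profile.segments)
    return num / profile.covered_length


def fraction_cn_range_het(
    profile: CopyNumberProfile,
    lo: int = 3,
    hi: int = 6,
    over: str = "covered",
) -> float:
    """Fraction of the genome at total copy number ``lo``–``hi`` with both
    alleles present (heterozygous gain)."""
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    hit = sum(
        s.length
        for s in profile.segments
        if lo <= s.total_cn <= hi and s.minor_cn >= 1
    )
    denom = _denominator(profile, over)
    return hit / denom if denom else 0.0


def call_wgd(
    profile: CopyNumberProfile,
    ploidy_min: float = 2.7,
    fraction_min: float = 0.5,
) -> bool:
    """Whole-genome doubling: ploidy > 2.7 and > 50% of the genome at copy
    number 3–6 with two alleles present.  Both inequalities strict."""
    if not profile.segments:
        raise ValueError(f"sample {profile.sample}: empty copy-number profile")
    return (
        ploidy(profile) > ploidy_min
        and fraction_cn_range_het(profile) > fraction_min
    )


def call_wgd_cna_preset(
    profile: CopyNumberProfile,
    cna_min: float = 0.9,
    fraction_cn36_min: float = 0.7,
) -> bool:
    """Alternative WGD preset: > 90% of the genome altered and > 70% at
    total copy number 3–6 (heterozygous).  Not the default rule."""
    return (
        cna_fraction(profile) > cna_min
        and fraction_cn_range_het(profile) > fraction_cn36_min
    )


def loh_fraction(profile: CopyNumberProfile, over: str = "covered") -> float:
    """Fraction of the genome with loss of heterozygosity (minor copy
    number 0, at least one copy retained)."""
    hit = sum(s.length for s in profile.segments if s.is_loh)
    denom = _denominator(profile, over)
    return hit / denom if denom else 0.0


def flag_near_haploidization(
    profile: CopyNumberProfile, threshold: float = 0.7
) -> bool:
    """Genome-wide LOH (near-haploidization): LOH fraction strictly above
    ``threshold``.  The default 0.7 is a package judgement call; the
    flagged cohort case had LOH over almost 80% of its genome."""
    return loh_fraction(profile) > threshold


def extreme_cn_events(
    profile: CopyNumberProfile, gain_min: int = 6
) -> tuple[list[AlleleSpecificSegment], list[AlleleSpecificSegment]]:
    """(high-gain segments with total CN >= gain_min, homozygous deletions)."""
    high_gain = [s for s in profile.segments if s.total_cn >= gain_min]
    homdel = [s for s in profile.segments if s.total_cn == 0]
    return high_gain, homdel


def cna_fraction(
    profile: CopyNumberProfile, neutral_total: int = 2, over: str = "covered"
) -> float:
    """Fraction of the genome carrying any copy-number alteration.

    A segment counts as altered when its total copy number differs from
    the neutral total (2) or when it is copy-neutral LOH (minor allele 0):
    allelic loss is an alteration even at neutral total copy number.
    """
    hit = sum(
        s.length
        for s in profile.segments
        if s.total_cn != neutral_total or s.minor_cn == 0
    )
    denom = _denominator(profile, over)
    return hit / denom if denom else 0.0


def write_segments_tsv(profiles, path) -> None:
    """Write one or more profiles to a segment TSV (shared cohort file)."""
    if isinstance(profiles, CopyNumberProfile):
        profiles = [profiles]
    df = pd.concat([p.to_frame() for p in profiles], ignore_index=True)
    df.to_csv(path, sep="\t", index=False)


def read_segments_tsv(path, genome: GenomeSpec) -> dict[str, CopyNumberProfile]:
    """Read a segment TSV into per-sample profiles (sample order preserved)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"segment table {path} missing columns: {sorted(missing)}")
    out: dict[str, CopyNumberProfile] = {}
    for sample, grp in df.groupby("sample", sort=False):
        segs = tuple(
            AlleleSpecificSegment(
                str(r.chrom), int(r.start), int(r.end), int(r.major_cn), int(r.minor_cn)
            )
            for r in grp.itertuples()
        )
        out[str(sample)] = CopyNumberProfile(str(sample), genome, segs)
    return out
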
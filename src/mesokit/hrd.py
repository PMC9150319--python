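"""Genomic-scar scores and homologous-recombination-deficiency classification.

Three allele-specific copy-number scar counts are combined into the
HRD-sum:

* HRD-LOH — LOH segments longer than 15 Mb that do not span a whole
  chromosome;
* TAI — telomeric allelic imbalance: imbalanced regions reaching a
  chromosome end without crossing the centromere;
* LST — large-scale state transitions: breakpoints between adjacent
  >= 10 Mb segments after smoothing away fragments < 3 Mb.

A sample is classed HR-deficient only when both indicators agree:
HRD-sum > 42 AND the (externally supplied) HRDetect probability > 0.7,
both strict.  The length constants follow the scar-score literature and
are configurable; on a linearly rescaled genome they must be rescaled by
the same factor (see :func:`HrdConstants.scaled`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .cnv import CopyNumberProfile
from .genome import GenomeSpec

__all__ = [
    "HrdConstants",
    "HrdResult",
    "hrd_loh_score",
    "tai_score",
    "lst_score",
    "hrd_sum",
    "classify_hr_deficient",
    "score_profile",
]


@dataclass(frozen=True)
class HrdConstants:
    loh_min_len_bp: float = 15e6
    lst_min_seg_bp: float = 10e6
    lst_smooth_below_bp: float = 3e6
    sum_min: float = 42.0
    prob_min: float = 0.7

    def scaled(self, factor: float) -> "HrdConstants":
        """Rescale the length thresholds for a genome scaled by ``factor``.
        The HRD-sum and HRDetect thresholds are scale-free and unchanged."""
        return replace(
            self,
            loh_min_len_bp=self.loh_min_len_bp * factor,
            lst_min_seg_bp=self.lst_min_seg_bp * factor,
            lst_smooth_below_bp=self.lst_smooth_below_bp * factor,
        )


@dataclass(frozen=True)
class HrdResult:
    sample: str
    loh_score: int
    tai_score: int
    lst_score: int
    hrdetect_prob: float
    hr_deficient: bool

    @property
    def hrd_sum(self) -> int:
        return self.loh_score + self.tai_score + self.lst_score


def hrd_loh_score(profile: CopyNumberProfile, min_len_bp: float = 15e6) -> int:
    """Count LOH segments longer than ``min_len_bp`` (strict) that do not
    span an entire chromosome."""
    n = 0
    for seg in profile.segments:
        if not seg.is_loh or seg.length <= min_len_bp:
            continue
        chrom = profile.genome[seg.chrom]
        if seg.start == 1 and seg.end == chrom.length:
            continue  # whole-chromosome LOH is excluded
        n += 1
    return n


def tai_score(profile: CopyNumberProfile, genome: GenomeSpec | None = None) -> int:
    """Count allelic-imbalance regions that reach a chromosome end without
    crossing (overlapping) the centromere interval."""
    genome = genome or profile.genome
    n = 0
    for seg in profile.segments:
        if not seg.is_imbalanced:
            continue
        chrom = genome[seg.chrom]
        if chrom.centromere_start is None:
            raise ValueError(f"{chrom.name}: centromere interval required for TAI")
        at_end = seg.start == 1 or seg.end == chrom.length
        crosses = seg.start <= chrom.centromere_end and seg.end >= chrom.centromere_start
        if at_end and not crosses:
            n += 1
    return n


def lst_score(
    profile: CopyNumberProfile,
    min_seg_bp: float = 10e6,
    smooth_below_bp: float = 3e6,
) -> int:
    """Count large-scale state transitions per chromosome.

    Segments shorter than ``smooth_below_bp`` are removed, adjacent
    equal-state neighbours merged, and each remaining breakpoint counts
    when both flanking segments are at least ``min_seg_bp`` long.
    """
    total = 0
    for name in profile.genome.names:
        segs = [s for s in profile.by_chromosome(name) if s.length >= smooth_below_bp]
        merged: list[tuple[tuple[int, int], int]] = []  # (state, length)
        for s in segs:
            if merged and merged[-1][0] == s.state:
                merged[-1] = (s.state, merged[-1][1] + s.length)
            else:
                merged.append((s.state, s.length))
        for (_, la), (_, lb) in zip(merged, merged[1:]):
            if la >= min_seg_bp and lb >= min_seg_bp:
                total += 1
    return total


def hrd_sum(profile: CopyNumberProfile, constants: HrdConstants = HrdConstants()) -> int:
    return (
        hrd_loh_score(profile, constants.loh_min_len_bp)
        + tai_score(profile)
        + lst_score(profile, constants.lst_min_seg_bp, constants.lst_smooth_below_bp)
    )


def classify_hr_deficient(
    hrd_sum_score: float,
    hrdetect_prob: float,
    sum_min: float = 42.0,
    prob_min: float = 0.7,
) -> bool:
    """HR deficient iff predicted by both indicators (strict inequalities)."""
    if not 0.0 <= hrdetect_prob <= 1.0:
        raise ValueError("hrdetect_prob must lie in [0, 1]")
    return hrd_sum_score > sum_min and hrdetect_prob > prob_min


def score_profile(
    profile: CopyNumberProfile,
    hrdetect_prob: float,
    constants: HrdConstants = HrdConstants(),
) -> HrdResult:
    """Compute all scar scores for one profile and classify it."""
    loh = hrd_loh_score(profile, constants.loh_min_len_bp)
    tai = tai_score(profile)
    lst = lst_score(profile, constants.lst_min_seg_bp, constants.lst_smooth_below_bp)
    return HrdResult(
        sample=profile.sample,
        loh_score=loh,
        tai_score=tai,
        lst_score=lst,
        hrdetect_prob=hrdetect_prob,
        hr_deficient=classify_hr_deficient(
            loh + tai + lst, hrdetect_prob, constants.sum_min, constants.prob_min
        ),
    )
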
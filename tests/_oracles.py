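"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles — per-basepair
array arithmetic, exhaustive enumeration, hand-rolled Mantel–Cox tables —
and never calls the implementation (or the library standing behind it)
that it is used to check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# --- per-basepair copy-number arithmetic -----------------------------------


def expand_per_bp(profile):
    """(total_cn, minor_cn) arrays over every covered basepair."""
    totals, minors = [], []
    for seg in profile.segments:
        totals.extend([seg.total_cn] * seg.length)
        minors.extend([seg.minor_cn] * seg.length)
    return np.array(totals), np.array(minors)


def bp_ploidy(profile) -> float:
    totals, _ = expand_per_bp(profile)
    return float(totals.mean())


def bp_fraction_cn_range_het(profile, lo=3, hi=6) -> float:
    totals, minors = expand_per_bp(profile)
    return float(((totals >= lo) & (totals <= hi) & (minors >= 1)).mean())


def bp_loh_fraction(profile) -> float:
    totals, minors = expand_per_bp(profile)
    return float(((minors == 0) & (totals >= 1)).mean())


def bp_cna_fraction(profile, neutral=2) -> float:
    totals, minors = expand_per_bp(profile)
    return float(((totals != neutral) | (minors == 0)).mean())


def bp_call_wgd(profile, ploidy_min=2.7, fraction_min=0.5) -> bool:
    return (
        bp_ploidy(profile) > ploidy_min
        and bp_fraction_cn_range_het(profile) > fraction_min
    )


# --- HRD scar rules, rule-by-rule ------------------------------------------


def brute_hrd_loh(profile, min_len_bp) -> int:
    n = 0
    for seg in profile.segments:
        whole = seg.start == 1 and seg.end == profile.genome[seg.chrom].length
        if (
            seg.minor_cn == 0
            and seg.total_cn >= 1
            and (seg.end - seg.start + 1) > min_len_bp
            and not whole
        ):
            n += 1
    return n


def brute_tai(profile) -> int:
    n = 0
    for seg in profile.segments:
        chrom = profile.genome[seg.chrom]
        if seg.major_cn == seg.minor_cn:
            continue
        touches_end = seg.start == 1 or seg.end == chrom.length
        overlaps_cen = not (
            seg.end < chrom.centromere_start or seg.start > chrom.centromere_end
        )
        if touches_end and not overlaps_cen:
            n += 1
    return n


def brute_lst(profile, min_seg_bp, smooth_below_bp) -> int:
    total = 0
    for name in profile.genome.names:
        kept = [
            (s.major_cn, s.minor_cn, s.end - s.start + 1)
            for s in profile.segments
            if s.chrom == name and (s.end - s.start + 1) >= smooth_below_bp
        ]
        merged = []
        for state_a, state_b, length in kept:
            if merged and merged[-1][0] == (state_a, state_b):
                merged[-1][1] += length
            else:
                merged.append([(state_a, state_b), length])
        for (_, la), (_, lb) in zip(merged, merged[1:]):
            if la >= min_seg_bp and lb >= min_seg_bp:
                total += 1
    return total


# --- SBS96 strand folding ---------------------------------------------------


def fold_192_to_96(five, ref, three, alt) -> str:
    """Independent pyrimidine-strand fold of any of the 192 stranded
    substitution-in-context combinations."""
    if ref in "CT":
        return f"{five}[{ref}>{alt}]{three}"
    return (
        f"{_COMP[three]}[{_COMP[ref]}>{_COMP[alt]}]{_COMP[five]}"
    )


# --- survival ----------------------------------------------------------------


def hand_km(times, events):
    """Product-limit estimate computed directly from the definition.
    Returns dict time -> S(t) at each observed event time."""
    order = sorted(set(t for t, e in zip(times, events) if e))
    s = 1.0
    out = {}
    for t in order:
        at_risk = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, ei in zip(times, events) if ei and ti == t)
        s *= 1.0 - d / at_risk
        out[t] = s
    return out


def hand_logrank(times, events, groups):
    """Mantel–Cox chi-square from the O/E/V table, summed over event times."""
    labels = sorted(set(groups))
    assert len(labels) == 2
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(t for t, e in zip(times, events) if e)):
        n = sum(1 for ti in times if ti >= t)
        n1 = sum(1 for ti, g in zip(times, groups) if ti >= t and g == labels[0])
        d = sum(1 for ti, ei in zip(times, events) if ei and ti == t)
        d1 = sum(
            1
            for ti, ei, g in zip(times, events, groups)
            if ei and ti == t and g == labels[0]
        )
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


# --- exact rank-sum ----------------------------------------------------------


def exact_ranksum_p(a, b) -> float:
    """Two-sided exact rank-sum p-value by full enumeration of all
    C(n_a + n_b, n_a) assignments of pooled ranks (assumes no ties)."""
    pooled = sorted(list(a) + list(b))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n = len(pooled)
    na = len(a)
    observed = sum(ranks[v] for v in a)
    mean = na * (n + 1) / 2
    obs_dev = abs(observed - mean)
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, n + 1), na):
        total += 1
        if abs(sum(combo) - mean) >= obs_dev - 1e-12:
            count += 1
    return count / total


def exact_ranksum_min_p(na: int, nb: int) -> float:
    """Smallest attainable two-sided exact p for group sizes na, nb."""
    return 2.0 / math.comb(na + nb, na)
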
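"""SBS96 mutation catalogues and reference-signature exposure refitting.

Single-base substitutions are binned into the standard 96 trinucleotide
channels (pyrimidine-strand convention: purine-reference variants are
reverse-complemented).  Exposures to a fixed reference signature matrix S
(channels x signatures, columns summing to 1) are refit by non-negative
least squares,

    minimise || c - S e ||_2   subject to  e >= 0,

and a relative-exposure cutoff (default 10%) is applied by iteratively
dropping the weakest signature and refitting until every retained
signature carries at least the cutoff share of the catalogue.  Because the
two flat signatures SBS5 and SBS40 are near-degenerate and their split is
unreliable, downstream dominance calls always use their combined mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "SBS96_CHANNELS",
    "MutationCatalogue",
    "SignatureMatrix",
    "ExposureVector",
    "sbs96_channel",
    "build_sbs_catalogue",
    "snvs_from_vcf",
    "fit_exposures",
    "apply_exposure_cutoff",
    "cosine_similarity",
    "dominance_flag",
]

_PYRIMIDINES = ("C", "T")
_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _make_channels() -> tuple[str, ...]:
    chans = []
    for sub in _SUBS:
        ref = sub[0]
        for five in _BASES:
            for three in _BASES:
                chans.append(f"{five}[{sub}]{three}")
    # COSMIC ordering groups by substitution first, then 5'/3' context
    return tuple(chans)


SBS96_CHANNELS: tuple[str, ...] = _make_channels()
_CHANNEL_INDEX = {c: i for i, c in enumerate(SBS96_CHANNELS)}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def sbs96_channel(trinucleotide: str, alt: str) -> str:
    """Map a ref-strand trinucleotide and alternate base to its SBS96 channel.

    The middle base is the reference base; purine references are folded
    onto the pyrimidine strand by reverse complement.
    """
    tri = trinucleotide.upper()
    alt = alt.upper()
    if len(tri) != 3 or any(b not in _BASES for b in tri) or alt not in _BASES:
        raise ValueError(f"invalid trinucleotide/alt: {trinucleotide!r}/{alt!r}")
    if tri[1] == alt:
        raise ValueError("alt equals reference base")
    if tri[1] not in _PYRIMIDINES:
        tri = revcomp(tri)
        alt = _COMP[alt]
    channel = f"{tri[0]}[{tri[1]}>{alt}]{tri[2]}"
    return channel


@dataclass(frozen=True)
class MutationCatalogue:
    """Per-channel mutation counts over a fixed, ordered channel set."""

    channels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (len(self.channels),):
            raise ValueError("counts length must match channel count")
        if (counts < 0).any():
            raise ValueError("catalogue counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def __add__(self, other: "MutationCatalogue") -> "MutationCatalogue":
        if self.channels != other.channels:
            raise ValueError("catalogues use different channel sets")
        return MutationCatalogue(self.channels, self.counts + other.counts)

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(self.channels))

    @classmethod
    def zeros(cls, channels=SBS96_CHANNELS) -> "MutationCatalogue":
        return cls(tuple(channels), np.zeros(len(channels)))


@dataclass(frozen=True)
class SignatureMatrix:
    """Reference signatures: channels x signatures, columns sum to 1."""

    channels: tuple[str, ...]
    names: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.channels), len(self.names)):
            raise ValueError("matrix shape must be (n_channels, n_signatures)")
        if (m < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        sums = m.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = [self.names[i] for i in np.flatnonzero(~np.isclose(sums, 1.0, atol=1e-6))]
            raise ValueError(f"signature columns must sum to 1: {bad}")
        object.__setattr__(self, "matrix", m)

    def column(self, name: str) -> np.ndarray:
        try:
            return self.matrix[:, self.names.index(name)]
        except ValueError:
            raise KeyError(name) from None

    def subset(self, names) -> "SignatureMatrix":
        idx = [self.names.index(n) for n in names]
        return SignatureMatrix(self.channels, tuple(names), self.matrix[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.channels), columns=list(self.names))

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "Type"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureMatrix":
        return cls(tuple(df.index.astype(str)), tuple(df.columns.astype(str)), df.to_numpy())

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        """Read a channels-x-signatures TSV (COSMIC v3 layout: first column
        holds the channel label, e.g. ``A[C>A]A``)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(df)


@dataclass(frozen=True)
class ExposureVector:
    """Fitted per-signature mutation counts; proportions derived."""

    names: tuple[str, ...]
    exposures: np.ndarray
    retained: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.exposures, dtype=float)
        if e.shape != (len(self.names),):
            raise ValueError("exposures length must match signature names")
        if (e < -1e-9).any():
            raise ValueError("exposures must be non-negative")
        object.__setattr__(self, "exposures", np.clip(e, 0.0, None))
        if self.retained is None:
            object.__setattr__(
                self, "retained", tuple(n for n, v in zip(self.names, e) if v > 0)
            )

    @property
    def total(self) -> float:
        return float(self.exposures.sum())

    @property
    def proportions(self) -> pd.Series:
        tot = self.total
        vals = self.exposures / tot if tot > 0 else np.zeros_like(self.exposures)
        return pd.Series(vals, index=list(self.names))

    def __getitem__(self, name: str) -> float:
        try:
            return float(self.exposures[self.names.index(name)])
        except ValueError:
            raise KeyError(name) from None

    def to_series(self) -> pd.Series:
        return pd.Series(self.exposures, index=list(self.names))


def build_sbs_catalogue(variants, reference) -> MutationCatalogue:
    """Bin SNVs into the 96 trinucleotide channels.

    Parameters
    ----------
    variants
        Iterable of ``(chrom, pos, ref, alt)`` with 1-based positions.
    reference
        Mapping-like sequence source: ``reference[chrom]`` must support
        string slicing with 0-based indices (a ``pyfaidx.Fasta`` or a
        plain ``dict`` of strings both work).

    Raises
    ------
    ValueError
        If a variant's stated reference base disagrees with the sequence,
        naming the offending record.
    """
    counts = np.zeros(len(SBS96_CHANNELS))
    for chrom, pos, ref, alt in variants:
        ref = str(ref).upper()
        alt = str(alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            raise ValueError(f"not a single-base substitution: {chrom}:{pos} {ref}>{alt}")
        tri = str(reference[chrom][pos - 2 : pos + 1]).upper()
        if len(tri) != 3:
            raise ValueError(f"reference context unavailable at {chrom}:{pos}")
        if tri[1] != ref:
            raise ValueError(
                f"reference mismatch at {chrom}:{pos}: variant ref {ref!r}, "
                f"sequence {tri[1]!r}"
            )
        counts[_CHANNEL_INDEX[sbs96_channel(tri, alt)]] += 1
    return MutationCatalogue(SBS96_CHANNELS, counts)


def snvs_from_vcf(path):
    """Yield ``(chrom, pos, ref, alt)`` for biallelic SNVs in a VCF."""
    from cyvcf2 import VCF

    for rec in VCF(str(path)):
        if len(rec.REF) != 1 or len(rec.ALT) != 1 or len(rec.ALT[0]) != 1:
            continue
        yield rec.CHROM, rec.POS, rec.REF, rec.ALT[0]


def fit_exposures(
    catalogue: MutationCatalogue, signatures: SignatureMatrix
) -> ExposureVector:
    """Refit signature exposures by non-negative least squares."""
    if catalogue.channels != signatures.channels:
        raise ValueError("catalogue and signature matrix use different channels")
    e, _ = nnls(signatures.matrix, catalogue.counts)
    return ExposureVector(signatures.names, e)


def apply_exposure_cutoff(
    exposures: ExposureVector,
    catalogue: MutationCatalogue,
    signatures: SignatureMatrix,
    cutoff: float = 0.10,
    iterative: bool = True,
) -> ExposureVector:
    """Drop signatures below the relative-exposure cutoff and refit.

    Default semantics: while any retained signature has relative exposure
    strictly below ``cutoff``, remove the smallest one and refit on the
    remaining set.  A signature at exactly the cutoff is kept.  With
    ``iterative=False`` all sub-cutoff signatures are zeroed in one shot
    and a single refit is performed on the survivors.
    """
    retained = [n for n, v in zip(exposures.names, exposures.exposures) if v > 0]
    if not retained:
        return ExposureVector(signatures.names, np.zeros(len(signatures.names)), retained=())

    def _refit(names):
        sub = signatures.subset(names)
        e, _ = nnls(sub.matrix, catalogue.counts)
        return e

    current = _refit(retained) if tuple(retained) != exposures.names else np.array(
        exposures.exposures
    )
    if not iterative:
        tot = current.sum()
        props = current / tot if tot > 0 else current
        retained = [n for n, p in zip(retained, props) if p >= cutoff]
        current = _refit(retained) if retained else np.array([])
    else:
        while retained:
            tot = current.sum()
            if tot <= 0:
                retained, current = [], np.array([])
                break
            props = current / tot
            weakest = int(np.argmin(props))
            if props[weakest] >= cutoff:
                break
            del retained[weakest]
            if retained:
                current = _refit(retained)
    full = np.zeros(len(signatures.names))
    for n, v in zip(retained, current):
        full[signatures.names.index(n)] = v
    return ExposureVector(signatures.names, full, retained=tuple(retained))


def cosine_similarity(a, b) -> float:
    """Cosine similarity of two non-negative vectors, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def dominance_flag(
    exposures: ExposureVector,
    signature_set=("SBS5", "SBS40"),
    threshold: float = 0.5,
) -> bool:
    """True iff the summed relative exposure of ``signature_set`` strictly
    exceeds ``threshold``.  SBS5 and SBS40 are reported jointly because
    their individual split is unreliable."""
    props = exposures.proportions
    for name in signature_set:
        if name not in props.index:
            raise KeyError(f"signature {name!r} not in exposure vector")
    return float(props.loc[list(signature_set)].sum()) > threshold
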
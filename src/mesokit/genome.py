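"""Genome coordinate systems for copy-number arithmetic.

All genome fractions computed elsewhere in the package (ploidy, LOH
fraction, CNA fraction, scar scores) are length-weighted over a declared
:class:`GenomeSpec`, so the spec is the single source of truth for
chromosome lengths and centromere intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["Chromosome", "GenomeSpec", "toy_genome", "grch37_autosomes"]

# GRCh37 autosome lengths (bp) and approximate centromere midpoints (bp).
_GRCH37_AUTOSOMES: list[tuple[str, int, int]] = [
    ("chr1", 249_250_621, 125_000_000),
    ("chr2", 243_199_373, 93_300_000),
    ("chr3", 198_022_430, 91_000_000),
    ("chr4", 191_154_276, 50_400_000),
    ("chr5", 180_915_260, 48_400_000),
    ("chr6", 171_115_067, 61_000_000),
    ("chr7", 159_138_663, 59_900_000),
    ("chr8", 146_364_022, 45_600_000),
    ("chr9", 141_213_431, 49_000_000),
    ("chr10", 135_534_747, 40_200_000),
    ("chr11", 135_006_516, 53_700_000),
    ("chr12", 133_851_895, 35_800_000),
    ("chr13", 115_169_878, 17_900_000),
    ("chr14", 107_349_540, 17_600_000),
    ("chr15", 102_531_392, 19_000_000),
    ("chr16", 90_354_753, 36_600_000),
    ("chr17", 81_195_210, 24_000_000),
    ("chr18", 78_077_248, 17_200_000),
    ("chr19", 59_128_983, 26_500_000),
    ("chr20", 63_025_520, 27_500_000),
    ("chr21", 48_129_895, 13_200_000),
    ("chr22", 51_304_566, 14_700_000),
]

_CENTROMERE_HALF_WIDTH = 1_500_000  # bp on the full-size genome


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: 1-based inclusive coordinates, centromere interval."""

    name: str
    length: int
    centromere_start: int
    centromere_end: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be positive")
        if not (1 <= self.centromere_start <= self.centromere_end <= self.length):
            raise ValueError(
                f"{self.name}: centromere [{self.centromere_start}, "
                f"{self.centromere_end}] outside chromosome 1..{self.length}"
            )


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered set of chromosomes over which genome fractions are computed."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must declare at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")

    @property
    def total_length_bp(self) -> int:
        return sum(c.length for c in self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [c.name for c in self.chromosomes],
                "length": [c.length for c in self.chromosomes],
                "centromere_start": [c.centromere_start for c in self.chromosomes],
                "centromere_end": [c.centromere_end for c in self.chromosomes],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenomeSpec":
        chroms = tuple(
            Chromosome(
                str(r.chrom), int(r.length), int(r.centromere_start), int(r.centromere_end)
            )
            for r in df.itertuples()
        )
        return cls(chroms)

    @classmethod
    def from_tsv(cls, path) -> "GenomeSpec":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def grch37_autosomes(scale: float = 1.0) -> GenomeSpec:
    """The 22 GRCh37 autosomes, optionally linearly rescaled.

    Fractions of the genome are scale-free, so a rescaled genome gives
    identical ploidy/LOH/CNA fractions at a fraction of the arithmetic.
    Length-threshold scores (HRD scars) must rescale their constants by the
    same factor; see :mod:`mesokit.hrd`.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    chroms = []
    for name, length, cen_mid in _GRCH37_AUTOSOMES:
        cen_lo = max(1, int((cen_mid - _CENTROMERE_HALF_WIDTH) * scale))
        cen_hi = int((cen_mid + _CENTROMERE_HALF_WIDTH) * scale)
        chroms.append(Chromosome(name, int(length * scale), cen_lo, cen_hi))
    return GenomeSpec(tuple(chroms))


def toy_genome() -> GenomeSpec:
    """Default desk-scale genome: GRCh37 autosomes at 1/100 (~28.8 Mb)."""
    return grch37_autosomes(scale=0.01)
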
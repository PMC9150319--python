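import numpy as np
import pytest

from mesokit.cnv import AlleleSpecificSegment, CopyNumberProfile
from mesokit.genome import Chromosome, GenomeSpec
from mesokit.simulate import make_synthetic_cell_reference, make_synthetic_signatures


@pytest.fixture(scope="session")
def mini_genome() -> GenomeSpec:
    """Three small chromosomes with centromeres; lengths sum to 24,000 bp."""
    return GenomeSpec(
        (
            Chromosome("chrA", 10_000, 4_000, 4_400),
            Chromosome("chrB", 8_000, 3_200, 3_500),
            Chromosome("chrC", 6_000, 2_400, 2_600),
        )
    )


@pytest.fixture(scope="session")
def sig_matrix():
    return make_synthetic_signatures()


@pytest.fixture(scope="session")
def cell_ref():
    return make_synthetic_cell_reference()


def uniform_profile(genome: GenomeSpec, major: int, minor: int, sample="s"):
    """One segment per chromosome, all in the same allele-specific state."""
    segs = tuple(
        AlleleSpecificSegment(c.name, 1, c.length, major, minor)
        for c in genome.chromosomes
    )
    return CopyNumberProfile(sample, genome, segs)


def random_profile(genome: GenomeSpec, rng: np.random.Generator, max_segments=10):
    """Random gap-free profile with <= max_segments segments in total."""
    n_break = int(rng.integers(0, max_segments - len(genome.chromosomes) + 1))
    segs = []
    budget = n_break
    for chrom in genome.chromosomes:
        k = int(rng.integers(0, budget + 1)) if budget else 0
        budget -= k
        cuts = (
            np.sort(rng.choice(np.arange(2, chrom.length), size=k, replace=False))
            if k
            else np.array([], dtype=int)
        )
        bounds = [1, *cuts.tolist(), chrom.length + 1]
        for s, e in zip(bounds, bounds[1:]):
            total = int(rng.integers(0, 7))
            minor = int(rng.integers(0, total // 2 + 1))
            segs.append(
                AlleleSpecificSegment(chrom.name, s, e - 1, total - minor, minor)
            )
    return CopyNumberProfile("rand", genome, tuple(segs))
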
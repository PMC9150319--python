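"""Synthetic cohort generation with recorded ground truth.

Every input the classification pipeline consumes — allele-specific
segment tables, per-sample SNV VCFs with a matching reference contig,
promoter pileups, TPM expression, neoantigen tables, SMG q-value tables,
HRDetect probabilities and clinical outcomes — can be generated here with
known per-sample truth, so classifier outputs are checkable label by
label.

Study-scale defaults mirror the cohort the rules were defined on: 58
samples, 17 whole-genome doubled, 3 TERT-promoter mutant, 54 with
combined SBS5/SBS40 exposure above one half, ~3,000 SNVs per sample, one
near-haploid case, and a survival disadvantage for WGD tumours.  All
randomness flows through seeds derived from a single root seed; identical
config + seed reproduces byte-identical output files.
"""

from __future__ import annotations

import json
import shutil
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import AlleleSpecificSegment, CopyNumberProfile, loh_fraction, write_segments_tsv
from .genome import GenomeSpec, toy_genome
from .signatures import SBS96_CHANNELS, MutationCatalogue, SignatureMatrix, sbs96_channel
from .somatic import TERT_PROMOTER_SITES

__all__ = [
    "CohortConfig",
    "CohortTruth",
    "make_synthetic_signatures",
    "make_synthetic_cell_reference",
    "gen_cn_profile",
    "gen_scarred_profile",
    "gen_catalogue",
    "gen_expression",
    "gen_clinical",
    "gen_driver_tables",
    "gen_reference_contig",
    "gen_cohort",
]

CELL_TYPES = ("B_cells", "CD4_T", "CD8_T", "NK", "Monocytes", "M2_macrophages")
SIGNATURE_NAMES = ("SBS1", "SBS2", "SBS5", "SBS13", "SBS18", "SBS40")
DRIVER_GENES = ("BAP1", "NF2", "TP53", "SETD2", "LATS2", "DDX3X", "SETDB1", "PBRM1")
OTHER_GENES = ("LATS1", "SETD5", "TTN", "MUC16")

_BASES = np.array(["A", "C", "G", "T"])


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    """Derived generator: deterministic child stream for a sub-task."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# bundled synthetic references


def make_synthetic_signatures() -> SignatureMatrix:
    """Six-signature synthetic SBS96 reference.

    SBS5 and SBS40 are flat, mutually similar signatures (as in the
    real catalogue, making their individual split unreliable while their
    combined mass stays identifiable); the other four are concentrated on
    disjoint-ish channel blocks and well separated.
    """
    idx = {c: i for i, c in enumerate(SBS96_CHANNELS)}
    cols = {}

    def norm(v):
        return v / v.sum()

    v = np.zeros(96)
    for x in "ACGT":  # CpG deamination flavour: N[C>T]G
        v[idx[f"{x}[C>T]G"]] = 1.0
    cols["SBS1"] = norm(v)

    v = np.zeros(96)
    for x in "ACGT":  # APOBEC flavour: T[C>T]N
        v[idx[f"T[C>T]{x}"]] = 1.0
    cols["SBS2"] = norm(v)

    v = np.zeros(96)
    for x in "ACGT":  # APOBEC flavour: T[C>G]N
        v[idx[f"T[C>G]{x}"]] = 1.0
    cols["SBS13"] = norm(v)

    v = np.zeros(96)
    for c in SBS96_CHANNELS:  # oxidative-damage flavour: C>A block
        if "[C>A]" in c:
            v[idx[c]] = 1.0
    cols["SBS18"] = norm(v)

    v = np.ones(96)  # flat, tilted toward C>T
    for c in SBS96_CHANNELS:
        if "[C>T]" in c:
            v[idx[c]] += 1.0
    cols["SBS5"] = norm(v)

    v = np.ones(96)  # flat, tilted toward T>N
    for c in SBS96_CHANNELS:
        if "[T>" in c:
            v[idx[c]] += 1.0
    cols["SBS40"] = norm(v)

    m = np.column_stack([cols[n] for n in SIGNATURE_NAMES])
    return SignatureMatrix(SBS96_CHANNELS, SIGNATURE_NAMES, m)


def make_synthetic_cell_reference() -> pd.DataFrame:
    """Cell-type reference expression matrix (genes x 6 cell types).

    Eight synthetic marker genes per type plus the named genes the
    downstream scores read: GZMA/PRF1 (cytolytic, CD8/NK), the
    M2-macrophage-associated markers CCL2/TGFB1/MMP2/MMP14, and the
    checkpoint panel (T-cell weighted).  Values are noiseless constants.
    """
    genes: dict[str, dict[str, float]] = {}
    base = 1.0
    for ct in CELL_TYPES:
        for j in range(8):
            genes[f"{ct}_MARK{j + 1}"] = {ct: 30.0}
    genes["GZMA"] = {"CD8_T": 40.0, "NK": 10.0}
    genes["PRF1"] = {"CD8_T": 35.0, "NK": 15.0}
    for g in ("CCL2", "TGFB1", "MMP2", "MMP14"):
        genes[g] = {"M2_macrophages": 25.0, "Monocytes": 3.0}
    for g in ("VSIR", "CD276", "PDCD1", "CTLA4", "CD274", "LAG3", "HAVCR2", "TIGIT"):
        genes[g] = {"CD8_T": 6.0, "CD4_T": 5.0}
    ref = pd.DataFrame(base, index=sorted(genes), columns=list(CELL_TYPES))
    for g, levels in genes.items():
        for ct, v in levels.items():
            ref.at[g, ct] += v
    return ref


# ---------------------------------------------------------------------------
# copy-number profiles

_WGD_HET_STATES = [(2, 2), (3, 1), (3, 2), (4, 2)]  # all total 4-6, minor >= 1


def _split_block(start: int, end: int, rng: np.random.Generator, max_pieces: int = 3):
    """Split [start, end] into 1..max_pieces random contiguous sub-blocks."""
    length = end - start + 1
    n = int(rng.integers(1, max_pieces + 1))
    n = min(n, length)
    if n == 1:
        return [(start, end)]
    cuts = np.sort(rng.choice(np.arange(1, length), size=n - 1, replace=False))
    bounds = [0, *cuts.tolist(), length]
    return [(start + a, start + b - 1) for a, b in zip(bounds, bounds[1:])]


def gen_cn_profile(
    genome: GenomeSpec,
    wgd: bool,
    loh_fraction_target: float,
    seed: int,
    sample: str = "synthetic",
) -> CopyNumberProfile:
    """Generate a gap-free profile on the requested side of the WGD rule
    with LOH fraction within +/-0.05 of target.

    WGD profiles tile the non-LOH genome with heterozygous-gain states
    (total 4-6, minor allele present) and the LOH portion with 2+0, so
    ploidy > 2.7 and heterozygous-gain fraction > 0.5 hold whenever the
    LOH target permits; non-WGD profiles use 1+1 / 1+0.  A WGD profile
    with LOH target above 0.45 is unconstructible (the heterozygous-gain
    majority cannot coexist with that much LOH) and raises ``ValueError``.
    """
    if not 0.0 <= loh_fraction_target <= 1.0:
        raise ValueError("loh_fraction_target must lie in [0, 1]")
    if wgd and loh_fraction_target > 0.45:
        raise ValueError(
            "unreachable combination: WGD requires > 50% heterozygous-gain "
            f"genome, impossible with LOH target {loh_fraction_target}"
        )
    rng = np.random.default_rng(seed)
    loh_state = (2, 0) if wgd else (1, 0)
    segments: list[AlleleSpecificSegment] = []
    for chrom in genome.chromosomes:
        t = loh_fraction_target
        if 0.0 < t < 1.0:
            t = float(np.clip(t + rng.uniform(-0.03, 0.03), 0.0, 1.0))
        loh_len = int(round(t * chrom.length))
        loh_first = bool(rng.integers(0, 2))
        blocks = []  # (start, end, is_loh)
        if loh_len >= chrom.length:
            blocks.append((1, chrom.length, True))
        elif loh_len <= 0:
            blocks.append((1, chrom.length, False))
        elif loh_first:
            blocks.append((1, loh_len, True))
            blocks.append((loh_len + 1, chrom.length, False))
        else:
            blocks.append((1, chrom.length - loh_len, False))
            blocks.append((chrom.length - loh_len + 1, chrom.length, True))
        for bstart, bend, is_loh in blocks:
            for s, e in _split_block(bstart, bend, rng):
                if is_loh:
                    major, minor = loh_state
                else:
                    major, minor = (
                        _WGD_HET_STATES[rng.integers(len(_WGD_HET_STATES))]
                        if wgd
                        else (1, 1)
                    )
                segments.append(AlleleSpecificSegment(chrom.name, s, e, major, minor))
    profile = CopyNumberProfile(sample, genome, tuple(segments))
    achieved = loh_fraction(profile)
    if abs(achieved - loh_fraction_target) > 0.05:
        raise RuntimeError(
            f"generated LOH fraction {achieved:.3f} misses target "
            f"{loh_fraction_target:.3f}"
        )
    return profile


def gen_scarred_profile(
    genome: GenomeSpec,
    n_scars: int,
    seed: int,
    wgd: bool = False,
    scar_len_bp: int | None = None,
    spacer_len_bp: int | None = None,
    sample: str = "synthetic",
) -> CopyNumberProfile:
    """Profile carrying ``n_scars`` interstitial LOH scar segments.

    Used to construct HR-deficient synthetic samples: each scar is an LOH
    segment long enough to count toward the HRD-LOH score (and flanked by
    long balanced spacers, so each scar also contributes two large-scale
    state transitions).  Scar/spacer lengths default to 2x and 1.5x the
    HRD-LOH length floor scaled to the genome (1/100 of 15 Mb on the toy
    genome).
    """
    scale = genome.total_length_bp / 2_875_001_522  # GRCh37 autosome total
    scar_len = int(scar_len_bp if scar_len_bp is not None else 2 * 15e6 * scale)
    spacer_len = int(spacer_len_bp if spacer_len_bp is not None else 1.5 * 10e6 * scale)
    rng = np.random.default_rng(seed)
    base_state = (2, 2) if wgd else (1, 1)
    loh_state = (2, 0) if wgd else (1, 0)
    segments: list[AlleleSpecificSegment] = []
    placed = 0
    for chrom in genome.chromosomes:
        pos = 1
        while placed < n_scars and pos + spacer_len + scar_len + spacer_len - 1 <= chrom.length:
            segments.append(
                AlleleSpecificSegment(
                    chrom.name, pos, pos + spacer_len - 1, *base_state
                )
            )
            pos += spacer_len
            segments.append(
                AlleleSpecificSegment(chrom.name, pos, pos + scar_len - 1, *loh_state)
            )
            pos += scar_len
            placed += 1
        if pos <= chrom.length:
            segments.append(
                AlleleSpecificSegment(chrom.name, pos, chrom.length, *base_state)
            )
    if placed < n_scars:
        raise ValueError(f"genome too small for {n_scars} scar segments")
    del rng  # layout is deterministic; seed kept for interface symmetry
    return CopyNumberProfile(sample, genome, tuple(segments))


# ---------------------------------------------------------------------------
# mutation catalogues and variants


def gen_catalogue(
    signatures: SignatureMatrix,
    exposure_truth: dict[str, float],
    n_mutations: int,
    seed: int | np.random.Generator,
) -> MutationCatalogue:
    """Multinomial catalogue draw from the mixture S . e."""
    if n_mutations < 0:
        raise ValueError("n_mutations must be non-negative")
    unknown = set(exposure_truth) - set(signatures.names)
    if unknown:
        raise KeyError(f"signatures absent from matrix: {sorted(unknown)}")
    e = np.array([exposure_truth.get(n, 0.0) for n in signatures.names])
    if abs(e.sum() - 1.0) > 1e-9:
        raise ValueError("exposure_truth must sum to 1")
    p = signatures.matrix @ e
    p = p / p.sum()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multinomial(n_mutations, p)
    return MutationCatalogue(signatures.channels, counts.astype(float))


def gen_reference_contig(length: int = 120_000, seed: int = 0) -> str:
    """Random reference contig used to place synthetic SNVs in context."""
    rng = np.random.default_rng(seed)
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def index_trinucleotide_sites(seq: str) -> dict[str, list[tuple[int, str, str]]]:
    """Map each SBS96 channel to the ``(pos, ref, alt)`` records (1-based)
    that realise it on ``seq``."""
    sites: dict[str, list[tuple[int, str, str]]] = {c: [] for c in SBS96_CHANNELS}
    for i in range(1, len(seq) - 1):
        tri = seq[i - 1 : i + 2]
        ref = tri[1]
        for alt in "ACGT":
            if alt == ref:
                continue
            sites[sbs96_channel(tri, alt)].append((i + 1, ref, alt))
    return sites


def catalogue_to_variants(
    catalogue: MutationCatalogue,
    sites: dict[str, list[tuple[int, str, str]]],
    contig: str,
    rng: np.random.Generator,
) -> list[tuple[str, int, str, str]]:
    """Draw concrete SNVs realising a catalogue (channel-exact)."""
    variants: list[tuple[str, int, str, str]] = []
    for channel, count in zip(catalogue.channels, catalogue.counts):
        count = int(count)
        if count == 0:
            continue
        pool = sites[channel]
        if count > len(pool):
            raise ValueError(
                f"reference contig has only {len(pool)} sites for channel "
                f"{channel}; {count} requested"
            )
        picks = rng.choice(len(pool), size=count, replace=False)
        for k in picks:
            pos, ref, alt = pool[k]
            variants.append((contig, pos, ref, alt))
    variants.sort(key=lambda v: v[1])
    return variants


def write_minimal_vcf(variants, path, contig_name: str, contig_length: int) -> None:
    """Write a sites-only VCF v4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig_name},length={contig_length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in variants:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# expression, clinical, drivers


def gen_expression(
    cell_ref: pd.DataFrame,
    fractions: dict[str, float],
    marker_boost: dict[str, float] | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """One synthetic TPM column: ``cell_ref @ fractions`` with optional
    per-gene multiplicative boosts and log-normal noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    f = np.array([fractions.get(ct, 0.0) for ct in cell_ref.columns])
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    col = pd.Series(cell_ref.to_numpy(dtype=float) @ f, index=cell_ref.index)
    for gene, mult in (marker_boost or {}).items():
        if gene in col.index:
            col[gene] *= mult
    if noise_sd > 0:
        rng = (
            seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        )
        col = col * np.exp(rng.normal(0.0, noise_sd, size=len(col)))
    return col


def gen_clinical(
    n: int,
    group_flags,
    hazard_ratio: float,
    baseline_hazard: float = 1 / 400.0,
    censor_rate: float = 0.2,
    seed: int | np.random.Generator = 0,
    samples=None,
) -> pd.DataFrame:
    """Exponential proportional-hazards survival table.

    Event times are exponential with hazard ``baseline_hazard`` times
    ``hazard_ratio`` for flagged samples; a ``censor_rate`` fraction of
    subjects (independent coin flips) is censored uniformly before its
    event time.
    """
    if n < 2:
        raise ValueError("need at least two subjects")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    flags = np.asarray(group_flags, dtype=bool)
    if flags.shape != (n,):
        raise ValueError("group_flags must have length n")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hazards = baseline_hazard * np.where(flags, hazard_ratio, 1.0)
    times = rng.exponential(1.0 / hazards)
    censored = rng.random(n) < censor_rate
    observed = np.where(censored, rng.uniform(0.0, times), times)
    observed = np.maximum(observed, 1e-6)
    if samples is None:
        samples = [f"S{i + 1:03d}" for i in range(n)]
    return pd.DataFrame(
        {
            "sample": samples,
            "time_days": observed,
            "event": (~censored).astype(int),
            "group": flags.astype(int),
        }
    )


def gen_driver_tables(
    n_samples: int,
    n_with_driver: int,
    seed: int,
    samples=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SMG q-value table and sample x gene mutation indicator.

    The q-value table makes the seven canonical drivers significant in at
    least two tools and PBRM1 in MutPanning only (the exception-set
    route); the indicator gives exactly ``n_with_driver`` samples at
    least one mutated consensus driver.
    """
    if not 0 <= n_with_driver <= n_samples:
        raise ValueError("n_with_driver must lie in [0, n_samples]")
    rng = np.random.default_rng(seed)
    genes = list(DRIVER_GENES) + list(OTHER_GENES)
    q = pd.DataFrame(
        np.nan, index=genes, columns=["OncodriveFML", "MutSigCV", "MutPanning"]
    )
    for g in DRIVER_GENES[:-1]:  # significant in 2 or 3 tools
        tools = rng.choice(3, size=int(rng.integers(2, 4)), replace=False)
        for t in tools:
            q.iloc[genes.index(g), t] = round(float(rng.uniform(1e-6, 0.04)), 6)
        for t in range(3):
            if np.isnan(q.iloc[genes.index(g), t]):
                q.iloc[genes.index(g), t] = round(float(rng.uniform(0.1, 0.9)), 6)
    q.loc["PBRM1"] = [0.31, 0.42, 0.012]  # exception gene: MutPanning only
    for g in OTHER_GENES:
        q.loc[g] = np.round(rng.uniform(0.06, 0.95, size=3), 6)

    if samples is None:
        samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    indicator = pd.DataFrame(0, index=samples, columns=genes)
    with_driver = rng.choice(n_samples, size=n_with_driver, replace=False)
    for i in with_driver:
        hit = rng.choice(len(DRIVER_GENES), size=int(rng.integers(1, 4)), replace=False)
        for g in hit:
            indicator.iloc[i, g] = 1
    # background mutations in non-driver genes everywhere
    noise = rng.random((n_samples, len(OTHER_GENES))) < 0.3
    indicator.loc[:, OTHER_GENES] = noise.astype(int)
    indicator.index.name = "sample"
    return q, indicator


# ---------------------------------------------------------------------------
# whole-cohort generation


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs for a full synthetic cohort."""

    n_samples: int = 58
    n_wgd: int = 17
    n_tert_mutant: int = 3
    n_sbs5_40_dominant: int = 54
    n_hr_deficient: int = 2
    n_cd8_high: int = 5
    n_with_driver: int = 35
    include_near_haploid: bool = True
    n_mutations: int = 3000
    dominant_sbs5_40_mass: float = 0.65
    background_sbs5_40_mass: float = 0.20
    expression_noise_sd: float = 0.1
    wgd_hazard_ratio: float = 2.5
    baseline_hazard: float = 1 / 400.0
    censor_rate: float = 0.2
    n_hrd_scars: int = 20
    contig_length: int = 120_000
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        for name in (
            "n_wgd",
            "n_tert_mutant",
            "n_sbs5_40_dominant",
            "n_hr_deficient",
            "n_cd8_high",
            "n_with_driver",
        ):
            v = getattr(self, name)
            if not 0 <= v <= self.n_samples:
                raise ValueError(f"{name}={v} outside [0, n_samples]")


@dataclass
class CohortTruth:
    """Recorded ground truth for a generated cohort."""

    config: CohortConfig
    samples: list[str]
    per_sample: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "schema_version": 1,
            "config": asdict(self.config),
            "samples": self.samples,
            "per_sample": self.per_sample,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "CohortTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            config=CohortConfig(**payload["config"]),
            samples=payload["samples"],
            per_sample=payload["per_sample"],
        )


def _exposure_truth(dominant: bool, cfg: CohortConfig) -> dict[str, float]:
    mass = cfg.dominant_sbs5_40_mass if dominant else cfg.background_sbs5_40_mass
    rest = 1.0 - mass
    return {
        "SBS5": round(mass * 0.55, 12),
        "SBS40": round(mass * 0.45, 12),
        "SBS1": round(rest / 2, 12),
        "SBS18": round(rest / 2, 12),
    }


def _cold_fractions(rng: np.random.Generator) -> dict[str, float]:
    alpha = np.array([1.0, 2.0, 0.8, 0.8, 2.5, 5.0])  # M2-heavy microenvironment
    f = rng.dirichlet(alpha)
    cd8 = list(CELL_TYPES).index("CD8_T")
    m2 = list(CELL_TYPES).index("M2_macrophages")
    if f[cd8] > 0.15:  # keep cold samples clear of the CD8-high rule
        f[m2] += f[cd8] - 0.15
        f[cd8] = 0.15
    return {ct: float(v) for ct, v in zip(CELL_TYPES, f)}


def _hot_fractions(rng: np.random.Generator) -> dict[str, float]:
    # CD8 pinned above the CD8-high threshold; remainder Dirichlet.
    others = [ct for ct in CELL_TYPES if ct != "CD8_T"]
    alpha = np.array([1.0, 2.0, 1.0, 2.5, 5.0])  # B, CD4, NK, Mono, M2
    f = rng.dirichlet(alpha) * 0.70
    out = {ct: float(v) for ct, v in zip(others, f)}
    out["CD8_T"] = 0.30
    return out


def gen_cohort(config: CohortConfig, outdir, overwrite: bool = False) -> CohortTruth:
    """Generate a complete cohort on disk plus its truth record.

    All files are written to a temporary directory and moved into place
    only on success, so a failure leaves no partial output.  Identical
    config (including seed) reproduces byte-identical files.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()):
        if not overwrite:
            raise FileExistsError(f"output directory {outdir} is not empty")
        shutil.rmtree(outdir)
    outdir.parent.mkdir(parents=True, exist_ok=True)

    cfg = config
    seed = cfg.seed
    genome = toy_genome()
    signatures = make_synthetic_signatures()
    cell_ref = make_synthetic_cell_reference()
    samples = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]

    # --- assign per-sample truth flags ------------------------------------
    root = _rng_for(seed, 0)
    idx = np.arange(cfg.n_samples)
    wgd_set = set(root.choice(idx, size=cfg.n_wgd, replace=False).tolist())
    hrd_set = set(root.choice(idx, size=cfg.n_hr_deficient, replace=False).tolist())
    tert_set = set(root.choice(idx, size=cfg.n_tert_mutant, replace=False).tolist())
    dom_set = set(root.choice(idx, size=cfg.n_sbs5_40_dominant, replace=False).tolist())
    hot_set = set(root.choice(idx, size=cfg.n_cd8_high, replace=False).tolist())
    near_haploid_i = None
    if cfg.include_near_haploid:
        candidates = [i for i in idx if i not in wgd_set and i not in hrd_set]
        if not candidates:
            raise ValueError("no sample available for the near-haploid case")
        near_haploid_i = int(root.choice(candidates))

    contig_name = "contig1"
    contig = gen_reference_contig(cfg.contig_length, seed=int(_rng_for(seed, 1).integers(2**31)))
    sites = index_trinucleotide_sites(contig)

    truth = CohortTruth(config=cfg, samples=samples)
    tmp = Path(tempfile.mkdtemp(prefix=".cohort-", dir=outdir.parent))
    try:
        (tmp / "vcf").mkdir()
        profiles = []
        pileup_rows = []
        neo_rows = []
        hrdetect_rows = []
        expr_cols = {}
        frac_truth_rows = []

        for i, sample in enumerate(samples):
            srng = _rng_for(seed, 2, i)
            wgd = i in wgd_set
            hrd = i in hrd_set
            hot = i in hot_set
            dominant = i in dom_set
            tert = i in tert_set

            # copy number
            if hrd:
                profile = gen_scarred_profile(
                    genome, cfg.n_hrd_scars, seed=int(srng.integers(2**31)),
                    wgd=wgd, sample=sample,
                )
            elif near_haploid_i == i:
                profile = gen_cn_profile(
                    genome, wgd=False, loh_fraction_target=0.8,
                    seed=int(srng.integers(2**31)), sample=sample,
                )
            else:
                target = float(srng.uniform(0.05, 0.35))
                profile = gen_cn_profile(
                    genome, wgd=wgd, loh_fraction_target=target,
                    seed=int(srng.integers(2**31)), sample=sample,
                )
            profiles.append(profile)

            # catalogue -> concrete variants
            exp_truth = _exposure_truth(dominant, cfg)
            catalogue = gen_catalogue(signatures, exp_truth, cfg.n_mutations, srng)
            variants = catalogue_to_variants(catalogue, sites, contig_name, srng)
            write_minimal_vcf(
                variants, tmp / "vcf" / f"{sample}.vcf", contig_name, cfg.contig_length
            )

            # promoter pileups: all assessed sites, one mutant site if flagged
            site_keys = sorted(TERT_PROMOTER_SITES)
            mutant_key = site_keys[int(srng.integers(len(site_keys)))] if tert else None
            for (chrom, pos) in site_keys:
                ref, alt = TERT_PROMOTER_SITES[(chrom, pos)]
                depth = 100
                alt_n = 30 if (chrom, pos) == mutant_key else 2
                counts = {b: 0 for b in "ACGT"}
                counts[alt] = alt_n
                counts[ref] = depth - alt_n
                pileup_rows.append(
                    (sample, chrom, pos, ref, counts["A"], counts["C"], counts["G"], counts["T"])
                )

            # neoantigens
            n_neo = int(srng.poisson(30))
            n_binding = 0
            n_expressed = 0
            for j in range(n_neo):
                ic50 = float(np.exp(srng.normal(np.log(500.0), 1.2)))
                alt_reads = int(srng.poisson(8))
                ref_reads = int(srng.poisson(30))
                peptide = "".join(
                    np.array(list("ACDEFGHIKLMNPQRSTVWY"))[
                        srng.integers(0, 20, size=9)
                    ]
                )
                neo_rows.append(
                    (sample, f"{sample}_mut{j + 1}", peptide, round(ic50, 3), ref_reads, alt_reads)
                )
                if ic50 <= 500.0:
                    n_binding += 1
                    if alt_reads >= 10:
                        n_expressed += 1

            # HRDetect probability (external-tool stand-in input)
            prob = 0.95 if hrd else 0.05
            hrdetect_rows.append((sample, prob))

            # expression
            frng = _rng_for(seed, 3, i)
            fr = _hot_fractions(frng) if hot else _cold_fractions(frng)
            boost = {g: 32.0 for g in (
                "VSIR", "CD276", "PDCD1", "CTLA4", "CD274", "LAG3", "HAVCR2", "TIGIT"
            )} if hot else None
            expr_cols[sample] = gen_expression(
                cell_ref, fr, marker_boost=boost,
                noise_sd=cfg.expression_noise_sd, seed=frng,
            )
            frac_truth_rows.append(fr)

            truth.per_sample[sample] = {
                "wgd": wgd,
                "loh_fraction": round(loh_fraction(profile), 6),
                "near_haploid": near_haploid_i == i,
                "exposure_truth": exp_truth,
                "sbs5_40_dominant": dominant,
                "hr_deficient": hrd and prob > 0.7,
                "hrdetect_prob": prob,
                "tert_mutant": tert,
                "n_neoantigens_binding": n_binding,
                "n_neoantigens_expressed": n_expressed,
                "fraction_truth": {k: round(v, 12) for k, v in fr.items()},
                "cd8_high": fr["CD8_T"] > 0.2,
                "immune_hot": hot,
                "hazard_multiplier": cfg.wgd_hazard_ratio if wgd else 1.0,
                "seed": seed,
            }

        # --- cohort-level files ------------------------------------------
        write_segments_tsv(profiles, tmp / "segments.tsv")
        genome.to_tsv(tmp / "genome.tsv")
        with open(tmp / "reference.fa", "w") as fh:
            fh.write(f">{contig_name}\n")
            for k in range(0, len(contig), 80):
                fh.write(contig[k : k + 80] + "\n")
        signatures.to_tsv(tmp / "signatures_ref.tsv")
        cell_ref.rename_axis("gene").to_csv(tmp / "cell_ref.tsv", sep="\t")
        pd.DataFrame(
            pileup_rows,
            columns=["sample", "chrom", "pos", "ref", "A", "C", "G", "T"],
        ).to_csv(tmp / "pileups.tsv", sep="\t", index=False)
        pd.DataFrame(
            neo_rows,
            columns=["sample", "mutation_id", "peptide", "ic50_nM", "rna_ref_reads", "rna_alt_reads"],
        ).to_csv(tmp / "neoantigens.tsv", sep="\t", index=False)
        pd.DataFrame(hrdetect_rows, columns=["sample", "hrdetect_prob"]).to_csv(
            tmp / "hrdetect.tsv", sep="\t", index=False
        )
        expr = pd.DataFrame(expr_cols)
        expr.rename_axis("gene").to_csv(
            tmp / "expression_tpm.tsv", sep="\t", float_format="%.6f"
        )

        qvals, indicator = gen_driver_tables(
            cfg.n_samples, cfg.n_with_driver, seed=int(_rng_for(seed, 4).integers(2**31)),
            samples=samples,
        )
        qvals.rename_axis("gene").to_csv(tmp / "smg_qvalues.tsv", sep="\t")
        indicator.to_csv(tmp / "mutation_indicator.tsv", sep="\t")

        flags = np.array([i in wgd_set for i in idx])
        clinical = gen_clinical(
            cfg.n_samples, flags, cfg.wgd_hazard_ratio, cfg.baseline_hazard,
            cfg.censor_rate, seed=_rng_for(seed, 5), samples=samples,
        )
        clinical.round({"time_days": 4}).to_csv(tmp / "clinical.tsv", sep="\t", index=False)

        meta = {
            "schema_version": 1,
            "seed": seed,
            "genome_scale": genome.total_length_bp / 2_875_001_522,
            "n_samples": cfg.n_samples,
            "contig": contig_name,
        }
        with open(tmp / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
            fh.write("\n")
        truth.to_json(tmp / "truth.json")

        if outdir.exists():
            shutil.rmtree(outdir)
        tmp.rename(outdir)
    except BaseException:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    return truth
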
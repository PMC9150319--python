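"""End-to-end orchestration: simulate a cohort, classify it, report.

``run_classify`` reads a cohort directory (the file layout written by
:func:`mesokit.simulate.gen_cohort`, which mirrors standard upstream tool
outputs), computes one :class:`SampleReport` per sample and the
cohort-level tables (driver consensus, survival comparison, immune
grouping, marker correlations), and writes them to an output directory.
Outputs are deterministic for a fixed input directory and seed; partial
outputs are removed on failure.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from . import cnv, cohort, hrd, immune, signatures as sigs, somatic
from .genome import GenomeSpec
from .simulate import CohortConfig, CohortTruth, gen_cohort

__all__ = ["SampleReport", "CohortResult", "run_simulate", "run_classify"]

SCHEMA_VERSION = 1


@dataclass
class SampleReport:
    """Per-sample classification bundle."""

    sample: str
    wgd: bool
    ploidy: float
    loh_fraction: float
    cna_fraction: float
    near_haploid: bool
    exposures: dict[str, float]          # post-cutoff relative exposures
    sbs5_40_dominant: bool
    hrd_loh: int
    hrd_tai: int
    hrd_lst: int
    hrd_sum: int
    hrdetect_prob: float
    hr_deficient: bool
    tert_calls: list[dict]
    tert_mutant: bool
    burden_per_mb: float
    n_neoantigens_binding: int
    n_neoantigens_expressed: int
    cytolytic_score: float
    immune_fractions: dict[str, float]
    immune_pvalue: float
    cd8_high: bool
    immune_group: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class CohortResult:
    samples: list[SampleReport]
    consensus_drivers: pd.DataFrame
    driver_coverage: tuple[int, float]
    survival_logrank: tuple[float, float]
    marker_correlations: pd.DataFrame | None


def run_simulate(config: CohortConfig, outdir, overwrite: bool = False) -> CohortTruth:
    """Generate a synthetic cohort (CLI-facing wrapper over gen_cohort)."""
    return gen_cohort(config, outdir, overwrite=overwrite)


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input file missing: {path}")
    return path


def run_classify(
    indir,
    outdir,
    seed: int = 0,
    n_perm: int = 100,
    overwrite: bool = False,
) -> CohortResult:
    """Classify every sample in a cohort directory and write reports."""
    indir = Path(indir)
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {outdir} is not empty")

    with open(_require(indir / "meta.json")) as fh:
        meta = json.load(fh)
    genome = GenomeSpec.from_tsv(_require(indir / "genome.tsv"))
    scale = float(meta.get("genome_scale", 1.0))
    constants = hrd.HrdConstants().scaled(scale)

    profiles = cnv.read_segments_tsv(_require(indir / "segments.tsv"), genome)
    if not profiles:
        raise ValueError("cohort contains no samples")
    samples = list(profiles)

    sig_matrix = sigs.SignatureMatrix.from_tsv(_require(indir / "signatures_ref.tsv"))
    reference = Fasta(str(_require(indir / "reference.fa")))
    pileup_df = somatic.read_pileup_tsv(_require(indir / "pileups.tsv"))
    neo_df = somatic.read_neoantigen_tsv(_require(indir / "neoantigens.tsv"))
    hrdetect = pd.read_csv(_require(indir / "hrdetect.tsv"), sep="\t").set_index("sample")
    expr = pd.read_csv(_require(indir / "expression_tpm.tsv"), sep="\t", index_col=0)
    cell_ref = pd.read_csv(_require(indir / "cell_ref.tsv"), sep="\t", index_col=0)
    qvals = pd.read_csv(_require(indir / "smg_qvalues.tsv"), sep="\t", index_col=0)
    indicator = pd.read_csv(
        _require(indir / "mutation_indicator.tsv"), sep="\t", index_col=0
    )
    clinical = pd.read_csv(_require(indir / "clinical.tsv"), sep="\t")

    genome_mb = genome.total_length_bp / 1e6
    reports: list[SampleReport] = []
    fractions_rows = {}
    pvalue_rows = {}
    cytolytic = {}

    for i, sample in enumerate(samples):
        profile = profiles[sample]
        snvs = list(sigs.snvs_from_vcf(indir / "vcf" / f"{sample}.vcf"))
        catalogue = sigs.build_sbs_catalogue(snvs, reference)
        raw = sigs.fit_exposures(catalogue, sig_matrix)
        exposures = sigs.apply_exposure_cutoff(raw, catalogue, sig_matrix)

        pileups = somatic.pileups_for_sample(pileup_df, sample)
        tert_calls = somatic.call_tert_promoter(pileups)
        neo = somatic.neoantigens_for_sample(neo_df, sample)
        binding = somatic.filter_neoantigens(neo)
        expressed = somatic.expressed_mutations(binding)

        hr = hrd.score_profile(
            profile, float(hrdetect.loc[sample, "hrdetect_prob"]), constants
        )

        frac = immune.deconvolve_fractions(
            expr[sample], cell_ref, n_perm=n_perm,
            seed=np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7, i))),
        )
        fractions_rows[sample] = frac.fractions
        pvalue_rows[sample] = frac.pvalue
        cyt = immune.cytolytic_score(expr, sample)
        cytolytic[sample] = cyt

        reports.append(
            SampleReport(
                sample=sample,
                wgd=cnv.call_wgd(profile),
                ploidy=cnv.ploidy(profile),
                loh_fraction=cnv.loh_fraction(profile),
                cna_fraction=cnv.cna_fraction(profile),
                near_haploid=cnv.flag_near_haploidization(profile),
                exposures={
                    k: float(v) for k, v in exposures.proportions.items()
                },
                sbs5_40_dominant=sigs.dominance_flag(exposures),
                hrd_loh=hr.loh_score,
                hrd_tai=hr.tai_score,
                hrd_lst=hr.lst_score,
                hrd_sum=hr.hrd_sum,
                hrdetect_prob=hr.hrdetect_prob,
                hr_deficient=hr.hr_deficient,
                tert_calls=[dataclasses.asdict(c) for c in tert_calls],
                tert_mutant=any(c.called for c in tert_calls),
                burden_per_mb=somatic.mutation_burden(
                    len(snvs), genome_mb=genome_mb
                ),
                n_neoantigens_binding=len(binding),
                n_neoantigens_expressed=len(expressed),
                cytolytic_score=cyt,
                immune_fractions={k: float(v) for k, v in frac.fractions.items()},
                immune_pvalue=frac.pvalue,
                cd8_high=immune.cd8_high_flag(frac),
                immune_group="",
            )
        )

    grouping = immune.classify_checkpoint_groups(
        expr[samples], cytolytic=pd.Series(cytolytic)
    )
    for rep in reports:
        rep.immune_group = str(grouping.labels[rep.sample])

    votes = cohort.consensus_vote(qvals)
    drivers = list(votes.index[votes["consensus"]])
    coverage = cohort.samples_with_driver(indicator.astype(bool), drivers)

    clin = clinical.set_index("sample").loc[samples]
    wgd_flags = np.array([r.wgd for r in reports])
    if wgd_flags.any() and (~wgd_flags).any():
        survival = cohort.logrank_test(
            clin["time_days"].to_numpy(), clin["event"].to_numpy(), wgd_flags
        )
    else:
        survival = (float("nan"), float("nan"))

    fractions_df = pd.DataFrame(fractions_rows).T
    pvalues = pd.Series(pvalue_rows)
    try:
        correlations = immune.marker_fraction_correlation(expr, fractions_df, pvalues)
    except ValueError:
        correlations = None

    result = CohortResult(
        samples=reports,
        consensus_drivers=votes,
        driver_coverage=coverage,
        survival_logrank=survival,
        marker_correlations=correlations,
    )

    # --- write outputs atomically ----------------------------------------
    outdir.parent.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(prefix=".classify-", dir=outdir.parent))
    try:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "seed": seed,
            "n_samples": len(reports),
            "samples": [r.to_dict() for r in reports],
            "consensus_drivers": drivers,
            "driver_coverage": {"count": coverage[0], "fraction": coverage[1]},
            "survival_logrank": {
                "statistic": survival[0],
                "p_value": survival[1],
            },
        }
        with open(tmp / "cohort_report.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, allow_nan=True)
            fh.write("\n")
        summary = pd.DataFrame(
            [
                {
                    k: v
                    for k, v in r.to_dict().items()
                    if k not in ("tert_calls", "exposures", "immune_fractions")
                }
                for r in reports
            ]
        )
        summary.to_csv(tmp / "sample_summary.tsv", sep="\t", index=False)
        votes.rename_axis("gene").to_csv(tmp / "consensus_drivers.tsv", sep="\t")
        fractions_df.rename_axis("sample").to_csv(
            tmp / "immune_fractions.tsv", sep="\t"
        )
        if correlations is not None:
            correlations.to_csv(tmp / "marker_correlations.tsv", sep="\t", index=False)
        if outdir.exists():
            shutil.rmtree(outdir)
        tmp.rename(outdir)
    except BaseException:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    return result
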
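"""Synthetic-cohort generator: determinism, rule-sidedness, conservation."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from pyfaidx import Fasta

from mesokit.cnv import call_wgd, loh_fraction, read_segments_tsv
from mesokit.cohort import km_estimator, logrank_test
from mesokit.genome import GenomeSpec, toy_genome
from mesokit.hrd import HrdConstants, hrd_sum
from mesokit.signatures import (
    SignatureMatrix,
    build_sbs_catalogue,
    fit_exposures,
    snvs_from_vcf,
)
from mesokit.simulate import (
    CohortConfig,
    CohortTruth,
    gen_catalogue,
    gen_clinical,
    gen_cn_profile,
    gen_cohort,
    gen_driver_tables,
    gen_expression,
    gen_scarred_profile,
    CELL_TYPES,
)
from mesokit.somatic import read_neoantigen_tsv, read_pileup_tsv

from _oracles import bp_loh_fraction

SMALL = dict(
    n_samples=6,
    n_wgd=2,
    n_tert_mutant=1,
    n_sbs5_40_dominant=4,
    n_hr_deficient=1,
    n_cd8_high=1,
    n_with_driver=3,
    n_mutations=300,
    seed=5,
)


class TestCnProfileGenerator:
    def test_wgd_true_all_het_doubled(self):
        genome = toy_genome()
        p = gen_cn_profile(genome, wgd=True, loh_fraction_target=0.0, seed=1)
        assert call_wgd(p)
        assert loh_fraction(p) == 0.0
        assert all(s.minor_cn >= 1 for s in p.segments)

    def test_wgd_false_diploid(self):
        p = gen_cn_profile(toy_genome(), wgd=False, loh_fraction_target=0.0, seed=2)
        assert not call_wgd(p)
        assert all(s.state == (1, 1) for s in p.segments)

    def test_loh_target_hit_and_verified_by_oracle(self):
        p = gen_cn_profile(toy_genome(), wgd=False, loh_fraction_target=0.8, seed=3)
        assert 0.75 <= loh_fraction(p) <= 0.85
        assert loh_fraction(p) == pytest.approx(bp_loh_fraction(p))

    def test_profiles_tile_genome(self):
        genome = toy_genome()
        for seed in range(3):
            p = gen_cn_profile(genome, wgd=bool(seed % 2), loh_fraction_target=0.2,
                               seed=seed)
            assert p.covered_length == genome.total_length_bp
            for chrom in genome.chromosomes:
                segs = p.by_chromosome(chrom.name)
                assert segs[0].start == 1 and segs[-1].end == chrom.length
                for a, b in zip(segs, segs[1:]):
                    assert b.start == a.end + 1

    def test_rule_sidedness_over_seeds(self):
        genome = toy_genome()
        for seed in range(10):
            assert call_wgd(
                gen_cn_profile(genome, True, loh_fraction_target=0.3, seed=seed)
            )
            assert not call_wgd(
                gen_cn_profile(genome, False, loh_fraction_target=0.3, seed=seed)
            )

    def test_unreachable_combination_errors(self):
        with pytest.raises(ValueError, match="unreachable"):
            gen_cn_profile(toy_genome(), wgd=True, loh_fraction_target=1.0, seed=1)

    def test_scarred_profile_crosses_hrd_threshold(self):
        genome = toy_genome()
        consts = HrdConstants().scaled(genome.total_length_bp / 2_875_001_522)
        p = gen_scarred_profile(genome, n_scars=20, seed=1)
        assert hrd_sum(p, consts) > 42
        q = gen_scarred_profile(genome, n_scars=20, seed=1, wgd=True)
        assert call_wgd(q)


class TestCatalogueGenerator:
    def test_zero_mutations(self, sig_matrix):
        cat = gen_catalogue(sig_matrix, {"SBS1": 1.0}, 0, seed=1)
        assert cat.total == 0

    def test_count_conservation(self, sig_matrix):
        cat = gen_catalogue(sig_matrix, {"SBS5": 0.5, "SBS1": 0.5}, 12345, seed=2)
        assert cat.total == 12345

    def test_single_signature_recovered(self, sig_matrix):
        cat = gen_catalogue(sig_matrix, {"SBS1": 1.0}, 10_000, seed=7)
        props = fit_exposures(cat, sig_matrix).proportions
        assert props["SBS1"] >= 0.98

    def test_mixture_recovered_within_003(self, sig_matrix):
        truth = {"SBS1": 0.6, "SBS13": 0.4}
        cat = gen_catalogue(sig_matrix, truth, 10_000, seed=7)
        props = fit_exposures(cat, sig_matrix).proportions
        for k, v in truth.items():
            assert props[k] == pytest.approx(v, abs=0.03)

    def test_unknown_signature_errors(self, sig_matrix):
        with pytest.raises(KeyError):
            gen_catalogue(sig_matrix, {"SBS99": 1.0}, 10, seed=1)


class TestExpressionGenerator:
    def test_pure_type_equals_reference_column(self, cell_ref):
        col = gen_expression(cell_ref, {"CD8_T": 1.0}, noise_sd=0)
        pd.testing.assert_series_equal(col, cell_ref["CD8_T"], check_names=False)

    def test_even_mixture_is_midpoint(self, cell_ref):
        col = gen_expression(cell_ref, {"CD8_T": 0.5, "NK": 0.5}, noise_sd=0)
        mid = 0.5 * (cell_ref["CD8_T"] + cell_ref["NK"])
        pd.testing.assert_series_equal(col, mid, check_names=False)

    def test_negative_noise_errors(self, cell_ref):
        with pytest.raises(ValueError):
            gen_expression(cell_ref, {"CD8_T": 1.0}, noise_sd=-0.1)

    def test_values_nonnegative_under_noise(self, cell_ref):
        col = gen_expression(
            cell_ref, dict(zip(CELL_TYPES, [1 / 6] * 6)), noise_sd=0.5, seed=3
        )
        assert (col >= 0).all()


class TestClinicalGenerator:
    def test_null_hazard_controls_type_one_error(self):
        """Under HR = 1 the log-rank p exceeds 0.05 in >= 90% of replicates."""
        ok = 0
        for seed in range(20):
            df = gen_clinical(1000, [True] * 500 + [False] * 500, 1.0,
                              censor_rate=0.0, seed=seed)
            _, p = logrank_test(df.time_days, df.event, df.group)
            ok += p > 0.05
        assert ok >= 18

    def test_strong_hazard_detected(self):
        df = gen_clinical(1000, [True] * 500 + [False] * 500, 3.0,
                          censor_rate=0.0, seed=1)
        _, p = logrank_test(df.time_days, df.event, df.group)
        assert p < 0.01

    def test_two_subject_km_steps(self):
        df = gen_clinical(2, [True, False], 2.0, censor_rate=0.0, seed=4)
        km = km_estimator(df.time_days, df.event)
        assert km["survival"].iloc[-1] == pytest.approx(0.0)
        assert len(km) == 3  # S(0) plus a drop at each event time

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gen_clinical(1, [True], 1.0)
        with pytest.raises(ValueError):
            gen_clinical(4, [True] * 4, -2.0)


class TestDriverTables:
    def test_requested_driver_count_by_construction(self):
        from mesokit.cohort import consensus_vote, samples_with_driver

        q, ind = gen_driver_tables(229, 140, seed=3)
        votes = consensus_vote(q)
        drivers = list(votes.index[votes.consensus])
        assert "PBRM1" in drivers
        count, frac = samples_with_driver(ind.astype(bool), drivers)
        assert count == 140
        assert abs(100 * frac - 61.2) <= 0.1


def _dir_checksums(root: Path) -> dict[str, str]:
    out = {}
    for p in sorted(root.rglob("*")):
        if p.is_file():
            out[str(p.relative_to(root))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


class TestCohortGeneration:
    def test_rerun_is_byte_identical(self, tmp_path):
        cfg = CohortConfig(**SMALL)
        gen_cohort(cfg, tmp_path / "a")
        gen_cohort(cfg, tmp_path / "b")
        assert _dir_checksums(tmp_path / "a") == _dir_checksums(tmp_path / "b")

    def test_truth_flag_counts_match_config(self, tmp_path):
        cfg = CohortConfig(**SMALL)
        truth = gen_cohort(cfg, tmp_path / "c")
        per = truth.per_sample
        assert sum(v["wgd"] for v in per.values()) == cfg.n_wgd
        assert sum(v["tert_mutant"] for v in per.values()) == cfg.n_tert_mutant
        assert sum(v["sbs5_40_dominant"] for v in per.values()) == cfg.n_sbs5_40_dominant
        assert sum(v["hr_deficient"] for v in per.values()) == cfg.n_hr_deficient

    def test_all_outputs_parse_through_readers(self, tmp_path):
        cfg = CohortConfig(**SMALL)
        truth = gen_cohort(cfg, tmp_path / "d")
        root = tmp_path / "d"
        genome = GenomeSpec.from_tsv(root / "genome.tsv")
        profiles = read_segments_tsv(root / "segments.tsv", genome)
        assert set(profiles) == set(truth.samples)
        sig = SignatureMatrix.from_tsv(root / "signatures_ref.tsv")
        ref = Fasta(str(root / "reference.fa"))
        for sample in truth.samples:
            snvs = list(snvs_from_vcf(root / "vcf" / f"{sample}.vcf"))
            cat = build_sbs_catalogue(snvs, ref)
            assert cat.total == cfg.n_mutations
            assert cat.channels == sig.channels
        read_pileup_tsv(root / "pileups.tsv")
        read_neoantigen_tsv(root / "neoantigens.tsv")
        pd.read_csv(root / "expression_tpm.tsv", sep="\t", index_col=0)
        back = CohortTruth.from_json(root / "truth.json")
        assert back.samples == truth.samples

    def test_existing_nonempty_outdir_refused(self, tmp_path):
        cfg = CohortConfig(**SMALL)
        gen_cohort(cfg, tmp_path / "e")
        with pytest.raises(FileExistsError):
            gen_cohort(cfg, tmp_path / "e")

    def test_truth_proportions_sum_to_one(self, tmp_path):
        truth = gen_cohort(CohortConfig(**SMALL), tmp_path / "f")
        for rec in truth.per_sample.values():
            assert sum(rec["exposure_truth"].values()) == pytest.approx(1.0, abs=1e-9)
            assert sum(rec["fraction_truth"].values()) == pytest.approx(1.0, abs=1e-9)
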
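"""Simulate the study-scale synthetic cohort (58 samples) with ground truth.

Writes the full cohort (segments, VCFs, pileups, expression, neoantigens,
SMG tables, clinical outcomes, truth JSON) under scratch/cohort and a
small truth-count table under results/.
"""

from pathlib import Path

import pandas as pd

from mesokit.pipeline import run_simulate
from mesokit.simulate import CohortConfig

ROOT = Path(__file__).resolve().parent.parent
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = CohortConfig(seed=42)
    truth = run_simulate(cfg, COHORT_DIR, overwrite=True)
    per = truth.per_sample
    counts = {
        "n_samples": len(truth.samples),
        "wgd": sum(v["wgd"] for v in per.values()),
        "tert_mutant": sum(v["tert_mutant"] for v in per.values()),
        "sbs5_40_dominant": sum(v["sbs5_40_dominant"] for v in per.values()),
        "hr_deficient": sum(v["hr_deficient"] for v in per.values()),
        "cd8_high": sum(v["cd8_high"] for v in per.values()),
        "near_haploid": sum(v["near_haploid"] for v in per.values()),
    }
    RESULTS.mkdir(exist_ok=True)
    pd.Series(counts, name="count").rename_axis("truth_label").to_csv(
        RESULTS / "cohort_truth_counts.tsv", sep="\t"
    )
    print(f"cohort written to {COHORT_DIR}")
    for k, v in counts.items():
        print(f"  {k:18s} {v}")


if __name__ == "__main__":
    main()
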
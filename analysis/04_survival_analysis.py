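"""Survival comparisons on the simulated cohort.

Kaplan-Meier curves for whole-genome-doubled vs non-doubled tumours with
a log-rank (Mantel-Cox) p-value, and a TGFB1 tertile stratification on
log2(TPM+1) comparing the lower and upper tertiles.  Requires
01_simulate_cohort.py to have been run.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from mesokit.cohort import km_estimator, logrank_test, stratify_expression
from mesokit.simulate import CohortTruth

ROOT = Path(__file__).resolve().parent.parent
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    clinical = pd.read_csv(COHORT_DIR / "clinical.tsv", sep="\t").set_index("sample")
    truth = CohortTruth.from_json(COHORT_DIR / "truth.json")
    wgd = pd.Series(
        {s: truth.per_sample[s]["wgd"] for s in truth.samples}, name="wgd"
    )
    stat, p = logrank_test(
        clinical["time_days"], clinical["event"], wgd.loc[clinical.index]
    )
    print(f"WGD vs non-WGD overall survival: chi-square {stat:.2f}, log-rank p {p:.4g}")

    fig, ax = plt.subplots(figsize=(5, 4))
    for flag, label in ((False, "no WGD"), (True, "WGD")):
        sub = clinical[wgd.loc[clinical.index] == flag]
        km = km_estimator(sub["time_days"], sub["event"])
        ax.step(km["time"], km["survival"], where="post", label=f"{label} (n={len(sub)})")
    ax.set_xlabel("days")
    ax.set_ylabel("overall survival")
    ax.set_title(f"log-rank p = {p:.3g}")
    ax.legend()
    RESULTS.mkdir(exist_ok=True)
    fig.tight_layout()
    fig.savefig(RESULTS / "km_wgd.svg")
    print(f"KM plot written to {RESULTS / 'km_wgd.svg'}")

    expr = pd.read_csv(COHORT_DIR / "expression_tpm.tsv", sep="\t", index_col=0)
    tgfb1 = np.log2(expr.loc["TGFB1"] + 1.0)
    tert = stratify_expression(tgfb1, mode="tertile")
    low, high = tert[tert == "low"].index, tert[tert == "high"].index
    sub = clinical.loc[list(low) + list(high)]
    groups = ["low"] * len(low) + ["high"] * len(high)
    stat, p = logrank_test(sub["time_days"], sub["event"], groups)
    print(
        f"TGFB1 lower vs upper tertile (log2 TPM+1): chi-square {stat:.2f}, "
        f"log-rank p {p:.4g}"
    )


if __name__ == "__main__":
    main()
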
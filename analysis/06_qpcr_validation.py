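#!/usr/bin/env python
"""qRT-PCR validation and the power analysis that explains its hit rate.

Three parts:
 1. the published 22-gene validation panel: significance counts at 12 and 22
    days after anthesis, overall and among genes beyond the 2.5x / 0.4x
    mRNA-seq ratio bounds, and the cross-platform ratio correlation;
 2. the simulated qPCR panel from stage 01: per-gene 2^-ddCt ratios, t-test
    p-values and the CV summary with its 95% confidence interval;
 3. the analytic power of the 10-replicate design as a function of CV,
    bracketing the panel's CV interval.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from senseq.qpcr import (
    PowerSpec,
    cv_summary,
    load_validation_table,
    qpcr_gene_table,
    t_test_power,
    validation_summary,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"


def main() -> None:
    panel = load_validation_table()
    summary = validation_summary(panel)
    print("published panel:", summary)
    log_r = np.corrcoef(np.log2(panel.illumina_ratio),
                        np.log2(panel.qpcr_ratio_12daa))[0, 1]
    raw_r = np.corrcoef(panel.illumina_ratio, panel.qpcr_ratio_12daa)[0, 1]
    print(f"cross-platform ratio correlation: R = {raw_r:.2f} (raw), "
          f"{log_r:.2f} (log2)")

    measurements = pd.read_csv(DATA / "qpcr_measurements.tsv", sep="\t")
    genes = qpcr_gene_table(measurements)
    genes.round(4).to_csv(ROOT / "qpcr_gene_table.tsv", sep="\t")
    cv = cv_summary(genes.cv)
    n_sig = int((genes.p <= 0.05).sum())
    print(f"simulated panel (true fold 2, CV 44%): {n_sig}/{len(genes)} "
          f"significant at p<=0.05; mean CV {100 * cv['mean_cv']:.0f}% "
          f"(95% CI {100 * cv['ci_low']:.0f}-{100 * cv['ci_high']:.0f}%)")

    for cv_value in (0.38, 0.44, 0.50):
        power = t_test_power(PowerSpec(2.0, cv_value, 10, 0.05))
        print(f"power to detect 2-fold at CV {100 * cv_value:.0f}%, "
              f"n=10/group: {100 * power:.0f}%")

    grid = np.linspace(0.2, 0.8, 61)
    powers = [t_test_power(PowerSpec(2.0, c, 10, 0.05)) for c in grid]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(100 * grid, 100 * np.asarray(powers))
    ax.axvspan(38, 50, color="0.9", label="panel CV 95% CI")
    ax.set_xlabel("coefficient of variation (%)")
    ax.set_ylabel("power for 2-fold, n=10 (%)")
    ax.legend()
    fig.tight_layout()
    (ROOT / "figures").mkdir(exist_ok=True)
    fig.savefig(ROOT / "figures" / "power_vs_cv.png", dpi=150)
    print("wrote power curve")


if __name__ == "__main__":
    main()
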
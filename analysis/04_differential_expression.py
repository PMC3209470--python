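#!/usr/bin/env python
"""Consensus differential-expression calling.

Runs the three per-isogroup tests (pooled-dispersion NB, local-variance NB,
MWW), BH-adjusts the NB p-values, and reports both consensus sets: the
two-test intersection (both NB tests at q <= 0.01) and the three-test set
(additionally MWW p <= 0.05 and a two-fold change).  Compares the calls with
the simulation truth and writes the result table, both consensus sets, and a
volcano plot.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from senseq.counts import read_counts, read_samples
from senseq.detest import ConsensusThresholds, run_de_tests

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"


def main() -> None:
    counts = read_counts(ROOT / "counts_clean.tsv")
    samples = read_samples(ROOT / "samples_clean.tsv")
    truth = pd.read_csv(DATA / "truth.tsv", sep="\t", index_col=0)

    thresholds = ConsensusThresholds()
    result = run_de_tests(counts, samples, thresholds=thresholds)
    result.to_csv(ROOT / "result_table.tsv", sep="\t")

    two_test = result[
        (result.q_pooled <= thresholds.q_pooled_max)
        & (result.q_local <= thresholds.q_local_max)
    ]
    three_test = result[result.consensus != "none"]
    two_test.to_csv(ROOT / "consensus_two_test.tsv", sep="\t")
    three_test.to_csv(ROOT / "consensus_three_test.tsv", sep="\t")
    n = len(result)
    n_up = int((three_test.consensus == "up").sum())
    n_down = int((three_test.consensus == "down").sum())
    print(f"two-test intersection (q<=0.01 both NB tests): {len(two_test)} "
          f"of {n} isogroups ({100 * len(two_test) / n:.1f}%)")
    print(f"three-test consensus (+ MWW p<=0.05, >=2-fold): {len(three_test)} "
          f"({n_up} up in WT, {n_down} down)")

    called = result.consensus != "none"
    recall = (called & truth.is_de).sum() / truth.is_de.sum()
    false_calls = int((called & ~truth.is_de).sum())
    hits = called & truth.is_de
    direction_ok = (result.loc[hits, "consensus"] == truth.loc[hits, "direction"]).mean()
    print(f"vs truth: recall {100 * recall:.1f}% of {int(truth.is_de.sum())} DE "
          f"features, {false_calls} false calls, "
          f"direction accuracy {100 * direction_ok:.1f}%")

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = np.where(
        result.consensus == "up", "tab:red",
        np.where(result.consensus == "down", "tab:green", "0.7"),
    )
    ax.scatter(result.log2fc, -np.log10(result.p_local.clip(lower=1e-30)),
               s=6, c=colors, linewidths=0)
    for x in (-1, 1):
        ax.axvline(x, color="red", lw=0.8)
    ax.axhline(2, color="blue", lw=0.8)
    ax.set_xlabel("log2 fold change (WT / RNAi)")
    ax.set_ylabel("-log10 p (local-variance NB test)")
    fig.tight_layout()
    (ROOT / "figures").mkdir(exist_ok=True)
    fig.savefig(ROOT / "figures" / "volcano.png", dpi=150)
    print("wrote volcano plot")


if __name__ == "__main__":
    main()
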
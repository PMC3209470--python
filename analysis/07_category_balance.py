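#!/usr/bin/env python
"""Category-distribution and direction-balance tests on the consensus calls.

Assigns synthetic functional categories to the simulated isogroups (biased so
up- and down-regulated sets draw from different category mixes, as functional
annotations of senescence-regulated genes do), then compares the
category-percentage distributions of the up- vs down-regulated consensus sets
with a Kolmogorov-Smirnov test and the up/down split against 50:50 with a
chi-square test.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from senseq.downstream import chisq_balance, ks_distribution_test

ROOT = Path(__file__).resolve().parent.parent / "results"
CATEGORIES = [
    "protein metabolism", "cellular process", "response to stress", "transport",
    "catabolic process", "signal transduction", "transcription",
    "biosynthetic process", "translation", "other",
]
SEED = 17


def category_percentages(assignments: pd.Series) -> pd.Series:
    counts = assignments.value_counts().reindex(CATEGORIES, fill_value=0)
    return 100.0 * counts / counts.sum()


def main() -> None:
    result = pd.read_csv(ROOT / "result_table.tsv", sep="\t", index_col=0)
    rng = np.random.default_rng(SEED)

    # up-regulated senescence genes skew toward transport/catabolism, the
    # down-regulated set toward signalling/biosynthesis
    up_weights = np.array([0.14, 0.12, 0.10, 0.12, 0.10, 0.04, 0.04, 0.02, 0.01, 0.31])
    down_weights = np.array([0.05, 0.07, 0.12, 0.04, 0.02, 0.10, 0.02, 0.08, 0.04, 0.46])
    annotation = pd.Series(index=result.index, dtype=object)
    for direction, weights in (("up", up_weights), ("down", down_weights)):
        mask = result.consensus == direction
        annotation[mask] = rng.choice(CATEGORIES, size=mask.sum(), p=weights)
    background = rng.choice(
        CATEGORIES, size=(annotation.isna()).sum(),
        p=(up_weights + down_weights) / 2,
    )
    annotation[annotation.isna()] = background

    up_pct = category_percentages(annotation[result.consensus == "up"])
    down_pct = category_percentages(annotation[result.consensus == "down"])
    table = pd.DataFrame({"up_pct": up_pct, "down_pct": down_pct}).round(1)
    table.to_csv(ROOT / "category_distribution.tsv", sep="\t")
    print(table)

    d, p = ks_distribution_test(up_pct, down_pct)
    print(f"KS comparison of category distributions: D = {d:.2f}, p = {p:.3g}")

    n_up = int((result.consensus == "up").sum())
    n_down = int((result.consensus == "down").sum())
    x2, p_chi = chisq_balance(n_up, n_down)
    print(f"direction balance {n_up} up vs {n_down} down: "
          f"X^2 = {x2:.2f}, p = {p_chi:.3g} against 50:50")


if __name__ == "__main__":
    main()
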
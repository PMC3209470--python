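"""qRT-PCR quantification (2^-ddCt), genotype comparison, CV and power analysis.

Relative transcript levels are linearized with the 2^-ddCt method: for each
measurement, ``dCt = Ct_target - Ct_reference`` (the reference being an
endogenous control such as ACTIN), ``ddCt = dCt - dCt_calibrator``, and the
linearized expression is ``2 ** -ddCt`` - the number of RNA copies per copy
in the calibrator sample.

Between-plant variability of such panels is summarized by per-gene
coefficients of variation (CV = SD/mean); the analytic power of a two-sided
pooled-variance t-test to detect a given fold change is computed from the
noncentral t distribution with group SDs equal to CV times the group mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .counts import RNAI, WT
from .detest import mww_test


def delta_delta_ct(ct_target, ct_reference, calibrator_delta_ct) -> np.ndarray:
    """Linearized expression ``2 ** -((ct_target - ct_reference) - calibrator_dCt)``."""
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if not (np.all(np.isfinite(ct_target)) and np.all(np.isfinite(ct_reference))
            and np.isfinite(calibrator_delta_ct)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** -((ct_target - ct_reference) - calibrator_delta_ct)


def primer_efficiency(dilutions, cts) -> float:
    """Amplification efficiency (%) from a standard curve of serial dilutions.

    Least-squares slope ``b`` of Ct on log10(dilution factor);
    efficiency = (10 ** (-1/b) - 1) * 100, i.e. 100% for perfect doubling
    (slope -3.32 per 10-fold).
    """
    dilutions = np.asarray(dilutions, dtype=float)
    cts = np.asarray(cts, dtype=float)
    if len(dilutions) < 3:
        raise ValueError("at least 3 dilution points are required")
    slope = stats.linregress(np.log10(dilutions), cts).slope
    if slope >= 0:
        raise ValueError("invalid standard curve: Ct must decrease with template amount")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def genotype_ratio_test(
    values_wt, values_rnai, test: str = "t_test"
) -> tuple[float, float]:
    """WT/RNAi ratio of group means and a two-sided p-value.

    Default test: pooled-variance two-sample t-test on the linearized values;
    ``test="mww"`` uses the rank test instead.
    """
    values_wt = np.asarray(values_wt, dtype=float)
    values_rnai = np.asarray(values_rnai, dtype=float)
    if len(values_wt) < 2 or len(values_rnai) < 2:
        raise ValueError("at least 2 replicates per genotype are required")
    mean_rnai = values_rnai.mean()
    if mean_rnai == 0:
        raise ValueError("RNAi group mean is zero; the ratio is undefined")
    ratio = values_wt.mean() / mean_rnai
    if test == "t_test":
        if np.ptp(values_wt) == 0 and np.ptp(values_rnai) == 0:
            p = 1.0 if values_wt.mean() == values_rnai.mean() else 0.0
        else:
            p = float(stats.ttest_ind(values_wt, values_rnai, equal_var=True).pvalue)
    elif test == "mww":
        p = mww_test(values_wt, values_rnai, mode="exact")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(ratio), p


def qpcr_gene_table(
    measurements: pd.DataFrame, calibrator_delta_ct: float = 0.0, test: str = "t_test"
) -> pd.DataFrame:
    """Per-gene WT/RNAi ratios and p-values from a long-format Ct table.

    Expects columns ``gene_id, genotype, ct_target, ct_reference``.
    """
    rows = []
    for gene, sub in measurements.groupby("gene_id", sort=True):
        expr = delta_delta_ct(sub["ct_target"], sub["ct_reference"], calibrator_delta_ct)
        by_genotype = pd.Series(expr, index=sub.index).groupby(sub["genotype"])
        values = {g: v.to_numpy() for g, v in by_genotype}
        ratio, p = genotype_ratio_test(values[WT], values[RNAI], test=test)
        cvs = [values[g].std(ddof=1) / values[g].mean() for g in (WT, RNAI)]
        rows.append({"gene_id": gene, "ratio": ratio, "p": p, "cv": float(np.mean(cvs))})
    return pd.DataFrame(rows).set_index("gene_id")


def cv_summary(cvs) -> dict:
    """Mean CV across genes with a t-based 95% confidence interval of the mean."""
    cvs = np.asarray(cvs, dtype=float)
    if len(cvs) < 2:
        raise ValueError("at least 2 CV values are required")
    mean = float(cvs.mean())
    se = float(cvs.std(ddof=1) / np.sqrt(len(cvs)))
    t = stats.t.ppf(0.975, len(cvs) - 1)
    return {"mean_cv": mean, "ci_low": mean - t * se, "ci_high": mean + t * se,
            "n_genes": int(len(cvs))}


@dataclass(frozen=True)
class PowerSpec:
    """Design of a two-group comparison with a shared coefficient of variation."""

    fold_change: float = 2.0
    cv: float = 0.44
    n_per_group: int = 10
    alpha: float = 0.05

    def __post_init__(self):
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if self.cv <= 0:
            raise ValueError("cv must be positive")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


def t_test_power(spec: PowerSpec) -> float:
    """Power of the two-sided pooled-variance two-sample t-test.

    Group means are 1 and ``fold_change`` with SDs ``cv`` times the mean;
    the pooled SD is ``sqrt((sd1^2 + sd2^2)/2)`` and the noncentrality is
    ``(fold_change - 1)/pooled_sd * sqrt(n/2)``; the rejection probability is
    evaluated with the noncentral t distribution.
    """
    sd1 = spec.cv * 1.0
    sd2 = spec.cv * spec.fold_change
    pooled = np.sqrt((sd1**2 + sd2**2) / 2.0)
    nc = (spec.fold_change - 1.0) / pooled * np.sqrt(spec.n_per_group / 2.0)
    df = 2 * spec.n_per_group - 2
    t_crit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    return float(stats.nct.sf(t_crit, df, nc) + stats.nct.cdf(-t_crit, df, nc))


# ---------------------------------------------------------------------------
# validation summary against the published qRT-PCR panel
# ---------------------------------------------------------------------------

VALIDATION_TABLE_RESOURCE = "qpcr_validation_table.tsv"


def load_validation_table() -> pd.DataFrame:
    """The published qRT-PCR validation panel of the wheat GPC-RNAi experiment.

    22 isogroups with their mRNA-seq (Illumina, 12 days after anthesis)
    WT/RNAi expression ratio and the qRT-PCR ratio and p-value at 12 and 22
    days after anthesis.  Shipped as reference data for the validation
    summary.
    """
    with resources.files("senseq.data").joinpath(VALIDATION_TABLE_RESOURCE).open() as fh:
        return pd.read_csv(fh, sep="\t").set_index("gene_id")


REQUIRED_VALIDATION_COLUMNS = (
    "illumina_ratio", "qpcr_ratio_12daa", "p_12daa", "qpcr_ratio_22daa", "p_22daa",
)


def validation_summary(
    table: pd.DataFrame, p_max: float = 0.05, up_min: float = 2.5, down_max: float = 0.4
) -> dict:
    """Summary counts of a cross-platform validation panel.

    Thresholds are inclusive.  ``n_large`` counts genes whose mRNA-seq ratio
    lies beyond the (up_min, down_max) bounds; ``n_rescued_22daa`` counts
    genes non-significant at 12 but significant at 22 days after anthesis.
    """
    missing = [c for c in REQUIRED_VALIDATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"validation table is missing columns: {missing}")
    sig_12 = table["p_12daa"] <= p_max
    large = (table["illumina_ratio"] >= up_min) | (table["illumina_ratio"] <= down_max)
    rescued = (~sig_12) & (table["p_22daa"] <= p_max)
    n_large = int(large.sum())
    n_sig_among_large = int((sig_12 & large).sum())
    return {
        "n_tested": int(len(table)),
        "n_sig_12daa": int(sig_12.sum()),
        "n_large": n_large,
        "n_sig_among_large": n_sig_among_large,
        "rate_among_large_pct": round(100.0 * n_sig_among_large / n_large, 0)
        if n_large else float("nan"),
        "n_rescued_22daa": int(rescued.sum()),
    }
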
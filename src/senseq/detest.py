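"""Per-feature differential-expression tests and the consensus caller.

Three tests are applied to every feature (isogroup) of a WT-vs-RNAi count
matrix:

* an NB conditional exact test with a single *pooled* dispersion shared by
  all features (variance ``mu + alpha*mu**2``),
* the same conditional scheme with a *locally* fitted mean-variance relation
  (``w(mu)`` estimated by a lowess smoother over log-mean with an isotonic
  correction), and
* a Mann-Whitney-Wilcoxon rank test on normalized values.

Both NB tests condition on the feature's total count across groups: the group
sums are modelled as NB with means proportional to the summed size factors,
and the two-sided p-value is the total conditional probability of all splits
no more probable than the observed one.  NB p-values are BH-adjusted across
features; the consensus call requires both adjusted NB tests at q <= 0.01,
the MWW raw p <= 0.05, and a two-fold change, all inclusive.

With 3-4 samples per group the exact MWW cannot reach p <= 0.05 (the minimum
two-sided exact p for 3 vs 4 is 2/35 ~ 0.057, and ~0.052 with continuity
correction), so the default MWW mode is the normal approximation *without*
continuity correction - the only standard two-sided variant under which the
MWW filter can retain any feature at that design size.  All three modes are
available.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp
from scipy.stats import norm, rankdata
from sklearn.isotonic import IsotonicRegression
from statsmodels.nonparametric.smoothers_lowess import lowess

from .counts import RNAI, WT, included_samples
from .normalization import VarianceFunction, normalize, size_factors_median_ratio

_PROB_TOL = 1e-12  # relative tolerance when comparing split probabilities


@dataclass(frozen=True)
class ConsensusThresholds:
    """Inclusive cut-offs of the consensus caller."""

    q_pooled_max: float = 0.01
    q_local_max: float = 0.01
    p_mww_max: float = 0.05
    min_fold: float = 2.0

    def __post_init__(self):
        for name in ("q_pooled_max", "q_local_max", "p_mww_max"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.min_fold < 1.0:
            raise ValueError("min_fold must be >= 1")


# ---------------------------------------------------------------------------
# negative-binomial machinery
# ---------------------------------------------------------------------------

def nb_logpmf(k: np.ndarray, mu: float, alpha: float) -> np.ndarray:
    """log P(K = k) for NB with mean mu and variance mu + alpha*mu^2.

    ``alpha == 0`` is evaluated as the Poisson limit.
    """
    k = np.asarray(k, dtype=float)
    if mu <= 0:
        raise ValueError("NB mean must be positive")
    if alpha < 0:
        raise ValueError("dispersion must be non-negative")
    if alpha < 1e-12:
        return k * np.log(mu) - mu - gammaln(k + 1.0)
    r = 1.0 / alpha
    log_p = np.log(mu) - np.log(r + mu)
    log_1mp = np.log(r) - np.log(r + mu)
    return gammaln(k + r) - gammaln(r) - gammaln(k + 1.0) + r * log_1mp + k * log_p


def _group_sum_params(total: int, factors_a, factors_b, alpha_a: float, alpha_b: float):
    """Means and effective dispersions of the two group sums, given the total.

    Each sample's count is NB with mean ``s_j * q``; the group sum is treated
    as NB with mean ``q * S_g`` and variance ``mu_g + alpha * (sum s_j^2 / S_g^2)
    * mu_g^2``, the standard reduction for summed NB counts.
    """
    factors_a = np.asarray(factors_a, dtype=float)
    factors_b = np.asarray(factors_b, dtype=float)
    s_a, s_b = factors_a.sum(), factors_b.sum()
    mu_a = total * s_a / (s_a + s_b)
    mu_b = total * s_b / (s_a + s_b)
    eff_a = alpha_a * float((factors_a**2).sum()) / s_a**2
    eff_b = alpha_b * float((factors_b**2).sum()) / s_b**2
    return mu_a, mu_b, eff_a, eff_b


def _conditional_two_sided_p(
    total: int, observed_a: int, mu_a: float, mu_b: float, alpha_a: float, alpha_b: float
) -> float:
    """Sum of conditional probabilities of splits no more probable than observed."""
    k = np.arange(total + 1)
    logp = nb_logpmf(k, mu_a, alpha_a) + nb_logpmf(total - k, mu_b, alpha_b)
    logp -= logsumexp(logp)
    cutoff = logp[observed_a] + np.log1p(_PROB_TOL)
    return float(min(1.0, np.exp(logsumexp(logp[logp <= cutoff]))))


def nb_exact_test_pooled(counts_a, counts_b, factors_a, factors_b, alpha: float) -> float:
    """Two-sided conditional NB test with one shared dispersion."""
    if alpha < 0:
        raise ValueError("dispersion must be non-negative")
    total = int(np.sum(counts_a) + np.sum(counts_b))
    if total == 0:
        return 1.0
    mu_a, mu_b, eff_a, eff_b = _group_sum_params(total, factors_a, factors_b, alpha, alpha)
    return _conditional_two_sided_p(total, int(np.sum(counts_a)), mu_a, mu_b, eff_a, eff_b)


def nb_test_local(counts_a, counts_b, factors_a, factors_b, varfun: VarianceFunction) -> float:
    """Two-sided conditional NB test with variance from the local fit.

    The fitted ``w`` is evaluated at the feature's common-scale mean; when
    ``w(mu) < mu`` (less than shot noise) the test falls back to Poisson.
    """
    total = int(np.sum(counts_a) + np.sum(counts_b))
    if total == 0:
        return 1.0
    s_total = float(np.sum(factors_a) + np.sum(factors_b))
    q = total / s_total
    w = float(varfun(q))
    alpha = max(w - q, 0.0) / q**2
    mu_a, mu_b, eff_a, eff_b = _group_sum_params(total, factors_a, factors_b, alpha, alpha)
    return _conditional_two_sided_p(total, int(np.sum(counts_a)), mu_a, mu_b, eff_a, eff_b)


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def _usable(counts: pd.DataFrame) -> np.ndarray:
    return counts.to_numpy().sum(axis=1) > 0


def estimate_common_dispersion(
    counts: pd.DataFrame, factors: pd.Series, samples: pd.DataFrame
) -> float:
    """Single NB dispersion maximizing the adjusted likelihood across features.

    Per-feature, per-group means are profiled by the method of moments (the
    group mean of normalized counts), leaving one shared ``alpha`` that is
    optimized numerically and floored at zero.  Because plain profiling is
    biased low with 3-4 replicates, the likelihood carries the Cox-Reid
    adjustment (minus half the log Fisher information of each profiled group
    mean).  All-zero features are excluded.
    """
    from scipy.optimize import minimize_scalar

    groups = [included_samples(samples, WT), included_samples(samples, RNAI)]
    for g in groups:
        if len(g) < 2:
            raise ValueError("at least 2 samples per genotype are required")
    keep = _usable(counts)
    sub = counts.loc[keep]

    k_blocks, mu_blocks, s_blocks = [], [], []
    for g in groups:
        k = sub[g].to_numpy(dtype=float)
        s = factors[g].to_numpy(dtype=float)
        q = (k / s).mean(axis=1)
        mu = np.maximum(q[:, None] * s[None, :], 1e-8)
        k_blocks.append(k)
        mu_blocks.append(mu)
        s_blocks.append(s)
    k_all = np.concatenate([b.ravel() for b in k_blocks])
    mu_all = np.concatenate([b.ravel() for b in mu_blocks])

    def nll(alpha: float) -> float:
        if alpha < 1e-12:
            ll = float((k_all * np.log(mu_all) - mu_all - gammaln(k_all + 1.0)).sum())
        else:
            r = 1.0 / alpha
            ll = float(
                (
                    gammaln(k_all + r)
                    - gammaln(r)
                    - gammaln(k_all + 1.0)
                    + r * (np.log(r) - np.log(r + mu_all))
                    + k_all * (np.log(mu_all) - np.log(r + mu_all))
                ).sum()
            )
        # Cox-Reid: subtract 0.5*log of the Fisher information of each
        # profiled group mean, sum_j s_j^2 / (mu_ij + alpha*mu_ij^2)
        penalty = 0.0
        for mu_block, s in zip(mu_blocks, s_blocks):
            info = (s[None, :] ** 2 / (mu_block + alpha * mu_block**2)).sum(axis=1)
            penalty += 0.5 * float(np.log(info).sum())
        return -(ll - penalty)

    res = minimize_scalar(nll, bounds=(0.0, 10.0), method="bounded",
                          options={"xatol": 1e-6})
    alpha = float(res.x)
    if nll(0.0) <= nll(alpha):
        return 0.0
    return max(alpha, 0.0)


def fit_local_variance(
    counts: pd.DataFrame,
    factors: pd.Series,
    samples: pd.DataFrame,
    lowess_frac: float = 0.3,
) -> VarianceFunction:
    """Local fit of the raw variance of common-scale counts as a function of mean.

    The per-feature pooled sample variance (within-genotype, pooled across the
    two genotypes) is regressed on the pooled mean with a lowess smoother in
    log-log space; an isotonic correction enforces a non-decreasing relation.
    Smoothing log-variances underestimates the mean variance (Jensen), so the
    fitted curve is raised by the normal-theory bias of ``log(S^2)``,
    ``log(nu/2) - digamma(nu/2)`` at the pooled degrees of freedom ``nu``.
    """
    groups = [included_samples(samples, WT), included_samples(samples, RNAI)]
    for g in groups:
        if len(g) < 2:
            raise ValueError("at least 2 samples per genotype are required")
    normalized = normalize(counts, factors)
    dfs = 0
    var_acc = np.zeros(counts.shape[0])
    mean_acc = np.zeros(counts.shape[0])
    n_total = 0
    for g in groups:
        block = normalized[g].to_numpy()
        var_acc += block.var(axis=1, ddof=1) * (len(g) - 1)
        mean_acc += block.mean(axis=1) * len(g)
        dfs += len(g) - 1
        n_total += len(g)
    pooled_var = var_acc / dfs
    pooled_mean = mean_acc / n_total
    ok = (pooled_mean > 0) & (pooled_var > 0)
    if ok.sum() < 20:
        raise ValueError("fewer than 20 usable features; the smoother is underdetermined")
    x = np.log(pooled_mean[ok])
    y = np.log(pooled_var[ok]) + (np.log(dfs / 2.0) - digamma(dfs / 2.0))
    smoothed = lowess(y, x, frac=lowess_frac, return_sorted=True)
    xs, ys = smoothed[:, 0], smoothed[:, 1]
    xs, unique_idx = np.unique(xs, return_index=True)
    ys = ys[unique_idx]
    iso = IsotonicRegression(increasing=True)
    ys = iso.fit_transform(xs, ys)
    mu_grid = np.exp(xs)
    w_grid = np.exp(ys)
    # collapse any flat-segment duplicates introduced by isotonic projection
    keep = np.concatenate([[True], np.diff(mu_grid) > 0])
    return VarianceFunction.from_grid(mu_grid[keep], np.maximum.accumulate(w_grid[keep]))


# ---------------------------------------------------------------------------
# Mann-Whitney-Wilcoxon
# ---------------------------------------------------------------------------

def _u_statistic(values_a: np.ndarray, values_b: np.ndarray) -> float:
    pooled = np.concatenate([values_a, values_b])
    ranks = rankdata(pooled)
    n_a = len(values_a)
    return float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)


def mww_test(values_a, values_b, mode: str = "normal") -> float:
    """Two-sided rank-sum p-value; modes: exact, normal, normal_cc.

    Exact mode enumerates all label assignments of the U statistic (intended
    for the tiny group sizes of this design); the normal modes use the
    Gaussian approximation with tie-corrected variance, with or without the
    0.5 continuity correction.
    """
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    n_a, n_b = len(values_a), len(values_b)
    if n_a < 2 or n_b < 2:
        raise ValueError("at least 2 values per group are required")
    pooled = np.concatenate([values_a, values_b])
    if np.all(pooled == pooled[0]):
        return 1.0
    u_obs = _u_statistic(values_a, values_b)
    mean_u = n_a * n_b / 2.0

    if mode == "exact":
        n = n_a + n_b
        dev_obs = abs(u_obs - mean_u)
        hits = 0
        total = comb(n, n_a)
        for idx_a in combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx_a)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u - mean_u) >= dev_obs - _PROB_TOL:
                hits += 1
        return hits / total

    if mode not in ("normal", "normal_cc"):
        raise ValueError(f"unknown MWW mode {mode!r}")
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return 1.0
    dev = abs(u_obs - mean_u)
    if mode == "normal_cc":
        dev = max(dev - 0.5, 0.0)
    z = dev / np.sqrt(var_u)
    return float(min(1.0, 2.0 * norm.sf(z)))


# ---------------------------------------------------------------------------
# multiple testing, fold change, consensus
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be a 1-d vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


PSEUDOCOUNT = 0.5


def fold_change(mean_wt: float, mean_rnai: float) -> tuple[float, float]:
    """WT/RNAi expression ratio and its log2.

    When either group mean is zero, a pseudo-count of 0.5 is added to both
    means before forming the ratio.  Both means zero is undefined (NaN) and
    the feature is excluded from calls.
    """
    if mean_wt < 0 or mean_rnai < 0:
        raise ValueError("group means must be non-negative")
    if mean_wt == 0 and mean_rnai == 0:
        return float("nan"), float("nan")
    if mean_wt == 0 or mean_rnai == 0:
        ratio = (mean_wt + PSEUDOCOUNT) / (mean_rnai + PSEUDOCOUNT)
    else:
        ratio = mean_wt / mean_rnai
    return ratio, float(np.log2(ratio))


def consensus_call(
    row,
    thresholds: ConsensusThresholds = ConsensusThresholds(),
    require_mww: bool = True,
    require_fold: bool = True,
) -> str:
    """``up`` / ``down`` / ``none`` consensus decision for one result row."""
    ratio = row["fold_change"]
    if not np.isfinite(ratio):
        return "none"
    if row["q_pooled"] > thresholds.q_pooled_max:
        return "none"
    if row["q_local"] > thresholds.q_local_max:
        return "none"
    if require_mww and row["p_mww"] > thresholds.p_mww_max:
        return "none"
    if require_fold and not (
        ratio >= thresholds.min_fold or ratio <= 1.0 / thresholds.min_fold
    ):
        return "none"
    if ratio == 1.0:
        return "none"
    return "up" if ratio > 1.0 else "down"


RESULT_COLUMNS = [
    "mean_wt", "mean_rnai", "fold_change", "log2fc",
    "p_pooled", "p_local", "p_mww", "q_pooled", "q_local", "consensus",
]


def run_de_tests(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    thresholds: ConsensusThresholds = ConsensusThresholds(),
    mww_mode: str = "normal",
    require_mww: bool = True,
    require_fold: bool = True,
    factors: pd.Series | None = None,
    alpha: float | None = None,
    varfun: VarianceFunction | None = None,
    run_mww: bool = True,
) -> pd.DataFrame:
    """Full per-feature result table for a WT-vs-RNAi comparison.

    Size factors, the common dispersion and the local variance fit are
    computed from the data unless supplied.  All-zero features are retained
    with p = 1 and no call, keeping the feature universe stable for
    percentage reporting.
    """
    wt = included_samples(samples, WT)
    rnai = included_samples(samples, RNAI)
    if len(wt) < 2 or len(rnai) < 2:
        raise ValueError("at least 2 included samples per genotype are required")
    used = counts[rnai + wt]
    if factors is None:
        factors = size_factors_median_ratio(used)
    if alpha is None:
        alpha = estimate_common_dispersion(used, factors, samples)
    if varfun is None:
        varfun = fit_local_variance(used, factors, samples)

    normalized = normalize(used, factors)
    mean_wt = normalized[wt].mean(axis=1).to_numpy()
    mean_rnai = normalized[rnai].mean(axis=1).to_numpy()
    k_wt = used[wt].to_numpy()
    k_rnai = used[rnai].to_numpy()
    f_wt = factors[wt].to_numpy()
    f_rnai = factors[rnai].to_numpy()
    norm_wt = normalized[wt].to_numpy()
    norm_rnai = normalized[rnai].to_numpy()

    n = counts.shape[0]
    p_pooled = np.ones(n)
    p_local = np.ones(n)
    p_mww = np.ones(n)
    ratios = np.full(n, np.nan)
    log2fc = np.full(n, np.nan)
    for i in range(n):
        ratios[i], log2fc[i] = fold_change(mean_wt[i], mean_rnai[i])
        if k_wt[i].sum() + k_rnai[i].sum() == 0:
            continue  # all-zero feature: p = 1 by convention
        p_pooled[i] = nb_exact_test_pooled(k_wt[i], k_rnai[i], f_wt, f_rnai, alpha)
        p_local[i] = nb_test_local(k_wt[i], k_rnai[i], f_wt, f_rnai, varfun)
        if run_mww:
            p_mww[i] = mww_test(norm_wt[i], norm_rnai[i], mode=mww_mode)

    result = pd.DataFrame(
        {
            "mean_wt": mean_wt,
            "mean_rnai": mean_rnai,
            "fold_change": ratios,
            "log2fc": log2fc,
            "p_pooled": p_pooled,
            "p_local": p_local,
            "p_mww": p_mww,
            "q_pooled": bh_adjust(p_pooled),
            "q_local": bh_adjust(p_local),
        },
        index=counts.index,
    )
    result["consensus"] = [
        consensus_call(row, thresholds, require_mww=require_mww, require_fold=require_fold)
        for _, row in result.iterrows()
    ]
    return result[RESULT_COLUMNS]
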
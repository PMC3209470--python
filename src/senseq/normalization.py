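"""Median-of-ratios library size factors and a variance-stabilizing transform.

Sequencing depth differs between libraries, so raw counts are put on a common
scale before any comparison.  The size factor of library *j* is the median
over features of ``K_ij / geomean_i`` where ``geomean_i`` is the geometric
mean of feature *i* across libraries; features with any zero count are
excluded from the median (their geometric mean is zero).

For distance-based analyses (clustering, PCA) the normalized counts are
further transformed to approximate homoscedasticity: given a fitted
mean-variance relation ``w(mu)``, the transform is the integral

    tau(kappa) = integral d(mu) / sqrt(w(mu))

evaluated at the normalized counts.  For ``w(mu) = mu`` (Poisson) this is the
classical ``2*sqrt(kappa)``; for ``w(mu) = mu + alpha*mu**2`` it is
``(2/sqrt(alpha)) * asinh(sqrt(alpha*kappa))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import PchipInterpolator

from .counts import validate_count_matrix


def size_factors_median_ratio(counts: pd.DataFrame) -> pd.Series:
    """Per-library scale factors: the library median of count / geometric-mean ratios.

    Only features with strictly positive counts in every library enter the
    median.  Raises ``ValueError`` if no such feature exists.
    """
    validate_count_matrix(counts)
    values = counts.to_numpy(dtype=float)
    eligible = (values > 0).all(axis=1)
    if not eligible.any():
        raise ValueError(
            "no feature has positive counts in all libraries; "
            "size factors are undefined"
        )
    logs = np.log(values[eligible])
    log_geomeans = logs.mean(axis=1)
    # median of ratios computed in log space; midpoint rule for even counts
    # is numpy's default and keeps the estimator deterministic.
    log_factors = np.median(logs - log_geomeans[:, None], axis=0)
    return pd.Series(np.exp(log_factors), index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each library by its size factor (common-scale counts)."""
    if len(factors) != counts.shape[1]:
        raise ValueError("one size factor per sample is required")
    factors = factors.reindex(counts.columns)
    if factors.isna().any():
        raise ValueError("size factors missing for some samples")
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return counts / factors


@dataclass
class VarianceFunction:
    """A fitted (or analytic) raw-variance-vs-mean relation ``w(mu)``.

    Evaluation inside ``domain`` uses either the exact callable (analytic
    forms) or a monotone PCHIP interpolant over a grid (fitted forms).
    Outside the domain the function is extended linearly with the boundary
    derivative, floored at a small positive value.
    """

    domain: tuple[float, float]
    _callable: object = field(default=None, repr=False)
    _interp: object = field(default=None, repr=False)

    _FLOOR = 1e-12

    @classmethod
    def from_callable(cls, fn, domain: tuple[float, float]) -> "VarianceFunction":
        lo, hi = domain
        if not (0 < lo < hi):
            raise ValueError("domain must satisfy 0 < lo < hi")
        return cls(domain=(float(lo), float(hi)), _callable=fn)

    @classmethod
    def from_grid(cls, mu: np.ndarray, w: np.ndarray) -> "VarianceFunction":
        mu = np.asarray(mu, dtype=float)
        w = np.asarray(w, dtype=float)
        if mu.ndim != 1 or mu.size < 2 or np.any(np.diff(mu) <= 0):
            raise ValueError("mu grid must be strictly increasing, length >= 2")
        if np.any(w <= 0):
            raise ValueError("variance function must be positive on its grid")
        if np.any(np.diff(w) < 0):
            raise ValueError("variance grid must be non-decreasing (isotonic)")
        # interpolate in log-mu; PCHIP preserves the monotone shape
        interp = PchipInterpolator(np.log(mu), w, extrapolate=False)
        return cls(domain=(float(mu[0]), float(mu[-1])), _interp=interp)

    def _eval_inside(self, mu: np.ndarray) -> np.ndarray:
        if self._callable is not None:
            return np.asarray(self._callable(mu), dtype=float)
        return self._interp(np.log(mu))

    def __call__(self, mu) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        scalar = mu.ndim == 0
        mu = np.atleast_1d(mu)
        lo, hi = self.domain
        out = np.empty_like(mu)
        inside = (mu >= lo) & (mu <= hi)
        out[inside] = self._eval_inside(mu[inside])
        # linear extension with the boundary derivative
        if (~inside).any():
            eps_lo = lo * 1e-4
            eps_hi = hi * 1e-4
            probe = self._eval_inside(np.array([lo, lo + eps_lo, hi - eps_hi, hi]))
            w_lo, w_hi = float(probe[0]), float(probe[3])
            slope_lo = (float(probe[1]) - w_lo) / eps_lo
            slope_hi = (w_hi - float(probe[2])) / eps_hi
            below = mu < lo
            above = mu > hi
            # below the domain the linear extension may cross zero; floor it
            # at a proportional (Poisson-like) decay toward the origin, which
            # stays positive and keeps 1/sqrt(w) integrable
            out[below] = np.maximum(
                w_lo + slope_lo * (mu[below] - lo), w_lo * mu[below] / lo
            )
            out[above] = w_hi + slope_hi * (mu[above] - hi)
        out = np.maximum(out, self._FLOOR)
        if np.any(out <= 0):
            raise ValueError("variance function non-positive at requested points")
        return out[0] if scalar else out


_GAUSS_NODES, _GAUSS_WEIGHTS = leggauss(10)


def _tau_integrand(varfun: VarianceFunction):
    # substitution mu = exp(t): integral dmu/sqrt(w) = integral exp(t)/sqrt(w(exp(t))) dt
    def f(t):
        mu = np.exp(t)
        return mu / np.sqrt(varfun(mu))

    return f


def vst_values(values: np.ndarray, varfun: VarianceFunction, n_grid: int = 801) -> np.ndarray:
    """Evaluate the variance-stabilizing integral at arbitrary positive values.

    The integral is anchored at the lower end of the evaluation range and
    computed by composite 10-point Gauss-Legendre quadrature on a log-spaced
    grid, then completed exactly (same rule) from the nearest node below each
    requested point.  The short per-interval spans make the rule accurate to
    well below 1e-8 relative for smooth variance functions.

    Zero values are mapped through a left linear extension of the transform
    (slope ``1/sqrt(w(lo))``), keeping the output monotone.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("variance-stabilization input must be non-negative")
    positive = values[values > 0]
    lo = min(positive.min(), varfun.domain[0]) if positive.size else varfun.domain[0]
    hi = max(positive.max(), varfun.domain[1]) if positive.size else varfun.domain[1]
    lo = max(lo, 1e-8)
    t_grid = np.linspace(np.log(lo), np.log(hi), n_grid)
    f = _tau_integrand(varfun)

    # node integrals: composite Gauss-Legendre over each grid interval
    a, b = t_grid[:-1], t_grid[1:]
    half = (b - a) / 2.0
    mid = (b + a) / 2.0
    samples = mid[:, None] + half[:, None] * _GAUSS_NODES[None, :]
    interval = half * (f(samples.ravel()).reshape(samples.shape) @ _GAUSS_WEIGHTS)
    tau_nodes = np.concatenate([[0.0], np.cumsum(interval)])

    out = np.empty_like(values)
    pos_mask = values > 0
    t = np.log(values[pos_mask])
    idx = np.clip(np.searchsorted(t_grid, t, side="right") - 1, 0, n_grid - 2)
    t0 = t_grid[idx]
    half = (t - t0) / 2.0
    mid = (t + t0) / 2.0
    samples = mid[:, None] + half[:, None] * _GAUSS_NODES[None, :]
    tail = half * (f(samples.ravel()).reshape(samples.shape) @ _GAUSS_WEIGHTS)
    out[pos_mask] = tau_nodes[idx] + tail
    if (~pos_mask).any():
        slope = lo / np.sqrt(float(varfun(lo)))  # d tau / d t at the anchor
        out[~pos_mask] = -slope * 1.0  # one log-unit below the anchor
    return out


def variance_stabilize(
    counts: pd.DataFrame, factors: pd.Series, varfun: VarianceFunction
) -> pd.DataFrame:
    """Normalize then apply the variance-stabilizing transform elementwise."""
    normalized = normalize(counts, factors)
    transformed = vst_values(normalized.to_numpy().ravel(), varfun)
    return pd.DataFrame(
        transformed.reshape(normalized.shape),
        index=normalized.index,
        columns=normalized.columns,
    )
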
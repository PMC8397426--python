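"""Spectral preprocessing: 0.02-ppm binning, exclusion, normalization,
and per-bin normality (Johnson) transformation.

The analyzed variable for every downstream model is the integrated area of a
fixed 0.02-ppm spectral window ("bin"), normalized to the total spectral
integral per sample and transformed toward normality bin-by-bin.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import ndtri

logger = logging.getLogger(__name__)

__all__ = [
    "BinGrid",
    "SpectrumCoverageError",
    "bin_spectrum",
    "normalize_total_area",
    "johnson_transform",
    "rank_inverse_normal",
    "transform_bins",
]


class SpectrumCoverageError(ValueError):
    """Spectrum does not cover the requested bin grid."""


@dataclass(frozen=True)
class BinGrid:
    """Uniform ppm bin grid with excluded regions.

    A bin labeled by its center ``c`` covers ``[c - width/2, c + width/2)``.
    Defaults give 500 bins over 0-10 ppm; excluding the water/urea window
    [4.50, 6.50) removes 100 of them, leaving the 400 analyzed bins.
    """

    ppm_min: float = 0.0
    ppm_max: float = 10.0
    width: float = 0.02
    excluded_regions: tuple[tuple[float, float], ...] = ((4.50, 6.50),)

    def __post_init__(self) -> None:
        n = (self.ppm_max - self.ppm_min) / self.width
        if abs(n - round(n)) > 1e-9 or n <= 0:
            raise ValueError("grid span must be an integral number of bins")
        for lo, hi in self.excluded_regions:
            if not (self.ppm_min <= lo < hi <= self.ppm_max):
                raise ValueError(f"excluded region [{lo}, {hi}) outside the grid")

    @property
    def n_bins(self) -> int:
        return int(round((self.ppm_max - self.ppm_min) / self.width))

    def edges(self) -> np.ndarray:
        return self.ppm_min + self.width * np.arange(self.n_bins + 1)

    def centers(self) -> np.ndarray:
        return self.ppm_min + self.width * (np.arange(self.n_bins) + 0.5)

    def labels(self) -> list[str]:
        return [f"{c:.2f}" for c in self.centers()]

    def retained_mask(self) -> np.ndarray:
        centers = self.centers()
        keep = np.ones(self.n_bins, dtype=bool)
        for lo, hi in self.excluded_regions:
            keep &= ~((centers >= lo) & (centers < hi))
        return keep

    def retained_labels(self) -> list[str]:
        return [l for l, k in zip(self.labels(), self.retained_mask()) if k]


def bin_spectrum(spectrum: pd.DataFrame | np.ndarray, grid: BinGrid | None = None) -> pd.Series:
    """Integrate a spectrum into fixed-width bins (trapezoidal area).

    ``spectrum`` is a two-column table (ppm, intensity) with a monotone ppm
    axis in either direction. Returns a Series over *all* grid bins (before
    exclusion), indexed by center label.
    """
    grid = grid or BinGrid()
    arr = np.asarray(spectrum if not isinstance(spectrum, pd.DataFrame) else spectrum[["ppm", "intensity"]])
    ppm, intensity = arr[:, 0].astype(float), arr[:, 1].astype(float)
    d = np.diff(ppm)
    if np.all(d < 0):
        ppm, intensity = ppm[::-1], intensity[::-1]
    elif not np.all(d > 0):
        raise ValueError("ppm axis must be strictly monotone")
    if ppm[0] > grid.ppm_min + 1e-9 or ppm[-1] < grid.ppm_max - 1e-9:
        raise SpectrumCoverageError(
            f"spectrum covers [{ppm[0]:.4f}, {ppm[-1]:.4f}] ppm but the grid "
            f"requires [{grid.ppm_min:.2f}, {grid.ppm_max:.2f}]"
        )
    cum = np.concatenate([[0.0], integrate.cumulative_trapezoid(intensity, ppm)])
    at_edges = np.interp(grid.edges(), ppm, cum)
    areas = np.diff(at_edges)
    return pd.Series(areas, index=grid.labels(), name="area")


def normalize_total_area(bins: pd.DataFrame) -> pd.DataFrame:
    """Normalize each sample (row) to its total spectral integral.

    Rows are samples, columns retained bins; every returned row sums to 1.
    """
    totals = bins.sum(axis=1)
    bad = totals <= 0
    if bad.any():
        raise ValueError(f"sample(s) with non-positive total integral: {list(bins.index[bad])}")
    return bins.div(totals, axis=0)


def rank_inverse_normal(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offsets."""
    x = np.asarray(values, dtype=float)
    ranks = stats.rankdata(x, method="average")
    return ndtri((ranks - offset) / (len(x) + 1.0 - 2.0 * offset))


def _johnson_percentile_fit(x: np.ndarray, z: float = 0.524):
    """Slifker-Shapiro percentile selection of the Johnson family.

    Four empirical quantiles at normal deviates ±z, ±3z determine the family
    (S_U / S_B / S_L) through the ratio m*n/p**2 and the closed-form
    parameter estimates. Returns a monotone callable or None when the fit
    is numerically invalid.
    """
    probs = stats.norm.cdf([-3 * z, -z, z, 3 * z])
    x3l, xl, xu, x3u = np.quantile(x, probs)
    m = x3u - xu
    n = xl - x3l
    p = xu - xl
    if p <= 0 or m <= 0 or n <= 0:
        return None
    ratio = m * n / p**2
    tol = 0.05
    try:
        if ratio > 1.0 + tol:  # unbounded
            t = 0.5 * (m / p + n / p)
            eta = 2.0 * z / np.arccosh(t)
            gamma = eta * np.arcsinh((n / p - m / p) / (2.0 * np.sqrt(ratio - 1.0)))
            lam = (
                2.0 * p * np.sqrt(ratio - 1.0)
                / ((m / p + n / p - 2.0) * np.sqrt(m / p + n / p + 2.0))
            )
            eps = 0.5 * (xu + xl) + p * (n / p - m / p) / (2.0 * (m / p + n / p - 2.0))
            if not (np.isfinite([eta, gamma, lam, eps]).all() and eta > 0 and lam > 0):
                return None
            return lambda v: gamma + eta * np.arcsinh((v - eps) / lam)
        if ratio < 1.0 - tol:  # bounded
            t = 0.5 * np.sqrt((1.0 + p / m) * (1.0 + p / n))
            eta = z / np.arccosh(t)
            gamma = eta * np.arcsinh(
                (p / n - p / m)
                * np.sqrt((1.0 + p / m) * (1.0 + p / n) - 4.0)
                / (2.0 * (p**2 / (m * n) - 1.0))
            )
            lam = (
                p
                * np.sqrt(((1.0 + p / m) * (1.0 + p / n) - 2.0) ** 2 - 4.0)
                / (p**2 / (m * n) - 1.0)
            )
            eps = 0.5 * (xu + xl) - 0.5 * lam + p * (p / n - p / m) / (
                2.0 * (p**2 / (m * n) - 1.0)
            )
            if not (np.isfinite([eta, gamma, lam, eps]).all() and eta > 0 and lam > 0):
                return None
            lo, hi = eps, eps + lam
            if x.min() <= lo or x.max() >= hi:
                return None

            return lambda v: gamma + eta * np.log((v - lo) / (hi - v))
        # lognormal boundary family
        if m / p <= 1.0:
            return None
        eta = 2.0 * z / np.log(m / p)
        gamma = eta * np.log((m / p - 1.0) / (p * np.sqrt(m / p)))
        eps = 0.5 * (xu + xl) - 0.5 * p * (m / p + 1.0) / (m / p - 1.0)
        if not (np.isfinite([eta, gamma, eps]).all() and eta > 0) or x.min() <= eps:
            return None
        return lambda v: gamma + eta * np.log(v - eps)
    except (FloatingPointError, ValueError):
        return None


def johnson_transform(values: np.ndarray, z: float = 0.524) -> np.ndarray:
    """Transform one bin's values toward normality.

    Fits a Johnson family (S_U/S_B/S_L) by the percentile method and applies
    the fitted monotone transform. Falls back to the rank-based
    inverse-normal transform (with a logged warning) when the percentile fit
    fails, when ties are heavy, or when the fit does not adequately
    normalize (|skewness| >= 0.5 or |excess kurtosis| >= 1).

    Raises on constant input or fewer than 8 distinct values.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    n_distinct = np.unique(x).size
    if n_distinct < 2:
        raise ValueError("constant input cannot be normality-transformed")
    if n_distinct < 8:
        raise ValueError("need at least 8 distinct values")
    if n_distinct < 0.5 * x.size:  # heavy ties
        logger.warning("heavy ties (%d/%d distinct): rank-based inverse normal used",
                       n_distinct, x.size)
        return rank_inverse_normal(x)
    with np.errstate(all="raise"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = _johnson_percentile_fit(x, z=z)
    if fit is not None:
        with np.errstate(all="ignore"):
            y = np.asarray(fit(x), dtype=float)
        if np.all(np.isfinite(y)) and abs(stats.skew(y)) < 0.5 and abs(stats.kurtosis(y)) < 1.0:
            return y
    logger.warning("Johnson percentile fit failed or under-normalized; "
                   "rank-based inverse normal used")
    return rank_inverse_normal(x)


def transform_bins(bins: pd.DataFrame, z: float = 0.524) -> pd.DataFrame:
    """Apply :func:`johnson_transform` column-by-column to a bin matrix."""
    out = {}
    for col in bins.columns:
        out[col] = johnson_transform(bins[col].to_numpy(), z=z)
    return pd.DataFrame(out, index=bins.index)
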
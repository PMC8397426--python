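"""Metabolome conservation indices.

How recognizable is an individual's metabolomic profile after two months?
For each individual *i*, Pearson correlations are computed between their
baseline profile and every participant's 2-month profile (row *i* of an
N x N, generally asymmetric, correlation matrix). The self-correlation
(diagonal) is ranked against the row (descending, average ranks on ties)
and the conservation index is

    index_i = 1 - (rank_i - 1) / (N - 1)

so an individual most similar to themselves scores exactly 1.00. Two
variants: correlations over the stable bin subset, or over the full profile
with per-bin weights given by covariate-adjusted longitudinal (baseline vs
2-month) bin correlations, negatives clipped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConservationResult",
    "profile_correlations",
    "conservation_index",
    "conservation_indices",
    "longitudinal_bin_weights",
    "summarize_conservation",
]

#: band label -> membership test, a partition of [0, 1]
BAND_ORDER = ("1.00", "0.90-0.99", "0.70-0.89", "<0.70")


def _band(index: float, rank_is_top: bool) -> str:
    if rank_is_top and index >= 1.0:
        return "1.00"
    if index >= 0.90:
        return "0.90-0.99"
    if index >= 0.70:
        return "0.70-0.89"
    return "<0.70"


@dataclass(frozen=True)
class ConservationResult:
    individual_id: object
    intra_correlation: float
    rank: float
    n: int
    index: float
    band: str


def _weighted_standardize(m: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Rows scaled to weighted mean 0 and weighted SD 1 (weights sum to 1)."""
    mu = m @ w
    c = m - mu[:, None]
    sd = np.sqrt((c**2) @ w)
    if np.any(sd <= 0):
        bad = np.where(sd <= 0)[0]
        raise ValueError(f"zero-variance profile for row index {bad.tolist()}")
    return c / sd[:, None]


def profile_correlations(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
    bins: list[str] | None = None,
    weights: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """N x N matrix of (weighted) Pearson correlations across bins.

    Entry (i, j) correlates individual i's baseline profile with individual
    j's follow-up profile. Rows/columns are indexed by the shared individual
    index. ``weights`` (per retained bin, >= 0) turn the plain Pearson into
    its weighted form (weighted means, variances and covariance); uniform
    weights reproduce the unweighted matrix.
    """
    if not baseline.index.equals(followup.index):
        raise ValueError("baseline and follow-up must share individuals")
    if bins is not None:
        baseline = baseline[list(bins)]
        followup = followup[list(bins)]
    if baseline.shape[1] < 3:
        raise ValueError("need at least 3 bins to correlate profiles")
    if not baseline.columns.equals(followup.columns):
        raise ValueError("baseline and follow-up must share bins")
    if weights is None:
        w = np.full(baseline.shape[1], 1.0 / baseline.shape[1])
    else:
        w = np.asarray(
            weights[baseline.columns] if isinstance(weights, pd.Series) else weights,
            dtype=float,
        )
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be >= 0 with positive sum")
        w = w / w.sum()
    b = _weighted_standardize(baseline.to_numpy(float), w)
    f = _weighted_standardize(followup.to_numpy(float), w)
    corr = (b * w) @ f.T
    return pd.DataFrame(corr, index=baseline.index, columns=followup.index)


def conservation_index(matrix: pd.DataFrame, individual) -> ConservationResult:
    """Conservation index for one individual from the correlation matrix."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 individuals")
    row = matrix.loc[individual].to_numpy(float)
    if not np.all(np.isfinite(row)):
        raise ValueError(f"non-finite correlation in row for {individual!r}")
    i = matrix.index.get_loc(individual)
    ranks = stats.rankdata(-row, method="average")
    rank_i = float(ranks[i])
    n = len(row)
    index = 1.0 - (rank_i - 1.0) / (n - 1.0)
    return ConservationResult(
        individual_id=individual,
        intra_correlation=float(row[i]),
        rank=rank_i,
        n=n,
        index=index,
        band=_band(index, rank_is_top=rank_i == 1.0),
    )


def conservation_indices(matrix: pd.DataFrame) -> pd.DataFrame:
    """Conservation results for every individual, as a table."""
    rows = [conservation_index(matrix, ind) for ind in matrix.index]
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in rows],
            "intra_correlation": [r.intra_correlation for r in rows],
            "rank": [r.rank for r in rows],
            "N": [r.n for r in rows],
            "index": [r.index for r in rows],
            "band": [r.band for r in rows],
        }
    )


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def longitudinal_bin_weights(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.Series:
    """Per-bin test-retest weights: covariate-adjusted longitudinal Pearson
    correlations between the same bin at baseline and follow-up, clipped at 0.

    With covariates, the partial correlation is computed by residualizing
    both time points on the covariate design (with intercept) and
    correlating the residuals. A negative test-retest correlation carries no
    conservation signal, hence the clipping.
    """
    if not baseline.index.equals(followup.index):
        raise ValueError("baseline and follow-up must share individuals")
    n = len(baseline)
    if n < 8:
        raise ValueError("need at least 8 individuals for weight estimation")
    b = baseline.to_numpy(float)
    f = followup.to_numpy(float)
    if covariates is not None and covariates.shape[1] > 0:
        design = np.column_stack(
            [np.ones(n), covariates.loc[baseline.index].to_numpy(float)]
        )
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("singular covariate design")
        b = _residualize(b, design)
        f = _residualize(f, design)
    else:
        b = b - b.mean(axis=0)
        f = f - f.mean(axis=0)
    num = (b * f).sum(axis=0)
    den = np.sqrt((b**2).sum(axis=0) * (f**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return pd.Series(np.clip(r, 0.0, 1.0), index=baseline.columns, name="weight")


def summarize_conservation(results: pd.DataFrame) -> pd.DataFrame:
    """Band counts and percentages from a conservation results table."""
    if len(results) == 0:
        raise ValueError("no conservation results to summarize")
    counts = results["band"].value_counts()
    n = len(results)
    return pd.DataFrame(
        {
            "band": BAND_ORDER,
            "n": [int(counts.get(b, 0)) for b in BAND_ORDER],
            "percent": [100.0 * counts.get(b, 0) / n for b in BAND_ORDER],
        }
    )
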
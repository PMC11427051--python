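"""Cohort-level descriptive statistics: proportion chi-square and rate-CV correlation.

Proportion comparisons follow the operational convention of the source data:
inputs may be fractional (proportion x n), are rounded to the nearest whole
integer (half-up) before testing, and firing-mode classes observed in neither
cohort are dropped from the table with a correspondingly reduced df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

log = logging.getLogger(__name__)


def round_half_up(x) -> np.ndarray:
    """Round to the nearest integer with .5 always rounding up."""
    x = np.asarray(x, dtype=float)
    return np.floor(x + 0.5).astype(int)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float
    rounded_a: np.ndarray
    rounded_b: np.ndarray
    dropped_classes: tuple[int, ...]


def chi_square_proportions(counts_a, counts_b) -> ChiSquareResult:
    """Pearson chi-square between two firing-mode count vectors.

    Both vectors are rounded half-up first; classes with zero total count
    across both cohorts are dropped (logged) and df reduced accordingly.
    Expected counts come from the table marginals (no continuity correction).
    """
    a = round_half_up(counts_a)
    b = round_half_up(counts_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("counts must be equal-length 1-D vectors")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    keep = (a + b) > 0
    dropped = tuple(int(i) for i in np.nonzero(~keep)[0])
    if dropped:
        log.warning("dropping zero-count classes %s from chi-square", dropped)
    a_k, b_k = a[keep], b[keep]
    if a_k.size < 2:
        raise ValueError("fewer than two non-empty classes; chi-square undefined")
    table = np.vstack([a_k, b_k])
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal after dropping classes")
    stat, p, df, _ = sstats.chi2_contingency(table, correction=False)
    return ChiSquareResult(
        statistic=float(stat),
        df=int(df),
        pvalue=float(p),
        rounded_a=a,
        rounded_b=b,
        dropped_classes=dropped,
    )


def rate_cv_correlation(rates, cvs) -> tuple[float, float]:
    """Pearson correlation between firing rate and IEI CV across cells.

    Tonically active cells show a negative correlation: faster pacemaking
    comes with lower spike-timing variability.
    """
    rates = np.asarray(rates, dtype=float)
    cvs = np.asarray(cvs, dtype=float)
    if rates.size != cvs.size or rates.size < 3:
        raise ValueError("need at least three (rate, cv) pairs")
    if np.ptp(rates) == 0 or np.ptp(cvs) == 0:
        raise ValueError("zero variance in rates or CVs")
    r, p = sstats.pearsonr(rates, cvs)
    return float(r), float(p)
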
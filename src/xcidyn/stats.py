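"""Statistical primitives shared by every analysis stage.

The silencing, escape and Hi-C stages all lean on the same four tools: an
exact two-sided binomial test (allelic-imbalance calls), Benjamini–Hochberg
FDR control (cluster enrichment), the McGill notched-boxplot comparison of
medians, and a tie-aware Spearman rank correlation (Hi-C replicate
agreement).  The notch comparison follows McGill, Tukey & Larsen: the notch
extends 1.58 * IQR / sqrt(n) on either side of the median, an approximate
95 % interval for the median, and two samples are declared different at
p < 0.05 when their notches do not overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NotchSummary",
    "binomial_two_sided",
    "bh_fdr",
    "notch_interval",
    "notch_compare",
    "spearman_rho",
]

#: half-width multiplier of the McGill notch
NOTCH_FACTOR = 1.58


@dataclass(frozen=True)
class NotchSummary:
    """Median, quartiles and notch interval of one sample."""

    median: float
    q1: float
    q3: float
    n: int
    notch_lo: float
    notch_hi: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value (minimum-likelihood rule).

    Sums the probabilities of all outcomes whose point probability does not
    exceed that of the observed ``k`` (the standard exact two-sided
    convention).

    Parameters
    ----------
    k : observed successes, ``0 <= k <= n``.
    n : number of trials, ``n >= 1``.
    p0 : success probability under the null, in (0, 1).
    """
    if n <= 0:
        raise ValueError("binomial test needs at least one trial")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("null probability must be in (0, 1)")
    return float(_sps.binomtest(k, n, p0, alternative="two-sided").pvalue)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def notch_interval(sample: Sequence[float]) -> NotchSummary:
    """Median, quartiles (linear-interpolation convention) and McGill notch."""
    x = np.asarray(list(sample), dtype=float)
    if x.size < 2:
        raise ValueError("notch interval needs n >= 2")
    q1, med, q3 = np.percentile(x, [25.0, 50.0, 75.0])
    half = NOTCH_FACTOR * (q3 - q1) / math.sqrt(x.size)
    return NotchSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        n=int(x.size),
        notch_lo=float(med - half),
        notch_hi=float(med + half),
    )


def notch_compare(a: Sequence[float], b: Sequence[float]) -> dict:
    """McGill notched-boxplot comparison of two samples.

    Significant (approximately p < 0.05) iff the two notch intervals do not
    overlap; intervals sharing exactly one endpoint count as overlapping.
    ``direction`` is the sign of median(b) - median(a): +1 when b sits higher.
    """
    na, nb = notch_interval(a), notch_interval(b)
    disjoint = na.notch_hi < nb.notch_lo or nb.notch_hi < na.notch_lo
    diff = nb.median - na.median
    return {
        "significant": bool(disjoint),
        "direction": int(np.sign(diff)),
        "median_a": na.median,
        "median_b": nb.median,
        "notch_a": (na.notch_lo, na.notch_hi),
        "notch_b": (nb.notch_lo, nb.notch_hi),
    }


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN when either vector is constant (the correlation is
    undefined there).
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("vectors must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return float("nan")
    return float(_sps.spearmanr(xa, ya).statistic)
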
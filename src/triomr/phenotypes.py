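"""Exposure and outcome derivation.

Coffee and caffeine aggregation with the 3.5 L/day exclusion, scale-score
mean imputation, rank-based inverse normal transformation, and the
PCA-based effective number of tests used for multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "EffectiveTests",
    "aggregate_coffee",
    "aggregate_caffeine",
    "impute_scale_score",
    "rank_inverse_normal",
    "effective_tests_threshold",
    "DEFAULT_CUP_VOLUME_ML",
    "EXCLUSION_VOLUME_ML",
]

DEFAULT_CUP_VOLUME_ML = 125.0
EXCLUSION_VOLUME_ML = 3500.0  # > 3.5 litres/day of coffee excludes the mother


@dataclass(frozen=True)
class EffectiveTests:
    """PCA-derived effective number of independent outcomes.

    ``alpha`` is the family-wise threshold divided by the number of
    principal components needed to reach the variance target.
    """

    eigen_fractions: tuple[float, ...]
    n_components: int
    alpha: float


def aggregate_coffee(
    per_type_cups: dict[str, float],
    cup_volume_ml: float = DEFAULT_CUP_VOLUME_ML,
) -> tuple[float, bool]:
    """Total cups/day across coffee types, with the 3.5 L/day exclusion flag.

    Coffee intake is summed over types (filtered, instant, boiled, latte,
    espresso, ...); a mother is flagged for exclusion when her total volume
    exceeds 3.5 litres per day at the configured cup volume.
    """
    for k, v in per_type_cups.items():
        if v < 0:
            raise ValueError(f"negative intake for {k!r}: {v}")
    if cup_volume_ml <= 0:
        raise ValueError("cup_volume_ml must be positive")
    cups = float(sum(per_type_cups.values()))
    return cups, cups * cup_volume_ml > EXCLUSION_VOLUME_ML


def aggregate_caffeine(
    source_amounts: dict[str, float], content_table: dict[str, float]
) -> float:
    """Daily caffeine (mg) aggregated over sources.

    ``content_table`` maps a source to its caffeine content per serving;
    it is pure configuration (coffee types, teas, soft and energy drinks).
    """
    unknown = set(source_amounts) - set(content_table)
    if unknown:
        raise KeyError(f"sources missing from content table: {sorted(unknown)}")
    return float(sum(amt * content_table[src] for src, amt in source_amounts.items()))


def impute_scale_score(items) -> float:
    """Sum score with mean imputation when >= 50% of items are observed.

    Missing items are replaced by the mean of the observed items and the
    score is the sum; with fewer than half the items observed, the score
    itself is missing (NaN). Invariant to item order.
    """
    arr = np.asarray(items, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError("items must be a non-empty 1-d vector")
    obs = ~np.isnan(arr)
    if obs.sum() * 2 < arr.size:
        return float("nan")
    mean = arr[obs].mean()
    return float(arr[obs].sum() + (arr.size - obs.sum()) * mean)


def rank_inverse_normal(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset by default).

    A value of rank r among n observed values maps to
    Phi^-1((r - offset) / (n - 2*offset + 1)); ties receive average ranks
    and missing entries stay missing.
    """
    arr = np.asarray(values, dtype=float)
    obs = ~np.isnan(arr)
    n = int(obs.sum())
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    out = np.full(arr.shape, np.nan)
    ranks = rankdata(arr[obs], method="average")
    out[obs] = norm.ppf((ranks - offset) / (n - 2 * offset + 1))
    return out


def effective_tests_threshold(
    data,
    variance_target: float = 0.8,
    alpha_total: float = 0.05,
    *,
    eigen_fractions=None,
) -> EffectiveTests:
    """Effective number of tests from a PCA of the outcome correlation matrix.

    ``n_components`` is the smallest k whose cumulative eigenvalue fraction
    reaches ``variance_target``; the corrected threshold is
    ``alpha_total / n_components``. Accepts either an outcomes matrix
    (complete-case rows; PCA on the correlation matrix) or precomputed
    ``eigen_fractions``.
    """
    if eigen_fractions is not None:
        frac = np.asarray(eigen_fractions, dtype=float)
    else:
        x = np.asarray(pd.DataFrame(data).dropna(), dtype=float)
        if x.shape[1] < 2:
            raise ValueError("need at least 2 outcomes")
        corr = np.corrcoef(x, rowvar=False)
        eig = np.linalg.eigvalsh(corr)[::-1]
        frac = eig / eig.sum()
    if frac.size < 2:
        raise ValueError("need at least 2 outcomes")
    cum = np.cumsum(frac)
    # tolerate float round-off at the boundary (16 * 0.05 must count as 0.8)
    k = int(np.argmax(cum >= variance_target - 1e-12)) + 1
    return EffectiveTests(tuple(frac), k, alpha_total / k)
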
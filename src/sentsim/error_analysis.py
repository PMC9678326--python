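"""Similarity-error analysis: per-pair error, density, extremes.

The signed similarity error of a method on a pair is its score minus
the normalized human judgement, ``e = sim - human`` in [-1, 1]. Its
estimated probability density (Gaussian KDE) shows whether a method
systematically under- or over-estimates similarity; the pairs with
the lowest and highest absolute error are the method's best and
worst cases and drive qualitative error analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ErrorRecord",
    "similarity_error",
    "error_density",
    "extreme_pairs",
    "score_summary",
]


@dataclass(frozen=True)
class ErrorRecord:
    """Signed similarity error of one method on one pair."""

    pair_id: int
    method_id: str
    sim: float
    human: float

    @property
    def e_sim(self) -> float:
        return self.sim - self.human


def similarity_error(sim: float, human: float) -> float:
    """Signed error ``sim - human``; both inputs must lie in [0, 1]."""
    if not 0.0 <= sim <= 1.0:
        raise ValueError(f"sim score {sim} outside [0, 1]")
    if not 0.0 <= human <= 1.0:
        raise ValueError(f"human score {human} outside [0, 1]")
    return sim - human


def error_density(
    errors: Sequence[float], grid_points: int = 512
) -> tuple[np.ndarray, np.ndarray, float]:
    """Gaussian KDE of the error sample (Silverman bandwidth).

    Returns ``(x, f(x), mean)`` with the grid spanning
    ``[min - 3 bw, max + 3 bw]`` and ``mean`` the arithmetic sample
    mean. These defaults mirror the common statistical-package
    ``density`` defaults.
    """
    e = np.asarray(errors, dtype=float)
    if len(e) < 2:
        raise ValueError("need at least 2 error values")
    if np.ptp(e) == 0:
        raise ValueError("degenerate error sample (zero variance)")
    kde = stats.gaussian_kde(e, bw_method="silverman")
    bw = float(np.sqrt(kde.covariance[0, 0]))
    x = np.linspace(e.min() - 3 * bw, e.max() + 3 * bw, grid_points)
    return x, kde(x), float(np.mean(e))


def extreme_pairs(
    records: Sequence[ErrorRecord], k: int
) -> tuple[list[ErrorRecord], list[ErrorRecord]]:
    """The k records with lowest and highest absolute error.

    Ties are broken by pair_id ascending; the output is a
    deterministic function of the records.
    """
    if not records:
        raise ValueError("no error records")
    if not 1 <= k <= len(records):
        raise ValueError(f"k={k} not in [1, {len(records)}]")
    lowest = sorted(records, key=lambda rec: (abs(rec.e_sim), rec.pair_id))[:k]
    highest = sorted(records, key=lambda rec: (-abs(rec.e_sim), rec.pair_id))[:k]
    return lowest, highest


def score_summary(scores: Sequence[float]) -> tuple[float, float, float]:
    """(mean, min, max) of a raw score vector."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty score vector")
    return float(s.mean()), float(s.min()), float(s.max())
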
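"""Scoring a measure over a dataset and the survey's metrics.

A method's quality on a benchmark is summarized by three numbers: the
Pearson correlation ``r`` between its scores and the human judgements,
the Spearman rank correlation ``rho``, and their harmonic mean
``h = 2 r rho / (r + rho)``, the single ranking metric used to compare
methods and pre-processing configurations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from sentsim.corpus_io import AnnotationSet, PairDataset, write_raw_scores
from sentsim.preprocessing import PreprocessingConfig, preprocess, resolve_stopwords

__all__ = [
    "EvaluationRow",
    "pearson",
    "spearman",
    "harmonic",
    "score_dataset",
    "evaluate_measure",
    "sweep_preprocessing",
    "results_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationRow:
    """(r, rho, h) for one measure on one dataset under one configuration."""

    dataset: str
    method_id: str
    r: float
    rho: float
    h: float
    config_label: str = ""


def _check_vectors(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if len(xa) < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("undefined correlation: zero variance input")
    return xa, ya


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson linear correlation coefficient."""
    xa, ya = _check_vectors(x, y)
    return float(stats.pearsonr(xa, ya).statistic)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    xa, ya = _check_vectors(x, y)
    return float(stats.spearmanr(xa, ya).statistic)


def harmonic(r: float, rho: float) -> float:
    """Harmonic mean of Pearson and Spearman correlations."""
    if r + rho == 0:
        raise ValueError("harmonic score undefined when r + rho = 0")
    return 2.0 * r * rho / (r + rho)


def score_dataset(
    dataset: PairDataset,
    measure: Callable,
    config: PreprocessingConfig,
    annotations: AnnotationSet | None = None,
) -> list[float]:
    """Compute the raw similarity score of every pair in the dataset.

    A pair whose pre-processing empties both sentences (or otherwise
    makes the measure undefined) scores 0 with a logged warning rather
    than aborting the run.
    """
    stopwords = resolve_stopwords(config.stopword_list)
    scores: list[float] = []
    for pair in dataset:
        t1, t2 = preprocess(pair, config, annotations, stopwords=stopwords)
        try:
            scores.append(float(measure(t1, t2)))
        except ValueError as exc:
            logger.warning(
                "dataset %s pair %d: %s; scoring 0", dataset.name, pair.pair_id, exc
            )
            scores.append(0.0)
    return scores


def evaluate_measure(
    dataset: PairDataset,
    method_id: str,
    measure: Callable,
    config: PreprocessingConfig,
    annotations: AnnotationSet | None = None,
    raw_scores_path: str | Path | None = None,
) -> EvaluationRow:
    """Score a measure on a dataset and summarize with (r, rho, h).

    Raw per-pair scores are persisted as CSV when a path is given.
    """
    scores = score_dataset(dataset, measure, config, annotations)
    if raw_scores_path is not None:
        write_raw_scores(dataset, method_id, scores, raw_scores_path)
    r = pearson(scores, dataset.human_scores())
    rho = spearman(scores, dataset.human_scores())
    return EvaluationRow(dataset.name, method_id, r, rho, harmonic(r, rho), config.label())


def sweep_preprocessing(
    datasets: Sequence[PairDataset],
    method_id: str,
    measure: Callable,
    config_grid: Sequence[PreprocessingConfig],
    annotations: dict[str, AnnotationSet] | None = None,
) -> tuple[list[EvaluationRow], PreprocessingConfig]:
    """Evaluate a measure under every configuration of the grid.

    Returns all per-dataset rows sorted by h descending, plus the best
    configuration: the argmax of average h across the supplied datasets
    (ties broken by earliest grid position).
    """
    if not config_grid:
        raise ValueError("empty configuration grid")
    annotations = annotations or {}
    rows: list[EvaluationRow] = []
    best_config = None
    best_avg = -np.inf
    for config in config_grid:
        hs = []
        for ds in datasets:
            row = evaluate_measure(
                ds, method_id, measure, config, annotations.get(ds.name)
            )
            rows.append(row)
            hs.append(row.h)
        avg_h = float(np.mean(hs))
        if avg_h > best_avg:  # strict: earliest grid order wins ties
            best_avg = avg_h
            best_config = config
    rows.sort(key=lambda row: -row.h)
    return rows, best_config


def results_table(rows: Sequence[EvaluationRow], path: str | Path | None = None):
    """Render evaluation rows as a DataFrame (3-dp, round-half-even).

    Optionally written as CSV; a plain-text aligned rendering is
    emitted next to it with suffix ``.txt``.
    """
    import pandas as pd

    frame = pd.DataFrame(
        [
            {
                "dataset": row.dataset,
                "method": row.method_id,
                "config": row.config_label,
                "r": row.r,
                "rho": row.rho,
                "h": row.h,
            }
            for row in rows
        ]
    )
    rounded = frame.copy()
    for col in ("r", "rho", "h"):
        rounded[col] = np.round(frame[col].to_numpy(), 3)  # round-half-even
    if path is not None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        rounded.to_csv(path, index=False)
        path.with_suffix(".txt").write_text(rounded.to_string(index=False) + "\n")
    return rounded
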
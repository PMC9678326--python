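"""Statistical significance machinery for method comparisons.

Benchmarks for sentence similarity are few and of very different
sizes, so correlation statistics computed on them are not identically
distributed. The harness therefore (a) divides a large benchmark into
near-equal parts treated as independent datasets, (b) compares two
methods by a paired one-sided t-test on their harmonic-score vectors
across those datasets, and (c) applies a Bonferroni-corrected
threshold ``alpha_c = alpha / m`` when a family of ``m`` pairwise
comparisons backs a single claim. A Monte-Carlo subset study checks
the normality assumption behind the t-test and how the harmonic
score's dispersion shrinks with subset size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from sentsim.corpus_io import PairDataset
from sentsim.evaluation import harmonic, pearson, spearman

__all__ = [
    "SplitPlan",
    "SignificanceCell",
    "split_uniform",
    "paired_t_pvalue",
    "bonferroni_alpha",
    "significance_matrix",
    "subset_distribution",
    "evaluate_on_split",
    "SubsetStudy",
]


@dataclass(frozen=True)
class SplitPlan:
    """Deterministic partition of a dataset into near-equal parts."""

    source: str
    part_sizes: tuple[int, ...]
    assignment: tuple[tuple[int, ...], ...]  # pair_ids per part

    def __post_init__(self) -> None:
        if max(self.part_sizes) - min(self.part_sizes) > 1:
            raise ValueError("part sizes must differ by at most 1")


@dataclass(frozen=True)
class SignificanceCell:
    """One directional comparison: is method_a better than method_b?"""

    method_a: str
    method_b: str
    p_value: float
    m: int
    alpha_c: float
    significant: bool
    degenerate: bool = False  # zero-variance differences (limit p-value)


def split_uniform(
    dataset: PairDataset, k: int, seed: int | None = None
) -> SplitPlan:
    """Partition a dataset into ``k`` parts with sizes as equal as possible.

    The default split is contiguous in file order (larger parts first)
    and fully deterministic; pass ``seed`` for a shuffled assignment.
    """
    n = len(dataset)
    if k < 1 or k > n:
        raise ValueError(f"k={k} not in [1, {n}]")
    base, extra = divmod(n, k)
    sizes = [base + 1] * extra + [base] * (k - extra)
    ids = [p.pair_id for p in dataset.pairs]
    if seed is not None:
        rng = np.random.default_rng(seed)
        ids = list(rng.permutation(ids))
    parts, pos = [], 0
    for size in sizes:
        parts.append(tuple(ids[pos : pos + size]))
        pos += size
    return SplitPlan(dataset.name, tuple(sizes), tuple(parts))


def paired_t_pvalue(h_a: Sequence[float], h_b: Sequence[float]) -> tuple[float, bool]:
    """One-sided p-value of the paired t-test for mean(h_a - h_b) > 0.

    Returns ``(p, degenerate)``; ``degenerate`` flags zero-variance
    difference vectors, for which the limit p-value is reported (0.5
    for all-zero differences, 0 or 1 for a constant nonzero shift).
    """
    a = np.asarray(h_a, dtype=float)
    b = np.asarray(h_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("harmonic-score vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 paired observations")
    diff = a - b
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            return 0.5, True
        return (0.0 if diff[0] > 0 else 1.0), True
    res = stats.ttest_rel(a, b, alternative="greater")
    return float(res.pvalue), False


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Corrected rejection threshold ``alpha / m`` for m comparisons."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def significance_matrix(
    h_scores: dict[str, Sequence[float]],
    alpha: float = 0.05,
    m: int | None = None,
) -> list[SignificanceCell]:
    """All ordered pairwise comparisons on per-dataset harmonic vectors.

    ``h_scores`` maps method id -> harmonic scores over the same
    ordered list of (sub)datasets. ``m`` is the family size used for
    the Bonferroni threshold; by default the number of directional
    cells emitted. Missing or ragged vectors raise with the gaps named.
    """
    methods = list(h_scores)
    if len(methods) < 2:
        raise ValueError("need at least 2 methods")
    lengths = {mid: len(h_scores[mid]) for mid in methods}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"ragged evaluations: {lengths}")
    cells: list[SignificanceCell] = []
    n_cells = len(methods) * (len(methods) - 1)
    family = m if m is not None else n_cells
    alpha_c = bonferroni_alpha(alpha, family)
    for ma in methods:
        for mb in methods:
            if ma == mb:
                continue
            p, degen = paired_t_pvalue(h_scores[ma], h_scores[mb])
            cells.append(
                SignificanceCell(ma, mb, p, family, alpha_c, p < alpha_c, degen)
            )
    return cells


@dataclass
class SubsetStudy:
    """Monte-Carlo distribution of the harmonic score over random subsets."""

    subset_size: int
    n_samples: int
    h_values: np.ndarray
    shapiro_p: float
    chi2_p: float
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    degenerate: bool = False

    @property
    def h_mean(self) -> float:
        return float(np.mean(self.h_values))

    @property
    def h_std(self) -> float:
        return float(np.std(self.h_values, ddof=1))


def _chi2_normality_p(sample: np.ndarray) -> float:
    """Chi-square goodness of fit to the moment-matched normal.

    Bins by Sturges' rule; expected counts from the fitted normal CDF;
    two parameters estimated from the data (ddof = 2).
    """
    n = len(sample)
    n_bins = int(np.ceil(np.log2(n) + 1))
    mu, sd = float(np.mean(sample)), float(np.std(sample, ddof=1))
    edges = np.linspace(sample.min(), sample.max(), n_bins + 1)
    observed, _ = np.histogram(sample, bins=edges)
    cdf = stats.norm.cdf(edges, loc=mu, scale=sd)
    cdf[0], cdf[-1] = 0.0, 1.0  # open outer bins
    expected = n * np.diff(cdf)
    # merge sparse bins so the chi-square approximation holds
    keep = expected > 1e-12
    observed, expected = observed[keep], expected[keep]
    expected *= observed.sum() / expected.sum()
    ddof = min(2, len(observed) - 2)
    return float(stats.chisquare(observed, expected, ddof=ddof).pvalue)


def subset_distribution(
    human_scores: Sequence[float],
    sim_scores: Sequence[float],
    subset_size: int,
    n_samples: int,
    seed: int,
) -> SubsetStudy:
    """Sample the harmonic score on random equal-size subsets of a dataset.

    ``sim_scores`` are the per-pair scores of one measure on the full
    dataset (computed once); each of the ``n_samples`` draws picks
    ``subset_size`` pairs uniformly without replacement and records the
    harmonic score on that subset. Reports Shapiro-Wilk and chi-square
    normality p-values and Q-Q points against the fitted normal.
    """
    human = np.asarray(human_scores, dtype=float)
    sim = np.asarray(sim_scores, dtype=float)
    if human.shape != sim.shape:
        raise ValueError("score vectors must have equal length")
    n = len(human)
    if not 2 <= subset_size <= n:
        raise ValueError(f"subset_size {subset_size} not in [2, {n}]")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    hs = np.empty(n_samples)
    for i in range(n_samples):
        idx = np.sort(rng.choice(n, size=subset_size, replace=False))
        r = pearson(sim[idx], human[idx])
        rho = spearman(sim[idx], human[idx])
        hs[i] = harmonic(r, rho)
    degenerate = bool(np.ptp(hs) == 0)
    if degenerate or n_samples < 3:
        return SubsetStudy(
            subset_size, n_samples, hs, float("nan"), float("nan"),
            np.array([]), np.array([]), degenerate=True,
        )
    shapiro_p = float(stats.shapiro(hs).pvalue)
    chi2_p = _chi2_normality_p(hs)
    order = np.sort(hs)
    probs = (np.arange(1, n_samples + 1) - 0.5) / n_samples
    theo = stats.norm.ppf(probs, loc=hs.mean(), scale=hs.std(ddof=1))
    return SubsetStudy(subset_size, n_samples, hs, shapiro_p, chi2_p, theo, order)


def evaluate_on_split(
    dataset: PairDataset,
    plan: SplitPlan,
    measure_scores: Sequence[float],
) -> list[float]:
    """Harmonic score of one measure on each part of a split plan.

    ``measure_scores`` are the per-pair scores on the full dataset,
    indexed by pair_id - 1.
    """
    sim = np.asarray(measure_scores, dtype=float)
    human = np.asarray(dataset.human_scores(), dtype=float)
    out = []
    for part in plan.assignment:
        idx = np.asarray(part) - 1
        r = pearson(sim[idx], human[idx])
        rho = spearman(sim[idx], human[idx])
        out.append(harmonic(r, rho))
    return out
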
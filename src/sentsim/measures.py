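"""String-based sentence similarity measures, including LiBlock.

All measures share one contract: they take two token sequences (the
pre-processed sentences) and return a similarity in [0, 1]. The
LiBlock measure is the equal-weight linear aggregation of

* ``sim_block`` — the Block (L1 / Manhattan) distance between word
  frequency profiles, transformed into a similarity, and
* ``sim_li_adapted`` — the cosine of the two binary occurrence
  vectors built over the union dictionary of the pair, an
  ontology-free adaptation of the Li et al. sentence measure,

falling back to ``sim_block`` alone when the binary cosine is zero
(no shared vocabulary).

A small registry maps the survey's method ids (M1-M6) to callables;
user-defined measures with the same signature can be registered too,
which is the hook for ontology- or embedding-based methods that need
resources this toolkit does not ship.
"""

from __future__ import annotations

from collections import Counter
from typing import Callable, Sequence

try:
    import edlib

    _HAVE_EDLIB = True
except ImportError:  # pragma: no cover
    _HAVE_EDLIB = False

__all__ = [
    "word_set",
    "sim_block",
    "sim_li_adapted",
    "sim_liblock",
    "sim_qgram",
    "sim_jaccard",
    "sim_overlap",
    "sim_levenshtein",
    "levenshtein_distance",
    "MEASURES",
    "register_measure",
]

Tokens = Sequence[str]


def _toks(s) -> tuple[str, ...]:
    """Accept TokenSequence or any sequence of strings."""
    return tuple(getattr(s, "tokens", s))


def word_set(s: Tokens) -> frozenset[str]:
    """The set of distinct tokens occurring in a sentence."""
    return frozenset(_toks(s))


def sim_block(s1: Tokens, s2: Tokens) -> float:
    """Block-distance similarity between word frequency profiles.

    ``1 - sum_w |fr(w, s1) - fr(w, s2)| / sum_w fr(w, s1 + s2)`` over
    the union dictionary. Equals 1 for identical sequences and 0 when
    the vocabularies are disjoint.
    """
    t1, t2 = _toks(s1), _toks(s2)
    if not t1 and not t2:
        raise ValueError("sim_block undefined on empty pair")
    f1, f2 = Counter(t1), Counter(t2)
    num = sum(abs(f1[w] - f2[w]) for w in f1.keys() | f2.keys())
    den = len(t1) + len(t2)
    return 1.0 - num / den


def sim_li_adapted(S1: frozenset[str] | Tokens, S2: frozenset[str] | Tokens) -> float:
    """Cosine of the binary occurrence vectors over the union dictionary.

    For word sets this closed form is ``|S1 & S2| / sqrt(|S1| * |S2|)``;
    it is 0 whenever either set is empty.
    """
    a = S1 if isinstance(S1, frozenset) else word_set(S1)
    b = S2 if isinstance(S2, frozenset) else word_set(S2)
    if not a or not b:
        return 0.0
    return len(a & b) / (len(a) * len(b)) ** 0.5


def sim_liblock(s1: Tokens, s2: Tokens, weight: float = 0.5) -> float:
    """LiBlock similarity: aggregate of Block distance and binary cosine.

    ``weight * block + (1 - weight) * cosine`` when the binary cosine is
    nonzero, else the Block similarity alone. The default equal weights
    are the measure's definition; the parameter exists for
    experimentation only.
    """
    block = sim_block(s1, s2)
    li_ad = sim_li_adapted(word_set(s1), word_set(s2))
    if li_ad == 0.0:
        return block
    return weight * block + (1.0 - weight) * li_ad


def sim_qgram(s1: Tokens, s2: Tokens, q: int = 3) -> float:
    """Dice coefficient over the multisets of token q-grams (default q=3).

    When both sequences are shorter than ``q`` the score is 1 if they
    are equal and 0 otherwise; if only one is shorter the score is 0.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    t1, t2 = _toks(s1), _toks(s2)
    g1 = Counter(t1[i : i + q] for i in range(len(t1) - q + 1))
    g2 = Counter(t2[i : i + q] for i in range(len(t2) - q + 1))
    if not g1 and not g2:
        return 1.0 if t1 == t2 else 0.0
    if not g1 or not g2:
        return 0.0
    shared = sum((g1 & g2).values())
    return 2.0 * shared / (sum(g1.values()) + sum(g2.values()))


def sim_jaccard(s1: Tokens, s2: Tokens) -> float:
    """Jaccard similarity of the two word sets: |A & B| / |A | B|."""
    a, b = word_set(s1), word_set(s2)
    if not a and not b:
        raise ValueError("sim_jaccard undefined on empty pair")
    return len(a & b) / len(a | b)


def sim_overlap(s1: Tokens, s2: Tokens) -> float:
    """Overlap coefficient: |A & B| / min(|A|, |B|)."""
    a, b = word_set(s1), word_set(s2)
    if not a or not b:
        raise ValueError("sim_overlap undefined when either sentence is empty")
    return len(a & b) / min(len(a), len(b))


def _levenshtein_dp(a: str, b: str) -> int:
    """Classic O(|a|*|b|) dynamic program, unit costs."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def levenshtein_distance(a: str, b: str) -> int:
    """Unit-cost character edit distance (insert/delete/substitute = 1)."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    if _HAVE_EDLIB and len(set(a) | set(b)) <= 256:
        return edlib.align(a, b, task="distance")["editDistance"]
    return _levenshtein_dp(a, b)


def sim_levenshtein(s1: Tokens | str, s2: Tokens | str) -> float:
    """Normalized character-level edit similarity on space-joined text.

    ``1 - d(a, b) / max(|a|, |b|)``; two empty strings score 1.
    """
    a = s1 if isinstance(s1, str) else " ".join(_toks(s1))
    b = s2 if isinstance(s2, str) else " ".join(_toks(s2))
    if not a and not b:
        return 1.0
    return 1.0 - levenshtein_distance(a, b) / max(len(a), len(b))


#: Measure registry keyed by the survey's method ids. Plug-in point for
#: user-supplied measures (ontology- or embedding-based methods).
MEASURES: dict[str, Callable[[Tokens, Tokens], float]] = {
    "M1": sim_qgram,
    "M2": sim_jaccard,
    "M3": sim_block,
    "M4": sim_liblock,
    "M5": sim_levenshtein,
    "M6": sim_overlap,
}

MEASURE_NAMES: dict[str, str] = {
    "M1": "Qgram",
    "M2": "Jaccard",
    "M3": "Block distance",
    "M4": "LiBlock",
    "M5": "Levenshtein",
    "M6": "Overlap coefficient",
}


def register_measure(
    method_id: str,
    fn: Callable[[Tokens, Tokens], float],
    name: str | None = None,
    overwrite: bool = False,
) -> None:
    """Register a user-supplied measure under ``method_id``.

    The callable must map two token sequences to a float in [0, 1].
    """
    if method_id in MEASURES and not overwrite:
        raise ValueError(f"method id {method_id!r} already registered")
    MEASURES[method_id] = fn
    MEASURE_NAMES[method_id] = name or method_id
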
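"""Readers and writers for every file format the toolkit touches.

Formats
-------
* **Pair file** — UTF-8 TSV, no header: ``sentence_1 <TAB> sentence_2
  <TAB> score``; a trailing 4th+ column is tolerated and ignored.
  Scores are normalized human similarity judgements in [0, 1]; raw
  scales (e.g. 0-4) are accepted only through an explicit
  ``raw_score_max`` divisor.
* **Annotation file** — TSV standoff format externalizing the output
  of a biomedical NER tool (MetaMap, MetaMap Lite, cTAKES): columns
  ``pair_id, sentence_index, start, end, cui``. Offsets are 0-based,
  half-open, counted in Unicode code points of the raw sentence.
* **Raw score file** — CSV ``pair_id,human,score``, one row per pair.
* **Stop-word list** — plain text, one lowercase token per line,
  ``#`` comments allowed.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "SentencePair",
    "PairDataset",
    "AnnotationSet",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "read_annotations",
    "read_stopwords",
    "write_raw_scores",
    "read_raw_scores",
]

_CUI_RE = re.compile(r"^C\d+$")


@dataclass(frozen=True)
class SentencePair:
    """One benchmark item: two raw sentences and a human score in [0, 1]."""

    pair_id: int
    sentence_1: str
    sentence_2: str
    human_score: float

    def __post_init__(self) -> None:
        if not self.sentence_1.strip() or not self.sentence_2.strip():
            raise ValueError(f"pair {self.pair_id}: empty sentence")
        if not 0.0 <= self.human_score <= 1.0:
            raise ValueError(
                f"pair {self.pair_id}: human score {self.human_score} outside [0, 1]"
            )


@dataclass
class PairDataset:
    """An ordered, named collection of sentence pairs."""

    name: str
    pairs: list[SentencePair]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError(f"dataset {self.name!r}: no pairs")
        ids = [p.pair_id for p in self.pairs]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(f"dataset {self.name!r}: pair ids not contiguous from 1")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[SentencePair]:
        return iter(self.pairs)

    def human_scores(self) -> list[float]:
        return [p.human_score for p in self.pairs]

    def subset(self, pair_ids: Iterable[int], name: str | None = None) -> "PairDataset":
        """Re-indexed dataset restricted to ``pair_ids`` (original order kept)."""
        wanted = set(pair_ids)
        picked = [p for p in self.pairs if p.pair_id in wanted]
        renum = [
            SentencePair(i + 1, p.sentence_1, p.sentence_2, p.human_score)
            for i, p in enumerate(picked)
        ]
        return PairDataset(name or f"{self.name}-subset", renum)


@dataclass
class AnnotationSet:
    """Standoff character-span -> CUI annotations, keyed by (pair_id, sentence_index).

    Spans for one sentence are kept sorted by start offset. Overlapping
    spans are permitted here; the pre-processing stage resolves them.
    """

    entries: dict[tuple[int, int], list[tuple[int, int, str]]] = field(
        default_factory=dict
    )

    def add(self, pair_id: int, sentence_index: int, start: int, end: int, cui: str) -> None:
        if sentence_index not in (1, 2):
            raise ValueError(f"sentence_index must be 1 or 2, got {sentence_index}")
        if start < 0 or end <= start:
            raise ValueError(f"bad span ({start}, {end})")
        if not _CUI_RE.match(cui):
            raise ValueError(f"bad CUI code {cui!r}")
        spans = self.entries.setdefault((pair_id, sentence_index), [])
        spans.append((start, end, cui))
        spans.sort(key=lambda t: (t[0], t[1]))

    def spans_for(self, pair_id: int, sentence_index: int) -> list[tuple[int, int, str]]:
        return self.entries.get((pair_id, sentence_index), [])

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())


def read_pairs_tsv(
    path: str | Path, name: str | None = None, raw_score_max: float | None = None
) -> PairDataset:
    """Read a sentence-pair benchmark TSV.

    Parameters
    ----------
    path
        TSV file, one pair per line: ``s1 <TAB> s2 <TAB> score``.
    name
        Dataset label; defaults to the file stem. The label is always
        caller-supplied data, never inferred from file content.
    raw_score_max
        If given, scores are divided by this maximum before the [0, 1]
        check (for benchmarks scored on a raw scale such as 0-4).
    """
    path = Path(path)
    pairs: list[SentencePair] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            s1, s2 = fields[0], fields[1]
            try:
                score = float(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path.name}:{lineno}: unparseable score {fields[2]!r}"
                ) from exc
            if raw_score_max is not None:
                score /= raw_score_max
            if not 0.0 <= score <= 1.0:
                raise ValueError(
                    f"{path.name}:{lineno}: score {score} outside [0, 1] "
                    "(pass raw_score_max to rescale)"
                )
            try:
                pairs.append(SentencePair(len(pairs) + 1, s1, s2, score))
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: {exc}") from exc
    if not pairs:
        raise ValueError(f"{path.name}: no pairs")
    return PairDataset(name or path.stem, pairs)


def write_pairs_tsv(dataset: PairDataset, path: str | Path) -> Path:
    """Write a dataset in the pair-file TSV dialect (inverse of read)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for p in dataset.pairs:
            fh.write(f"{p.sentence_1}\t{p.sentence_2}\t{p.human_score!r}\n")
    return path


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read a standoff CUI annotation file; an empty file means 'no NER'."""
    path = Path(path)
    out = AnnotationSet()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ValueError(
                    f"{path.name}:{lineno}: expected 5 fields, got {len(fields)}"
                )
            try:
                pair_id = int(fields[0])
                sent_idx = int(fields[1])
                start = int(fields[2])
                end = int(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: non-integer field") from exc
            try:
                out.add(pair_id, sent_idx, start, end, fields[4])
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: {exc}") from exc
    return out


def read_stopwords(path: str | Path) -> frozenset[str]:
    """Read a stop-word list: one lowercase token per line, '#' comments."""
    path = Path(path)
    words: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            word = line.split("#", 1)[0].strip()
            if word:
                words.add(word.lower())
    return frozenset(words)


def write_raw_scores(
    dataset: PairDataset, method_label: str, scores: list[float], path: str | Path
) -> Path:
    """Persist per-pair raw similarity scores as CSV ``pair_id,human,score``.

    All measures in this toolkit are bounded in [0, 1]; out-of-range
    scores are rejected rather than silently written.
    """
    if len(scores) != len(dataset):
        raise ValueError(
            f"{method_label}: {len(scores)} scores for {len(dataset)} pairs"
        )
    for s in scores:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"{method_label}: score {s} outside [0, 1]")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pair_id", "human", "score"])
        for pair, score in zip(dataset.pairs, scores):
            writer.writerow([pair.pair_id, repr(pair.human_score), repr(score)])
    return path


def read_raw_scores(path: str | Path) -> tuple[list[int], list[float], list[float]]:
    """Round-trip reader for :func:`write_raw_scores` output."""
    path = Path(path)
    ids: list[int] = []
    human: list[float] = []
    scores: list[float] = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["pair_id", "human", "score"]:
            raise ValueError(f"{path.name}: unexpected header {header}")
        for row in reader:
            ids.append(int(row[0]))
            human.append(float(row[1]))
            scores.append(float(row[2]))
    return ids, human, scores
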
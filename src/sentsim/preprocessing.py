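"""Configurable sentence pre-processing pipeline.

The pipeline applies five stages in a fixed order:

1. **Annotation substitution** — character spans recognized by an
   external biomedical NER tool are replaced by their UMLS CUI codes
   (``C`` + digits), turning e.g. ``Centrosomes increase ...`` into
   ``C0242608 increase ...``.
2. **Tokenization** — whitespace splitting or a deterministic
   rule-based (treebank-style) tokenizer.
3. **Lower-casing** — optional; CUI codes keep their uppercase ``C``
   prefix so they stay detectable downstream.
4. **Character filtering** — punctuation/special characters from a
   named dialect are mapped to spaces and tokens re-split.
5. **Stop-word removal** — against a plain-text word list.

Stage order is fixed; each stage is deterministic, so the same input
and configuration always produce the same token sequence.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from sentsim.corpus_io import AnnotationSet, SentencePair, read_stopwords

__all__ = [
    "PreprocessingConfig",
    "TokenSequence",
    "CHAR_FILTER_DIALECTS",
    "PACKAGED_STOPWORD_LISTS",
    "apply_annotations",
    "tokenize",
    "lowercase",
    "filter_chars",
    "remove_stopwords",
    "resolve_stopwords",
    "preprocess",
]

_CUI_RE = re.compile(r"^C\d+$")

# Unicode dash variants; hyphen-minus lives in string.punctuation already.
_DASHES = "‐‑‒–—―−"

#: Editable removal sets per character-filter dialect. 'default' strips all
#: ASCII punctuation plus Unicode dashes (this is what renders "miR-17–5p"
#: as "mir 17 5p"); 'biosses' adds typographic quotes and symbol characters;
#: 'blagec2019' behaves like 'default' but keeps periods that are internal
#: to abbreviations (flanked by alphanumerics on both sides).
CHAR_FILTER_DIALECTS: dict[str, str] = {
    "default": string.punctuation + _DASHES,
    "biosses": string.punctuation + _DASHES + "“”‘’«»…•·°§±×÷©®™",
    "blagec2019": string.punctuation + _DASHES,
}

#: Names of the stop-word lists shipped with the package (see data/).
PACKAGED_STOPWORD_LISTS = ("nltk2018", "biosses")


@dataclass(frozen=True)
class PreprocessingConfig:
    """One cell of the pre-processing configuration space.

    Parameters
    ----------
    ner_annotations
        Path to a standoff CUI annotation file, or None for no NER.
    tokenizer
        ``"whitespace"`` or ``"rulebased"``.
    lowercase
        Whether to lower-case tokens (CUI codes are exempt).
    char_filter
        ``"none"`` or a dialect name in :data:`CHAR_FILTER_DIALECTS`.
    stopword_list
        ``None``, a packaged list name (``"nltk2018"``, ``"biosses"``),
        or a path to a plain-text word list.
    """

    ner_annotations: str | None = None
    tokenizer: str = "whitespace"
    lowercase: bool = True
    char_filter: str = "none"
    stopword_list: str | None = None

    def __post_init__(self) -> None:
        if self.tokenizer not in ("whitespace", "rulebased"):
            raise ValueError(f"unknown tokenizer {self.tokenizer!r}")
        if self.char_filter != "none" and self.char_filter not in CHAR_FILTER_DIALECTS:
            raise ValueError(f"unknown char filter {self.char_filter!r}")

    def label(self) -> str:
        return (
            f"TOK-{self.tokenizer}"
            f"_LC-{'yes' if self.lowercase else 'no'}"
            f"_CF-{self.char_filter}"
            f"_SW-{self.stopword_list or 'none'}"
            f"_NER-{'yes' if self.ner_annotations else 'no'}"
        )


@dataclass(frozen=True)
class TokenSequence:
    """Ordered tokens (words or CUI codes) of one pre-processed sentence."""

    tokens: tuple[str, ...]
    provenance: PreprocessingConfig | None = None

    def __post_init__(self) -> None:
        for t in self.tokens:
            if not t or any(c.isspace() for c in t):
                raise ValueError(f"invalid token {t!r}")

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    def text(self) -> str:
        return " ".join(self.tokens)


def _resolve_overlaps(
    spans: Sequence[tuple[int, int, str]]
) -> list[tuple[int, int, str]]:
    """Longest span wins, then leftmost, then original file order."""
    ordered = sorted(
        enumerate(spans), key=lambda t: (-(t[1][1] - t[1][0]), t[1][0], t[0])
    )
    accepted: list[tuple[int, int, str]] = []
    for _, (start, end, cui) in ordered:
        if all(end <= a or start >= b for a, b, _ in accepted):
            accepted.append((start, end, cui))
    accepted.sort(key=lambda t: t[0])
    return accepted


def apply_annotations(
    sentence: str, spans: Sequence[tuple[int, int, str]]
) -> str:
    """Replace annotated character spans with their CUI codes.

    Overlapping spans are resolved first (longest, then leftmost, then
    file order); each surviving span's surface text is replaced by its
    CUI code delimited by spaces. Unannotated text is unchanged.
    """
    for start, end, _ in spans:
        if start < 0 or end > len(sentence) or end <= start:
            raise ValueError(
                f"span ({start}, {end}) out of bounds for sentence of "
                f"length {len(sentence)}"
            )
    out = sentence
    for start, end, cui in reversed(_resolve_overlaps(spans)):
        out = out[:start] + " " + cui + " " + out[end:]
    return out


# Treebank-style approximation: keep hyphenated/apostrophized words whole,
# emit each remaining punctuation character as its own token.
_RULEBASED_RE = re.compile(
    r"\w+(?:[-" + _DASHES + r"'’]\w+)*|[^\w\s]", re.UNICODE
)


def tokenize(sentence: str, mode: str = "whitespace") -> list[str]:
    """Split a sentence into tokens; the empty sentence yields []."""
    if mode == "whitespace":
        return sentence.split()
    if mode == "rulebased":
        return _RULEBASED_RE.findall(sentence)
    raise ValueError(f"unknown tokenizer {mode!r}")


def lowercase(tokens: Sequence[str], enabled: bool = True) -> list[str]:
    """Lower-case every token except CUI codes (uppercase 'C' kept)."""
    if not enabled:
        return list(tokens)
    return [t if _CUI_RE.match(t) else t.lower() for t in tokens]


def _filter_token(token: str, removal: str, keep_internal_periods: bool) -> list[str]:
    chars = []
    for i, c in enumerate(token):
        if c in removal:
            if (
                keep_internal_periods
                and c == "."
                and 0 < i < len(token) - 1
                and token[i - 1].isalnum()
                and token[i + 1].isalnum()
            ):
                chars.append(c)
            else:
                chars.append(" ")
        else:
            chars.append(c)
    return "".join(chars).split()


def filter_chars(tokens: Sequence[str], dialect: str = "none") -> list[str]:
    """Map a dialect's removal characters to spaces and re-split tokens.

    CUI codes pass through untouched; empty fragments are dropped;
    ``"none"`` is the identity.
    """
    if dialect == "none":
        return list(tokens)
    try:
        removal = CHAR_FILTER_DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown char filter {dialect!r}") from None
    keep_periods = dialect == "blagec2019"
    out: list[str] = []
    for token in tokens:
        if _CUI_RE.match(token):
            out.append(token)
        else:
            out.extend(_filter_token(token, removal, keep_periods))
    return out


def remove_stopwords(
    tokens: Sequence[str], stopwords: frozenset[str] | None
) -> list[str]:
    """Drop tokens whose lower-cased form is in the stop list."""
    if stopwords is None:
        return list(tokens)
    return [t for t in tokens if t.lower() not in stopwords]


def resolve_stopwords(spec: str | None) -> frozenset[str] | None:
    """Resolve a stop-list spec: None, a packaged name, or a file path."""
    if spec is None:
        return None
    if spec in PACKAGED_STOPWORD_LISTS:
        data_path = Path(__file__).parent / "data" / f"{spec}.txt"
        return read_stopwords(data_path)
    return read_stopwords(spec)


def preprocess(
    pair: SentencePair,
    config: PreprocessingConfig,
    annotations: AnnotationSet | None = None,
    stopwords: frozenset[str] | None = None,
) -> tuple[TokenSequence, TokenSequence]:
    """Run the full pipeline on both sentences of a pair.

    ``stopwords`` may be passed pre-resolved to avoid re-reading the
    list file per pair; otherwise it is resolved from the config.
    """
    if stopwords is None:
        stopwords = resolve_stopwords(config.stopword_list)
    results = []
    for idx, sentence in ((1, pair.sentence_1), (2, pair.sentence_2)):
        text = sentence
        if annotations is not None:
            text = apply_annotations(text, annotations.spans_for(pair.pair_id, idx))
        toks = tokenize(text, config.tokenizer)
        toks = lowercase(toks, config.lowercase)
        toks = filter_chars(toks, config.char_filter)
        toks = remove_stopwords(toks, stopwords)
        results.append(TokenSequence(tuple(toks), provenance=config))
    return results[0], results[1]
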
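"""Synthetic benchmarks and curated worked examples.

Two sources of test data make the whole toolkit exercisable without
downloading any benchmark:

* :func:`generate_dataset` builds synthetic sentence-pair benchmarks
  with a *planted* link between token-overlap fraction and the human
  score, so recovery of that signal by the string measures (and by
  the evaluation/significance harness downstream) can be checked
  quantitatively.
* :func:`worked_examples` packages a handful of real BIOSSES sentence
  pairs (the benchmark's sentences carry no licensing restrictions)
  together with their published pre-processed forms and reference
  human/method scores — the best- and worst-case pairs of the
  best-performing method of each family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from sentsim.corpus_io import AnnotationSet, PairDataset, SentencePair

__all__ = [
    "GeneratorSpec",
    "generate_dataset",
    "WorkedExample",
    "worked_examples",
    "worked_example_annotations",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic benchmark generator.

    Each pair shares a planted fraction of a common vocabulary; the
    human score is a monotone function of that overlap plus Gaussian
    noise, clipped to [0, 1]. The same spec always yields a
    byte-identical dataset.
    """

    n_pairs: int = 200
    vocab_size: int = 400
    sentence_length: tuple[int, int] = (6, 18)
    overlap_range: tuple[float, float] = (0.0, 1.0)
    link: Callable[[float], float] | None = None  # None = identity
    noise_sd: float = 0.05
    cui_fraction: float = 0.1
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        lo, hi = self.sentence_length
        if not 1 <= lo <= hi:
            raise ValueError(f"bad sentence length range ({lo}, {hi})")
        if not 0.0 <= self.overlap_range[0] <= self.overlap_range[1] <= 1.0:
            raise ValueError("overlap_range must be within [0, 1]")
        if 2 * hi > self.vocab_size:
            raise ValueError("vocabulary too small for the sentence lengths")


def _vocabulary(spec: GeneratorSpec, rng: np.random.Generator) -> list[str]:
    n_cui = int(round(spec.cui_fraction * spec.vocab_size))
    words = [f"w{i:04d}x" for i in range(spec.vocab_size - n_cui)]
    cuis = [f"C{7000000 + i}" for i in range(n_cui)]
    vocab = words + cuis
    rng.shuffle(vocab)
    return vocab


def generate_dataset(spec: GeneratorSpec) -> tuple[PairDataset, dict]:
    """Generate a synthetic benchmark with a planted overlap/score link.

    Returns the dataset plus metadata: the planted overlap fraction per
    pair (the realized Jaccard of the two token sets) and the realized
    Pearson correlation between those Jaccard values and the human
    scores (``planted_correlation``).
    """
    rng = np.random.default_rng(spec.seed)
    vocab = _vocabulary(spec, rng)
    link = spec.link or (lambda u: u)
    lo, hi = spec.sentence_length
    pairs: list[SentencePair] = []
    jaccards: list[float] = []
    for i in range(spec.n_pairs):
        n1 = int(rng.integers(lo, hi + 1))
        n2 = int(rng.integers(lo, hi + 1))
        u = float(rng.uniform(*spec.overlap_range))
        n_shared = int(round(u * min(n1, n2)))
        need = n1 + n2 - n_shared
        if need > len(vocab):
            raise ValueError("infeasible length/overlap combination")
        draw = rng.choice(len(vocab), size=need, replace=False)
        tokens = [vocab[j] for j in draw]
        shared = tokens[:n_shared]
        only1 = tokens[n_shared : n1]
        only2 = tokens[n1:]
        # the shared tokens form one contiguous common block (a shared
        # phrase) so order-sensitive measures see the overlap too
        rng.shuffle(only1)
        rng.shuffle(only2)
        cut1 = int(rng.integers(0, len(only1) + 1))
        cut2 = int(rng.integers(0, len(only2) + 1))
        t1 = only1[:cut1] + shared + only1[cut1:]
        t2 = only2[:cut2] + shared + only2[cut2:]
        jac = n_shared / (n1 + n2 - n_shared)
        jaccards.append(jac)
        human = link(jac) + float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd else link(jac)
        human = float(np.clip(human, 0.0, 1.0))
        pairs.append(SentencePair(i + 1, " ".join(t1), " ".join(t2), human))
    dataset = PairDataset(spec.name, pairs)
    humans = dataset.human_scores()
    if len(set(humans)) > 1 and len(set(jaccards)) > 1:
        r = float(np.corrcoef(jaccards, humans)[0, 1])
    else:
        r = float("nan")
    meta = {"planted_overlaps": jaccards, "planted_correlation": r, "spec": spec}
    return dataset, meta


@dataclass(frozen=True)
class WorkedExample:
    """One curated benchmark pair with its published reference values."""

    method_id: str
    case: str  # "low" or "high" absolute similarity error
    raw_s1: str
    raw_s2: str
    pre_s1: str  # pre-processed form, whitespace-joinable tokens
    pre_s2: str
    human: float
    method_score: float


_EXAMPLES: dict[tuple[str, str], WorkedExample] = {}


def _add(ex: WorkedExample) -> None:
    _EXAMPLES[(ex.method_id, ex.case)] = ex


# LiBlock (M4): best- and worst-case BIOSSES pairs under its best
# configuration (cTAKES annotations, rule-based tokenizer, lower-casing,
# default char filter, nltk2018 stop list).
_add(WorkedExample(
    "M4", "low",
    "Centrosomes increase both in size and in microtubule-nucleating "
    "capacity just before mitotic entry.",
    "Functional studies showed that, when introduced into cell lines, "
    "miR-146a was found to promote cell proliferation in cervical cancer "
    "cells, which suggests that miR-146a works as an oncogenic miRNA in "
    "these cancers.",
    "C0242608 increase size C0026046 nucleating capacity mitotic entry",
    "functional studies showed introduced C0007634 lines mir 146a found "
    "promote C0007634 C0334094 C4048328 C0007634 suggests mir 146a works "
    "oncogenic mirna C0006826",
    0.0, 0.0,
))
_add(WorkedExample(
    "M4", "high",
    "Consequently miRNAs have been demonstrated to act either as oncogenes "
    "(e.g., miR-155, miR-17–5p and miR-21) or tumor suppressors (e.g., "
    "miR-34, miR-15a, miR-16–1 and let-7)",
    "Given the extensive involvement of miRNA in physiology, dysregulation "
    "of miRNA expression can be associated with cancer pathobiology "
    "including oncogenesis], proliferation, epithelial-mesenchymal "
    "transition, metastasis, aberrations in metabolism, and angiogenesis, "
    "among others",
    "consequently mirnas demonstrated C0427611 either oncogenes e g mir 155 "
    "mir 17 5p mir 21 C0027651 suppressors e g mir 34 mir 15a mir 16 1 let 7",
    "given extensive involvement mirna physiology dysregulation mirna "
    "C0185117 associated C0006826 pathobiology including oncogenesis "
    "C0334094 epithelial mesenchymal transition metastasis aberrations "
    "C0025519 angiogenesis among others",
    0.7, 0.0,
))
# COM (M17): ontology-based aggregate; pre-processed forms shown for the
# UBSM component (cTAKES annotations). Carried as data only.
_add(WorkedExample(
    "M17", "low",
    "The in vivo data is still preliminary and other potential roadblocks "
    "such as drug resistance have not been examined.",
    "The GEM model used in this study retains wild-type Tp53, suggesting "
    "that the tumors successfully treated with bortezomib and fasudil "
    "might not be as aggressive as those in most NSCLC patients",
    "vivo data still preliminary potential roadblocks C0013227 resistance "
    "examined",
    "gem model used study retains wild type tp53 suggesting C0027651 "
    "successfully treated C1176309 fasudil might aggressive C0007131 "
    "patients",
    0.0, 0.0,
))
_add(WorkedExample(
    "M17", "high",
    "The oncogenic activity of mutant Kras appears dependent on functional "
    "Craf, but not on Braf",
    "Notably, c-Raf has recently been found essential for development of "
    "K-Ras-driven NSCLCs",
    "oncogenic C0026606 mutant kras appears dependent functional craf braf",
    "notably c raf recently found essential development k C0525678 driven "
    "nsclcs",
    0.75, 0.0,
))
# BioWordVec (M26): embedding method; scores carried as data only (no
# embedding computation in this toolkit).
_add(WorkedExample(
    "M26", "low",
    "The up-regulation of miR-146a was also detected in cervical cancer "
    "tissues.",
    "The expression of miR-146a has been found to be up-regulated in "
    "cervical cancer.",
    "the up regulation of mir 146a was also detected in cervical cancer "
    "tissues",
    "the expression of mir 146a has been found to be up regulated in "
    "cervical cancer",
    1.0, 0.986,
))
_add(WorkedExample(
    "M26", "high",
    "This oxidative branch activity is elevated in comparison to many "
    "cancer cell lines, where the oxidative branch is typically reduced "
    "and accounts for <20% of the carbon flow through PPP.",
    "The Downward laboratory went all the way from identifying GATA2 as a "
    "novel synthetic lethal gene to validating it using Kras-driven GEM "
    "models.",
    "this oxidative branch activity is elevated in comparison to many "
    "cancer cell lines where the oxidative branch is typically reduced and "
    "accounts for < 20% of the carbon flow through ppp",
    "the downward laboratory went all the way from identifying gata2 as a "
    "novel synthetic lethal gene to validating it using kras driven gem "
    "models",
    0.0, 0.912,
))


def worked_examples() -> dict[tuple[str, str], WorkedExample]:
    """All curated examples, keyed by (method id, 'low' | 'high')."""
    return dict(_EXAMPLES)


def worked_example_annotations() -> tuple[PairDataset, AnnotationSet]:
    """The LiBlock best-case pair with reconstructed CUI annotation spans.

    The spans are best-effort reconstructions from the published
    pre-processed form (surface string -> CUI); they exercise the
    annotation-substitution stage of the pipeline. Measure-level checks
    should use the verbatim pre-processed tokens from
    :func:`worked_examples` instead, which do not depend on this
    reconstruction.
    """
    ex = _EXAMPLES[("M4", "low")]
    dataset = PairDataset(
        "worked-example", [SentencePair(1, ex.raw_s1, ex.raw_s2, ex.human)]
    )
    ann = AnnotationSet()

    def _mark(sent_idx: int, text: str, surface: str, cui: str, start_at: int = 0) -> int:
        pos = text.find(surface, start_at)
        if pos < 0:
            raise AssertionError(f"surface {surface!r} not found")
        ann.add(1, sent_idx, pos, pos + len(surface), cui)
        return pos + len(surface)

    _mark(1, ex.raw_s1, "Centrosomes", "C0242608")
    _mark(1, ex.raw_s1, "microtubule", "C0026046")
    s2 = ex.raw_s2
    pos = _mark(2, s2, "cell", "C0007634")           # "cell lines"
    pos = _mark(2, s2, "cell", "C0007634", pos)      # "cell proliferation"
    _mark(2, s2, "proliferation", "C0334094")
    _mark(2, s2, "cervical cancer", "C4048328")
    _mark(2, s2, "cells", "C0007634", pos + 1)
    _mark(2, s2, "cancers", "C0006826")
    return dataset, ann
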
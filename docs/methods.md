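# Methods

## Measures

All measures operate on pre-processed token sequences and return a
similarity in [0, 1]; all are symmetric, score 1 on identical
non-empty inputs, and 0 on disjoint vocabularies (Levenshtein
excepted, which compares characters).

**LiBlock** is the equal-weight aggregation of the Block-distance
similarity and a binary-vector cosine, with a fallback branch:

    liblock(s1, s2) = block(s1, s2)                         if cos = 0
                      ½ block(s1, s2) + ½ cos(σ(s1), σ(s2)) otherwise

The binary vectors are built over the union dictionary D with
b_i = 1 iff the i-th dictionary word occurs in that sentence's own
word set. (A literal reading in which membership is tested against D
itself would make both vectors all-ones and the cosine identically 1;
the implemented reading is the only non-degenerate one and reduces to
the closed form |S₁∩S₂|/√(|S₁||S₂|).) The ½/½ weights are part of
the measure's definition; the constructor exposes them for
experimentation only.

Similarly, the Jaccard measure is the standard |∩|/|∪| (an inverted
form would exceed 1), and the q-gram measure is the Dice coefficient
over multisets of token q-grams, 2·|shared|/(|g₁|+|g₂|), with q = 3
by default, token-level grams, multiset counting, and no boundary
padding (padding is configurable ground we deliberately did not
take: unpadded is the simplest interpretation of "sets of q words").
Sequences shorter than q yield no grams; two equal short sequences
score 1, otherwise 0.

**Levenshtein** is character-level on the space-joined pre-processed
sentence, unit costs, normalized as 1 − d/max(|a|, |b|) so it is
bounded in [0, 1]; token-level granularity was considered and
rejected as the default because character-level is the convention of
the reference string-metric libraries. The distance itself is
computed by the `edlib` C library; a pure dynamic-programming
fallback handles alphabets beyond edlib's 256-symbol limit, and an
independent DP oracle checks both in the tests.

## Pre-processing pipeline

Fixed stage order: annotation substitution → tokenization →
lower-casing → character filtering → stop-word removal. Permuting
stages is not supported. Every stage is deterministic, never emits
empty or whitespace-containing tokens, and preserves CUI codes
(`C` + digits) intact — lower-casing keeps their uppercase prefix,
character filtering passes them through.

* **Annotations** come from standoff files (0-based, half-open
  code-point offsets) emulating the output of biomedical NER tools;
  the toolkit performs no NER itself. Overlapping spans are resolved
  longest-first, then leftmost, then file order; losers are dropped.
  The NER-tool side of that behaviour is undocumented upstream, so
  the rule is ours and is stated here.
* **Tokenizers**: whitespace, or a deterministic regex treebank-style
  rule set (hyphenated words kept whole, other punctuation split off)
  standing in for external Java tokenizers; the tokenizer choice is a
  string key so an exact external tokenizer can be substituted.
* **Character-filter dialects** live in one editable table.
  `default` removes ASCII punctuation plus Unicode dash variants
  (this is what turns "miR-17–5p" into "mir 17 5p"); `biosses` adds
  typographic quotes and symbol characters; `blagec2019` keeps
  periods internal to abbreviations. The exact membership of the
  named sets is not published anywhere we could consult, so the
  shipped tables are best-effort and user-overridable.
* **Stop lists**: two packaged plain-text lists — the widely
  distributed 179-word English list (`nltk2018`) and a compact
  synthetic best-effort `biosses`-style list — both replaceable by
  any file of one word per line.

## Evaluation

Pearson r, Spearman ρ (average ranks for ties — the classic
6Σd²/n(n²−1) shortcut is exact only without ties, and real
benchmarks have tied human scores), and h = 2rρ/(r+ρ). Correlations
on zero-variance inputs raise; a constant measure is reported as an
error per dataset rather than silently scored. During a full-dataset
run, a pair whose pre-processing leaves the measure undefined (e.g.
both sentences empty after stop-word removal) degrades to score 0
with a logged warning so that long sweeps complete. Report tables
round to 3 decimals, round-half-even.

## Significance machinery

Large benchmarks are split into k parts with sizes as equal as
possible (max−min ≤ 1), contiguous in file order, larger parts
first; the split is deterministic and unseeded by default, with an
optional seeded shuffle, and the plan is written out as data so its
effect can be probed. Methods are compared by a paired one-sided
t-test on their per-part harmonic-score vectors (H₀: mean difference
0), n−1 degrees of freedom. Zero-variance difference vectors do not
error: all-zero differences report the symmetric-null limit p = 0.5
and a constant nonzero shift reports the limit 0 (or 1), each
flagged as degenerate, so full method×method matrices always
complete. Bonferroni: α_c = α/m with m the number of comparisons
backing one claim; m is configurable per family because the family
size is a property of the claim, not of the matrix.

The subset study draws equal-size subsets uniformly without
replacement, computes h per subset, and reports the sample's
Shapiro–Wilk p, a chi-square goodness-of-fit p against the
moment-fitted normal (Sturges binning, ddof = 2 for the two
estimated parameters — the binning is unspecified upstream, so
Sturges is our documented choice), and Q-Q points. Subset indices
are sorted before scoring so that identical subsets give bit-identical
h regardless of draw order; full-size subsets are flagged degenerate.

## Error analysis

e = sim − human per pair; the density estimate is a Gaussian KDE
with Silverman's rule-of-thumb bandwidth on a 512-point grid over
[min − 3bw, max + 3bw], mirroring the defaults of the reference
statistical package's `density` function. The reported mean is the
arithmetic sample mean (not the density mean), and summaries
(mean/min/max) use raw measure outputs with no per-dataset
rescaling. Extreme pairs are selected by |e| with ties broken by
pair id ascending at both ends.

## Synthetic benchmark generator

Each generated pair shares a planted fraction u of tokens: the
shared tokens form one contiguous common block (a shared phrase) so
order-sensitive measures also see the overlap, side tokens are
disjoint between the two sentences, and tokens are distinct within a
sentence, making the realized Jaccard exactly
n_shared/(n₁+n₂−n_shared). The human score is link(u) plus Gaussian
noise, clipped to [0, 1]. Defaults — 200 pairs, 400-token vocabulary
with 10 % CUI-shaped tokens, sentence lengths 6–18, identity link,
noise sd 0.05 — were chosen once to resemble benchmarks of a few
hundred pairs whose human scores spread over the full scale; the CUI
fraction exists to exercise the pipeline's CUI-preservation rules.
Generation is fully reproducible: the same spec yields byte-identical
files.

What the generator does *not* emulate: biomedical vocabulary
statistics, syntax, synonymy/meronymy, or annotation noise. Passing
tests on generated data therefore demonstrate that the machinery
recovers a planted overlap signal, not that any measure attains a
particular score on real benchmarks.

The subset-normality tests use a deliberately "well-behaved"
generated dataset (mid-range link 0.15 + 0.7u, noise sd 0.3): when
the planted correlation is high, the sampling distribution of a
correlation statistic over subsets is noticeably left-skewed and
normality tests rightly reject, so a moderate correlation with
scores away from the clip boundaries is the regime in which the
h-distribution is close to normal.

## Worked examples

`fixtures.worked_examples()` carries a handful of real BIOSSES
sentence pairs (license-free) with their published pre-processed
forms and reference human/method scores — the best and worst cases
of the best-performing method of several families. The CUI
annotation spans for the LiBlock best case are reverse-engineered
from the published pre-processed form and are used only to test the
annotation-substitution stage; measure-level checks consume the
verbatim pre-processed tokens and do not depend on that
reconstruction. Embedding- and ontology-method examples are carried
as data only; no embedding or ontology computation is performed.

## Known limitations

* The rule-based tokenizer and the char-filter/stop-list tables are
  deterministic approximations of external tools and unpublished
  resources; exact replication of results that depend on those tools
  requires substituting them via the provided extension points.
* Ontology-, embedding- and BERT-based measures are out of scope:
  they enter only through the measure registry, and NER only through
  annotation files.
* Reproducing full published benchmark tables requires the licensed
  datasets and annotation tools; this package ships only the
  machinery plus license-free worked examples and synthetic data.
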
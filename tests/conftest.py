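import numpy as np
import pytest

from sentsim.fixtures import GeneratorSpec, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Mid-size planted-overlap benchmark shared across test modules."""
    spec = GeneratorSpec(n_pairs=200, seed=7)
    return generate_dataset(spec)


def well_behaved_study_data():
    """A 1,000-pair benchmark suited to the subset normality study.

    Moderate overlap/score correlation and human scores kept away from
    the [0, 1] boundaries, so the harmonic score's sampling distribution
    over random subsets is close to normal (a strong planted correlation
    skews it left).
    """
    from sentsim.measures import sim_jaccard

    spec = GeneratorSpec(
        n_pairs=1000, seed=11, vocab_size=300, sentence_length=(6, 12),
        noise_sd=0.3, link=lambda u: 0.15 + 0.7 * u,
    )
    ds, _ = generate_dataset(spec)
    scores = [sim_jaccard(p.sentence_1.split(), p.sentence_2.split()) for p in ds]
    return ds.human_scores(), scores


def random_token_pair(rng, max_len=10, vocab=8):
    """Two short random token sequences over a small shared vocabulary."""
    words = [f"t{i}" for i in range(vocab)]
    n1 = int(rng.integers(0, max_len + 1))
    n2 = int(rng.integers(0, max_len + 1))
    s1 = [words[i] for i in rng.integers(0, vocab, n1)]
    s2 = [words[i] for i in rng.integers(0, vocab, n2)]
    return s1, s2
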
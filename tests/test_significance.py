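import numpy as np
import pytest
from scipy import integrate, special

from sentsim.evaluation import harmonic, pearson, spearman
from sentsim.fixtures import GeneratorSpec, generate_dataset
from sentsim.measures import sim_jaccard
from sentsim.significance import (
    bonferroni_alpha,
    evaluate_on_split,
    paired_t_pvalue,
    significance_matrix,
    split_uniform,
    subset_distribution,
)


def oracle_t_pvalue_upper(t_stat: float, df: int) -> float:
    """One-sided upper tail of Student's t by numeric integration."""
    c = special.gamma((df + 1) / 2) / (np.sqrt(df * np.pi) * special.gamma(df / 2))

    def pdf(x):
        return c * (1 + x**2 / df) ** (-(df + 1) / 2)

    val, _ = integrate.quad(pdf, t_stat, np.inf)
    return val


class TestSplitUniform:
    def test_medsts_sized_partition(self):
        ds, _ = generate_dataset(GeneratorSpec(n_pairs=1068, seed=2, vocab_size=200,
                                               sentence_length=(6, 12)))
        plan = split_uniform(ds, 10)
        assert sorted(plan.part_sizes, reverse=True) == list(plan.part_sizes)
        assert plan.part_sizes == (107,) * 8 + (106,) * 2
        all_ids = [pid for part in plan.assignment for pid in part]
        assert all_ids == list(range(1, 1069))  # contiguous, exhaustive

    def test_singletons_and_identity(self):
        ds, _ = generate_dataset(GeneratorSpec(n_pairs=10, seed=3))
        assert split_uniform(ds, 10).part_sizes == (1,) * 10
        plan1 = split_uniform(ds, 1)
        assert plan1.assignment == (tuple(range(1, 11)),)

    def test_k_larger_than_dataset_rejected(self):
        ds, _ = generate_dataset(GeneratorSpec(n_pairs=5, seed=3))
        with pytest.raises(ValueError):
            split_uniform(ds, 6)

    def test_seeded_shuffle_is_a_permutation(self):
        ds, _ = generate_dataset(GeneratorSpec(n_pairs=20, seed=3))
        plan = split_uniform(ds, 4, seed=1)
        ids = sorted(pid for part in plan.assignment for pid in part)
        assert ids == list(range(1, 21))
        assert split_uniform(ds, 4, seed=1) == plan  # deterministic given seed


class TestPairedT:
    def test_identical_vectors_give_half(self):
        h = [0.7, 0.8, 0.75, 0.9]
        p, degen = paired_t_pvalue(h, h)
        assert p == 0.5 and degen

    def test_constant_nonzero_differences_flagged_limit(self):
        a = [0.5, 0.6, 0.7, 0.8]
        b = [v - 0.1 for v in a]
        p, degen = paired_t_pvalue(a, b)
        assert p == 0.0 and degen
        p_rev, degen_rev = paired_t_pvalue(b, a)
        assert p_rev == 1.0 and degen_rev

    def test_agrees_with_numeric_integration_oracle(self):
        diffs = np.array(
            [0.05, -0.01, 0.04, 0.02, 0.03, 0.02, 0.05, -0.02, 0.01, 0.03, 0.04, 0.00]
        )
        b = np.linspace(0.5, 0.61, len(diffs))
        a = b + diffs
        p, degen = paired_t_pvalue(a, b)
        assert not degen
        n = len(diffs)
        t_stat = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(n))
        assert p == pytest.approx(oracle_t_pvalue_upper(t_stat, n - 1), abs=1e-8)

    def test_directional_pvalues_sum_to_one(self, rng):
        for _ in range(100):
            a = rng.normal(0.7, 0.05, 12)
            b = rng.normal(0.68, 0.05, 12)
            pa, _ = paired_t_pvalue(a, b)
            pb, _ = paired_t_pvalue(b, a)
            assert pa + pb == pytest.approx(1.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t_pvalue([0.1, 0.2], [0.1])


class TestBonferroni:
    def test_published_threshold(self):
        assert bonferroni_alpha(0.05, 5) == pytest.approx(0.01)

    def test_single_comparison_identity(self):
        assert bonferroni_alpha(0.05, 1) == 0.05

    def test_division(self):
        assert bonferroni_alpha(0.05, 17) == pytest.approx(0.0029412, abs=5e-8)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_alpha(1.5, 3)

    def test_increasing_m_never_creates_significance(self, rng):
        a = rng.normal(0.7, 0.03, 12)
        b = rng.normal(0.65, 0.03, 12)
        p, _ = paired_t_pvalue(a, b)
        sig = [p < bonferroni_alpha(0.05, m) for m in range(1, 30)]
        # once non-significant, stays non-significant as m grows
        assert sig == sorted(sig, reverse=True)


def _twelve_subdataset_h_vectors(seed=3):
    """12 synthetic subdatasets; a faithful measure vs a noise measure.

    The generator plants human = overlap, so Jaccard tracks the human
    score almost perfectly (h near 1) while a pseudo-random scorer has
    h near 0: separation well above 0.3.
    """
    rng = np.random.default_rng(seed)

    def noise_measure(t1, t2):
        return float(rng.uniform())

    h_good, h_noise = [], []
    for i in range(12):
        ds, _ = generate_dataset(
            GeneratorSpec(n_pairs=100, seed=seed * 100 + i, noise_sd=0.02)
        )
        humans = ds.human_scores()
        for fn, out in ((sim_jaccard, h_good), (noise_measure, h_noise)):
            scores = [
                fn(p.sentence_1.split(), p.sentence_2.split()) for p in ds
            ]
            r = pearson(scores, humans)
            out.append(harmonic(r, spearman(scores, humans)))
    return h_good, h_noise


class TestSignificanceMatrix:
    def test_planted_separation_detected(self):
        h_good, h_noise = _twelve_subdataset_h_vectors()
        assert min(h_good) - max(h_noise) >= 0.3
        cells = significance_matrix({"good": h_good, "noise": h_noise}, alpha=0.05, m=1)
        by_dir = {(c.method_a, c.method_b): c for c in cells}
        assert by_dir[("good", "noise")].significant
        assert by_dir[("good", "noise")].p_value < 0.05
        assert not by_dir[("noise", "good")].significant

    def test_identical_methods_not_significant(self):
        h = [0.7, 0.75, 0.72, 0.8, 0.71, 0.77, 0.74, 0.73, 0.76, 0.7, 0.72, 0.75]
        cells = significance_matrix({"a": list(h), "b": list(h)}, alpha=0.05)
        assert all(c.p_value == 0.5 and not c.significant for c in cells)

    def test_three_methods_give_six_directional_cells(self):
        h = {"a": [0.1, 0.2, 0.3], "b": [0.2, 0.3, 0.1], "c": [0.3, 0.1, 0.2]}
        cells = significance_matrix(h, alpha=0.05, m=4)
        assert len(cells) == 6
        assert all(c.m == 4 and c.alpha_c == pytest.approx(0.0125) for c in cells)

    def test_ragged_evaluations_rejected_with_gaps_named(self):
        with pytest.raises(ValueError, match="ragged"):
            significance_matrix({"a": [0.1, 0.2], "b": [0.1]})


@pytest.fixture(scope="module")
def big_dataset_scores():
    from conftest import well_behaved_study_data

    return well_behaved_study_data()


class TestSubsetDistribution:

    def test_dispersion_strictly_decreases_with_subset_size(self, big_dataset_scores):
        human, scores = big_dataset_scores
        stds = [
            subset_distribution(human, scores, size, 2000, seed=11).h_std
            for size in (100, 300)
        ]
        assert stds[1] < stds[0]

    def test_full_size_subsets_degenerate(self, big_dataset_scores):
        human, scores = big_dataset_scores
        study = subset_distribution(human, scores, len(human), 50, seed=1)
        assert study.degenerate
        assert np.ptp(study.h_values) == 0

    def test_normality_passes_in_most_seeded_repetitions(self, big_dataset_scores):
        human, scores = big_dataset_scores
        passes = sum(
            subset_distribution(human, scores, 100, 200, seed=s).shapiro_p > 0.01
            for s in range(20)
        )
        assert passes >= 19

    def test_qq_points_cover_sample(self, big_dataset_scores):
        human, scores = big_dataset_scores
        study = subset_distribution(human, scores, 100, 300, seed=5)
        assert len(study.qq_sample) == 300
        assert np.all(np.diff(study.qq_sample) >= 0)
        assert study.chi2_p >= 0.0


def test_evaluate_on_split_matches_manual_parts():
    ds, _ = generate_dataset(GeneratorSpec(n_pairs=60, seed=9))
    scores = [sim_jaccard(p.sentence_1.split(), p.sentence_2.split()) for p in ds]
    plan = split_uniform(ds, 3)
    hs = evaluate_on_split(ds, plan, scores)
    human = np.asarray(ds.human_scores())
    sim = np.asarray(scores)
    for part, h in zip(plan.assignment, hs):
        idx = np.asarray(part) - 1
        r = pearson(sim[idx], human[idx])
        rho = spearman(sim[idx], human[idx])
        assert h == pytest.approx(harmonic(r, rho), abs=1e-12)
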
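import numpy as np
import pytest

from fscm import (
    Dataset,
    GAConfig,
    PeptideRecord,
    RegionSpec,
    build_initial_scorecard,
    cv_auc,
    fitness,
    multi_run,
    optimize,
    select_threshold,
)
from fscm.errors import ComputationError, ConfigError

DPS = RegionSpec.from_name("DPS")
FAST = dict(population_size=20, generations=8, full_set_auc=True, seed=0)


class TestGAConfig:
    @pytest.mark.parametrize("kwargs", [
        {"population_size": 1},
        {"population_size": 5, "elitism_count": 5},
        {"cv_folds": 1},
        {"crossover_rate": 1.5},
        {"mutation_rate": -0.1},
        {"n_runs": 0},
    ])
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            GAConfig(**kwargs)

    def test_defaults_match_fitness_weights(self):
        config = GAConfig()
        assert (config.w1, config.w2) == (0.9, 0.1)
        assert config.cv_folds == 10 and config.n_runs == 10

    def test_file_round_trip(self, tmp_path):
        config = GAConfig(population_size=33, generations=7, seed=42,
                          full_set_auc=True, mutation_sigma=12.5)
        path = tmp_path / "ga.cfg"
        config.to_file(path)
        assert GAConfig.from_file(path) == config


class TestCvAuc:
    def test_perfect_separation(self, separable_dataset):
        card = build_initial_scorecard(separable_dataset, DPS)
        assert cv_auc(card.scores, separable_dataset, DPS,
                      folds=3, seed=0) == 1.0

    def test_label_independent_scores_near_half(self, null_dataset):
        # scores drawn independently of the labels rank nothing
        rng = np.random.default_rng(21)
        scores = rng.uniform(0, 1000, 400)
        auc = cv_auc(scores, null_dataset, DPS, folds=10, seed=0)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_degenerate_fold_count_rejected(self, separable_dataset):
        card = build_initial_scorecard(separable_dataset, DPS)
        with pytest.raises(ComputationError):
            cv_auc(card.scores, separable_dataset, DPS,
                   folds=len(separable_dataset), seed=0)


class TestFitness:
    def test_self_correlation_anchor(self, separable_dataset):
        """candidate == init has R = 1, so F = w1 * AUC + w2."""
        card = build_initial_scorecard(separable_dataset, DPS)
        config = GAConfig(seed=0)
        auc = cv_auc(card.scores, separable_dataset, DPS,
                     config.cv_folds, config.seed)
        f = fitness(card.scores, card.scores, separable_dataset, DPS, config)
        assert f == pytest.approx(0.9 * auc + 0.1, abs=1e-12)

    def test_constant_candidate_scores_zero_correlation(self, separable_dataset):
        card = build_initial_scorecard(separable_dataset, DPS)
        config = GAConfig(seed=0, full_set_auc=True)
        f = fitness(np.full(400, 500.0), card.scores,
                    separable_dataset, DPS, config)
        # constant scores rank nothing: AUC 0.5, R treated as 0
        assert f == pytest.approx(0.9 * 0.5, abs=1e-12)

    def test_weight_arithmetic(self):
        # the composite is a plain weighted sum of its two terms
        assert 0.9 * 0.8 + 0.1 * 0.5 == pytest.approx(0.77)


class TestSelectThreshold:
    def test_separable_midpoint(self):
        scores = [900.0, 800.0, 100.0, 200.0]
        labels = ["positive", "positive", "negative", "negative"]
        assert select_threshold(scores, labels) == 500.0

    def test_two_point_midpoint(self):
        assert select_threshold([10.0, 0.0], ["positive", "negative"]) == 5.0

    def test_interleaved_majority_bound(self):
        scores = [1.0, 3.0, 2.0, 4.0]
        labels = ["positive", "positive", "negative", "negative"]
        cut = select_threshold(scores, labels)
        acc = np.mean([(s > cut) == (l == "positive")
                       for s, l in zip(scores, labels)])
        assert acc >= 0.5

    def test_all_identical_returns_value(self):
        assert select_threshold([7.0, 7.0], ["positive", "negative"]) == 7.0

    def test_single_class_rejected(self):
        with pytest.raises(ComputationError):
            select_threshold([1.0, 2.0], ["positive", "positive"])

    def test_maximizes_accuracy_over_candidates(self, synthetic_default,
                                                dps_region):
        from fscm import score_peptide
        card = build_initial_scorecard(synthetic_default, dps_region)
        scores = np.array([score_peptide(r.sequence, card)
                           for r in synthetic_default])
        y = np.array([r.label == "positive" for r in synthetic_default])
        cut = select_threshold(scores, y)
        best_acc = np.mean((scores > cut) == y)
        uniq = np.unique(scores)
        for other in (uniq[:-1] + uniq[1:]) / 2:
            assert best_acc >= np.mean((scores > other) == y)


class TestOptimize:
    def test_zero_generations_keeps_init(self, separable_dataset):
        card = build_initial_scorecard(separable_dataset, DPS)
        config = GAConfig(generations=0, full_set_auc=True, seed=1)
        result = optimize(card, separable_dataset, config)
        assert np.array_equal(result.best_card.scores, card.scores)
        assert result.best_card.provenance == "optimized"
        assert np.isfinite(result.best_card.threshold)

    def test_deterministic_for_fixed_seed(self, separable_dataset):
        card = build_initial_scorecard(separable_dataset, DPS)
        config = GAConfig(**FAST)
        a = optimize(card, separable_dataset, config)
        b = optimize(card, separable_dataset, config)
        assert np.array_equal(a.best_card.scores, b.best_card.scores)
        assert a.fitness_trace == b.fitness_trace
        assert a.best_card.threshold == b.best_card.threshold

    def test_trace_non_decreasing_and_scores_clipped(self, synthetic_default):
        card = build_initial_scorecard(synthetic_default, DPS)
        result = optimize(card, synthetic_default, GAConfig(**FAST))
        trace = np.array(result.fitness_trace)
        assert (np.diff(trace) >= 0).all()
        assert result.best_card.scores.min() >= 0.0
        assert result.best_card.scores.max() <= 1000.0

    def test_final_fitness_decomposition(self, separable_dataset):
        card = build_initial_scorecard(separable_dataset, DPS)
        config = GAConfig(**FAST)
        result = optimize(card, separable_dataset, config)
        assert result.final_fitness == pytest.approx(
            0.9 * result.final_auc + 0.1 * result.final_correlation
        )

    def test_pure_correlation_fitness_does_not_drift(self, synthetic_default):
        """With w1=0, w2=1 the optimum is the initial vector itself."""
        card = build_initial_scorecard(synthetic_default, DPS)
        config = GAConfig(population_size=20, generations=10, w1=0.0, w2=1.0,
                          full_set_auc=True, seed=3)
        result = optimize(card, synthetic_default, config)
        assert np.array_equal(result.best_card.scores, card.scores)
        assert result.final_correlation == pytest.approx(1.0)

    def test_optimized_auc_not_worse_than_init(self, synthetic_default):
        card = build_initial_scorecard(synthetic_default, DPS)
        config = GAConfig(population_size=30, generations=15,
                          full_set_auc=True, seed=2)
        result = optimize(card, synthetic_default, config)
        init_auc = cv_auc(card.scores, synthetic_default, DPS,
                          folds=10, seed=2)
        opti_auc = cv_auc(result.best_card.scores, synthetic_default, DPS,
                          folds=10, seed=2)
        assert opti_auc >= init_auc - 0.01


class TestMultiRun:
    def test_single_run_equals_optimize(self, separable_dataset):
        card = build_initial_scorecard(separable_dataset, DPS)
        config = GAConfig(n_runs=1, **FAST)
        multi = multi_run(card, separable_dataset, config)
        single = optimize(card, separable_dataset, config)
        assert np.array_equal(multi.selected.best_card.scores,
                              single.best_card.scores)

    def test_reproducible_triple_and_argmax(self, separable_dataset):
        card = build_initial_scorecard(separable_dataset, DPS)
        config = GAConfig(n_runs=3, **FAST)
        a = multi_run(card, separable_dataset, config)
        b = multi_run(card, separable_dataset, config)
        assert len(a.runs) == 3
        assert [r.run_seed for r in a.runs] == [0, 1, 2]
        for ra, rb in zip(a.runs, b.runs):
            assert np.array_equal(ra.best_card.scores, rb.best_card.scores)
        fits = [r.final_fitness for r in a.runs]
        assert a.selected.final_fitness == max(fits)
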
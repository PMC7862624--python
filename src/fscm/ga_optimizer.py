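"""Genetic-algorithm refinement of propensity scorecards.

The initial scorecard is a noisy statistical estimate; the GA perturbs it
under the composite fitness

    F = w1 * AUC + w2 * R        (defaults w1 = 0.9, w2 = 0.1)

where AUC is the (cross-validated) ranking performance of the candidate's
weighted-sum scores on the training set and R the Pearson correlation
between the candidate and the initial card — an anchor keeping the refined
card interpretable as a perturbation of the class-composition statistics.

Individuals are full score vectors on the 0-1000 scale.  The scheme is a
standard real-valued GA: tournament selection, uniform crossover, per-gene
Gaussian mutation, elitism, clipping to [0, 1000] after every generation.
The decision threshold is fitted post hoc on training scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .errors import ComputationError, ConfigError
from .peptide_io import POSITIVE, Dataset, RegionSpec
from .scorecard import ScoreCard

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GAConfig:
    """Tunable knobs of the GA and its fitness.

    ``mutation_rate`` is per gene; ``mutation_sigma`` is on the 0-1000 score
    scale.  ``full_set_auc`` replaces the tenfold cross-validated fitness
    AUC with the whole-training-set AUC — faster and, for a scorer with no
    per-fold fitting, typically indistinguishable in ranking candidates.
    """

    population_size: int = 100
    generations: int = 50
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    mutation_sigma: float = 50.0
    elitism_count: int = 1
    tournament_size: int = 3
    w1: float = 0.9
    w2: float = 0.1
    cv_folds: int = 10
    seed: int = 0
    n_runs: int = 10
    full_set_auc: bool = False

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ConfigError("population_size must be >= 2")
        if not 1 <= self.elitism_count < self.population_size:
            raise ConfigError(
                "need population_size > elitism_count >= 1, got "
                f"{self.population_size} / {self.elitism_count}"
            )
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.tournament_size < 1:
            raise ConfigError("tournament_size must be >= 1")
        if self.generations < 0:
            raise ConfigError("generations must be >= 0")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, value in vars(self).items():
                fh.write(f"{key} = {value}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "GAConfig":
        kwargs: dict = {}
        hints = {f: t for f, t in cls.__annotations__.items()}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in hints:
                raise ConfigError(f"unknown GA config key {key!r}")
            kind = hints[key]
            if kind == "bool":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif kind == "int":
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


@dataclass(frozen=True)
class OptimizationResult:
    """Best individual of one GA run plus its audit trail."""

    best_card: ScoreCard
    fitness_trace: tuple[float, ...]
    final_auc: float
    final_correlation: float
    run_seed: int
    config: GAConfig

    @property
    def final_fitness(self) -> float:
        return self.config.w1 * self.final_auc + self.config.w2 * self.final_correlation


# ---------------------------------------------------------------------------
# Fitness machinery (vectorized over a population)

def _feature_matrix(
    data: Dataset, region: RegionSpec, include_junction: bool
) -> tuple[np.ndarray, np.ndarray]:
    from .classifier_eval import feature_vector

    X = np.stack([
        feature_vector(rec.sequence, region, include_junction=include_junction)
        for rec in data
    ])
    y = np.array([rec.label == POSITIVE for rec in data])
    return X, y


def _auc_columns(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mann-Whitney AUC of each score column (ties half-credit)."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = rankdata(scores, axis=0)
    return (ranks[y].sum(axis=0) - n1 * (n1 + 1) / 2) / (n1 * n0)


def _fold_indices(y: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    n1, n0 = int(y.sum()), int((~y).sum())
    if folds > min(n1, n0):
        raise ComputationError(
            f"{folds}-fold partition impossible: class sizes {n1}/{n0}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    return [te for _, te in skf.split(np.zeros(len(y)), y)]


def _cv_auc_columns(
    scores: np.ndarray, y: np.ndarray, fold_idx: list[np.ndarray]
) -> np.ndarray:
    """Mean per-fold AUC of each column; one-class folds skipped."""
    parts = []
    for te in fold_idx:
        yf = y[te]
        if yf.all() or not yf.any():
            logger.warning("fold lacks one class; skipping its AUC")
            continue
        parts.append(_auc_columns(scores[te], yf))
    if not parts:
        raise ComputationError("no fold contained both classes")
    return np.mean(parts, axis=0)


def _pearson_to_init(pop: np.ndarray, init: np.ndarray) -> np.ndarray:
    """Pearson R of each population row against the initial scores.

    Constant rows have undefined correlation and are scored R = 0.
    """
    init_c = init - init.mean()
    init_norm = np.linalg.norm(init_c)
    if init_norm == 0:
        logger.warning("initial score vector is constant; correlations set to 0")
        return np.zeros(pop.shape[0])
    pop_c = pop - pop.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(pop_c, axis=1)
    out = np.zeros(pop.shape[0])
    ok = norms > 0
    if not ok.all():
        logger.warning("constant candidate vector(s); correlation set to 0")
    out[ok] = (pop_c[ok] @ init_c) / (norms[ok] * init_norm)
    # rounding can push |R| a hair past 1, which would let a duplicate of
    # the initial vector "beat" it under a pure-correlation fitness
    return np.clip(out, -1.0, 1.0)


def cv_auc(
    card_scores: np.ndarray,
    data: Dataset,
    region: RegionSpec,
    folds: int,
    seed: int,
    include_junction: bool = True,
) -> float:
    """Mean stratified-fold AUC of fixed candidate scores on a dataset."""
    X, y = _feature_matrix(data, region, include_junction)
    fold_idx = _fold_indices(y, folds, seed)
    scores = (X @ card_scores)[:, None]
    return float(_cv_auc_columns(scores, y, fold_idx)[0])


def fitness(
    candidate: np.ndarray,
    init: np.ndarray,
    train: Dataset,
    region: RegionSpec,
    config: GAConfig,
    include_junction: bool = True,
) -> float:
    """F = w1 * AUC + w2 * R for a single candidate score vector."""
    candidate = np.asarray(candidate, dtype=float)
    init = np.asarray(init, dtype=float)
    if candidate.shape != init.shape:
        raise ComputationError("candidate and initial scores differ in shape")
    X, y = _feature_matrix(train, region, include_junction)
    scores = (X @ candidate)[:, None]
    if config.full_set_auc:
        auc = float(_auc_columns(scores, y)[0])
    else:
        fold_idx = _fold_indices(y, config.cv_folds, config.seed)
        auc = float(_cv_auc_columns(scores, y, fold_idx)[0])
    r = float(_pearson_to_init(candidate[None, :], init)[0])
    return config.w1 * auc + config.w2 * r


# ---------------------------------------------------------------------------
# Threshold selection

def select_threshold(scores, labels) -> float:
    """Accuracy-maximizing cutoff over candidate cutoffs.

    Candidates are the midpoints of adjacent sorted unique scores plus the
    two boundary cutoffs (below the minimum: predict everything positive;
    at the maximum: predict everything negative, since classification is
    strictly greater-than).  Ties go to the lowest cutoff, favoring
    sensitivity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.array([lab == POSITIVE if isinstance(lab, str) else bool(lab)
                  for lab in labels])
    if len(s) != len(y) or len(s) == 0:
        raise ComputationError("scores and labels must be equal-length, non-empty")
    if not (y.any() and (~y).any()):
        raise ComputationError("threshold selection needs both classes")
    uniq = np.unique(s)
    if len(uniq) == 1:
        logger.warning("all scores identical; threshold set to that value")
        return float(uniq[0])
    candidates = np.concatenate((
        [uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1]],
    ))
    accuracy = [
        float(np.mean((s > c) == y)) for c in candidates
    ]
    return float(candidates[int(np.argmax(accuracy))])


# ---------------------------------------------------------------------------
# The GA itself

def optimize(
    init_card: ScoreCard,
    train: Dataset,
    config: GAConfig,
    include_junction: bool = True,
) -> OptimizationResult:
    """One seeded GA run refining an initial scorecard.

    The population is initialized as the initial scores plus Gaussian noise
    (one individual kept as the exact initial vector).  Each generation:
    elitism, tournament selection, uniform crossover, per-gene Gaussian
    mutation, clipping to [0, 1000].  With ``generations=0`` only the
    threshold is fitted.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    init = np.asarray(init_card.scores, dtype=float)
    dim = init.shape[0]
    X, y = _feature_matrix(train, region=init_card.region,
                           include_junction=include_junction)
    fold_idx = None
    if not config.full_set_auc:
        fold_idx = _fold_indices(y, config.cv_folds, config.seed)

    def evaluate(pop: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        scores = X @ pop.T
        if fold_idx is None:
            aucs = _auc_columns(scores, y)
        else:
            aucs = _cv_auc_columns(scores, y, fold_idx)
        rs = _pearson_to_init(pop, init)
        return config.w1 * aucs + config.w2 * rs, aucs, rs

    if config.generations == 0:
        best = init.copy()
        fit, aucs, rs = evaluate(best[None, :])
        trace = (float(fit[0]),)
        best_fit, best_auc, best_r = float(fit[0]), float(aucs[0]), float(rs[0])
    else:
        pop = np.clip(
            init + rng.normal(0.0, config.mutation_sigma,
                              size=(config.population_size, dim)),
            0.0, 1000.0,
        )
        pop[0] = init
        fit, aucs, rs = evaluate(pop)
        order = np.argsort(-fit)
        best = pop[order[0]].copy()
        best_fit = float(fit[order[0]])
        best_auc, best_r = float(aucs[order[0]]), float(rs[order[0]])
        trace_list = [best_fit]
        n_children = config.population_size - config.elitism_count
        for _ in range(config.generations):
            elite = pop[order[: config.elitism_count]].copy()
            # tournament selection of two parents per child
            contenders = rng.integers(
                0, config.population_size,
                size=(n_children, 2, config.tournament_size),
            )
            winners = contenders[
                np.arange(n_children)[:, None],
                np.arange(2)[None, :],
                np.argmax(fit[contenders], axis=2),
            ]
            mother = pop[winners[:, 0]]
            father = pop[winners[:, 1]]
            cross = rng.random(n_children) < config.crossover_rate
            take_father = rng.random((n_children, dim)) < 0.5
            children = mother.copy()
            swap = cross[:, None] & take_father
            children[swap] = father[swap]
            mutate = rng.random((n_children, dim)) < config.mutation_rate
            noise = rng.normal(0.0, config.mutation_sigma, size=(n_children, dim))
            children = np.clip(children + mutate * noise, 0.0, 1000.0)
            pop = np.vstack([elite, children])
            fit, aucs, rs = evaluate(pop)
            order = np.argsort(-fit)
            if float(fit[order[0]]) > best_fit:
                best_fit = float(fit[order[0]])
                best = pop[order[0]].copy()
                best_auc = float(aucs[order[0]])
                best_r = float(rs[order[0]])
            trace_list.append(best_fit)
        trace = tuple(trace_list)

    train_scores = X @ best
    threshold = select_threshold(train_scores, y)
    best_card = ScoreCard(
        region=init_card.region,
        scores=np.clip(best, 0.0, 1000.0),
        threshold=threshold,
        provenance="optimized",
        metadata={
            **init_card.metadata,
            "ga_seed": config.seed,
            "ga_generations": config.generations,
            "ga_population": config.population_size,
        },
    )
    return OptimizationResult(
        best_card=best_card,
        fitness_trace=trace,
        final_auc=best_auc,
        final_correlation=best_r,
        run_seed=config.seed,
        config=config,
    )


@dataclass(frozen=True)
class MultiRunResult:
    runs: tuple[OptimizationResult, ...]
    selected_index: int

    @property
    def selected(self) -> OptimizationResult:
        return self.runs[self.selected_index]


def multi_run(
    init_card: ScoreCard,
    train: Dataset,
    config: GAConfig,
    include_junction: bool = True,
) -> MultiRunResult:
    """n_runs independent GA runs (seeds seed+0 .. seed+n-1); best kept.

    The selected run is the one with the highest final fitness.
    """
    runs = []
    for i in range(config.n_runs):
        run_config = replace(config, seed=config.seed + i)
        runs.append(
            optimize(init_card, train, run_config, include_junction=include_junction)
        )
    best = int(np.argmax([r.final_fitness for r in runs]))
    return MultiRunResult(runs=tuple(runs), selected_index=best)
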
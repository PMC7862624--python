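"""Weighted-sum scoring, thresholded classification, and evaluation.

A peptide P is scored as S(P) = sum_i x_i * PS_i, where x is the normalized
composition of the (region-sliced) peptide and PS the scorecard.  Because x
sums to 1, S(P) is a weighted mean of propensity scores and stays on the
0-1000 scale regardless of peptide length; a raw-count variant is kept for
comparison.  P is called positive iff S(P) strictly exceeds the threshold.

Evaluation reports the standard binary-classification suite: accuracy,
sensitivity, specificity, Matthews correlation coefficient and ROC AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm
from sklearn.model_selection import StratifiedKFold

from .composition import (
    GRANULARITY_AMINO_ACID,
    aac,
    dipeptide_counts,
    dpc,
)
from .errors import ComputationError, SchemaError, UnscorableError
from .peptide_io import (
    NEGATIVE,
    POSITIVE,
    Dataset,
    PeptideRecord,
    RegionSpec,
    extract_region,
    junction_position,
)
from .scorecard import ScoreCard, build_initial_scorecard

logger = logging.getLogger(__name__)


def feature_vector(
    sequence: str,
    region: RegionSpec,
    include_junction: bool = True,
) -> np.ndarray:
    """Normalized composition of the region slice (AAC or DPC)."""
    seg = extract_region(sequence, region)
    if region.granularity == GRANULARITY_AMINO_ACID:
        if len(seg) < 1:
            raise UnscorableError(f"empty region slice of {sequence!r}")
        return aac(seg)
    if len(seg) < 2:
        raise UnscorableError(
            f"region {region.name} slice of {sequence!r} has no dipeptide"
        )
    exclusions = None
    if not include_junction:
        j = junction_position(sequence, region)
        if j is not None:
            exclusions = (j,)
    return dpc(seg, junction_exclusions=exclusions)


def score_peptide(
    sequence: str,
    card: ScoreCard,
    include_junction: bool = True,
    raw_counts: bool = False,
) -> float:
    """S(P): composition-weighted sum of propensity scores.

    With ``raw_counts=True`` the dot product uses integer occurrence counts
    instead of proportions, so the result scales with peptide length.
    """
    if raw_counts and card.granularity != GRANULARITY_AMINO_ACID:
        seg = extract_region(sequence, card.region)
        if len(seg) < 2:
            raise UnscorableError(
                f"region {card.region.name} slice of {sequence!r} has no dipeptide"
            )
        return float(dipeptide_counts(seg) @ card.scores)
    x = feature_vector(sequence, card.region, include_junction=include_junction)
    return float(x @ card.scores)


def classify(score: float, threshold: float) -> str:
    """Positive iff score strictly exceeds the threshold."""
    return POSITIVE if score > threshold else NEGATIVE


@dataclass(frozen=True)
class PredictionResult:
    """One scored peptide with its per-symbol score decomposition."""

    id: str
    sequence: str
    score: float
    predicted: str
    threshold: float
    contributions: tuple[tuple[str, float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.contributions:
            total = sum(c[3] for c in self.contributions)
            if abs(total - self.score) > 1e-9:
                raise ComputationError(
                    f"contributions sum {total} != score {self.score}"
                )


def predict_peptide(
    record: PeptideRecord,
    card: ScoreCard,
    include_junction: bool = True,
    with_contributions: bool = False,
) -> PredictionResult:
    """Score and classify one peptide against a scorecard."""
    x = feature_vector(record.sequence, card.region, include_junction=include_junction)
    score = float(x @ card.scores)
    contributions: tuple = ()
    if with_contributions:
        nz = np.nonzero(x)[0]
        contributions = tuple(
            (card.symbols[i], float(x[i]), float(card.scores[i]),
             float(x[i] * card.scores[i]))
            for i in nz
        )
    return PredictionResult(
        id=record.id,
        sequence=record.sequence,
        score=score,
        predicted=classify(score, card.threshold),
        threshold=card.threshold,
        contributions=contributions,
    )


# ---------------------------------------------------------------------------
# Metrics

@dataclass(frozen=True)
class EvalMetrics:
    """Confusion counts plus Ac/Sn/Sp/MCC and (optionally) ROC AUC."""

    tp: int
    tn: int
    fp: int
    fn: int
    ac: float
    sn: float
    sp: float
    mcc: float
    auc: float = float("nan")
    roc_points: tuple[tuple[float, float], ...] = ()

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> dict[str, float]:
        return {
            "ac": self.ac, "sn": self.sn, "sp": self.sp,
            "mcc": self.mcc, "auc": self.auc,
        }


def _as_bool(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "bui":
        return arr.astype(bool)
    return np.array([lab == POSITIVE for lab in labels], dtype=bool)


def confusion_metrics(truth, predicted) -> EvalMetrics:
    """Ac, Sn, Sp and MCC from paired truth/prediction label lists.

    MCC's zero-denominator case (a degenerate margin) is reported as 0.
    """
    t = _as_bool(truth)
    p = _as_bool(predicted)
    if len(t) != len(p):
        raise ComputationError(
            f"truth has {len(t)} labels, predictions {len(p)}"
        )
    if len(t) == 0:
        raise ComputationError("cannot evaluate an empty label list")
    tp = int(np.sum(t & p))
    tn = int(np.sum(~t & ~p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    n = tp + tn + fp + fn
    ac = (tp + tn) / n
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        logger.warning("MCC denominator is zero; reporting MCC = 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    return EvalMetrics(tp=tp, tn=tn, fp=fp, fn=fn, ac=ac, sn=sn, sp=sp, mcc=float(mcc))


def roc_auc(scores, truth) -> tuple[float, tuple[tuple[float, float], ...]]:
    """ROC AUC (Mann-Whitney, ties half-credit) and the swept ROC points."""
    y = _as_bool(truth)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ComputationError("ROC needs both classes present")
    auc = float(_skm.roc_auc_score(y, s))
    fpr, tpr, _ = _skm.roc_curve(y, s)
    return auc, tuple(zip(fpr.tolist(), tpr.tolist()))


def evaluate_model(
    card: ScoreCard,
    data: Dataset,
    include_junction: bool = True,
) -> EvalMetrics:
    """Score, classify and fully evaluate a labeled dataset."""
    truth = [rec.label for rec in data]
    scores = [
        score_peptide(rec.sequence, card, include_junction=include_junction)
        for rec in data
    ]
    predicted = [classify(s, card.threshold) for s in scores]
    base = confusion_metrics(truth, predicted)
    auc, points = roc_auc(scores, truth)
    return EvalMetrics(
        tp=base.tp, tn=base.tn, fp=base.fp, fn=base.fn,
        ac=base.ac, sn=base.sn, sp=base.sp, mcc=base.mcc,
        auc=auc, roc_points=points,
    )


# ---------------------------------------------------------------------------
# Cross-validated training protocol

@dataclass(frozen=True)
class CrossValidationResult:
    per_fold: tuple[EvalMetrics, ...]
    mean: dict[str, float]


def cross_validate(
    train: Dataset,
    region: RegionSpec,
    ga_config=None,
    optimize: bool = False,
    include_junction: bool = True,
) -> CrossValidationResult:
    """Stratified k-fold protocol over a labeled training set.

    Each fold builds the initial scorecard on the fold-training part,
    optionally refines it with the genetic algorithm, fits the decision
    threshold on fold-training scores, and evaluates on the held-out fold.
    """
    from .ga_optimizer import GAConfig, optimize as ga_optimize, select_threshold

    config = ga_config if ga_config is not None else GAConfig()
    y = np.array([rec.label == POSITIVE for rec in train])
    if y.all() or not y.any():
        raise ComputationError("cross-validation needs both labels")
    skf = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed % (2**31)
    )
    per_fold: list[EvalMetrics] = []
    for tr_idx, te_idx in skf.split(np.zeros(len(y)), y):
        fold_train = train.subset(tr_idx.tolist())
        fold_test = train.subset(te_idx.tolist())
        card = build_initial_scorecard(
            fold_train, region, include_junction=include_junction
        )
        if optimize:
            card = ga_optimize(
                card, fold_train, config, include_junction=include_junction
            ).best_card
        tr_scores = [
            score_peptide(r.sequence, card, include_junction=include_junction)
            for r in fold_train
        ]
        card = card.with_threshold(
            select_threshold(tr_scores, [r.label for r in fold_train])
        )
        per_fold.append(
            evaluate_model(card, fold_test, include_junction=include_junction)
        )
    mean = {
        key: float(np.mean([m.as_dict()[key] for m in per_fold]))
        for key in ("ac", "sn", "sp", "mcc", "auc")
    }
    return CrossValidationResult(per_fold=tuple(per_fold), mean=mean)
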
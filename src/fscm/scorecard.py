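"""Propensity scorecards: initialization, normalization, reduction, IO.

A scorecard assigns every dipeptide (or residue) a propensity score on a
0-1000 scale expressing how strongly it associates with the positive class.
The initial card is purely statistical: pooled class compositions are
differenced (NPS+ - NPS-) and min-max scaled to [0, 1000].  Worked example:
a dipeptide counted 280 times among 450 positive-class pairs and 40 times
among 200 negative-class pairs has NPS+ = 0.622, NPS- = 0.2 and raw score
0.422 before scaling.

Amino-acid propensities derive from a dipeptide card by averaging, for each
residue r, the 40-slot multiset {rX} + {Xr} (the doubled pair rr counts
twice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .composition import (
    AA_TO_INDEX,
    DIMENSION,
    GRANULARITY_AMINO_ACID,
    GRANULARITY_DIPEPTIDE,
    amino_acid_counts,
    canonical_index,
    dipeptide_counts,
)
from .errors import ComputationError, SchemaError
from .peptide_io import NEGATIVE, POSITIVE, Dataset, RegionSpec, extract_region

logger = logging.getLogger(__name__)

PROVENANCE = ("initial", "optimized", "reference")


@dataclass(frozen=True)
class ClassCompositionSummary:
    """Pooled symbol counts and class totals for positives and negatives.

    ``positive_total`` / ``negative_total`` are the class-wide numbers of
    counted symbols (pairs for dipeptide granularity, residues otherwise);
    normalized class compositions (NPS+ / NPS-) are counts over totals.
    """

    granularity: str
    positive_counts: np.ndarray
    negative_counts: np.ndarray
    positive_total: int
    negative_total: int

    def __post_init__(self) -> None:
        dim = DIMENSION[self.granularity]
        for arr in (self.positive_counts, self.negative_counts):
            if arr.shape != (dim,):
                raise SchemaError(
                    f"count vector has shape {arr.shape}, expected ({dim},)"
                )
        if self.positive_total <= 0 or self.negative_total <= 0:
            raise ComputationError(
                "a class has zero counted symbols; cannot form compositions"
            )

    @property
    def nps_pos(self) -> np.ndarray:
        return self.positive_counts / self.positive_total

    @property
    def nps_neg(self) -> np.ndarray:
        return self.negative_counts / self.negative_total


@dataclass(frozen=True)
class ScoreCard:
    """Propensity scores on the 0-1000 scale plus a decision threshold."""

    region: RegionSpec
    scores: np.ndarray
    threshold: float = 500.0
    provenance: str = "initial"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        dim = DIMENSION[self.region.granularity]
        if self.scores.shape != (dim,):
            raise SchemaError(
                f"scorecard for {self.region.name} needs {dim} scores, "
                f"got shape {self.scores.shape}"
            )
        if not np.isfinite(self.threshold):
            raise SchemaError("scorecard threshold must be finite")
        if self.provenance not in PROVENANCE:
            raise SchemaError(f"unknown provenance {self.provenance!r}")

    @property
    def granularity(self) -> str:
        return self.region.granularity

    @property
    def symbols(self) -> tuple[str, ...]:
        return canonical_index(self.granularity)

    def score_of(self, symbol: str) -> float:
        return float(self.scores[self.symbols.index(symbol)])

    def with_threshold(self, threshold: float) -> "ScoreCard":
        return replace(self, threshold=float(threshold))


# ---------------------------------------------------------------------------
# Initialization (class composition difference, min-max scaled)

def class_composition(
    train: Dataset,
    region: RegionSpec,
    include_junction: bool = True,
) -> ClassCompositionSummary:
    """Pool region-sliced symbol counts per class over a training set.

    For NC regions with ``include_junction=False`` the concatenation
    junction pair of each peptide is left out of the pooled counts.
    """
    from .peptide_io import junction_position

    dim = DIMENSION[region.granularity]
    pos = np.zeros(dim, dtype=np.int64)
    neg = np.zeros(dim, dtype=np.int64)
    seen = {POSITIVE: False, NEGATIVE: False}
    for rec in train:
        if rec.label not in (POSITIVE, NEGATIVE):
            raise ComputationError(
                f"record {rec.id!r} is unlabeled; cannot build class compositions"
            )
        seen[rec.label] = True
        seg = extract_region(rec.sequence, region)
        if region.granularity == GRANULARITY_AMINO_ACID:
            counts = amino_acid_counts(seg)
        else:
            counts = dipeptide_counts(seg).copy()
            if not include_junction:
                j = junction_position(rec.sequence, region)
                if j is not None:
                    counts[20 * AA_TO_INDEX[seg[j]] + AA_TO_INDEX[seg[j + 1]]] -= 1
        if rec.label == POSITIVE:
            pos += counts
        else:
            neg += counts
    if not (seen[POSITIVE] and seen[NEGATIVE]):
        raise ComputationError("training set must contain both labels")
    return ClassCompositionSummary(
        granularity=region.granularity,
        positive_counts=pos,
        negative_counts=neg,
        positive_total=int(pos.sum()),
        negative_total=int(neg.sum()),
    )


def initial_propensity(summary: ClassCompositionSummary) -> np.ndarray:
    """Raw propensity: NPS+ - NPS- per symbol (higher = more positive-like)."""
    return summary.nps_pos - summary.nps_neg


def normalize_0_1000(raw: np.ndarray) -> np.ndarray:
    """Affine min-max map onto [0, 1000].

    A constant input vector (no spread to scale) maps to the direction-neutral
    midpoint 500 everywhere.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ComputationError("cannot normalize an empty score vector")
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        logger.warning("constant raw score vector; normalizing to all-500")
        return np.full_like(raw, 500.0)
    out = 1000.0 * (raw - lo) / (hi - lo)
    # pin the endpoints: the affine map must hit 0 and 1000 exactly
    out[raw == lo] = 0.0
    out[raw == hi] = 1000.0
    return out


def build_initial_scorecard(
    train: Dataset,
    region: RegionSpec,
    include_junction: bool = True,
) -> ScoreCard:
    """Initial scorecard from pooled class compositions (threshold unfitted).

    The returned threshold is the scale midpoint 500; training workflows
    replace it with an accuracy-maximizing cutoff.
    """
    summary = class_composition(train, region, include_junction=include_junction)
    scores = normalize_0_1000(initial_propensity(summary))
    return ScoreCard(
        region=region,
        scores=scores,
        threshold=500.0,
        provenance="initial",
        metadata={"dataset": train.name, "n_records": len(train)},
    )


def aa_propensity_from_dipeptides(card: ScoreCard) -> ScoreCard:
    """Reduce a 400-entry dipeptide card to 20 amino-acid propensities.

    Residue r averages the 40-slot multiset of dipeptides containing r:
    the 20 pairs rX plus the 20 pairs Xr, so rr contributes twice.
    """
    if card.granularity != GRANULARITY_DIPEPTIDE:
        raise SchemaError("amino-acid reduction needs a dipeptide scorecard")
    mat = card.scores.reshape(20, 20)
    aa_scores = (mat.sum(axis=1) + mat.sum(axis=0)) / 40.0
    # Amino-acid cards are whole-sequence by construction; the source region
    # is preserved in metadata.
    return ScoreCard(
        region=RegionSpec("FULL", granularity=GRANULARITY_AMINO_ACID),
        scores=aa_scores,
        threshold=card.threshold,
        provenance=card.provenance,
        metadata={**card.metadata, "reduced_from": card.region.name},
    )


# ---------------------------------------------------------------------------
# Serialization: headered TSV with a commented metadata block

def write_scorecard(card: ScoreCard, path: str | Path) -> None:
    """Write a scorecard as TSV: '# key<TAB>value' metadata, then symbol/score."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# region\t{card.region.name}\n")
        fh.write(f"# granularity\t{card.granularity}\n")
        fh.write(f"# threshold\t{card.threshold!r}\n")
        fh.write(f"# provenance\t{card.provenance}\n")
        for key in sorted(card.metadata):
            fh.write(f"# meta:{key}\t{card.metadata[key]}\n")
        fh.write("symbol\tscore\n")
        for sym, sc in zip(card.symbols, card.scores):
            fh.write(f"{sym}\t{float(sc)!r}\n")


def read_scorecard(path: str | Path) -> ScoreCard:
    """Read a scorecard TSV, validating the symbol set exactly."""
    path = Path(path)
    meta: dict[str, str] = {}
    extra: dict[str, str] = {}
    rows: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                try:
                    key, value = line[1:].strip().split("\t", 1)
                except ValueError:
                    raise SchemaError(f"{path}:{lineno}: malformed metadata line")
                if key.startswith("meta:"):
                    extra[key[5:]] = value
                else:
                    meta[key] = value
                continue
            if line.startswith("symbol\t"):
                continue
            try:
                sym, score = line.split("\t")
                value = float(score)
            except ValueError:
                raise SchemaError(f"{path}:{lineno}: malformed score row {line!r}")
            if sym in rows:
                raise SchemaError(f"{path}: duplicate symbol {sym!r}")
            rows[sym] = value
    for key in ("region", "granularity", "threshold", "provenance"):
        if key not in meta:
            raise SchemaError(f"{path}: missing metadata field {key!r}")
    granularity = meta["granularity"]
    if granularity not in DIMENSION:
        raise SchemaError(f"{path}: unknown granularity {granularity!r}")
    region = RegionSpec.from_name(meta["region"])
    if region.granularity != granularity:
        raise SchemaError(
            f"{path}: region {meta['region']!r} is {region.granularity}-granular, "
            f"file says {granularity!r}"
        )
    expected = canonical_index(granularity)
    missing = set(expected) - set(rows)
    surplus = set(rows) - set(expected)
    if missing:
        raise SchemaError(f"{path}: missing symbol {sorted(missing)[0]!r}")
    if surplus:
        raise SchemaError(f"{path}: unexpected symbol {sorted(surplus)[0]!r}")
    scores = np.array([rows[s] for s in expected], dtype=float)
    return ScoreCard(
        region=region,
        scores=scores,
        threshold=float(meta["threshold"]),
        provenance=meta["provenance"],
        metadata=extra,
    )
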
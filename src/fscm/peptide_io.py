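"""Reading, validating, region-slicing and splitting labeled peptide sets.

The benchmark convention is a pair of FASTA files (positives, negatives).
Region slicing implements the 11 feature classes of the flexible scoring
card method: the whole sequence at amino-acid (APS) or dipeptide (DPS)
granularity, and dipeptide composition on the first/last 5, 10 or 15
residues (N5 ... C15) or their concatenation (N5C5 ... N15C15).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .composition import (
    AA_TO_INDEX,
    GRANULARITY_AMINO_ACID,
    GRANULARITY_DIPEPTIDE,
)
from .errors import (
    ConfigError,
    FastaParseError,
    SequenceError,
    StratificationError,
)

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class PeptideRecord:
    """One labeled peptide: identifier, validated sequence, optional label."""

    id: str
    sequence: str
    label: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise SequenceError(
                f"record {self.id!r}: sequence {self.sequence!r} is too short "
                "(need length >= 2, at least one dipeptide)"
            )
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in AA_TO_INDEX:
                raise SequenceError(
                    f"record {self.id!r}: illegal residue {aa!r} at position {pos}"
                )
        if self.label not in (POSITIVE, NEGATIVE, None):
            raise ConfigError(f"record {self.id!r}: unknown label {self.label!r}")


@dataclass(frozen=True)
class Dataset:
    """An ordered collection of peptide records with unique identifiers."""

    records: tuple[PeptideRecord, ...]
    name: str = "dataset"

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FastaParseError(
                f"dataset {self.name!r}: duplicate ids {dupes[:5]}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            key = r.label if r.label is not None else "unlabeled"
            out[key] = out.get(key, 0) + 1
        return out

    def subset(self, indices, name: str | None = None) -> "Dataset":
        return Dataset(
            tuple(self.records[i] for i in indices),
            name=name or self.name,
        )

    def with_label(self, label: str) -> "Dataset":
        return Dataset(
            tuple(replace(r, label=label) for r in self.records),
            name=self.name,
        )


# ---------------------------------------------------------------------------
# Region specification

_KINDS = ("FULL", "N", "C", "NC")

#: The 11 feature classes, by conventional name.
REGION_NAMES = (
    "APS", "DPS",
    "N5", "C5", "N5C5",
    "N10", "C10", "N10C10",
    "N15", "C15", "N15C15",
)


@dataclass(frozen=True)
class RegionSpec:
    """Which part of the peptide is scored, and at what granularity.

    ``kind`` is FULL, N, C or NC; ``window`` (5, 10 or 15) applies to the
    terminal kinds; granularity is amino_acid only for the whole-sequence
    APS class, dipeptide everywhere else.
    """

    kind: str
    window: int | None = None
    granularity: str = GRANULARITY_DIPEPTIDE

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigError(f"unknown region kind {self.kind!r}")
        if self.kind == "FULL":
            if self.window is not None:
                raise ConfigError("FULL region takes no window")
        else:
            if self.window not in (5, 10, 15):
                raise ConfigError(
                    f"terminal region window must be 5, 10 or 15, got {self.window!r}"
                )
            if self.granularity != GRANULARITY_DIPEPTIDE:
                raise ConfigError("terminal regions are dipeptide-granular")
        if self.granularity not in (GRANULARITY_AMINO_ACID, GRANULARITY_DIPEPTIDE):
            raise ConfigError(f"unknown granularity {self.granularity!r}")

    @property
    def name(self) -> str:
        """Conventional feature-class name (APS, DPS, N5, ..., N15C15)."""
        if self.kind == "FULL":
            return "APS" if self.granularity == GRANULARITY_AMINO_ACID else "DPS"
        if self.kind == "NC":
            return f"N{self.window}C{self.window}"
        return f"{self.kind}{self.window}"

    @classmethod
    def from_name(cls, name: str) -> "RegionSpec":
        """Parse a feature-class name; a trailing 'PS' suffix is accepted."""
        key = name.strip().upper()
        if key.endswith("PS") and key not in ("APS", "DPS"):
            key = key[:-2]
        if key == "APS":
            return cls("FULL", granularity=GRANULARITY_AMINO_ACID)
        if key == "DPS":
            return cls("FULL", granularity=GRANULARITY_DIPEPTIDE)
        for kind, pattern in (("NC", "N{w}C{w}"), ("N", "N{w}"), ("C", "C{w}")):
            for w in (5, 10, 15):
                if key == pattern.format(w=w):
                    return cls(kind, window=w)
        raise ConfigError(
            f"unknown region name {name!r}; expected one of {', '.join(REGION_NAMES)}"
        )


def all_regions() -> tuple[RegionSpec, ...]:
    """The 11 feature classes in conventional order."""
    return tuple(RegionSpec.from_name(n) for n in REGION_NAMES)


def extract_region(sequence: str, region: RegionSpec) -> str:
    """Slice a peptide to a region.

    FULL returns the sequence unchanged.  N/C with window ``w`` return the
    first/last ``min(w, L)`` residues; sequences shorter than the window are
    used whole (truncation convention).  NC concatenates the N-segment and
    the C-segment, which duplicates residues when ``2w > L``.
    """
    if region.kind == "FULL":
        return sequence
    w = region.window
    assert w is not None
    if region.kind == "N":
        return sequence[:w]
    if region.kind == "C":
        return sequence[-w:]
    return sequence[:w] + sequence[-w:]


def junction_position(sequence: str, region: RegionSpec) -> int | None:
    """0-based pair index of the artificial N/C junction, or None.

    Only NC regions have a junction: the pair formed by the last N-segment
    residue and the first C-segment residue.
    """
    if region.kind != "NC":
        return None
    assert region.window is not None
    return min(region.window, len(sequence)) - 1


# ---------------------------------------------------------------------------
# Validation and FASTA IO

def validate_sequence(raw: str, policy: str = "reject") -> str:
    """Uppercase and validate a raw sequence string.

    Under ``reject`` any violation raises :class:`SequenceError` naming the
    position; ``skip`` is handled by the caller (the error is still raised
    here, the caller catches it and drops the record).
    """
    if policy not in ("reject", "skip"):
        raise ConfigError(f"unknown validation policy {policy!r}")
    seq = raw.strip().upper()
    if len(seq) < 2:
        raise SequenceError(
            f"sequence {seq!r} is too short (need length >= 2)"
        )
    for pos, aa in enumerate(seq, start=1):
        if aa not in AA_TO_INDEX:
            raise SequenceError(f"illegal residue {aa!r} at position {pos}")
    return seq


def read_fasta(
    path: str | Path,
    label: str | None = None,
    policy: str = "skip",
    name: str | None = None,
) -> Dataset:
    """Read a FASTA file into a labeled :class:`Dataset`.

    Sequences are uppercased; the id is the header token before the first
    whitespace; wrapped sequence lines are joined.  Records violating the
    20-letter alphabet or the minimum length are dropped with a warning
    under ``policy="skip"`` or raise under ``policy="reject"``.
    """
    path = Path(path)
    if not path.exists():
        raise FastaParseError(f"no such file: {path}")
    with open(path) as handle:
        first = handle.readline()
        while first and not first.strip():
            first = handle.readline()
        if not first:
            raise FastaParseError(f"empty FASTA file: {path}")
        if not first.startswith(">"):
            raise FastaParseError(
                f"{path}: line 1 does not start with '>' — not FASTA"
            )
    records: list[PeptideRecord] = []
    skipped = 0
    with open(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            try:
                seq = validate_sequence(str(entry.seq), policy="reject")
            except SequenceError as exc:
                if policy == "reject":
                    raise SequenceError(f"record {entry.id!r}: {exc}") from None
                skipped += 1
                logger.warning("skipping record %r: %s", entry.id, exc)
                continue
            records.append(PeptideRecord(entry.id, seq, label))
    if skipped:
        logger.warning("%s: skipped %d invalid record(s)", path, skipped)
    if not records:
        raise FastaParseError(f"{path}: no valid peptide records")
    return Dataset(tuple(records), name=name or path.stem)


def write_fasta(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset as plain FASTA (one line per sequence)."""
    path = Path(path)
    with open(path, "w") as handle:
        for rec in dataset:
            handle.write(f">{rec.id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# Stratified splitting

def split_dataset(
    dataset: Dataset,
    train_fraction: float,
    seed: int,
) -> tuple[Dataset, Dataset]:
    """Stratified train/test partition, deterministic for a fixed seed.

    Each label class is shuffled independently and split at
    ``round(train_fraction * n_class)``; the two parts are exact complements
    and preserve the input record order within each part.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ConfigError(
            f"train_fraction must be in (0, 1), got {train_fraction}"
        )
    by_label: dict[str | None, list[int]] = {}
    for i, rec in enumerate(dataset):
        by_label.setdefault(rec.label, []).append(i)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in sorted(by_label, key=str):
        idx = by_label[label]
        if len(idx) < 2:
            raise StratificationError(
                f"label {label!r} has {len(idx)} record(s); need >= 2 to split"
            )
        perm = rng.permutation(len(idx))
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        chosen = {idx[j] for j in perm[:n_train]}
        train_idx.extend(i for i in idx if i in chosen)
        test_idx.extend(i for i in idx if i not in chosen)
    return (
        dataset.subset(sorted(train_idx), name=f"{dataset.name}-train"),
        dataset.subset(sorted(test_idx), name=f"{dataset.name}-test"),
    )
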
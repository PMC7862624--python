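"""Amino-acid and dipeptide composition vectors.

The scoring card method represents a peptide by its amino-acid composition
(AAC, 20 proportions) or its dipeptide composition (DPC, 400 proportions of
overlapping adjacent residue pairs).  Every vector in the package is aligned
to a single canonical ordering: residues alphabetical by one-letter code,
dipeptides lexicographic, so ``index("KK") == 20 * index("K") + index("K")``.

Serialized artefacts always carry explicit symbol labels, so the ordering is
a convenience, never load-bearing across files.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np

from .errors import SequenceError

#: The 20 standard residues, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_TO_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: The 400 dipeptides in lexicographic order ("AA", "AC", ..., "YY").
DIPEPTIDES: tuple[str, ...] = tuple(a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)

DP_TO_INDEX: dict[str, int] = {dp: i for i, dp in enumerate(DIPEPTIDES)}

GRANULARITY_AMINO_ACID = "amino_acid"
GRANULARITY_DIPEPTIDE = "dipeptide"

#: Feature-vector dimension per granularity.
DIMENSION = {GRANULARITY_AMINO_ACID: 20, GRANULARITY_DIPEPTIDE: 400}


def canonical_index(granularity: str) -> tuple[str, ...]:
    """Return the fixed symbol ordering for a granularity.

    Parameters
    ----------
    granularity
        ``"amino_acid"`` (20 symbols) or ``"dipeptide"`` (400 symbols).
    """
    if granularity == GRANULARITY_AMINO_ACID:
        return tuple(AMINO_ACIDS)
    if granularity == GRANULARITY_DIPEPTIDE:
        return DIPEPTIDES
    raise ValueError(f"unknown granularity: {granularity!r}")


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([AA_TO_INDEX[aa] for aa in sequence], dtype=np.intp)
    except KeyError as exc:
        raise SequenceError(
            f"illegal residue {exc.args[0]!r} in sequence {sequence!r}"
        ) from None


def aac(sequence: str) -> np.ndarray:
    """Amino-acid composition: proportion of each residue, canonical order.

    Entries sum to 1 for any non-empty sequence.
    """
    if len(sequence) < 1:
        raise SequenceError("cannot compute AAC of an empty sequence")
    counts = np.bincount(_encode(sequence), minlength=20).astype(float)
    return counts / len(sequence)


def amino_acid_counts(sequence: str) -> np.ndarray:
    """Integer residue counts in canonical order; totals ``len(sequence)``."""
    if len(sequence) < 1:
        raise SequenceError("cannot count residues of an empty sequence")
    return np.bincount(_encode(sequence), minlength=20)


def dipeptide_counts(sequence: str) -> np.ndarray:
    """Counts of the 400 overlapping adjacent pairs; totals ``L - 1``."""
    if len(sequence) < 2:
        raise SequenceError(
            f"sequence {sequence!r} has no dipeptide (length < 2)"
        )
    enc = _encode(sequence)
    pair_codes = 20 * enc[:-1] + enc[1:]
    return np.bincount(pair_codes, minlength=400)


def dpc(
    sequence: str,
    junction_exclusions: Iterable[int] | None = None,
) -> np.ndarray:
    """Dipeptide composition: pair counts normalized by pairs counted.

    ``junction_exclusions`` lists 0-based pair start positions to skip before
    normalization — used for joined N/C terminal regions whose junction pair
    is an artefact of concatenation rather than a real adjacency.
    """
    if len(sequence) < 2:
        raise SequenceError(
            f"sequence {sequence!r} has no dipeptide (length < 2)"
        )
    enc = _encode(sequence)
    pair_codes = 20 * enc[:-1] + enc[1:]
    if junction_exclusions:
        keep = np.ones(len(pair_codes), dtype=bool)
        for pos in junction_exclusions:
            if 0 <= pos < len(pair_codes):
                keep[pos] = False
        pair_codes = pair_codes[keep]
    if len(pair_codes) == 0:
        raise SequenceError(
            "no dipeptide left after junction exclusion"
        )
    counts = np.bincount(pair_codes, minlength=400).astype(float)
    return counts / counts.sum()
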
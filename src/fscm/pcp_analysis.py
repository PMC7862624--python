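"""Correlating amino-acid propensity scores with physicochemical properties.

Each physicochemical property (PCP) is an AAindex-style record: an
accession, a description and 20 per-residue values.  Properties with any
missing (NA) value are excluded; the remainder are ranked by the absolute
Pearson correlation of their values with the 20 amino-acid propensity
scores, and those with |R| strictly greater than 0.5 are flagged as
informative candidates for interpreting the activity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .composition import AMINO_ACIDS, GRANULARITY_AMINO_ACID
from .errors import ComputationError, SchemaError
from .scorecard import ScoreCard

logger = logging.getLogger(__name__)

SELECTION_CUTOFF = 0.5


@dataclass(frozen=True)
class PCPRecord:
    """One property: accession, description, 20 values in canonical order.

    Missing entries are NaN; only complete records are usable downstream.
    """

    accession: str
    description: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 20:
            raise SchemaError(
                f"property {self.accession!r} has {len(self.values)} values, "
                "expected 20"
            )

    @property
    def is_complete(self) -> bool:
        return not any(math.isnan(v) for v in self.values)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson R of one property against the propensity scores."""

    accession: str
    description: str
    r: float
    selected: bool
    rank: int


def load_pcp_table(path: str | Path) -> list[PCPRecord]:
    """Read a flat TSV property table, dropping records with NA values.

    Format: a header line ``accession<TAB>description<TAB>A<TAB>C...Y``
    followed by one record per line; residue columns follow the canonical
    alphabetical ordering.  Empty value cells or the literal ``NA`` mark a
    missing entry.
    """
    path = Path(path)
    records: list[PCPRecord] = []
    excluded = 0
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        logger.warning("%s: empty property table", path)
        return []
    start = 1 if lines[0].lower().startswith("accession") else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        cells = line.split("\t")
        if len(cells) != 22:
            accession = cells[0] if cells else "?"
            raise SchemaError(
                f"{path}:{lineno}: property {accession!r} has "
                f"{len(cells) - 2} value columns, expected 20"
            )
        accession, description, *raw = cells
        values = tuple(
            float("nan") if v.strip() in ("", "NA", "na", "NaN") else float(v)
            for v in raw
        )
        rec = PCPRecord(accession, description, values)
        if rec.is_complete:
            records.append(rec)
        else:
            excluded += 1
    if excluded:
        logger.warning("%s: excluded %d record(s) with NA entries", path, excluded)
    return records


def write_pcp_table(records: list[PCPRecord], path: str | Path) -> None:
    """Write records in the flat TSV format read by :func:`load_pcp_table`."""
    with open(Path(path), "w") as fh:
        fh.write("accession\tdescription\t" + "\t".join(AMINO_ACIDS) + "\n")
        for rec in records:
            cells = ["NA" if math.isnan(v) else repr(v) for v in rec.values]
            fh.write(f"{rec.accession}\t{rec.description}\t" + "\t".join(cells) + "\n")


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two 20-vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ComputationError("pearson needs two equal-length 1-D vectors")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ComputationError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / (np.linalg.norm(xc) * np.linalg.norm(yc)))


def select_informative(
    aa_card: ScoreCard,
    records: list[PCPRecord],
    cutoff: float = SELECTION_CUTOFF,
) -> list[CorrelationResult]:
    """Correlate every property with the propensity scores; rank by |R|.

    Selection uses the strict rule |R| > cutoff.  Properties whose
    correlation is undefined (constant values) are reported unselectable
    with R = NaN rather than aborting the analysis.
    """
    if aa_card.granularity != GRANULARITY_AMINO_ACID:
        raise SchemaError("PCP analysis needs an amino-acid scorecard")
    ps = np.asarray(aa_card.scores, dtype=float)
    raw: list[tuple[PCPRecord, float]] = []
    for rec in records:
        if not rec.is_complete:
            logger.warning("property %s has NA entries; unselectable", rec.accession)
            raw.append((rec, float("nan")))
            continue
        try:
            raw.append((rec, pearson(ps, rec.values)))
        except ComputationError as exc:
            logger.warning("property %s unselectable: %s", rec.accession, exc)
            raw.append((rec, float("nan")))
    raw.sort(key=lambda item: (math.isnan(item[1]), -abs(item[1])
                               if not math.isnan(item[1]) else 0.0))
    return [
        CorrelationResult(
            accession=rec.accession,
            description=rec.description,
            r=r,
            selected=(not math.isnan(r)) and abs(r) > cutoff,
            rank=i + 1,
        )
        for i, (rec, r) in enumerate(raw)
    ]


def write_correlation_report(
    results: list[CorrelationResult], path: str | Path
) -> None:
    with open(Path(path), "w") as fh:
        fh.write("accession\tr\tselected\trank\tdescription\n")
        for res in results:
            r_txt = "NA" if math.isnan(res.r) else f"{res.r:.6f}"
            fh.write(
                f"{res.accession}\t{r_txt}\t{int(res.selected)}\t"
                f"{res.rank}\t{res.description}\n"
            )
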
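"""Synthetic peptide datasets with planted dipeptide signal, plus fixtures.

The generator emulates the structure the scoring card method exploits:
class-discriminating adjacent residue pairs.  Positive peptides are sampled
from a first-order Markov chain whose transition weights are a background
residue distribution, multiplied by ``effect_size ** weight`` for each
enriched dipeptide (divided for depleted ones); negative peptides come from
the pure background chain.  At ``effect_size = 1`` the two classes are
exchangeable — an exact null for calibration checks.

The default enrichment weight of 4 makes the planted transitions dominate
their source-residue rows at the default ``effect_size = 5`` (a source
residue emits its planted partner ~99% of the time), so the planted pairs
carry enough per-peptide signal for end-to-end recovery of the pipeline to
be a sharp test rather than a coin flip.

The module also packages two printed reference fixtures: a 20-residue
amino-acid propensity column with three physicochemical property records
(for the correlation analysis), and the worked class-composition example
used by the scorecard arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .composition import AA_TO_INDEX, AMINO_ACIDS, GRANULARITY_AMINO_ACID
from .errors import ConfigError
from .peptide_io import NEGATIVE, POSITIVE, Dataset, PeptideRecord, RegionSpec, write_fasta
from .pcp_analysis import PCPRecord
from .scorecard import ClassCompositionSummary, ScoreCard

DEFAULT_ENRICHED = {"KK": 4.0, "LW": 4.0, "GH": 4.0}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic benchmark stand-in.

    ``enriched_dipeptides`` / ``depleted_dipeptides`` map dipeptides to
    enrichment weights; the positive-class transition weight of pair (a, b)
    is the background probability of b times ``effect_size ** weight``
    (divided for depleted pairs).  ``effect_size = 1`` is an exact null.
    """

    n_positive: int = 200
    n_negative: int = 200
    length_range: tuple[int, int] = (10, 30)
    background: tuple[float, ...] | None = None
    enriched_dipeptides: dict = field(default_factory=lambda: dict(DEFAULT_ENRICHED))
    depleted_dipeptides: dict = field(default_factory=dict)
    effect_size: float = 5.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.n_negative < 1:
            raise ConfigError("need at least one peptide per class")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ConfigError(
                f"length_range must satisfy 2 <= min <= max, got {self.length_range}"
            )
        if self.effect_size <= 0:
            raise ConfigError("effect_size must be > 0")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or (bg < 0).any() or not np.isclose(bg.sum(), 1.0):
                raise ConfigError("background must be 20 probabilities summing to 1")
        for dp in list(self.enriched_dipeptides) + list(self.depleted_dipeptides):
            if len(dp) != 2 or any(a not in AA_TO_INDEX for a in dp):
                raise ConfigError(f"invalid dipeptide {dp!r}")

    @property
    def background_probs(self) -> np.ndarray:
        if self.background is None:
            return np.full(20, 1.0 / 20.0)
        return np.asarray(self.background, dtype=float)


def _transition_matrix(config: SyntheticConfig) -> np.ndarray:
    bg = config.background_probs
    T = np.tile(bg, (20, 1))
    for dp, weight in config.enriched_dipeptides.items():
        T[AA_TO_INDEX[dp[0]], AA_TO_INDEX[dp[1]]] *= config.effect_size ** weight
    for dp, weight in config.depleted_dipeptides.items():
        T[AA_TO_INDEX[dp[0]], AA_TO_INDEX[dp[1]]] /= config.effect_size ** weight
    row_sums = T.sum(axis=1)
    if (row_sums == 0).any():
        raise ConfigError("degenerate background: a transition row sums to zero")
    return T / row_sums[:, None]


def generate_dataset(config: SyntheticConfig) -> Dataset:
    """Sample a labeled synthetic dataset; deterministic for a fixed seed.

    Each sequence draws from its own counter-derived substream, so the
    dataset is stable under reordering or resizing of the other class.
    """
    T_pos = _transition_matrix(config)
    bg = config.background_probs
    T_neg = np.tile(bg, (20, 1))
    lo, hi = config.length_range
    records: list[PeptideRecord] = []
    for label, cls_code, n, T in (
        (POSITIVE, 1, config.n_positive, T_pos),
        (NEGATIVE, 0, config.n_negative, T_neg),
    ):
        prefix = "pos" if label == POSITIVE else "neg"
        for i in range(n):
            rng = np.random.default_rng([config.seed, cls_code, i])
            length = int(rng.integers(lo, hi + 1))
            state = int(rng.choice(20, p=bg))
            encoded = [state]
            for _ in range(length - 1):
                state = int(rng.choice(20, p=T[state]))
                encoded.append(state)
            records.append(PeptideRecord(
                id=f"{prefix}_{i + 1:04d}",
                sequence="".join(AMINO_ACIDS[j] for j in encoded),
                label=label,
            ))
    return Dataset(tuple(records), name=f"synthetic-seed{config.seed}")


def write_synthetic(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the generated dataset as a positives/negatives FASTA pair
    plus a flat config echo sufficient to regenerate it."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = generate_dataset(config)
    pos = Dataset(tuple(r for r in data if r.label == POSITIVE), name="positives")
    neg = Dataset(tuple(r for r in data if r.label == NEGATIVE), name="negatives")
    paths = {
        "positives": out / "positives.fasta",
        "negatives": out / "negatives.fasta",
        "config": out / "synthetic_config.txt",
    }
    write_fasta(pos, paths["positives"])
    write_fasta(neg, paths["negatives"])
    with open(paths["config"], "w") as fh:
        fh.write(f"n_positive: {config.n_positive}\n")
        fh.write(f"n_negative: {config.n_negative}\n")
        fh.write(f"length_range: {config.length_range[0]} {config.length_range[1]}\n")
        fh.write(f"effect_size: {config.effect_size}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write("enriched_dipeptides: "
                 + " ".join(f"{d}={w}" for d, w in
                            sorted(config.enriched_dipeptides.items())) + "\n")
        fh.write("depleted_dipeptides: "
                 + " ".join(f"{d}={w}" for d, w in
                            sorted(config.depleted_dipeptides.items())) + "\n")
    return paths


# ---------------------------------------------------------------------------
# Printed reference fixtures
#
# A published amino-acid propensity column (scores on the 0-1000 scale, two
# decimals) together with the three physicochemical property indices it was
# reported to correlate with: an amphiphilicity index (MITS020101), the
# alpha-helix weight at window position 6 of the Qian-Sejnowski model
# (QIAN880113), and the Jones 1975 hydrophobicity scale (JOND750101).
# Stored at printed precision, keyed by residue, canonical order applied on
# construction.

_REFERENCE_PROPENSITY = {
    "Y": 355.55, "W": 328.60, "H": 317.03, "M": 311.58, "K": 296.78,
    "A": 295.15, "L": 288.23, "P": 276.55, "E": 272.83, "S": 268.65,
    "I": 247.03, "D": 244.80, "F": 243.43, "T": 242.05, "N": 232.70,
    "R": 229.63, "C": 226.38, "G": 225.08, "V": 212.55, "Q": 198.45,
}

_REFERENCE_PCPS = {
    "MITS020101": ("Amphiphilicity index (Mitaku et al., 2002)", {
        "Y": 5.06, "W": 6.93, "H": 1.45, "M": 0.0, "K": 3.67,
        "A": 0.0, "L": 0.0, "P": 0.0, "E": 1.27, "S": 0.0,
        "I": 0.0, "D": 0.0, "F": 0.0, "T": 0.0, "N": 0.0,
        "R": 2.45, "C": 0.0, "G": 0.0, "V": 0.0, "Q": 1.25,
    }),
    "QIAN880113": ("Weights for alpha-helix at the window position of 6 "
                   "(Qian-Sejnowski, 1988)", {
        "Y": 0.0, "W": 0.36, "H": 0.29, "M": 0.11, "K": 0.45,
        "A": -0.08, "L": 0.28, "P": -0.42, "E": -0.19, "S": 0.07,
        "I": -0.01, "D": -0.24, "F": 0.0, "T": -0.33, "N": -0.08,
        "R": 0.05, "C": -0.25, "G": -0.1, "V": -0.13, "Q": -0.28,
    }),
    "JOND750101": ("Hydrophobicity (Jones, 1975)", {
        "Y": 2.67, "W": 3.77, "H": 0.87, "M": 1.67, "K": 1.64,
        "A": 0.87, "L": 2.17, "P": 2.77, "E": 0.67, "S": 0.07,
        "I": 3.15, "D": 0.66, "F": 2.87, "T": 0.07, "N": 0.09,
        "R": 0.85, "C": 1.52, "G": 0.1, "V": 1.87, "Q": 0.0,
    }),
}


def table6_fixture() -> tuple[ScoreCard, list[PCPRecord]]:
    """The packaged propensity column and its three property records."""
    scores = np.array([_REFERENCE_PROPENSITY[aa] for aa in AMINO_ACIDS])
    card = ScoreCard(
        region=RegionSpec("FULL", granularity=GRANULARITY_AMINO_ACID),
        scores=scores,
        threshold=500.0,
        provenance="reference",
        metadata={"source": "published amino-acid propensity column"},
    )
    records = [
        PCPRecord(
            accession=acc,
            description=desc,
            values=tuple(values[aa] for aa in AMINO_ACIDS),
        )
        for acc, (desc, values) in _REFERENCE_PCPS.items()
    ]
    return card, records


def worked_example_fixture() -> ClassCompositionSummary:
    """The printed class-composition example for one dipeptide (KK).

    KK occurs 280 times among 450 positive-class pairs and 40 times among
    200 negative-class pairs; all other dipeptide counts are unreported and
    set to zero, so only the KK column of the summary is meaningful.
    """
    pos = np.zeros(400, dtype=np.int64)
    neg = np.zeros(400, dtype=np.int64)
    kk = 20 * AA_TO_INDEX["K"] + AA_TO_INDEX["K"]
    pos[kk] = 280
    neg[kk] = 40
    return ClassCompositionSummary(
        granularity="dipeptide",
        positive_counts=pos,
        negative_counts=neg,
        positive_total=450,
        negative_total=200,
    )
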
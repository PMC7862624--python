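import numpy as np
import pytest

from fscm import (
    Dataset,
    PeptideRecord,
    RegionSpec,
    SyntheticConfig,
    generate_dataset,
)


@pytest.fixture(scope="session")
def synthetic_default() -> Dataset:
    """The generator's default study conditions (planted KK/LW/GH signal)."""
    return generate_dataset(SyntheticConfig())


@pytest.fixture(scope="session")
def null_dataset() -> Dataset:
    """Exchangeable classes: effect_size 1 removes all planted signal."""
    return generate_dataset(SyntheticConfig(effect_size=1.0, seed=11))


@pytest.fixture
def separable_dataset() -> Dataset:
    """Tiny hand-built dataset where positives are lysine-rich."""
    pos = [PeptideRecord(f"p{i}", "KKKKKAKK"[: 5 + i % 3], "positive")
           for i in range(12)]
    neg = [PeptideRecord(f"n{i}", "DEDEDGDE"[: 5 + i % 3], "negative")
           for i in range(12)]
    return Dataset(tuple(pos + neg), name="separable")


@pytest.fixture
def dps_region() -> RegionSpec:
    return RegionSpec.from_name("DPS")


def brute_force_auc(scores, labels) -> float:
    """Pairwise Mann-Whitney oracle: fraction of (pos, neg) pairs ranked
    correctly, ties half-credit.  Independent of any library routine."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
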
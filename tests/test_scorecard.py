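import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fscm import (
    Dataset,
    PeptideRecord,
    RegionSpec,
    ScoreCard,
    aa_propensity_from_dipeptides,
    build_initial_scorecard,
    class_composition,
    initial_propensity,
    normalize_0_1000,
    read_scorecard,
    worked_example_fixture,
    write_scorecard,
)
from fscm.composition import AA_TO_INDEX, DIPEPTIDES, DP_TO_INDEX
from fscm.errors import ComputationError, SchemaError

KK = DP_TO_INDEX["KK"]
DPS = RegionSpec.from_name("DPS")


def _swap_labels(data: Dataset) -> Dataset:
    flip = {"positive": "negative", "negative": "positive"}
    return Dataset(tuple(
        PeptideRecord(r.id, r.sequence, flip[r.label]) for r in data
    ))


class TestClassComposition:
    def test_worked_example_ratios(self):
        summary = worked_example_fixture()
        assert summary.nps_pos[KK] == pytest.approx(280 / 450)
        assert round(summary.nps_pos[KK], 3) == 0.622
        assert summary.nps_neg[KK] == pytest.approx(0.2)

    def test_single_identical_sequence_both_classes(self):
        data = Dataset((
            PeptideRecord("p", "AA", "positive"),
            PeptideRecord("n", "AA", "negative"),
        ))
        summary = class_composition(data, DPS)
        assert summary.nps_pos[DP_TO_INDEX["AA"]] == 1.0
        assert summary.nps_neg[DP_TO_INDEX["AA"]] == 1.0

    def test_counts_pool_across_sequences(self):
        data = Dataset((
            PeptideRecord("p1", "KKA", "positive"),
            PeptideRecord("p2", "AKK", "positive"),
            PeptideRecord("n1", "DEDE", "negative"),
        ))
        summary = class_composition(data, DPS)
        assert summary.positive_counts[KK] == 2
        assert summary.positive_total == 4
        assert summary.negative_total == 3

    def test_missing_label_rejected(self):
        data = Dataset((
            PeptideRecord("p", "AA", "positive"),
            PeptideRecord("q", "CC", "positive"),
        ))
        with pytest.raises(ComputationError):
            class_composition(data, DPS)

    def test_junction_excluded_from_nc_pooling(self):
        nc = RegionSpec.from_name("N5C5")
        data = Dataset((
            PeptideRecord("p", "ACDEFGHIKL", "positive"),
            PeptideRecord("n", "ACDEFGHIKL", "negative"),
        ))
        with_j = class_composition(data, nc, include_junction=True)
        without_j = class_composition(data, nc, include_junction=False)
        fg = DP_TO_INDEX["FG"]
        assert with_j.positive_counts[fg] == 1
        assert without_j.positive_counts[fg] == 0
        assert without_j.positive_total == with_j.positive_total - 1


class TestInitialPropensity:
    def test_worked_example_difference(self):
        raw = initial_propensity(worked_example_fixture())
        assert round(raw[KK], 3) == 0.422

    def test_symmetric_classes_give_zero(self):
        data = Dataset((
            PeptideRecord("p", "ACAC", "positive"),
            PeptideRecord("n", "ACAC", "negative"),
        ))
        raw = initial_propensity(class_composition(data, DPS))
        assert np.allclose(raw, 0.0)

    def test_pure_negative_symbol_is_negative(self):
        pos = np.zeros(400, dtype=np.int64)
        neg = np.zeros(400, dtype=np.int64)
        pos[DP_TO_INDEX["AA"]] = 10
        neg[DP_TO_INDEX["AA"]] = 5
        neg[DP_TO_INDEX["CC"]] = 5
        from fscm import ClassCompositionSummary
        summary = ClassCompositionSummary("dipeptide", pos, neg, 10, 10)
        raw = initial_propensity(summary)
        assert raw[DP_TO_INDEX["CC"]] == pytest.approx(-0.5)


class TestNormalize:
    def test_minmax_endpoints(self):
        assert np.allclose(normalize_0_1000(np.array([-0.5, 0.0, 0.5])),
                           [0.0, 500.0, 1000.0])

    def test_idempotent_on_normalized(self):
        vec = np.array([0.0, 250.0, 1000.0])
        assert np.allclose(normalize_0_1000(vec), vec)

    def test_constant_maps_to_midpoint(self):
        assert np.allclose(normalize_0_1000(np.full(5, 3.7)), 500.0)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=50, unique=True))
    def test_exact_range_property(self, values):
        out = normalize_0_1000(np.array(values))
        assert out.min() == 0.0
        assert out.max() == 1000.0
        assert ((0.0 <= out) & (out <= 1000.0)).all()


class TestLabelSwapAntisymmetry:
    def test_normalized_scores_reflect(self, synthetic_default):
        card = build_initial_scorecard(synthetic_default, DPS)
        swapped = build_initial_scorecard(_swap_labels(synthetic_default), DPS)
        assert np.allclose(swapped.scores, 1000.0 - card.scores, atol=1e-9)


class TestAAReduction:
    def test_constant_card_preserved(self):
        card = ScoreCard(DPS, np.full(400, 300.0))
        reduced = aa_propensity_from_dipeptides(card)
        assert np.allclose(reduced.scores, 300.0)
        assert reduced.granularity == "amino_acid"

    def _oracle(self, scores, residue):
        """Brute-force: mean over the 40-slot multiset {rX} + {Xr}."""
        slots = [scores[DP_TO_INDEX[residue + x]] for x in "ACDEFGHIKLMNPQRSTVWY"]
        slots += [scores[DP_TO_INDEX[x + residue]] for x in "ACDEFGHIKLMNPQRSTVWY"]
        assert len(slots) == 40
        return sum(slots) / 40.0

    def test_single_heteropair(self):
        scores = np.zeros(400)
        scores[DP_TO_INDEX["KA"]] = 1000.0
        reduced = aa_propensity_from_dipeptides(ScoreCard(DPS, scores))
        assert reduced.scores[AA_TO_INDEX["K"]] == pytest.approx(25.0)
        assert reduced.scores[AA_TO_INDEX["A"]] == pytest.approx(25.0)
        assert reduced.scores[AA_TO_INDEX["C"]] == 0.0

    def test_homopair_counted_twice(self):
        scores = np.zeros(400)
        scores[KK] = 400.0
        reduced = aa_propensity_from_dipeptides(ScoreCard(DPS, scores))
        assert reduced.scores[AA_TO_INDEX["K"]] == pytest.approx(20.0)

    def test_matches_oracle_on_random_card(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0, 1000, 400)
        reduced = aa_propensity_from_dipeptides(ScoreCard(DPS, scores))
        for i, residue in enumerate("ACDEFGHIKLMNPQRSTVWY"):
            assert reduced.scores[i] == pytest.approx(self._oracle(scores, residue))

    def test_amino_acid_card_rejected(self):
        card = ScoreCard(RegionSpec.from_name("APS"), np.full(20, 1.0))
        with pytest.raises(SchemaError):
            aa_propensity_from_dipeptides(card)


class TestSerialization:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        card = ScoreCard(
            RegionSpec.from_name("C15"), rng.uniform(0, 1000, 400),
            threshold=311.0, provenance="optimized",
            metadata={"dataset": "demo", "seed": "7"},
        )
        path = tmp_path / "card.tsv"
        write_scorecard(card, path)
        back = read_scorecard(path)
        assert back.region == card.region
        assert back.threshold == card.threshold
        assert back.provenance == card.provenance
        assert np.array_equal(back.scores, card.scores)
        assert back.metadata == {"dataset": "demo", "seed": "7"}

    def test_missing_symbol_detected(self, tmp_path):
        card = ScoreCard(DPS, np.zeros(400))
        path = tmp_path / "card.tsv"
        write_scorecard(card, path)
        lines = [ln for ln in path.read_text().splitlines()
                 if not ln.startswith("WY\t")]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(SchemaError, match="WY"):
            read_scorecard(path)

    def test_duplicate_symbol_detected(self, tmp_path):
        card = ScoreCard(DPS, np.zeros(400))
        path = tmp_path / "card.tsv"
        write_scorecard(card, path)
        with open(path, "a") as fh:
            fh.write("AA\t1.0\n")
        with pytest.raises(SchemaError, match="duplicate"):
            read_scorecard(path)


class TestEnrichmentRecovery:
    def test_planted_dipeptide_scores_above_median(self, synthetic_default):
        card = build_initial_scorecard(synthetic_default, DPS)
        median = np.median(card.scores)
        for dp in ("KK", "LW", "GH"):
            assert card.scores[DP_TO_INDEX[dp]] > median
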
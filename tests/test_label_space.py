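"""Label vocabulary, multi-hot encoding, manifests, fixtures and the split."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ldinet as L
from ldinet.label_space import (
    HEALTHY,
    LabelSpaceError,
    ManifestError,
    ManifestRecord,
    TripleLabel,
    load_fixture,
)


@pytest.fixture(scope="module")
def space():
    return L.default_label_space()


@pytest.fixture(scope="module")
def small_space():
    return L.build_label_space(["A", "B"], ["d1", "d2", "d3"])


class TestBuildLabelSpace:
    def test_packaged_vocabulary_has_34_labels(self, space):
        assert len(space.plants) == 12
        assert len(space.diseases) == 19
        assert len(space.severities) == 3
        assert space.total == 34
        assert space.plant_range == range(0, 12)
        assert space.disease_range == range(12, 31)
        assert space.severity_range == range(31, 34)

    def test_minimal_space(self):
        sp = L.build_label_space(["A"], ["d"], ["Healthy"])
        assert sp.total == 3
        assert (sp.plant_range, sp.disease_range, sp.severity_range) == (
            range(0, 1), range(1, 2), range(2, 3))

    @pytest.mark.parametrize("plants,diseases", [
        (["A", "A"], ["d"]),            # duplicate within group
        (["A"], ["A"]),                 # duplicate across groups
        ([], ["d"]),                    # empty group
    ])
    def test_invalid_vocabulary_rejected(self, plants, diseases):
        with pytest.raises(LabelSpaceError):
            L.build_label_space(plants, diseases)

    def test_yaml_json_round_trip(self, small_space, tmp_path):
        small_space.to_yaml(tmp_path / "s.yaml")
        small_space.to_json(tmp_path / "s.json")
        assert L.LabelSpace.from_yaml(tmp_path / "s.yaml") == small_space
        assert L.LabelSpace.from_json(tmp_path / "s.json") == small_space


class TestEncodeDecode:
    def test_diseased_triple_has_three_ones(self, space):
        bits = L.encode_triple(space, TripleLabel("Tomato", "Late Blight", "Serious"))
        assert bits.sum() == 3
        expect = {space.label_index("plant", "Tomato"),
                  space.label_index("disease", "Late Blight"),
                  space.label_index("severity", "Serious")}
        assert set(np.nonzero(bits)[0]) == expect

    def test_healthy_triple_has_two_ones_and_empty_disease_block(self, space):
        bits = L.encode_triple(space, TripleLabel("Apple", None, "Healthy"))
        assert bits.sum() == 2
        dr = space.disease_range
        assert bits[dr.start:dr.stop].sum() == 0

    def test_healthy_with_disease_rejected(self):
        with pytest.raises(LabelSpaceError):
            TripleLabel("Apple", "Scab", "Healthy")
        with pytest.raises(LabelSpaceError):
            TripleLabel("Apple", None, "Serious")

    def test_unknown_name_rejected(self, space):
        with pytest.raises(LabelSpaceError):
            L.encode_triple(space, TripleLabel("Kiwi", None, "Healthy"))

    def test_decode_round_trip(self, space):
        triple = TripleLabel("Tomato", "Late Blight", "Serious")
        assert L.decode_scores(space, L.encode_triple(space, triple)) == triple

    def test_decode_all_zeros_ties_break_low(self, space):
        t = L.decode_scores(space, np.zeros(34))
        assert t.plant == space.plants[0]
        assert t.severity == space.severities[0]  # Healthy → disease gated off
        assert t.disease is None

    def test_decode_picks_highest_disease_score(self, space):
        scores = np.zeros(34)
        scores[space.label_index("plant", "Citrus")] = 0.9
        scores[space.label_index("disease", "Greening June")] = 0.999
        scores[space.label_index("disease", "YLCV Virus")] = 0.384
        scores[space.label_index("severity", "Serious")] = 0.8
        assert L.decode_scores(space, scores).disease == "Greening June"

    def test_decode_wrong_length_rejected(self, space):
        with pytest.raises(LabelSpaceError):
            L.decode_scores(space, np.zeros(33))

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_encode_decode_identity_property(self, data):
        """encode∘decode is the identity on valid triples; bit-sum ∈ {2, 3}."""
        space = L.build_label_space(["A", "B", "C"], ["d1", "d2"])
        plant = data.draw(st.sampled_from(space.plants))
        severity = data.draw(st.sampled_from(space.severities))
        disease = (None if severity == HEALTHY
                   else data.draw(st.sampled_from(space.diseases)))
        triple = TripleLabel(plant, disease, severity)
        bits = L.encode_triple(space, triple)
        assert bits.sum() == (2 if severity == HEALTHY else 3)
        assert L.decode_scores(space, bits.astype(float)) == triple


class TestManifest:
    def test_round_trip_identity(self, small_space, tmp_path):
        records = [
            ManifestRecord("img/a.png", TripleLabel("A", "d1", "Serious")),
            ManifestRecord("img/b.png", TripleLabel("B", None, "Healthy")),
        ]
        path = tmp_path / "m.csv"
        L.write_manifest(records, path)
        assert L.read_manifest(path, small_space) == records

    def test_single_row_parse(self, space, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("path,plant,disease,severity\n"
                        "img/a.png,Tomato,Late Blight,Serious\n")
        (rec,) = L.read_manifest(path, space)
        assert rec.triple == TripleLabel("Tomato", "Late Blight", "Serious")

    def test_empty_disease_with_serious_severity_rejected(self, space, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("path,plant,disease,severity\nimg/a.png,Tomato,,Serious\n")
        with pytest.raises(ManifestError, match=":2"):
            L.read_manifest(path, space)

    def test_malformed_row_reports_line_number(self, space, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("path,plant,disease,severity\nimg/a.png,Tomato\n")
        with pytest.raises(ManifestError, match=":2"):
            L.read_manifest(path, space)


class TestStratifiedSplit:
    @staticmethod
    def _records(space, sizes):
        out = []
        triples = [TripleLabel("A", "d1", "Serious"),
                   TripleLabel("B", None, "Healthy"),
                   TripleLabel("A", "d2", "General")]
        for triple, n in zip(triples, sizes):
            out += [ManifestRecord(f"{triple.plant}_{i}.png", triple)
                    for i in range(n)]
        return out

    def test_80_20_on_one_class_of_ten(self, small_space):
        records = self._records(small_space, [10])
        tr, va = L.split_stratified(records, 0.8, seed=0)
        assert (len(tr), len(va)) == (8, 2)

    def test_per_class_proportions_preserved(self, small_space):
        records = self._records(small_space, [5, 5])
        tr, va = L.split_stratified(records, 0.8, seed=3)
        for cls in ("A", "B"):
            assert sum(r.triple.plant == cls for r in tr) == 4
            assert sum(r.triple.plant == cls for r in va) == 1

    def test_partition_and_determinism(self, small_space):
        records = self._records(small_space, [7, 4, 9])
        tr1, va1 = L.split_stratified(records, 0.8, seed=11)
        tr2, va2 = L.split_stratified(records, 0.8, seed=11)
        assert (tr1, va1) == (tr2, va2)
        assert sorted(map(repr, tr1 + va1)) == sorted(map(repr, records))
        assert not set(map(repr, tr1)) & set(map(repr, va1))

    def test_per_class_train_counts_round_half_up(self, small_space):
        records = self._records(small_space, [7, 4, 9])
        tr, _ = L.split_stratified(records, 0.8, seed=5)
        by_class = {}
        for r in tr:
            key = (r.triple.plant, r.triple.disease, r.triple.severity)
            by_class[key] = by_class.get(key, 0) + 1
        assert by_class == {("A", "d1", "Serious"): 6,   # round(5.6)
                            ("B", None, "Healthy"): 3,   # round(3.2)
                            ("A", "d2", "General"): 7}   # round(7.2)
        for n, got in ((7, 6), (4, 3), (9, 7)):
            assert abs(got / n - 0.8) < 1 / n

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            L.split_stratified([], 0.8, seed=0)


class TestFixtures:
    def test_plant_column_sums_match_reported_totals(self):
        fx = load_fixture("plant")
        assert L.sum_fixture_column(fx, "train") == 24159
        assert L.sum_fixture_column(fx, "val") == 6054
        assert L.sum_fixture_column(fx, "test") == 4324

    def test_disease_train_sum_is_total_minus_healthy(self):
        # healthy images carry no disease row, so the disease table's train
        # column must fall short of the overall train total by the Healthy cell
        diseases = load_fixture("disease")
        severities = load_fixture("severity")
        healthy_train = severities.rows["Healthy"][0]
        assert L.sum_fixture_column(diseases, "train") == 24159 - healthy_train

    @pytest.mark.parametrize("column,idx", [("train", 0), ("val", 1), ("test", 2)])
    def test_severity_sums_equal_plant_sums(self, column, idx):
        # both tables describe the same image sets
        assert (L.sum_fixture_column(load_fixture("severity"), column)
                == L.sum_fixture_column(load_fixture("plant"), column))

    def test_fixture_names_match_label_space_groups(self):
        space = L.default_label_space()
        assert load_fixture("plant").names == space.plants
        assert load_fixture("disease").names == space.diseases
        assert set(load_fixture("severity").names) == set(space.severities)

    def test_unknown_column_rejected(self):
        with pytest.raises(ValueError):
            L.sum_fixture_column(load_fixture("plant"), "bogus")
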
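import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spotclust.spot_data import (
    ReplicateTable,
    SpotMatrix,
    consensus_proteomes,
    consolidate_replicates,
    occurrence_frequency,
    read_spot_table,
)


def write_inputs(tmp_path, table_text, ann_text):
    spots = tmp_path / "spots.tsv"
    ann = tmp_path / "ann.tsv"
    spots.write_text(table_text)
    ann.write_text(ann_text)
    return spots, ann


ANN2 = "sample_id\tspecies\nX\tsp1\nY\tsp2\n"


class TestReadSpotTable:
    def test_toy_sample_level_parse(self, tmp_path):
        spots, ann = write_inputs(
            tmp_path, "spot_id\tX\tY\na\t1\t0\nb\t0\t0\nc\t1\t1\n", ANN2
        )
        m, _ = read_spot_table(spots, ann)
        assert isinstance(m, SpotMatrix)
        assert m.values.sum(axis=0).tolist() == [2, 1]
        assert m.values[:, 0].tolist() == [1, 0, 1]

    def test_round_trip_identity(self, tmp_path, rng):
        from tests.conftest import binary_matrix

        m = binary_matrix(rng, 15, 4)
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        ann = tmp_path / "ann.tsv"
        ann.write_text(
            "sample_id\tspecies\n" + "".join(f"{s}\tsp\n" for s in m.sample_ids)
        )
        m2, _ = read_spot_table(path, ann)
        assert m2.spot_ids == m.spot_ids
        assert m2.sample_ids == m.sample_ids
        assert np.array_equal(m2.values, m.values)

    def test_unknown_column_is_named_in_error(self, tmp_path):
        spots, ann = write_inputs(tmp_path, "spot_id\tX\tZZZ\na\t1\t0\n", ANN2)
        with pytest.raises(ValueError, match="ZZZ"):
            read_spot_table(spots, ann)

    def test_non_binary_cell_reports_coordinates(self, tmp_path):
        spots, ann = write_inputs(tmp_path, "spot_id\tX\tY\na\t1\t0\nb\t7\t0\n", ANN2)
        with pytest.raises(ValueError, match="'b'"):
            read_spot_table(spots, ann)

    def test_replicate_columns_detected(self, tmp_path):
        spots, ann = write_inputs(
            tmp_path, "spot_id\tX_1\tX_2\tY_1\na\t1\t1\t0\n", ANN2
        )
        t, _ = read_spot_table(spots, ann)
        assert isinstance(t, ReplicateTable)
        assert t.columns == [("X", 1), ("X", 2), ("Y", 1)]


def oracle_consolidate(rep_counts: dict[str, int]) -> dict[str, bool]:
    """Hand-coded reliability rule over per-sample replicate counts."""
    n_samples_seen = sum(1 for c in rep_counts.values() if c > 0)
    return {
        s: c >= 2 or (c >= 1 and n_samples_seen >= 2) for s, c in rep_counts.items()
    }


class TestConsolidateReplicates:
    def make(self, pattern, n_reps=3):
        """One spot; pattern maps sample -> number of positive replicates."""
        cols, row = [], []
        for s, npos in pattern.items():
            for r in range(n_reps):
                cols.append((s, r + 1))
                row.append(1 if r < npos else 0)
        return ReplicateTable(["spot"], cols, np.array([row]))

    def test_two_replicates_same_sample_retained(self):
        m = consolidate_replicates(self.make({"A": 2, "B": 0}))
        assert m.spot_ids == ["spot"]
        assert m.to_frame().loc["spot"].tolist() == [1, 0]

    def test_single_replicates_in_two_samples_present_in_both(self):
        m = consolidate_replicates(self.make({"A": 1, "B": 1}))
        assert m.to_frame().loc["spot"].tolist() == [1, 1]

    def test_single_replicate_single_sample_dropped(self):
        m = consolidate_replicates(self.make({"A": 1, "B": 0}))
        assert m.spot_ids == []

    def test_enumerated_patterns_match_oracle(self):
        samples = ["A", "B", "C"]
        for counts in itertools.product(range(4), repeat=3):
            pattern = dict(zip(samples, counts))
            m = consolidate_replicates(self.make(pattern))
            want = oracle_consolidate(pattern)
            if not any(want.values()):
                assert m.spot_ids == []
            else:
                got = dict(zip(m.sample_ids, m.values[0]))
                assert {s: bool(v) for s, v in got.items()} == want

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            consolidate_replicates(
                ReplicateTable([], [("A", 1)], np.zeros((0, 1), dtype=int))
            )


class TestGroupOps:
    def test_consensus_is_union(self, annotation_factory):
        m = SpotMatrix(["a", "b"], ["x1", "x2"], np.array([[1, 0], [0, 1]]))
        ann = annotation_factory(["x1", "x2"], ["sp", "sp"])
        cons = consensus_proteomes(m, ann)
        assert cons.to_frame()["sp"].tolist() == [1, 1]

    def test_single_sample_group_is_identity(self, annotation_factory, rng):
        from tests.conftest import binary_matrix

        m = binary_matrix(rng, 10, 3)
        ann = annotation_factory(m.sample_ids, ["s1", "s2", "s3"])
        cons = consensus_proteomes(m, ann)
        for j, sp in enumerate(["s1", "s2", "s3"]):
            assert np.array_equal(cons.to_frame()[sp].to_numpy(), m.values[:, j])

    def test_consensus_matches_brute_force(self, annotation_factory, rng):
        from tests.conftest import binary_matrix

        m = binary_matrix(rng, 20, 12)
        species = [f"g{j % 3}" for j in range(12)]
        ann = annotation_factory(m.sample_ids, species)
        cons = consensus_proteomes(m, ann)
        for g in ("g0", "g1", "g2"):
            cols = [j for j, s in enumerate(species) if s == g]
            brute = np.array([any(m.values[i, j] for j in cols) for i in range(20)])
            assert np.array_equal(cons.to_frame()[g].to_numpy().astype(bool), brute)

    def test_frequency_is_ratio(self, annotation_factory):
        m = SpotMatrix(
            ["a"], ["x1", "x2", "x3", "x4"], np.array([[1, 1, 0, 0]])
        )
        ann = annotation_factory(m.sample_ids, ["sp"] * 4)
        f = occurrence_frequency(m, ann)
        assert f.values[0, 0] == pytest.approx(0.5)

    def test_frequency_threshold_equals_consensus(self, annotation_factory, rng):
        from tests.conftest import binary_matrix

        m = binary_matrix(rng, 25, 9)
        species = [f"g{j % 4}" for j in range(9)]
        ann = annotation_factory(m.sample_ids, species)
        cons = consensus_proteomes(m, ann)
        thr = occurrence_frequency(m, ann).threshold()
        assert np.array_equal(
            thr.to_frame()[cons.sample_ids].to_numpy(), cons.values
        )


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.data())
def test_consensus_monotone_in_detections(data):
    """Adding a detection can never remove a consensus presence."""
    from spotclust.spot_data import SampleAnnotation

    n_spots = data.draw(st.integers(2, 6))
    n_samples = data.draw(st.integers(2, 6))
    cells = data.draw(
        st.lists(
            st.integers(0, 1), min_size=n_spots * n_samples, max_size=n_spots * n_samples
        )
    )
    vals = np.array(cells).reshape(n_spots, n_samples)
    ids = [f"x{j}" for j in range(n_samples)]
    ann = SampleAnnotation(
        pd.DataFrame({"sample_id": ids, "species": [f"g{j % 2}" for j in range(n_samples)]})
    )
    m = SpotMatrix([f"s{i}" for i in range(n_spots)], ids, vals)
    before = consensus_proteomes(m, ann).values
    i = data.draw(st.integers(0, n_spots - 1))
    j = data.draw(st.integers(0, n_samples - 1))
    vals2 = vals.copy()
    vals2[i, j] = 1
    after = consensus_proteomes(
        SpotMatrix(m.spot_ids, ids, vals2), ann
    ).values
    assert (after >= before).all()
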
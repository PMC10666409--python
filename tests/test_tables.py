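"""Feature-table, metadata and FASTA I/O plus relative abundances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ampdecon.mocksim import preset_design, simulate
from ampdecon.tables import (
    FeatureTable,
    SampleMetadata,
    Role,
    TableError,
    drop_features,
    normalize_sequence,
    read_fasta,
    read_feature_table,
    read_metadata,
    relative_abundance,
    write_fasta,
    write_feature_table,
    write_metadata,
)


class TestFeatureTableIO:
    def test_parse_toy_tsv(self, tmp_path, toy_table):
        p = tmp_path / "t.tsv"
        p.write_text("feature_id\tS1\tS2\nASV_1\t5\t0\nASV_2\t1\t4\n")
        t = read_feature_table(p)
        assert t.feature_ids == ["ASV_1", "ASV_2"]
        assert t.sample_ids == ["S1", "S2"]
        assert list(t.sample_totals()) == [6, 4]
        np.testing.assert_array_equal(t.counts, toy_table.counts)

    def test_duplicate_feature_id_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("feature_id\tS1\nASV_1\t5\nASV_1\t1\n")
        with pytest.raises(TableError, match="ASV_1"):
            read_feature_table(p)

    @pytest.mark.parametrize(
        "cell,message",
        [("-2", "negative"), ("1.5", "non-integer"), ("x", "non-numeric")],
    )
    def test_bad_cells_rejected_with_location(self, tmp_path, cell, message):
        p = tmp_path / "t.tsv"
        p.write_text(f"feature_id\tS1\nASV_1\t{cell}\n")
        with pytest.raises(TableError, match=message):
            read_feature_table(p)

    def test_round_trip_random_table(self, tmp_path, rng):
        counts = rng.integers(0, 100, size=(50, 10))
        t = FeatureTable(
            feature_ids=[f"F{i}" for i in range(50)],
            sample_ids=[f"S{j}" for j in range(10)],
            counts=counts,
            sequences=["ACGT" * 5] * 50,
            taxonomy=[f"g{i % 7}" for i in range(50)],
        )
        p = tmp_path / "t.tsv"
        write_feature_table(t, p)
        back = read_feature_table(p)
        np.testing.assert_array_equal(back.counts, t.counts)
        assert back.feature_ids == t.feature_ids
        assert back.sample_ids == t.sample_ids
        assert back.sequences == t.sequences
        assert back.taxonomy == t.taxonomy

    def test_simulated_table_round_trip(self, tmp_path):
        t, _, _, _ = simulate(preset_design("STAGGERED_B", seed=7))
        p = tmp_path / "sim.tsv"
        write_feature_table(t, p)
        back = read_feature_table(p)
        np.testing.assert_array_equal(back.counts, t.counts)
        assert back.sequences == t.sequences


class TestMetadata:
    def test_roles_normalised(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("sample_id\trole\nS1\tsample\nN1\tNEG2\n")
        m = read_metadata(p)
        assert m.role_of("S1") == Role.SAMPLE
        assert m.role_of("N1") == Role.NEG2
        assert m.biological_samples() == ["S1"]

    def test_unknown_role_rejected(self):
        with pytest.raises(TableError, match="unknown role"):
            SampleMetadata(pd.DataFrame({"sample_id": ["S1"], "role": ["negative"]}))

    def test_duplicate_sample_rejected(self):
        with pytest.raises(TableError, match="duplicate"):
            SampleMetadata(pd.DataFrame({"sample_id": ["S1", "S1"], "role": ["sample", "NEG1"]}))

    def test_orphan_samples_cross_validation(self, toy_table):
        m = SampleMetadata(
            pd.DataFrame({"sample_id": ["S1", "S2", "S3"], "role": ["sample"] * 3})
        )
        assert m.cross_validate(toy_table) == ["S3"]

    def test_round_trip(self, tmp_path):
        m = SampleMetadata(
            pd.DataFrame(
                {
                    "sample_id": ["S1", "N1"],
                    "role": ["sample", "NEG1"],
                    "group": ["d1", None],
                    "dna_quant": [3.5, None],
                }
            )
        )
        p = tmp_path / "m.tsv"
        write_metadata(m, p)
        back = read_metadata(p)
        assert back.role_of("N1") == Role.NEG1
        assert back.group_of("S1") == "d1"


class TestRelativeAbundance:
    def test_even_split(self):
        t = FeatureTable(["a", "b"], ["S1"], np.array([[5], [5]]))
        np.testing.assert_allclose(relative_abundance(t).values[:, 0], [0.5, 0.5])

    def test_zero_total_sample_flagged(self):
        t = FeatureTable(["a", "b"], ["S1", "S2"], np.array([[1, 0], [1, 0]]))
        v = relative_abundance(t)
        assert v.zero_total_samples == ["S2"]
        np.testing.assert_array_equal(v.values[:, 1], [0.0, 0.0])

    def test_columns_sum_to_one(self, rng):
        t = FeatureTable(
            [f"f{i}" for i in range(20)],
            [f"s{j}" for j in range(5)],
            rng.integers(0, 30, size=(20, 5)),
        )
        v = relative_abundance(t)
        for j, s in enumerate(t.sample_ids):
            if t.sample_totals()[j] > 0:
                assert v.values[:, j].sum() == pytest.approx(1.0, abs=1e-9)

    @given(st.integers(min_value=1, max_value=1000), st.integers(min_value=0, max_value=4))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_scale_invariance_per_sample(self, scale, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 20, size=(8, 3))
        t1 = FeatureTable([f"f{i}" for i in range(8)], ["a", "b", "c"], counts)
        scaled = counts.copy()
        scaled[:, 1] *= scale
        t2 = FeatureTable(t1.feature_ids, t1.sample_ids, scaled)
        np.testing.assert_allclose(
            relative_abundance(t1).values[:, 1], relative_abundance(t2).values[:, 1]
        )


class TestDropFeatures:
    def test_identity_and_full(self, toy_table):
        assert drop_features(toy_table, []).feature_ids == toy_table.feature_ids
        empty = drop_features(toy_table, toy_table.feature_ids)
        assert empty.n_features == 0
        assert empty.sample_ids == toy_table.sample_ids

    def test_unknown_id_rejected(self, toy_table):
        with pytest.raises(TableError, match="unknown feature"):
            drop_features(toy_table, ["nope"])

    def test_read_conservation(self, rng):
        counts = rng.integers(0, 40, size=(30, 6))
        t = FeatureTable([f"f{i}" for i in range(30)], [f"s{j}" for j in range(6)], counts)
        dropped_ids = t.feature_ids[::2]
        kept = drop_features(t, dropped_ids)
        dropped = t.subset_features(dropped_ids)
        np.testing.assert_array_equal(
            kept.sample_totals() + dropped.sample_totals(), t.sample_totals()
        )


class TestFasta:
    def test_basic_and_multiline(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">a\nACGT\n>b\nAC\nGT\n")
        assert read_fasta(p) == {"a": "ACGT", "b": "ACGT"}

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">a\nACGT\n>a\nTTTT\n")
        with pytest.raises(TableError, match="duplicate"):
            read_fasta(p)

    def test_round_trip_random_sequences(self, tmp_path, rng):
        seqs = {
            f"r{i}": "".join(rng.choice(list("ACGT"), size=rng.integers(10, 80)))
            for i in range(100)
        }
        p = tmp_path / "r.fasta"
        write_fasta(seqs, p)
        assert read_fasta(p) == seqs

    def test_u_normalised_and_invalid_rejected(self):
        assert normalize_sequence("acgu") == "ACGT"
        with pytest.raises(TableError, match="invalid"):
            normalize_sequence("ACGX")
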
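"""Contaminant classifiers: presence, ratio, span, combinations, adapters."""

import numpy as np
import pandas as pd
import pytest

from ampdecon.filters import (
    CombineMode,
    apply_result,
    combine_results,
    external_decisions,
    frequency_result,
    presence_filter,
    ratio_filter,
    span_filter,
    write_decisions,
)
from ampdecon.tables import FeatureTable, SampleMetadata, TableError
from tests.conftest import random_table_and_meta


def _toy(counts, roles):
    n_f, n_s = np.asarray(counts).shape
    ids = [f"f{i}" for i in range(n_f)]
    sids = [f"c{j}" for j in range(n_s)]
    t = FeatureTable(ids, sids, np.asarray(counts))
    m = SampleMetadata(pd.DataFrame({"sample_id": sids, "role": roles}))
    return t, m


class TestPresence:
    def test_single_control_read_removes(self):
        t, m = _toy([[0, 0, 1], [5, 5, 0]], ["sample", "sample", "NEG2"])
        r = presence_filter(t, m, "NEG2")
        assert r.removed == {"f0"}
        assert r.kept == {"f1"}

    def test_no_controls_is_error(self):
        t, m = _toy([[1]], ["sample"])
        with pytest.raises(TableError, match="no NEG2 controls"):
            presence_filter(t, m, "NEG2")

    def test_matches_bruteforce(self, rng):
        t, m = random_table_and_meta(rng, n_features=30)
        r = presence_filter(t, m, "NEG2")
        controls = [j for j, s in enumerate(t.sample_ids) if s.startswith("N")]
        expected = {
            f
            for i, f in enumerate(t.feature_ids)
            if any(t.counts[i, j] > 0 for j in controls)
        }
        assert r.removed == expected


class TestRatio:
    def test_strict_threshold(self):
        # control abundance 0.5, sample abundance 0.1 -> ratio 5
        t, m = _toy(
            [[10, 10, 50], [90, 90, 50]],
            ["sample", "sample", "NEG2"],
        )
        r2 = ratio_filter(t, m, "NEG2", threshold=2)
        assert r2.frame.loc["f0", "ratio"] == pytest.approx(5.0)
        assert r2.decision_of("f0").value == "REMOVE"
        r5 = ratio_filter(t, m, "NEG2", threshold=5)
        assert r5.decision_of("f0").value == "KEEP"  # strict >

    def test_control_only_feature_has_infinite_ratio(self):
        t, m = _toy([[0, 0, 3], [5, 5, 7]], ["sample", "sample", "NEG2"])
        r = ratio_filter(t, m, "NEG2", threshold=1e6)
        assert np.isinf(r.frame.loc["f0", "ratio"])
        assert "f0" in r.removed

    def test_all_zero_feature_kept_with_nan_ratio(self):
        t, m = _toy([[0, 0, 0], [5, 5, 7]], ["sample", "sample", "NEG2"])
        r = ratio_filter(t, m, "NEG2", threshold=0)
        assert np.isnan(r.frame.loc["f0", "ratio"])
        assert "f0" in r.kept

    def test_means_over_all_controls_include_zeros(self):
        # feature in 1 of 2 controls at 0.5 -> mean control abundance 0.25
        t, m = _toy([[2, 5, 0], [2, 5, 10]], ["sample", "NEG2", "NEG2"])
        r = ratio_filter(t, m, "NEG2", threshold=0.1)
        assert r.frame.loc["f0", "mean_control_abundance"] == pytest.approx(0.25)

    def test_threshold_grid_is_nested(self, rng):
        t, m = random_table_and_meta(rng, n_features=40)
        grid = [0.1, 0.5, 1.0, 2.0]
        removed = [ratio_filter(t, m, "NEG2", x).removed for x in grid]
        for a, b in zip(removed, removed[1:]):
            assert b <= a


class TestSpan:
    def test_count_semantics(self):
        t, m = _toy(
            [[1, 2, 2, 0], [1, 0, 0, 0]],
            ["sample", "NEG2", "NEG2", "NEG2"],
        )
        assert "f0" in span_filter(t, m, "NEG2", 2).removed
        assert "f0" in span_filter(t, m, "NEG2", 2).removed
        assert "f0" not in span_filter(t, m, "NEG2", 3).removed

    def test_k_out_of_range(self):
        t, m = _toy([[1, 1]], ["sample", "NEG2"])
        with pytest.raises(TableError, match="out of range"):
            span_filter(t, m, "NEG2", 2)
        with pytest.raises(TableError, match="out of range"):
            span_filter(t, m, "NEG2", 0)

    def test_matches_bruteforce(self, rng):
        t, m = random_table_and_meta(rng, n_features=30)
        controls = [j for j, s in enumerate(t.sample_ids) if s.startswith("N")]
        for k in (1, 2, 3):
            expected = {
                f
                for i, f in enumerate(t.feature_ids)
                if sum(t.counts[i, j] > 0 for j in controls) >= k
            }
            assert span_filter(t, m, "NEG2", k).removed == expected

    def test_k_monotonicity(self, rng):
        t, m = random_table_and_meta(rng)
        assert span_filter(t, m, "NEG2", 3).removed <= span_filter(t, m, "NEG2", 2).removed
        assert span_filter(t, m, "NEG2", 2).removed <= span_filter(t, m, "NEG2", 1).removed


class TestStatedEquivalences:
    """Equivalences that hold on every table, checked on many random instances."""

    @pytest.mark.parametrize("seed", range(25))
    def test_span_one_equals_presence(self, seed):
        rng = np.random.default_rng(seed)
        t, m = random_table_and_meta(rng, n_features=15, zero_prob=0.6)
        assert span_filter(t, m, "NEG2", 1).removed == presence_filter(t, m, "NEG2").removed

    @pytest.mark.parametrize("seed", range(25))
    def test_ratio_zero_equals_presence(self, seed):
        rng = np.random.default_rng(seed)
        t, m = random_table_and_meta(rng, n_features=15, zero_prob=0.6)
        assert ratio_filter(t, m, "NEG2", 0.0).removed == presence_filter(t, m, "NEG2").removed

    def test_decisions_ignore_sample_order(self, rng):
        t, m = random_table_and_meta(rng)
        perm = list(rng.permutation(t.sample_ids))
        r1 = ratio_filter(t, m, "NEG2", 1.0)
        r2 = ratio_filter(t.subset_samples(perm), m, "NEG2", 1.0)
        assert r1.removed == r2.removed


class TestCombine:
    def test_union_and_intersection(self):
        t, m = _toy([[1, 0, 1, 0], [1, 0, 0, 2]], ["sample", "sample", "NEG2", "NEG1"])
        a = presence_filter(t, m, "NEG2")  # removes f0
        b = presence_filter(t, m, "NEG1")  # removes f1
        assert combine_results(a, b, CombineMode.UNION).removed == {"f0", "f1"}
        assert combine_results(a, b, CombineMode.INTERSECTION).removed == set()

    def test_union_idempotent(self, rng):
        t, m = random_table_and_meta(rng)
        x = presence_filter(t, m, "NEG2")
        assert combine_results(x, x, "union").removed == x.removed

    def test_set_algebra_matches_bruteforce(self, rng):
        t, m = random_table_and_meta(rng, n_features=25)
        a = ratio_filter(t, m, "NEG2", 0.5)
        b = span_filter(t, m, "NEG2", 2)
        assert combine_results(a, b, "union").removed == a.removed | b.removed
        assert combine_results(a, b, "intersection").removed == a.removed & b.removed

    def test_mismatched_features_error(self, rng):
        t, m = random_table_and_meta(rng)
        a = presence_filter(t, m, "NEG2")
        t2 = t.subset_features(t.feature_ids[:-1])
        b = presence_filter(t2, m, "NEG2")
        with pytest.raises(TableError, match="identical feature sets"):
            combine_results(a, b, "union")


class TestExternalAndApply:
    def test_small_decision_file(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("feature_id\tdecision\nf1\tREMOVE\nf2\tKEEP\n")
        r = external_decisions(p)
        assert r.removed == {"f1"}

    def test_missing_feature_error(self, tmp_path, rng):
        t, _ = random_table_and_meta(rng, n_features=3)
        p = tmp_path / "d.tsv"
        p.write_text("feature_id\tdecision\nASV_1\tREMOVE\n")
        with pytest.raises(TableError, match="ASV_2"):
            external_decisions(p, table=t)

    def test_write_read_round_trip(self, tmp_path, rng):
        t, m = random_table_and_meta(rng)
        r = ratio_filter(t, m, "NEG2", 1.0)
        p = tmp_path / "d.tsv"
        write_decisions(r, p)
        back = external_decisions(p, table=t)
        assert back.removed == r.removed

    def test_apply_result_conserves_reads(self, rng):
        t, m = random_table_and_meta(rng)
        r = span_filter(t, m, "NEG2", 2)
        kept = apply_result(t, r)
        removed_total = t.total_reads() - kept.total_reads()
        assert removed_total == int(t.subset_features(sorted(r.removed)).counts.sum())
        assert set(kept.feature_ids) == set(t.feature_ids) - r.removed

    def test_frequency_classifier_ignores_controls(self):
        # feature abundant only in the control must still be removed
        t, m = _toy([[0, 0, 50], [10, 10, 50]], ["sample", "sample", "NEG2"])
        r = frequency_result(t, m, threshold=0.01)
        assert "f0" in r.removed
        assert "f1" in r.kept
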
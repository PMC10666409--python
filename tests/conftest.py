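"""Shared fixtures: small random tables with roles, and toy constructions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ampdecon.tables import FeatureTable, SampleMetadata


def random_table_and_meta(
    rng: np.random.Generator,
    n_features: int = 12,
    n_samples: int = 5,
    n_neg1: int = 2,
    n_neg2: int = 3,
    max_count: int = 50,
    zero_prob: float = 0.4,
) -> tuple[FeatureTable, SampleMetadata]:
    """A random sparse count table with biological samples and both control types."""
    n_cols = n_samples + n_neg1 + n_neg2
    counts = rng.integers(0, max_count + 1, size=(n_features, n_cols))
    counts[rng.random(counts.shape) < zero_prob] = 0
    sample_ids = (
        [f"S{i+1}" for i in range(n_samples)]
        + [f"P{i+1}" for i in range(n_neg1)]
        + [f"N{i+1}" for i in range(n_neg2)]
    )
    roles = ["sample"] * n_samples + ["NEG1"] * n_neg1 + ["NEG2"] * n_neg2
    table = FeatureTable(
        feature_ids=[f"ASV_{i+1}" for i in range(n_features)],
        sample_ids=sample_ids,
        counts=counts,
    )
    meta = SampleMetadata(pd.DataFrame({"sample_id": sample_ids, "role": roles}))
    return table, meta


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


@pytest.fixture
def toy_table() -> FeatureTable:
    """2 features x 2 samples with counts [[5, 0], [1, 4]]."""
    return FeatureTable(
        feature_ids=["ASV_1", "ASV_2"],
        sample_ids=["S1", "S2"],
        counts=np.array([[5, 0], [1, 4]]),
    )
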
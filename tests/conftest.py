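"""Shared fixtures: synthetic benchmarks at two scales.

The full-scale benchmark (50 kb genomes, the generator's defaults) is
session-scoped because simulating and counting it once is enough for every
test that needs it; small-scale variants are built per test.
"""

from __future__ import annotations

import numpy as np
import pytest

import kmerlogic as kl


@pytest.fixture(scope="session")
def default_benchmark():
    """Default study conditions: 4 species / 2 genera / 2 phyla, 10 x 50 kb."""
    spec = kl.SimSpec(seed=1)
    records, signatures = kl.simulate_dataset(spec)
    matrix = kl.build_matrix(records, k=4, strand_mode="both")
    return spec, records, signatures, matrix


@pytest.fixture(scope="session")
def small_benchmark():
    """Reduced-scale benchmark (10 kb genomes) for fast structural tests."""
    spec = kl.SimSpec(seed=11, genome_length=10_000)
    records, signatures = kl.simulate_dataset(spec)
    matrix = kl.build_matrix(records, k=4, strand_mode="both")
    return spec, records, signatures, matrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_separable_matrix(n_per_class: int = 10, seed: int = 0) -> kl.FeatureMatrix:
    """Two classes split perfectly by one feature ('ACGT') threshold."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    k = 3
    features = kl.all_kmers(k)
    values = rng.uniform(0.0, 0.01, size=(len(features), n))
    fi = features.index("ACG")
    values[fi, :n_per_class] = rng.uniform(0.001, 0.003, n_per_class)
    values[fi, n_per_class:] = rng.uniform(0.007, 0.009, n_per_class)
    labels = ["alpha"] * n_per_class + ["beta"] * n_per_class
    return kl.FeatureMatrix(
        k=k,
        feature_order=features,
        sample_ids=[f"s{i}" for i in range(n)],
        values=values,
        labels={"species": labels},
    )
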
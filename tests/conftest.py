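import numpy as np
import pytest

from brotree import (
    ExpressionDataset,
    Region,
    SampleAnnotation,
    SyntheticSpec,
    simulate_expression,
    simulate_ontology,
)
from brotree.ontology import build_ontology


@pytest.fixture
def tiny_ontology():
    """root -> {a, b}; a -> {a1, a2}; b -> {b1}."""
    return build_ontology(
        [
            Region("root", None),
            Region("a", "root"),
            Region("b", "root"),
            Region("a1", "a"),
            Region("a2", "a"),
            Region("b1", "b"),
        ]
    )


@pytest.fixture
def path_ontology():
    """A path tree p0 - p1 - p2 - p3 - p4 (distances = index differences)."""
    regions = [Region("p0", None)] + [Region(f"p{i}", f"p{i-1}") for i in range(1, 5)]
    return build_ontology(regions)


@pytest.fixture
def path_dataset(path_ontology):
    """One sample per path node with expression equal to the node index,
    so expression distance equals tree distance for gene g0."""
    samples = [SampleAnnotation(f"s{i}", f"p{i}", "d0") for i in range(5)]
    values = np.array([[0.0, 1.0, 2.0, 3.0, 4.0]])
    return ExpressionDataset(["g0"], samples, values)


@pytest.fixture
def star16():
    return simulate_ontology(depth=1, branching=16, seed=0)


@pytest.fixture
def tree16():
    """Depth-2, branching-4 tree: 16 leaf regions (21 nodes)."""
    return simulate_ontology(depth=2, branching=4, seed=0)


@pytest.fixture
def small_dataset(tree16):
    spec = SyntheticSpec(
        n_genes=10,
        n_donors=2,
        samples_per_region_per_donor=2,
        tree_signal_scale=1.5,
        donor_scale=0.3,
        noise_scale=0.5,
        seed=42,
    )
    ds, truth = simulate_expression(spec, tree16)
    return ds, truth


def random_dataset(ont, n_samples, rng, n_genes=1):
    """Samples at random regions, random expression — oracle-sized instances."""
    region_ids = ont.region_ids
    samples = [
        SampleAnnotation(f"s{i}", region_ids[rng.integers(len(region_ids))], "d0")
        for i in range(n_samples)
    ]
    values = rng.normal(size=(n_genes, n_samples))
    return ExpressionDataset([f"g{i}" for i in range(n_genes)], samples, values)
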
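import numpy as np
import pytest

from landgen import GenotypeMatrix, GenotypeSimConfig, simulate_genotypes


@pytest.fixture
def tiny_matrix() -> GenotypeMatrix:
    """2 populations x 2 loci, one missing genotype, hand-checkable."""
    calls = np.array([
        [[152, 152], [101, 103]],
        [[152, 156], [101, 101]],
        [[156, 156], [103, 103]],
        [[152, 156], [0, 0]],       # missing at locus B
    ])
    return GenotypeMatrix(
        individual_ids=["a1", "a2", "b1", "b2"],
        population_labels=["P1", "P1", "P2", "P2"],
        calls=calls,
        locus_names=["LocA", "LocB"],
        coordinates=np.array([[-75.0, 4.0], [-75.0, 4.01],
                              [-74.0, 5.0], [-74.0, 5.01]]),
    )


@pytest.fixture(scope="session")
def study_matrix():
    """Synthetic 12-site, 100-tree, 12-locus survey with study-like design."""
    G, truth = simulate_genotypes(GenotypeSimConfig(seed=42))
    return G, truth
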
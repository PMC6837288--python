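import numpy as np
import pytest

from altipop import coalescent
from altipop.popgen_core import MISSING, GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20190101)


@pytest.fixture
def small_genotypes():
    """Six samples in two populations, four sites (one with missing data)."""
    dosages = np.array([
        # s1 s2 s3 s4  sites ->
        [0, 1, 2, 2],
        [0, 1, 2, MISSING],
        [1, 0, 2, 1],
        [2, 2, 0, 0],
        [2, 1, 0, 1],
        [1, 2, 0, 0],
    ], dtype=np.int8)
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=[f"ind{i}" for i in range(6)],
        pop_labels=["A", "A", "A", "B", "B", "B"],
        site_ids=[("chr1", 100, "A", "G"), ("chr1", 200, "C", "T"),
                  ("chr1", 300, "G", "A"), ("chr2", 50, "T", "C")],
    )


@pytest.fixture(scope="session")
def island_model():
    """Two demes of 1000 diploids, ancient split, 0.5 migrants/generation."""
    return coalescent.DemographicModel(
        deme_names=["a", "b"], sizes=[1000.0, 1000.0],
        splits=[(2_000_000.0, 1, 0)],
        mig_high=[[0.0, 0.5], [0.5, 0.0]],
        mig_low=[[0.0, 0.5], [0.5, 0.0]],
    )
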
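import numpy as np
import pytest

from dompop.synthetic import SimulationScenario, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic study (53 trees, 23 genotyped, 103 loci)."""
    return simulate_dataset(SimulationScenario(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240601)


def random_binary_matrix(rng, n=12, L=30):
    """Random marker matrix helper used by several property tests."""
    from dompop.types import BinaryMarkerMatrix

    scores = (rng.random((n, L)) < rng.uniform(0.05, 0.95, L)).astype(np.int8)
    locus_ids = [f"P{1 + j % 3:02d}:L{j:03d}" for j in range(L)]
    return BinaryMarkerMatrix(
        [f"I{i:02d}" for i in range(n)],
        locus_ids,
        {l: l.split(":")[0] for l in locus_ids},
        scores,
    )
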
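import numpy as np
import pytest

from readmix.panel_io import PopulationRecord, ReferencePanel
from readmix.synth_eval import four_way_benchmark_panel, generate_panel


def make_panel(vectors, names=None, coords=None, variances=None):
    """Build a panel from raw admixture rows with defaulted metadata."""
    vectors = np.asarray(vectors, dtype=float)
    n = len(vectors)
    names = names or [f"P{i}" for i in range(n)]
    coords = coords or [(float(10 * i % 80 - 40), float(20 * i % 300 - 150)) for i in range(n)]
    records = [
        PopulationRecord(
            name=names[i],
            latitude=coords[i][0],
            longitude=coords[i][1],
            admixture=vectors[i],
            variance=None if variances is None else np.asarray(variances[i], float),
        )
        for i in range(n)
    ]
    return ReferencePanel(records)


@pytest.fixture
def identity_panel():
    """Three populations at the K=3 simplex vertices."""
    return make_panel(np.eye(3))


@pytest.fixture
def small_random_panel():
    """Seeded 20-population, K=5 panel with variances."""
    return generate_panel(20, 5, concentration=0.5, seed=42)


@pytest.fixture
def two_way_benchmark():
    """12-population K=4 panel with pure European and African sources."""
    panel, sources = four_way_benchmark_panel(12, sources=(0, 1), seed=7)
    return panel, sources
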
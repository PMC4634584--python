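import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from deges import CountMatrix, GroupDesign, SimulationConfig, simulate_counts


@pytest.fixture
def toy_matrix() -> CountMatrix:
    rng = np.random.default_rng(7)
    counts = rng.poisson(50, size=(20, 4))
    return CountMatrix([f"g{i}" for i in range(20)], ["s1", "s2", "s3", "s4"], counts)


@pytest.fixture
def three_group_design() -> GroupDesign:
    mapping = {
        "G1_rep1": "G1", "G1_rep2": "G1", "G1_rep3": "G1",
        "G2_rep1": "G2", "G2_rep2": "G2", "G2_rep3": "G2",
        "G3_rep1": "G3", "G3_rep2": "G3", "G3_rep3": "G3",
    }
    return GroupDesign(mapping, ("G1", "G2", "G3"))


@pytest.fixture(scope="session")
def biased_simulation():
    """A biased 3-group dataset: 25% DEGs, 80/10/10 split, 2000 genes."""
    cfg = SimulationConfig(
        n_gene=2000, p_deg=0.25, group_sizes=(3, 3, 3),
        deg_proportions=(0.8, 0.1, 0.1), seed=42,
    )
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def null_simulation():
    """A DEG-free 3-group dataset (p_deg = 0), 2000 genes."""
    cfg = SimulationConfig(n_gene=2000, p_deg=0.0, group_sizes=(3, 3, 3), seed=11)
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def null_simulation_large():
    """A DEG-free 3-group dataset at the standard 10,000-gene scale."""
    cfg = SimulationConfig(n_gene=10000, p_deg=0.0, group_sizes=(3, 3, 3), seed=11)
    return simulate_counts(cfg)
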
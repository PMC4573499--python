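import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import edscape as e


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))


@pytest.fixture(scope="session")
def small_dataset() -> e.SyntheticDataset:
    """A compact synthetic study reused across read-only tests."""
    cfg = e.SimulationConfig(
        n_strains=40, n_sites=6, n_variants_per_gene=6, seed=7, n_replicates=2
    )
    return e.simulate_dataset(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_915)
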
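import warnings

import numpy as np
import pandas as pd
import pytest

from symbionet import (
    BipartiteNetwork,
    CountMatrix,
    SampleMetadata,
    ScenarioConfig,
    TaxonAnnotation,
    scenario_paper_like,
)

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture
def tiny_cm():
    """3 taxa x 2 samples with known counts."""
    return CountMatrix(pd.DataFrame(
        {"s1": [1, 2, 0], "s2": [0, 5, 3]},
        index=["tA", "tB", "tC"],
    ))


@pytest.fixture
def tiny_meta():
    return SampleMetadata(pd.DataFrame(
        {"site_id": ["site1", "site1"], "substrate": ["crop", "soil"]},
        index=pd.Index(["s1", "s2"], name="sample_id"),
    ))


def make_meta(rows):
    """rows: list of (sample_id, site_id, substrate)."""
    return SampleMetadata(
        pd.DataFrame(rows, columns=["sample_id", "site_id", "substrate"])
        .set_index("sample_id")
    )


def random_network(rng, nr, nc, high=12, ensure_cover=True):
    w = rng.integers(0, high, size=(nr, nc))
    if ensure_cover:
        w += np.eye(nr, nc, dtype=np.int64)
        w[np.arange(nr) % nr, np.arange(nr) % nc] += 1
    return BipartiteNetwork.from_weights(
        w, [f"r{i}" for i in range(nr)], [f"c{j}" for j in range(nc)]
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced synthetic dataset (6 sites) for fast integration tests."""
    cfg = ScenarioConfig(
        n_sites=6, n_env_taxa=300, depth_env=2500, depth_tissue=2500, seed=42
    )
    return scenario_paper_like(seed=42, config=cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """One full-size default scenario (20 sites), shared across tests."""
    return scenario_paper_like(seed=7)
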
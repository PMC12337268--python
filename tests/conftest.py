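import warnings

import numpy as np
import pandas as pd
import pytest

from pavcoex.config import AnalysisConfig
from pavcoex.simulate import (PlantedCluster, PlantedModule, RepliconProfile,
                              SimParams, simulate_dataset)

warnings.filterwarnings("ignore", message=".*biomass values clipped.*")


def tiny_params(**overrides) -> SimParams:
    """A down-scaled study: same structure, desk-second runtimes."""
    defaults = dict(
        replicons={
            "chromosome": RepliconProfile(150, 0.561, 0.329, 0.110),
            "pSymA": RepliconProfile(120, 0.199, 0.601, 0.200),
            "pSymB": RepliconProfile(100, 0.679, 0.241, 0.080),
        },
        accessory_genes=10,
        planted_clusters=(
            PlantedCluster("plusA", 4, "pSymA", 0.5, +1.2),
            PlantedCluster("minusA", 6, "pSymA", 0.5, -1.2),
        ),
        symbiont_modules=(
            PlantedModule("s1", 40),
            PlantedModule("s2", 30, trait_coupling=0.6, quality_cor=0.95),
        ),
        host_modules=(
            PlantedModule("h1", 40, trait_coupling=0.4, quality_cor=0.95),
            PlantedModule("h2", 30),
        ),
        n_host_genes=300,
    )
    defaults.update(overrides)
    return SimParams(**defaults)


@pytest.fixture(scope="session")
def tiny_dataset():
    return simulate_dataset(tiny_params(), seed=11)


@pytest.fixture(scope="session")
def default_run():
    """One full-scale run at the default study conditions (shared by the
    acceptance tests; simulated once per session)."""
    from pavcoex.pipeline import evaluate_against_truth, run_on_dataset

    ds = simulate_dataset(seed=42)
    res = run_on_dataset(ds)
    ev = evaluate_against_truth(res, ds.truth)
    return ds, res, ev


@pytest.fixture
def small_counts():
    """A hand-sized counts matrix: 3 genes x 2 strains x 2 replicates."""
    from pavcoex.io import CountsMatrix

    genes = ["g1", "g2", "g3"]
    samples = ["A_r1", "A_r2", "B_r1", "B_r2"]
    counts = np.array([
        [10, 12, 0, 1],
        [100, 110, 95, 105],
        [0, 0, 0, 0],
    ])
    sheet = pd.DataFrame({
        "sample_id": samples,
        "strain_id": ["A", "A", "B", "B"],
        "replicate": [1, 2, 1, 2],
    })
    return CountsMatrix(pd.Index(genes), pd.Index(samples), counts), sheet


@pytest.fixture
def config():
    return AnalysisConfig()
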
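import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from decaylens.models import (
    ALL_CODONS,
    CodonUsageTable,
    GeneModel,
    GeneModelSet,
    RegionMap,
)
from decaylens.simulate import (
    SimulationParams,
    simulate_annotation,
    simulate_counts,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def uniform_usage() -> CodonUsageTable:
    return CodonUsageTable({c: 1.0 for c in ALL_CODONS})


@pytest.fixture(scope="session")
def example_usage() -> CodonUsageTable:
    """Uniform background with one skewed Glu family (GAA 20, GAG 10)."""
    freq = {c: 1.0 for c in ALL_CODONS}
    freq["GAA"], freq["GAG"] = 20.0, 10.0
    return CodonUsageTable(freq)


@pytest.fixture
def tiny_models() -> GeneModelSet:
    return GeneModelSet(
        [
            GeneModel("gA", "tA1", RegionMap.from_lengths(60, 300, 140)),
            GeneModel("gA", "tA2", RegionMap.from_lengths(30, 150, 70)),
            GeneModel("gB", "tB1", RegionMap.from_lengths(100, 300, 200), "-"),
        ]
    )


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    return SimulationParams(n_genes=150, seed=7, coverage_reads=40_000)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    """One small simulated dataset shared across tests (read-only)."""
    models, seqs = simulate_annotation(small_params)
    cm, labels = simulate_counts(models, small_params)
    return {
        "params": small_params,
        "models": models,
        "seqs": seqs,
        "cm": cm,
        "labels": labels,
    }


@pytest.fixture
def flat_design_counts():
    """Six-library single-period design with controlled library sizes
    (each column sums to 10^5, so cpm = count x 10)."""
    samples = [f"s{i}" for i in range(6)]
    design = pd.DataFrame(
        {
            "genotype": ["WT"] * 3 + ["mut"] * 3,
            "period": "O",
            "stage": "O1",
            "replicate": [1, 2, 3, 1, 2, 3],
        },
        index=pd.Index(samples, name="sample"),
    )
    counts = pd.DataFrame(
        0, index=[f"g{i}" for i in range(3)], columns=samples
    )
    return counts, design
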
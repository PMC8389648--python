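import numpy as np
import pandas as pd
import pytest

from gsreg.io import ExpressionMatrix, GeneSet, GeneSetCollection
from gsreg.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, two controls and two cases, no ties."""
    values = pd.DataFrame(
        {
            "c1": [1.0, 2.0, 3.0],
            "c2": [1.5, 2.5, 3.5],
            "k1": [3.0, 2.0, 1.0],
            "k2": [1.0, 2.0, 3.0],
        },
        index=["A", "B", "C"],
    )
    groups = pd.Series(
        ["control", "control", "case", "case"], index=["c1", "c2", "k1", "k2"]
    )
    return ExpressionMatrix(values, groups)


@pytest.fixture
def tiny_collection() -> GeneSetCollection:
    return GeneSetCollection([GeneSet("S1", "all three", ("A", "B", "C"))])


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-set cohort with 4 strongly dysregulated sets (theta = 1)."""
    config = SimulationConfig(
        n_genes=200, n_sets=20, set_size=10, n_controls=15, n_cases=15,
        frac_dysregulated=0.2, scramble_intensity=1.0, noise_sd=0.1, seed=7,
    )
    return simulate_cohort(config)
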
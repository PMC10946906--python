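import numpy as np
import pandas as pd
import pytest

from gescreen import ExpressionMatrix, GeneratorConfig


def two_group_matrix(treated_rows, vehicle_rows, genes=None):
    """Build a small treated/vehicle ExpressionMatrix from per-gene rows."""
    treated = np.atleast_2d(np.asarray(treated_rows, dtype=float))
    vehicle = np.atleast_2d(np.asarray(vehicle_rows, dtype=float))
    n_genes = treated.shape[0]
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = [f"t{i}" for i in range(treated.shape[1])] + \
              [f"v{i}" for i in range(vehicle.shape[1])]
    values = pd.DataFrame(np.hstack([treated, vehicle]), index=genes,
                          columns=samples)
    design = pd.Series(["treated"] * treated.shape[1]
                       + ["vehicle"] * vehicle.shape[1], index=samples)
    return ExpressionMatrix(values, design)


@pytest.fixture
def small_config():
    """A scaled-down generator configuration for fast tests."""
    return GeneratorConfig(seed=11, n_per_group=5, n_genes=50,
                           n_compounds=24, compounds_per_plate=8,
                           reps_per_dose=3)


@pytest.fixture
def default_two_group():
    from gescreen import generate_two_group
    return generate_two_group(GeneratorConfig(seed=1))
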
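import numpy as np
import pytest

from cytostate import (
    CohortConfig,
    PanelSpec,
    arcsinh_transform,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-group cohort, 3 patients/group x 300 cells, default planted shift."""
    cfg = CohortConfig(n_patients_per_group=3, n_cells_per_sample=300, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def neutral_cohort():
    """Single-group cohort with no planted effects (for recovery checks)."""
    cfg = CohortConfig(n_patients_per_group=6, groups=("A",),
                       state_shift_per_group={"A": 0.0},
                       n_cells_per_sample=300, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def panel(small_cohort):
    matrix, _meta, truth = small_cohort
    return PanelSpec(markers=matrix.markers, programs=truth.archetypes.marker_programs)


@pytest.fixture(scope="session")
def transformed(small_cohort):
    matrix, _meta, _truth = small_cohort
    return arcsinh_transform(matrix)


@pytest.fixture(scope="session")
def neutral_transformed(neutral_cohort):
    matrix, _meta, _truth = neutral_cohort
    return arcsinh_transform(matrix)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
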
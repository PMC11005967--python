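"""Shared fixtures.

The 81-case cohort and its per-modality plan evaluations are expensive, so
they are built once per session and shared by the unit and acceptance
tests.  Everything is generated programmatically; there are no data files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from overlapdose import (
    default_grid,
    evaluate_cohort,
    generate_simulation1_cases,
    generate_simulation2_cases,
    make_grid,
    preset,
)


@pytest.fixture(scope="session")
def grid2():
    """Default 2 mm phantom grid."""
    return default_grid(2.0)


@pytest.fixture(scope="session")
def small_grid():
    """Small isotropic grid for brute-force oracle tests."""
    return make_grid((32.0, 32.0, 32.0), 2.0)


@pytest.fixture(scope="session")
def sim1_cases(grid2):
    return generate_simulation1_cases(grid2, seed=0)


@pytest.fixture(scope="session")
def sim2_cases(grid2):
    return generate_simulation2_cases(grid2, seed=0)


@pytest.fixture(scope="session")
def imrt_table(sim2_cases) -> pd.DataFrame:
    return evaluate_cohort(sim2_cases, preset("IMRT"), seed=1)


@pytest.fixture(scope="session")
def vmat_table(sim2_cases) -> pd.DataFrame:
    return evaluate_cohort(sim2_cases, preset("VMAT"), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
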
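"""Shared fixtures: bench geometries and cached reference simulations.

Simulations are session-scoped because several tests interrogate the same
noiseless scenarios (inert and humic-retarded sulphapyridine transport);
each takes a fraction of a second but there is no point re-running them.
"""

import pytest

from gelcell import (
    CellGeometry,
    DEFAULT_GEOMETRY,
    TransportParams,
    closed_form_lag,
    simulate_cell,
)

D_SULPHA = 5.20e-10  # inert-gel sulphapyridine diffusivity, m2/s
C0_SULPHA = 25.0  # donor concentration, mg/dm3
K_HUMIC = 1.92  # first-stage binding constant of the humic gel


@pytest.fixture(scope="session")
def geometry():
    """The bench cell: 5 mm x 40 mm slab between 50 cm3 reservoirs."""
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def big_reservoir_geometry():
    """Same slab between 2 dm3 reservoirs: near-constant donor, sink acceptor."""
    return CellGeometry(donor_volume=2.0e-3, acceptor_volume=2.0e-3)


@pytest.fixture(scope="session")
def inert_params():
    return TransportParams(d_gel=D_SULPHA, c0_donor=C0_SULPHA)


@pytest.fixture(scope="session")
def reactive_params():
    return TransportParams(d_gel=D_SULPHA, c0_donor=C0_SULPHA, k_binding=K_HUMIC)


@pytest.fixture(scope="session")
def inert_trace_big(big_reservoir_geometry, inert_params):
    """Noiseless inert run, ~6 lag times, near-constant donor."""
    return simulate_cell(big_reservoir_geometry, inert_params, 4.8e4, 60.0)


@pytest.fixture(scope="session")
def reactive_trace_big(big_reservoir_geometry, reactive_params):
    """Noiseless humic-gel run (K = 1.92), ~6 lag times."""
    return simulate_cell(big_reservoir_geometry, reactive_params, 1.4e5, 120.0)


@pytest.fixture(scope="session")
def inert_trace_bench(geometry, inert_params):
    """Noiseless inert run in the finite 50 cm3 cell, ~10 lag times."""
    return simulate_cell(geometry, inert_params, 8.0e4, 60.0)


@pytest.fixture(scope="session")
def lag_inert():
    return closed_form_lag(5.0e-3, D_SULPHA)  # 8012.8 s = 133.5 min


@pytest.fixture(scope="session")
def lag_reactive():
    return closed_form_lag(5.0e-3, D_SULPHA, K_HUMIC)  # 23397 s = 390 min
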
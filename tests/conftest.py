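"""Shared fixtures for the hydropore test suite."""

import numpy as np
import pytest

from hydropore.energetics import ModelParams, ThermoState
from hydropore.lattice import GridSpec


@pytest.fixture
def spec40():
    return GridSpec(L=40)


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def thermo():
    return ThermoState(T_star=0.3, P_star=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(20261002)


@pytest.fixture(scope="session")
def cg_summaries():
    """Coil-globule T-sweep at the three lowest positive pressures.

    Shared by the acceptance tests for the pressure thresholds, the confined
    compactness maximum, stability-region nesting, and N_CP(T) nonmonotonicity.
    Run lengths are scaled down from the full-study schedule (see
    docs/methods.md); thresholds asserted on it are not.
    """
    from hydropore.analysis import sweep_phase_diagram
    from hydropore.engine import RunConfig

    grid = [(T, P) for P in (0.1, 0.2, 0.3)
            for T in (0.1, 0.15, 0.2, 0.3, 0.5)]
    template = RunConfig(n_steps=30_000, n_equil=10_000, sample_every=50,
                         seed=20261002, cluster_equil=True)
    return sweep_phase_diagram(grid, template)
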
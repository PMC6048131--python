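"""Shared fixtures.

The expensive simulation-calibration machinery (chain-expected spectra,
refined grids, the 100-replicate null ensemble and the 20-replicate power
ensemble) is computed once per session and shared by the simulator,
inference and acceptance tests.
"""

import numpy as np
import pytest

from domfit.calibration import run_null_calibration, run_power_analysis
from domfit.diffusion import DemographicModel
from domfit.wright_fisher import SimulationConfig


@pytest.fixture(scope="session")
def desk_demography():
    return DemographicModel(((0.25, 0.2), (1.2, 0.05)))


@pytest.fixture(scope="session")
def null_calibration():
    """Additive-truth LRT calibration: 100 field-engine replicates at the
    10x-reduced theta profile, nested menu refit per replicate."""
    return run_null_calibration(replicates=100, seed=11)


@pytest.fixture(scope="session")
def power_analysis():
    """Inverse h-s truth (intercept 0.5, h(-0.001) ~ 0.02): 20 replicates at
    the genome-wide theta profile."""
    return run_power_analysis(replicates=20, seed=7)


@pytest.fixture(scope="session")
def small_sim_config(desk_demography):
    """A small, fast simulation configuration for per-mutation engine tests."""
    return SimulationConfig(
        demography=desk_demography,
        thetas={"syn_inbreeding": 50.0, "nonsyn_inbreeding": 115.5,
                "syn_outcrossing": 100.0, "nonsyn_outcrossing": 231.0},
        N_e=2000.0, downscale=50.0,
        n_sample_outcrossing=10, n_sample_inbreeding=8,
        engine="per_mutation",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
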
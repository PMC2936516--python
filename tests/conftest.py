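import numpy as np
import pytest

from gammares.params import (
    ConnectivitySpec,
    GeometrySpec,
    ModelConfig,
    NeuronParameters,
    SimulationConfig,
    default_config,
)
from gammares.drive import DriveSpec, SpikeRaster, generate_poisson_raster
from gammares.engine import run_simulation
from gammares.experiments import make_fixture_network


@pytest.fixture(scope="session")
def neuron_params():
    return NeuronParameters()


@pytest.fixture(scope="session")
def calibrated_config():
    return default_config()


@pytest.fixture(scope="session")
def fixture_network(calibrated_config):
    """Quarter-scale network with drive-conserving weight rescale."""
    return make_fixture_network(calibrated_config, 0.25, seed=0)


@pytest.fixture(scope="session")
def static_run(fixture_network, calibrated_config):
    """One 4 s static-drive simulation of the fixture network, shared by
    every test that only needs a representative gamma-oscillating run."""
    net = fixture_network
    net.feedforward_gmax = calibrated_config.feedforward_gmax
    drive = DriveSpec(mean_rate=40.0, duration=4.0, seed=7)
    raster = generate_poisson_raster(drive, net.n_neurons)
    cfg = SimulationConfig(duration=4.0, warmup_discard=0.5, seed=7)
    return run_simulation(net, raster, cfg)


def poisson_raster(rate=40.0, duration=10.0, n=20, seed=0):
    return generate_poisson_raster(
        DriveSpec(mean_rate=rate, duration=duration, seed=seed), n
    )
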
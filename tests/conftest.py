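import numpy as np
import pytest

from icealgae import synthetic as syn
from icealgae.config import PipelineConfig
from icealgae.cube import SpectralCube
from icealgae.pipeline import run_pipeline


@pytest.fixture(scope="session")
def grid89():
    """PAR wavelength grid at ~3.4 nm spacing (under-ice sampling)."""
    return np.linspace(400.0, 700.0, 89)


@pytest.fixture(scope="session")
def solar_led(grid89):
    return syn.make_led_spectrum("solar", grid89, seed=11)


@pytest.fixture(scope="session")
def absorption(grid89):
    return syn.make_chla_absorption(grid89)


@pytest.fixture()
def small_truth(grid89):
    return syn.make_scene_truth((24, 24), grid89, seed=5, mean=20.0, sd=10.0,
                                correlation_length=2.0, pixel_pitch=2.4)


@pytest.fixture()
def cavity_truth(grid89):
    return syn.make_scene_truth((32, 32), grid89, seed=7, mean=20.0, sd=10.0,
                                correlation_length=2.0, pixel_pitch=2.4,
                                cavity_fraction=0.1)


@pytest.fixture()
def noiseless_transmittance(small_truth, solar_led, absorption):
    """Noiseless transmittance cube of a small core section."""
    from icealgae import preprocess as pp

    scan = syn.simulate_core_scan(small_truth, solar_led, absorption, seed=1)
    return pp.to_transmittance(scan, solar_led)


def constant_cube(value, shape=(4, 4), wavelengths=None,
                  units="transmittance"):
    if wavelengths is None:
        wavelengths = np.linspace(400.0, 700.0, 31)
    data = np.full(shape + (wavelengths.size,), float(value))
    return SpectralCube(data, wavelengths, units=units)


@pytest.fixture(scope="session")
def demo_result():
    """One shared small end-to-end pipeline run."""
    return run_pipeline(PipelineConfig.demo(seed=3))
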
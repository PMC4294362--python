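import numpy as np
import pytest

from stromascreen import DetectionParams, SimulationConfig
from stromascreen.classify import train
from stromascreen.pipeline import build_training_set


@pytest.fixture(scope="session")
def det_params() -> DetectionParams:
    return DetectionParams()


@pytest.fixture(scope="session")
def single_field_config():
    """Factory for one-field configs with the well disk inscribed in the
    field, so every placed cell is imaged and there are no field seams."""

    def make(**overrides) -> SimulationConfig:
        base = dict(fields_per_well=1, field_size_px=(256, 256), well_radius_px=128.0)
        base.update(overrides)
        return SimulationConfig(**base)

    return make


@pytest.fixture(scope="session")
def trained_bundle():
    """A classifier trained once per session on simulated ground truth.

    Returns (training config, training set, fitted model); the config's
    optics match the small evaluation wells used across tests.
    """
    config = SimulationConfig(
        field_size_px=(256, 256), well_radius_px=450.0, fields_per_well=9
    )
    training = build_training_set(config=config, seed=11, n_wells=3, counts=(120, 120, 60))
    model = train(training, seed=11)
    return config, training, model


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
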
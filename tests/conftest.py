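import logging

import numpy as np
import pytest

import emtcomp as ec

logging.getLogger("emtcomp").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def phantom():
    return ec.build_phantom(10, pitch=8.0, n_elevations=3)


@pytest.fixture(scope="session")
def suite():
    """The calibrated nine-scenario synthetic suite (seed 0)."""
    return ec.build_suite(0)


@pytest.fixture(scope="session")
def planar_exp():
    """Dropout-trained planar board experiment (seed 0); shared, read-only."""
    return ec.build_planar_experiment(0)


@pytest.fixture(scope="session")
def identity_model():
    """Small net trained on clean (undistorted, noise-free) pairs."""
    ph = ec.build_phantom(10, pitch=8.0, n_elevations=3)
    scen = ec.DistortionScenario("clean", (150.0, 0.0, 0.0), strength=0.0, noise_sd=0.0)
    ms = ec.generate_scenario_dataset(ph, scen, seed=3)
    pairs = ec.pair_dataset(ms, ph)
    cfg = ec.SiameseConfig(
        n_hidden_layers=2, units_per_layer=16, max_epochs=150, patience=150, seed=5
    )
    return ec.train_siamese(pairs[:600], pairs[600:700], cfg), pairs


@pytest.fixture(scope="session")
def dropout_model():
    """Small planar net trained with dropout, for MC-sampling unit tests."""
    rng = np.random.default_rng(11)
    pos = rng.uniform(-60, 60, size=(25, 2))
    ph = ec.CalibratedPhantom(grid_positions=pos, n_elevations=1)
    scen = ec.DistortionScenario("drop", (0.0, 150.0, 0.0), strength=3.0)
    ms = ec.generate_scenario_dataset(ph, scen, seed=13, rotations=(0.0,))
    pairs = ec.pair_dataset(ms, ph)
    cfg = ec.planar_config(
        units_per_layer=32, dropout_rate=0.10, max_epochs=120, patience=120, seed=7
    )
    return ec.train_siamese(pairs[:250], pairs[250:300], cfg)
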
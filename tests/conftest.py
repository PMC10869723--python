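import dataclasses

import numpy as np
import pytest

import spatialgain as sg


@pytest.fixture(scope="session")
def phantom_config() -> sg.PhantomConfig:
    """Default phantom (beta0 80, beta1 33.5, pennation 12 deg)."""
    return sg.PhantomConfig(seed=123)


@pytest.fixture(scope="session")
def noiseless_sweep(phantom_config) -> sg.SweepSet:
    """One noiseless frame per gel-pad angle (calibration oracle input)."""
    cfg = dataclasses.replace(phantom_config, frames_per_sweep=1)
    return sg.render_sweepset(cfg, noise=False)


@pytest.fixture(scope="session")
def noisy_frame(phantom_config):
    """A single speckled frame at gel-pad angle 0 plus its ground truth."""
    return sg.render_frame(phantom_config, 0.0, 0)


@pytest.fixture(scope="session")
def noise_only_frame() -> sg.Frame:
    """A frame containing nothing but smoothed speckle."""
    rng = np.random.default_rng(0)
    px = np.clip(rng.normal(62, 6, (512, 512)), 0, 255).astype(np.uint8)
    return sg.Frame(px)


@pytest.fixture(scope="session")
def cross_section_12pct():
    cfg = sg.CrossSectionConfig(seed=3, imct_fraction_true=12.0)
    return sg.render_cross_section(cfg)
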
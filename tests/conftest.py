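import numpy as np
import pytest

from polarmm.mm_core import normalize_mm
from polarmm.pbp import pbp_stack
from polarmm.phantom import PRESETS, GroupPreset, generate_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def normal_phantom():
    """Noise-free 64x64 normal-preset phantom with its ground truth."""
    return generate_phantom(PRESETS["normal"], 64, 64, seed=42)


@pytest.fixture(scope="session")
def normal_stack(normal_phantom):
    img, _ = normal_phantom
    norm, bg = normalize_mm(img)
    return pbp_stack(norm, "all", background=bg)


@pytest.fixture
def flat_preset():
    """Zero-dispersion preset: every foreground pixel identical."""
    return GroupPreset(
        "flat",
        delta_mean=0.9,
        delta_sd=0.0,
        diat_mean=0.1,
        diat_sd=0.0,
        orient_mean_deg=40.0,
        orient_sd_deg=0.0,
        depol_diag=(0.9, 0.9, 0.8),
        fiber_fill_fraction=1.0,
        noise_sigma=0.0,
    )
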
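"""Shared fixtures: noiseless and noisy synthetic renders at study geometry."""

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import spindleprofiler as sp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def noiseless_spec():
    return sp.SpindleSpec(noise_model="none")


@pytest.fixture
def noiseless_image(noiseless_spec):
    image, manifest = sp.render_spindle_image(noiseless_spec)
    return image, manifest


@pytest.fixture
def constant_image():
    """A 4-channel image whose every pixel is 50 (background only)."""
    spec = sp.SpindleSpec(
        channel_amplitudes={"pole": 0.0, "tubulin": 0.0, "dna": 0.0, "motor": 0.0},
        background=50.0,
        noise_model="none",
    )
    image, _ = sp.render_spindle_image(spec)
    return image


def make_scan(positions, **channels):
    """Build a LineScan from plain vectors (width 1, anonymous cell)."""
    return sp.LineScan(np.asarray(positions, float),
                       {k: np.asarray(v, float) for k, v in channels.items()},
                       width_px=1)


@pytest.fixture
def make_linescan():
    return make_scan
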
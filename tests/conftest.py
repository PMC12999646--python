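"""Shared fixtures: small phantoms and reusable cohorts.

Everything is generated programmatically from fixed seeds; the expensive
cohorts are session-scoped so multiple tests share one generation.
"""

import warnings

import numpy as np
import pytest

from lipidmsi.msi_io import (AcquisitionMetadata, PixelSpectrum,
                             SpectrumImage)
from lipidmsi.panel import default_panel, null_panel
from lipidmsi.synthetic import NoiseModel, PhantomConfig, generate_cohort


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*non-positive abundances.*")
        warnings.filterwarnings("ignore", message=".*zero-variance strata.*")
        yield


@pytest.fixture(scope="session")
def noise():
    return NoiseModel()


@pytest.fixture(scope="session")
def small_cfg():
    """Small phantom grid for fast unit tests."""
    return PhantomConfig(grid_shape=(60, 40))


@pytest.fixture(scope="session")
def small_cohort(small_cfg, noise):
    return generate_cohort(small_cfg, noise, seed=101)


@pytest.fixture(scope="session")
def default_cohort(noise):
    """One full-size cohort (120x80) shared across analysis tests."""
    cfg = PhantomConfig()
    return generate_cohort(cfg, noise, seed=7)


def make_image(pixel_peaks, grid_shape=(4, 3), **meta_kwargs):
    """Tiny SpectrumImage from {(x, y): [(mz, intensity), ...]}."""
    pixels = []
    for (x, y), peaks in pixel_peaks.items():
        peaks = sorted(peaks)
        pixels.append(PixelSpectrum(
            x, y,
            np.array([p[0] for p in peaks], dtype=float),
            np.array([p[1] for p in peaks], dtype=float),
        ))
    return SpectrumImage(pixels, grid_shape,
                         AcquisitionMetadata(**meta_kwargs))


@pytest.fixture
def tiny_image():
    return make_image({
        (0, 0): [(300.0, 10.0), (462.3425, 50.0)],
        (1, 0): [(462.3425, 30.0), (462.40, 99.0)],
        (2, 1): [(500.0, 5.0)],
        (0, 2): [],
    })
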
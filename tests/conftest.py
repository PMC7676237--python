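import numpy as np
import pytest

from livsampler.spectral_io import (
    DomainRect,
    SampleSet,
    SpectralMap,
    WavenumberAxis,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_domain():
    return DomainRect(0.0, 1.0, 0.0, 1.0)


@pytest.fixture
def small_axis():
    return WavenumberAxis(np.linspace(1000.0, 1900.0, 10))


def make_grid_map(n_rows=4, n_cols=4, n_features=10, fill=None, step=1.0):
    """Small raster map; ``fill(x, y)`` returns the spectrum at a grid point."""
    axis = WavenumberAxis(np.linspace(1000.0, 1000.0 + 100.0 * (n_features - 1), n_features))
    xs = (np.arange(n_cols) + 0.5) * step
    ys = (np.arange(n_rows) + 0.5) * step
    spectra = np.empty((n_rows * n_cols, n_features))
    for r in range(n_rows):
        for c in range(n_cols):
            if fill is None:
                spectra[r * n_cols + c] = np.arange(n_features) + r * n_cols + c
            else:
                spectra[r * n_cols + c] = fill(xs[c], ys[r])
    return SpectralMap(xs, ys, axis, spectra,
                       domain=DomainRect(0.0, n_cols * step, 0.0, n_rows * step))


def planar_map(n_rows=8, n_cols=8, n_features=4, step=1.0):
    """Map whose spectra are affine in (x, y) per channel: exactly linear data."""
    coeff = np.arange(1, n_features + 1, dtype=float)

    def fill(x, y):
        return coeff * (2.0 * x - 1.0 * y) + 3.0

    return make_grid_map(n_rows, n_cols, n_features, fill=fill, step=step)


@pytest.fixture
def grid_map():
    return make_grid_map()


@pytest.fixture
def affine_map():
    return planar_map()


def make_sample_set(points, spectra, axis, domain=None):
    points = np.asarray(points, dtype=float)
    if domain is None:
        domain = DomainRect(
            points[:, 0].min() - 1.0,
            points[:, 0].max() + 1.0,
            points[:, 1].min() - 1.0,
            points[:, 1].max() + 1.0,
        )
    return SampleSet(points, np.asarray(spectra, dtype=float), axis, domain)
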
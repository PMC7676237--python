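"""IR spectral preprocessing upstream of surrogate construction.

The adaptive acquisition loop preprocesses every spectrum acquired so far at
each iteration: restrict the spectral band, remove the baseline with a
rubber-band (lower convex hull) correction, then reduce dimensionality with
PCA (first five components by default).  The surrogate model and the
leave-one-out errors then operate on the PCA scores rather than the raw
high-dimensional spectra.

A signal-to-noise filter is also provided; it is used to build the
noise-removed reference subset from which on-target peak criteria are derived.
SNR here is the mean absolute intensity over a signal band divided by the
standard deviation over a quiet (signal-free) band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import overload

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from sklearn.decomposition import PCA

from .spectral_io import SampleSet, Spectrum, WavenumberAxis

__all__ = [
    "BandRestriction",
    "ReducedSampleSet",
    "restrict_band",
    "rubberband_baseline",
    "pca_reduce",
    "noise_filter",
]

DEFAULT_N_COMPONENTS = 5


@dataclass(frozen=True)
class BandRestriction:
    """Closed wavenumber interval [low, high] in cm^-1."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("band bounds must satisfy low < high")

    def mask(self, axis: WavenumberAxis) -> np.ndarray:
        return (axis.values >= self.low) & (axis.values <= self.high)

    def overlaps(self, other: "BandRestriction") -> bool:
        return self.low <= other.high and other.low <= self.high


@dataclass
class ReducedSampleSet:
    """PCA scores of a sample set: the low-dimensional view the sampler works in.

    ``scores`` is (n_points, n_components); ``loadings`` the component rows in
    spectral space; ``explained_variance_ratio`` the per-component fraction of
    total variance.  Scores are raw (not whitened) so that L2 distances weight
    components by the spectral variance they carry.
    """

    points: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    mean_spectrum: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@overload
def restrict_band(data: Spectrum, band: BandRestriction) -> Spectrum: ...
@overload
def restrict_band(data: SampleSet, band: BandRestriction) -> SampleSet: ...


def restrict_band(data, band):
    """Keep only the axis entries with ``low <= wavenumber <= high``."""
    axis = data.axis
    mask = band.mask(axis)
    if not np.any(mask):
        raise ValueError(
            f"empty band: [{band.low}, {band.high}] does not overlap the axis"
        )
    new_axis = WavenumberAxis(axis.values[mask])
    if isinstance(data, Spectrum):
        return Spectrum(new_axis, data.intensities[mask])
    if isinstance(data, SampleSet):
        return SampleSet(
            data.points,
            data.spectra[:, mask],
            new_axis,
            data.domain,
            order=data.order,
            seed=data.seed,
        )
    raise TypeError(f"unsupported type: {type(data).__name__}")


def _lower_hull_baseline(wavenumbers: np.ndarray, intensities: np.ndarray) -> np.ndarray:
    """Baseline = lower convex-hull envelope, linearly interpolated."""
    n = wavenumbers.size
    if n == 2:
        return intensities.copy()
    pts = np.column_stack([wavenumbers, intensities])
    try:
        hull = ConvexHull(pts)
        vertices = np.sort(hull.vertices)
    except QhullError:
        # Degenerate (collinear) spectrum: the line through the endpoints is
        # its own lower envelope.
        vertices = np.array([0, n - 1])
    # Walk the lower envelope: among hull vertices, keep those on the lower
    # chain by scanning for non-increasing-then-increasing support.  For a
    # convex hull of points sorted in x, the lower chain is the subsequence of
    # vertices between the leftmost and rightmost point that lies below the
    # connecting segment of its neighbours; equivalently, keep vertices where
    # the piecewise-linear interpolation stays below all points.
    lower = [0]
    for v in vertices:
        if v == 0:
            continue
        while len(lower) >= 2:
            x0, y0 = wavenumbers[lower[-2]], intensities[lower[-2]]
            x1, y1 = wavenumbers[lower[-1]], intensities[lower[-1]]
            x2, y2 = wavenumbers[v], intensities[v]
            # Drop the middle vertex if it lies on or above the chord.
            if (y1 - y0) * (x2 - x0) >= (y2 - y0) * (x1 - x0):
                lower.pop()
            else:
                break
        lower.append(int(v))
    idx = np.asarray(lower)
    return np.interp(wavenumbers, wavenumbers[idx], intensities[idx])


def rubberband_baseline(spectrum: Spectrum) -> Spectrum:
    """Rubber-band baseline correction.

    Subtracts the lower convex-hull envelope of the (wavenumber, intensity)
    points, linearly interpolated between hull vertices.  The corrected
    spectrum is non-negative up to numerical tolerance, with the first and
    last points mapped exactly to zero.  Idempotent on corrected spectra.
    """
    values = spectrum.axis.values
    if values[0] > values[-1]:  # operate on an ascending axis internally
        baseline = _lower_hull_baseline(values[::-1], spectrum.intensities[::-1])[::-1]
    else:
        baseline = _lower_hull_baseline(values, spectrum.intensities)
    return Spectrum(spectrum.axis, spectrum.intensities - baseline)


def rubberband_baseline_set(sample_set: SampleSet) -> SampleSet:
    """Apply the rubber-band correction to every spectrum of a sample set."""
    corrected = np.vstack(
        [
            rubberband_baseline(Spectrum(sample_set.axis, row)).intensities
            for row in sample_set.spectra
        ]
    )
    return SampleSet(
        sample_set.points,
        corrected,
        sample_set.axis,
        sample_set.domain,
        order=sample_set.order,
        seed=sample_set.seed,
    )


def pca_reduce(
    sample_set: SampleSet, n_components: int = DEFAULT_N_COMPONENTS
) -> ReducedSampleSet:
    """Mean-centred PCA scores of the sample spectra.

    The effective number of components is ``min(n_components, n_points - 1,
    n_features)``.  Components follow a deterministic sign convention: the
    loading element of largest magnitude is made positive, so repeated fits on
    the same data produce identical scores.
    """
    n_s = sample_set.n_points
    if n_s < 2:
        raise ValueError("insufficient samples: PCA needs at least 2 spectra")
    n_c = min(int(n_components), n_s - 1, sample_set.axis.n_features)
    pca = PCA(n_components=n_c, svd_solver="full")
    with np.errstate(invalid="ignore"):  # zero-variance data: ratio is 0/0
        scores = pca.fit_transform(sample_set.spectra)
    evr = np.nan_to_num(pca.explained_variance_ratio_, nan=0.0)
    loadings = pca.components_
    # Deterministic sign: largest-magnitude loading element positive.
    flip_idx = np.argmax(np.abs(loadings), axis=1)
    signs = np.sign(loadings[np.arange(n_c), flip_idx])
    signs[signs == 0] = 1.0
    return ReducedSampleSet(
        points=sample_set.points.copy(),
        scores=scores * signs,
        loadings=loadings * signs[:, None],
        explained_variance_ratio=evr,
        mean_spectrum=pca.mean_,
    )


def spectrum_snr(
    spectrum: Spectrum, signal_band: BandRestriction, quiet_band: BandRestriction
) -> float:
    """Mean |intensity| over the signal band / std over the quiet band."""
    signal = np.mean(np.abs(spectrum.intensities[signal_band.mask(spectrum.axis)]))
    noise = np.std(spectrum.intensities[quiet_band.mask(spectrum.axis)])
    if noise == 0.0:
        return float("inf")
    return float(signal / noise)


def noise_filter(
    sample_set: SampleSet,
    signal_band: BandRestriction,
    quiet_band: BandRestriction,
    snr_min: float,
) -> SampleSet:
    """Drop spectra whose SNR falls below ``snr_min``, preserving order.

    Spectra with zero variance in the quiet band are treated as noiseless
    (SNR = +inf) and kept.  Both bands must overlap the axis and must not
    overlap each other.
    """
    if signal_band.overlaps(quiet_band):
        raise ValueError("signal and quiet bands must be disjoint")
    for band, name in ((signal_band, "signal"), (quiet_band, "quiet")):
        if not np.any(band.mask(sample_set.axis)):
            raise ValueError(f"empty band: {name} band does not overlap the axis")
    keep = [
        i
        for i in range(sample_set.n_points)
        if spectrum_snr(
            Spectrum(sample_set.axis, sample_set.spectra[i]), signal_band, quiet_band
        )
        >= snr_min
    ]
    return sample_set.subset(keep)
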
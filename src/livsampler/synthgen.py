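"""Seeded generators of synthetic ground-truth spectral maps.

Two families of maps emulate the experimental regimes the sampler is designed
for, without requiring any instrument data:

* ``two_component`` — an abiotic two-component sample (silicone grease plus
  marker ink on an otherwise bare substrate): two spatially offset deposits
  with a mixing zone, each component carrying a distinct set of IR peaks
  (diagnostic peaks at 798 cm^-1 and 1580 cm^-1 respectively).
* ``wormlike`` — a nematode-like specimen: an elongated body with a few
  internal compartments of differing biochemical composition (protein-,
  lipid- and carbohydrate-dominated bands) and smooth gradients between them.

Concentration fields are sums of anisotropic Gaussian blobs — the simplest
structure with tunable gradient steepness and mixing zones — and each pixel's
spectrum is the concentration-weighted sum of the component standards plus
optional white noise:  Y(x, y) = sum_c conc_c(x, y) * S_c + noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral_io import DomainRect, SpectralMap, Spectrum, WavenumberAxis

__all__ = [
    "Peak",
    "ComponentSpec",
    "GaussianBlob",
    "ConcentrationField",
    "FieldSpec",
    "component_spectrum",
    "generate_map",
    "default_axis",
    "two_component_map",
    "wormlike_map",
    "PRESETS",
]


def default_axis(low: float = 650.0, high: float = 4000.0, step: float = 4.0) -> WavenumberAxis:
    """Mid-IR axis: 650-4000 cm^-1 at 4 cm^-1 spectral resolution by default."""
    return WavenumberAxis(np.arange(low, high + step / 2, step))


@dataclass(frozen=True)
class Peak:
    """One vibrational band: center (cm^-1), width (cm^-1), height (a.u.)."""

    center: float
    width: float
    height: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("peak width and height must be positive")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError("peak shape must be 'gaussian' or 'lorentzian'")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        d = wavenumbers - self.center
        if self.shape == "gaussian":
            return self.height * np.exp(-0.5 * (d / self.width) ** 2)
        return self.height * self.width**2 / (d**2 + self.width**2)


@dataclass(frozen=True)
class ComponentSpec:
    """A chemical component: its name and the peaks of its standard spectrum."""

    name: str
    peaks: tuple[Peak, ...]

    def validate_against(self, axis: WavenumberAxis) -> None:
        lo = min(axis.values[0], axis.values[-1])
        hi = max(axis.values[0], axis.values[-1])
        for p in self.peaks:
            if not lo <= p.center <= hi:
                raise ValueError(
                    f"peak center {p.center} outside axis [{lo}, {hi}] "
                    f"for component {self.name!r}"
                )


def component_spectrum(spec: ComponentSpec, axis: WavenumberAxis) -> Spectrum:
    """The component's standard spectrum: the sum of its peak profiles."""
    spec.validate_against(axis)
    total = np.zeros(axis.n_features)
    for peak in spec.peaks:
        total += peak.profile(axis.values)
    return Spectrum(axis, total)


@dataclass(frozen=True)
class GaussianBlob:
    """Anisotropic 2D (super-)Gaussian deposit: center (um), 2x2 covariance, amplitude.

    ``exponent = 1`` is an ordinary Gaussian; larger exponents give a
    flat-topped profile with steep margins, emulating a physical deposit of
    roughly uniform thickness (a grease smear, an ink stroke, a specimen
    body) rather than a diffuse cloud.
    """

    center: tuple[float, float]
    cov: tuple[tuple[float, float], tuple[float, float]]
    amplitude: float = 1.0
    exponent: float = 1.0

    def evaluate(self, xy: np.ndarray) -> np.ndarray:
        cov = np.asarray(self.cov, dtype=float)
        inv = np.linalg.inv(cov)
        d = xy - np.asarray(self.center, dtype=float)
        quad = np.einsum("ni,ij,nj->n", d, inv, d)
        return self.amplitude * np.exp(-0.5 * quad**self.exponent)


@dataclass(frozen=True)
class ConcentrationField:
    """Non-negative 2D concentration field: a sum of Gaussian blobs."""

    blobs: tuple[GaussianBlob, ...]

    def evaluate(self, xy: np.ndarray) -> np.ndarray:
        out = np.zeros(xy.shape[0])
        for blob in self.blobs:
            out += blob.evaluate(xy)
        return out


@dataclass(frozen=True)
class FieldSpec:
    """One concentration field per component, plus the additive noise level."""

    fields: tuple[ConcentrationField, ...]
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def generate_map(
    fields: FieldSpec,
    components: list[ComponentSpec],
    axis: WavenumberAxis,
    grid_shape: tuple[int, int],
    step: float,
    seed: int = 0,
) -> SpectralMap:
    """Raster map whose spectra are concentration-weighted component sums.

    ``grid_shape`` is (rows, cols); grid points sit at cell centers of a
    raster with the given step in um, so the domain is
    [0, cols*step) x [0, rows*step).  White Gaussian noise of standard
    deviation ``noise_sd`` (absorbance units) is added independently to every
    spectral channel; the same seed always produces a bit-identical map.
    """
    if len(fields.fields) != len(components):
        raise ValueError("one concentration field per component is required")
    rows, cols = grid_shape
    if rows < 1 or cols < 1:
        raise ValueError("grid_shape must be positive")
    x_coords = (np.arange(cols) + 0.5) * step
    y_coords = (np.arange(rows) + 0.5) * step
    xx, yy = np.meshgrid(x_coords, y_coords)
    xy = np.column_stack([xx.ravel(), yy.ravel()])
    standards = np.vstack(
        [component_spectrum(c, axis).intensities for c in components]
    )
    conc = np.column_stack([f.evaluate(xy) for f in fields.fields])
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    spectra = conc @ standards
    if fields.noise_sd > 0:
        rng = np.random.default_rng(seed)
        spectra = spectra + rng.normal(0.0, fields.noise_sd, spectra.shape)
    domain = DomainRect(0.0, cols * step, 0.0, rows * step)
    return SpectralMap(x_coords, y_coords, axis, spectra, domain=domain)


# --- presets -----------------------------------------------------------------

GREASE = ComponentSpec(
    "grease",
    peaks=(
        Peak(798.0, 14.0, 0.9),     # nu(Si-O-Si) symmetric stretch (silica filler)
        Peak(1262.0, 12.0, 0.6),    # Si-CH3 deformation
        Peak(2962.0, 18.0, 0.5),    # nu(C-H)
    ),
)

INK = ComponentSpec(
    "ink",
    peaks=(
        Peak(1580.0, 16.0, 1.0),    # conjugated nu(-C=C-) ring stretch
        Peak(1370.0, 14.0, 0.45),
        Peak(3050.0, 20.0, 0.35),   # aromatic nu(=C-H)
    ),
)

PROTEIN = ComponentSpec(
    "protein",
    peaks=(Peak(1655.0, 20.0, 1.0), Peak(1545.0, 18.0, 0.7), Peak(3290.0, 60.0, 0.5)),
)
LIPID = ComponentSpec(
    "lipid",
    peaks=(Peak(2925.0, 20.0, 1.0), Peak(2854.0, 15.0, 0.7), Peak(1740.0, 12.0, 0.5)),
)
CARBOHYDRATE = ComponentSpec(
    "carbohydrate",
    peaks=(Peak(1045.0, 30.0, 0.9), Peak(1150.0, 18.0, 0.5)),
)


def _rotated_cov(
    sigma_par: float, sigma_perp: float, theta: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    cov = rot @ np.diag([sigma_par**2, sigma_perp**2]) @ rot.T
    return ((cov[0, 0], cov[0, 1]), (cov[1, 0], cov[1, 1]))


def two_component_map(
    rows: int = 30,
    cols: int = 30,
    step: float = 1.5,
    noise_sd: float = 0.001,
    seed: int = 0,
    axis: WavenumberAxis | None = None,
    sharpness: float = 1.0,
    jitter: float = 1.0,
) -> SpectralMap:
    """Abiotic two-component sample: an ink stroke and a grease smear.

    The ink deposit is a stroke — a chain of flat-topped elongated blobs
    along a randomly oriented line — and the grease deposit a broader
    elongated smear placed beside it, close enough that the margins of the
    two deposits overlap in a mixing zone.  Deposits occupy a minority of the
    map (roughly 15-20% of pixels carry appreciable signal), the rest being
    bare-substrate background, as is typical when a mapped region is chosen
    with little prior knowledge of where the sample sits.

    Geometry is jittered reproducibly by ``seed`` (``jitter`` in um scales
    the positional scatter) so a collection of seeds forms distinct test
    cases.  ``sharpness`` scales the inverse cross-section of the deposits:
    larger values give steeper concentration gradients.  At the defaults the
    stroke half-width is two raster steps, so the map itself resolves every
    gradient while coarse uniform subgrids do not.
    """
    if axis is None:
        axis = default_axis()
    rng = np.random.default_rng(seed)
    w, h = cols * step, rows * step
    scale = min(w, h) / 45.0
    s_par = 8.0 * scale / sharpness       # stroke segment length scale (um)
    s_perp = 3.0 * scale / sharpness      # stroke half-width scale (um)
    theta = rng.uniform(0, np.pi)
    cx = w * rng.uniform(0.35, 0.65)
    cy = h * rng.uniform(0.35, 0.65)
    u = np.array([np.cos(theta), np.sin(theta)])
    stroke_body = tuple(
        GaussianBlob(
            tuple(np.array([cx, cy]) + t * u * 0.22 * w + rng.normal(0, jitter, 2)),
            _rotated_cov(s_par, s_perp, theta),
            0.8,
            exponent=2.0,
        )
        for t in (-1.0, -0.33, 0.33, 1.0)
    )
    # Thickness texture: resolvable-scale bumps along the stroke keep real
    # within-deposit gradients, as physical deposits are never uniformly thick.
    stroke_texture = tuple(
        GaussianBlob(
            tuple(
                np.array([cx, cy])
                + rng.uniform(-1.0, 1.0) * u * 0.22 * w
                + rng.normal(0, s_perp / 2, 2)
            ),
            _rotated_cov(rng.uniform(2.0, 3.0) * step, rng.uniform(1.5, 2.5) * step, theta),
            rng.uniform(0.2, 0.6),
        )
        for _ in range(5)
    )
    stroke = stroke_body + stroke_texture
    theta2 = theta + np.pi / 2 + rng.normal(0, 0.3)
    gx = cx + 0.28 * w * np.cos(theta2 + np.pi / 2) + rng.normal(0, 2 * jitter)
    gy = cy + 0.28 * h * np.sin(theta2 + np.pi / 2) + rng.normal(0, 2 * jitter)
    gx = float(np.clip(gx, 0.2 * w, 0.8 * w))
    gy = float(np.clip(gy, 0.2 * h, 0.8 * h))
    u2 = np.array([np.cos(theta2), np.sin(theta2)])
    smear_body = (
        GaussianBlob((gx, gy), _rotated_cov(7.0 * scale / sharpness, 1.6 * s_perp, theta2), 0.7, exponent=2.0),
        GaussianBlob(
            (gx + 4 * scale * np.cos(theta2), gy + 4 * scale * np.sin(theta2)),
            _rotated_cov(5.0 * scale / sharpness, 1.2 * s_perp, theta2),
            0.5,
            exponent=2.0,
        ),
    )
    smear_texture = tuple(
        GaussianBlob(
            tuple(
                np.array([gx, gy])
                + rng.uniform(-1.0, 1.0) * u2 * 6.0 * scale
                + rng.normal(0, s_perp, 2)
            ),
            _rotated_cov(rng.uniform(2.0, 3.0) * step, rng.uniform(1.5, 2.5) * step, theta2),
            rng.uniform(0.15, 0.5),
        )
        for _ in range(4)
    )
    smear = smear_body + smear_texture
    fields = FieldSpec(
        (ConcentrationField(smear), ConcentrationField(stroke)), noise_sd=noise_sd
    )
    return generate_map(fields, [GREASE, INK], axis, (rows, cols), step, seed=seed)


def wormlike_map(
    rows: int = 40,
    cols: int = 80,
    step: float = 1.5,
    noise_sd: float = 0.001,
    seed: int = 0,
    axis: WavenumberAxis | None = None,
) -> SpectralMap:
    """Elongated body with 2-3 internal compartments of differing composition.

    The body is a chain of overlapping anisotropic blobs elongated along x
    (protein background everywhere in the body); lipid- and
    carbohydrate-dominated compartments sit at reproducibly jittered
    positions along the body axis, giving smooth multi-compartment
    spatiochemical gradients.
    """
    if axis is None:
        axis = default_axis()
    rng = np.random.default_rng(seed)
    w, h = cols * step, rows * step
    body_y = 0.5 * h + rng.normal(0, 0.05 * h)
    seg_sx, seg_sy = w / 8.0, h / 7.0
    body = tuple(
        GaussianBlob(
            (x_frac * w, body_y + rng.normal(0, 0.04 * h)),
            ((seg_sx**2, 0.0), (0.0, seg_sy**2)),
            1.0,
        )
        for x_frac in (0.2, 0.4, 0.6, 0.8)
    )
    lipid = ConcentrationField(
        (
            GaussianBlob(
                (0.3 * w + rng.normal(0, 0.03 * w), body_y),
                ((0.2 * seg_sx**2, 0.0), (0.0, 0.5 * seg_sy**2)),
                0.8,
            ),
        )
    )
    carb = ConcentrationField(
        (
            GaussianBlob(
                (0.7 * w + rng.normal(0, 0.03 * w), body_y),
                ((0.25 * seg_sx**2, 0.0), (0.0, 0.5 * seg_sy**2)),
                0.7,
            ),
        )
    )
    fields = FieldSpec(
        (ConcentrationField(body), lipid, carb), noise_sd=noise_sd
    )
    return generate_map(
        fields, [PROTEIN, LIPID, CARBOHYDRATE], axis, (rows, cols), step, seed=seed
    )


PRESETS = {
    "two_component": two_component_map,
    "wormlike": wormlike_map,
}
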
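"""Data model and file I/O for spectral maps and acquired sample sets.

The central containers are :class:`SpectralMap` (a rectangular raster of IR
absorbance spectra that serves as the simulation "ground truth") and
:class:`SampleSet` (an ordered collection of continuously-positioned sample
points with their spectra, as produced by an acquisition run).  Positions are
continuous micrometre coordinates inside a half-open rectangular domain; grid
points of a map are cell-representative positions inside that rectangle.

On-disk format is a long-format delimited text file with the header
``x_um,y_um,wavenumber_cm1,absorbance`` (a ``SampleSet`` adds an ``order``
column); an HDF5 container with datasets ``/positions``, ``/axis`` and
``/spectra`` is supported as an alternative for large maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberAxis",
    "Spectrum",
    "DomainRect",
    "SpectralMap",
    "SampleSet",
    "read_spectral_map",
    "write_spectral_map",
    "read_sample_set",
    "write_sample_set",
    "nearest_grid_spectrum",
]

_CSV_COLUMNS = ["x_um", "y_um", "wavenumber_cm1", "absorbance"]


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly monotone axis of wavenumbers in cm^-1 (length ``n_features >= 2``)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("bad axis: need a 1-D axis with at least 2 wavenumbers")
        diffs = np.diff(values)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("bad axis: wavenumbers must be strictly monotone")
        object.__setattr__(self, "values", values)

    @property
    def n_features(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n_features

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:
        return hash(self.values.tobytes())

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the axis entry closest to ``wavenumber`` (ties -> lower index)."""
        return int(np.argmin(np.abs(self.values - wavenumber)))


@dataclass(frozen=True)
class Spectrum:
    """A single absorbance spectrum on a shared wavenumber axis."""

    axis: WavenumberAxis
    intensities: np.ndarray

    def __post_init__(self) -> None:
        intens = np.asarray(self.intensities, dtype=float)
        if intens.shape != (self.axis.n_features,):
            raise ValueError("intensities length must match axis")
        if not np.all(np.isfinite(intens)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "intensities", intens)


@dataclass(frozen=True)
class DomainRect:
    """Half-open rectangular map domain [x_min, x_max) x [y_min, y_max) in um."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("domain rectangle must have positive extent")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.x_max, self.y_min, self.y_max)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized membership test for an (n, 2) array of points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (
            (pts[:, 0] >= self.x_min)
            & (pts[:, 0] < self.x_max)
            & (pts[:, 1] >= self.y_min)
            & (pts[:, 1] < self.y_max)
        )

    def contains_point(self, x: float, y: float) -> bool:
        return bool(self.contains(np.array([[x, y]]))[0])


class SpectralMap:
    """Rectangular raster of spectra: grid positions, one spectrum per point.

    Grid points are stored in row-major order (rows vary along y, columns
    along x), so point ``i = row * n_cols + col``.  All spectra share one
    :class:`WavenumberAxis`.  The domain rectangle defaults to the raster
    footprint padded by half a step on every side so that each grid point is
    the representative of its raster cell.
    """

    def __init__(
        self,
        x_coords: np.ndarray,
        y_coords: np.ndarray,
        axis: WavenumberAxis,
        spectra: np.ndarray,
        domain: DomainRect | None = None,
    ) -> None:
        x_coords = np.asarray(x_coords, dtype=float)
        y_coords = np.asarray(y_coords, dtype=float)
        if x_coords.ndim != 1 or y_coords.ndim != 1:
            raise ValueError("x_coords and y_coords must be 1-D")
        if np.any(np.diff(x_coords) <= 0) or np.any(np.diff(y_coords) <= 0):
            raise ValueError("grid coordinates must be strictly increasing")
        spectra = np.asarray(spectra, dtype=float)
        n_rows, n_cols = y_coords.size, x_coords.size
        if spectra.shape != (n_rows * n_cols, axis.n_features):
            raise ValueError(
                f"spectra must have shape ({n_rows * n_cols}, {axis.n_features})"
            )
        self.x_coords = x_coords
        self.y_coords = y_coords
        self.axis = axis
        self.spectra = spectra
        if domain is None:
            step_x = float(np.mean(np.diff(x_coords))) if n_cols > 1 else 1.0
            step_y = float(np.mean(np.diff(y_coords))) if n_rows > 1 else 1.0
            domain = DomainRect(
                x_coords[0] - step_x / 2,
                x_coords[-1] + step_x / 2,
                y_coords[0] - step_y / 2,
                y_coords[-1] + step_y / 2,
            )
        if not np.all(domain.contains(self.positions)):
            raise ValueError("every grid point must lie inside the domain")
        self.domain = domain

    @property
    def n_rows(self) -> int:
        return self.y_coords.size

    @property
    def n_cols(self) -> int:
        return self.x_coords.size

    @property
    def n_points(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def positions(self) -> np.ndarray:
        """(n_points, 2) array of grid positions in row-major order."""
        xx, yy = np.meshgrid(self.x_coords, self.y_coords)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def spectrum_at(self, index: int) -> Spectrum:
        return Spectrum(self.axis, self.spectra[index])

    def __repr__(self) -> str:
        return (
            f"SpectralMap({self.n_rows}x{self.n_cols} grid, "
            f"{self.axis.n_features} wavenumbers)"
        )


@dataclass
class SampleSet:
    """Ordered acquired points with their spectra.

    ``points`` is an (n, 2) array in acquisition order; ``spectra`` is
    (n, n_features) on the shared ``axis``.  ``order`` records the acquisition
    index of each row and ``seed`` the RNG seed of the run that produced it
    (``None`` for externally assembled sets).
    """

    points: np.ndarray
    spectra: np.ndarray
    axis: WavenumberAxis
    domain: DomainRect
    order: np.ndarray = field(default=None)  # type: ignore[assignment]
    seed: int | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.spectra = np.asarray(self.spectra, dtype=float)
        n = self.points.shape[0]
        if self.spectra.shape != (n, self.axis.n_features):
            raise ValueError("spectra shape must be (n_points, n_features)")
        if self.order is None:
            self.order = np.arange(n)
        else:
            self.order = np.asarray(self.order, dtype=int)
            if self.order.shape != (n,):
                raise ValueError("order must have one entry per point")
        if n and not np.all(self.domain.contains(self.points)):
            raise ValueError("all sample points must lie inside the domain")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def __len__(self) -> int:
        return self.n_points

    def __iter__(self) -> Iterator[tuple[np.ndarray, Spectrum]]:
        for i in range(self.n_points):
            yield self.points[i], Spectrum(self.axis, self.spectra[i])

    def subset(self, indices: Sequence[int] | np.ndarray) -> "SampleSet":
        idx = np.asarray(indices, dtype=int)
        return SampleSet(
            self.points[idx],
            self.spectra[idx],
            self.axis,
            self.domain,
            order=self.order[idx],
            seed=self.seed,
        )


def nearest_grid_spectrum(spectral_map: SpectralMap, point: tuple[float, float]) -> Spectrum:
    """Spectrum of the grid point spatially closest to ``point``.

    This is the lookup a simulated instrument uses to serve spectra for
    continuously positioned sample requests.  Ties in Euclidean distance are
    broken by the lowest row-major grid index, which makes the lookup
    deterministic.
    """
    x, y = float(point[0]), float(point[1])
    if not spectral_map.domain.contains_point(x, y):
        raise ValueError(f"out of domain: point ({x}, {y})")
    pos = spectral_map.positions
    d2 = (pos[:, 0] - x) ** 2 + (pos[:, 1] - y) ** 2
    return spectral_map.spectrum_at(int(np.argmin(d2)))


def _float_fmt(value: float) -> str:
    return np.format_float_scientific(value, unique=True)


def write_spectral_map(spectral_map: SpectralMap, path: str | Path) -> None:
    """Write a map in long format; values round-trip bit-exactly."""
    _write_long(
        Path(path),
        spectral_map.positions,
        spectral_map.axis,
        spectral_map.spectra,
        order=None,
    )


def write_sample_set(sample_set: SampleSet, path: str | Path) -> None:
    _write_long(
        Path(path),
        sample_set.points,
        sample_set.axis,
        sample_set.spectra,
        order=sample_set.order,
    )


def _write_long(
    path: Path,
    positions: np.ndarray,
    axis: WavenumberAxis,
    spectra: np.ndarray,
    order: np.ndarray | None,
) -> None:
    columns = list(_CSV_COLUMNS)
    if order is not None:
        columns.append("order")
    with open(path, "w") as fh:
        fh.write(",".join(columns) + "\n")
        for i, (x, y) in enumerate(positions):
            xs, ys = _float_fmt(x), _float_fmt(y)
            tail = f",{order[i]}" if order is not None else ""
            for wn, ab in zip(axis.values, spectra[i]):
                fh.write(f"{xs},{ys},{_float_fmt(wn)},{_float_fmt(ab)}{tail}\n")


def read_spectral_map(path: str | Path) -> SpectralMap:
    """Read a long-format map file, inferring the raster from unique x/y values.

    Raises ``ValueError("ragged grid")`` if any raster cell is missing and
    ``ValueError("bad axis")`` if the wavenumber axis is not strictly monotone.
    """
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        return _read_map_hdf5(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    x_coords = np.unique(df["x_um"].to_numpy())
    y_coords = np.unique(df["y_um"].to_numpy())
    # Take the axis from whichever grid cell appears first in the file.
    axis_values = df.loc[
        (df["x_um"] == df["x_um"].iloc[0]) & (df["y_um"] == df["y_um"].iloc[0]),
        "wavenumber_cm1",
    ].to_numpy()
    axis = WavenumberAxis(axis_values)
    n_rows, n_cols, n_f = y_coords.size, x_coords.size, axis.n_features
    if len(df) != n_rows * n_cols * n_f:
        raise ValueError("ragged grid: some raster cells are missing or duplicated")
    # Scatter rows into row-major grid order, keeping the first cell's axis order.
    col_idx = np.searchsorted(x_coords, df["x_um"].to_numpy())
    row_idx = np.searchsorted(y_coords, df["y_um"].to_numpy())
    axis_sort = np.argsort(axis.values)
    band_idx = axis_sort[
        np.minimum(
            np.searchsorted(axis.values[axis_sort], df["wavenumber_cm1"].to_numpy()),
            n_f - 1,
        )
    ]
    spectra = np.full((n_rows * n_cols, n_f), np.nan)
    spectra[row_idx * n_cols + col_idx, band_idx] = df["absorbance"].to_numpy()
    if np.any(np.isnan(spectra)):
        raise ValueError("ragged grid: some raster cells are missing or duplicated")
    return SpectralMap(x_coords, y_coords, axis, spectra)


def read_sample_set(path: str | Path) -> SampleSet:
    """Read a long-format sample-set file (requires an ``order`` column)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = set(_CSV_COLUMNS) | {"order"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    groups = df.groupby("order", sort=True)
    points, spectra = [], []
    axis: WavenumberAxis | None = None
    for _, g in groups:
        wn = g["wavenumber_cm1"].to_numpy()
        if axis is None:
            axis = WavenumberAxis(wn)
        elif not np.array_equal(wn, axis.values):
            raise ValueError("mixed axes: all spectra must share one axis")
        points.append([g["x_um"].iloc[0], g["y_um"].iloc[0]])
        spectra.append(g["absorbance"].to_numpy())
    assert axis is not None
    points_arr = np.asarray(points)
    pad_x = 0.5 * max(np.ptp(points_arr[:, 0]), 1.0)
    pad_y = 0.5 * max(np.ptp(points_arr[:, 1]), 1.0)
    domain = DomainRect(
        points_arr[:, 0].min() - pad_x,
        points_arr[:, 0].max() + pad_x,
        points_arr[:, 1].min() - pad_y,
        points_arr[:, 1].max() + pad_y,
    )
    return SampleSet(
        points_arr,
        np.asarray(spectra),
        axis,
        domain,
        order=np.sort(df["order"].unique()),
    )


def write_spectral_map_hdf5(spectral_map: SpectralMap, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("positions", data=spectral_map.positions)
        fh.create_dataset("axis", data=spectral_map.axis.values)
        fh.create_dataset("spectra", data=spectral_map.spectra)
        fh.attrs["n_rows"] = spectral_map.n_rows
        fh.attrs["n_cols"] = spectral_map.n_cols
        fh.attrs["domain"] = spectral_map.domain.bounds


def _read_map_hdf5(path: Path) -> SpectralMap:
    import h5py

    with h5py.File(path, "r") as fh:
        positions = fh["positions"][:]
        axis = WavenumberAxis(fh["axis"][:])
        spectra = fh["spectra"][:]
        bounds = fh.attrs.get("domain")
    x_coords = np.unique(positions[:, 0])
    y_coords = np.unique(positions[:, 1])
    if x_coords.size * y_coords.size != positions.shape[0]:
        raise ValueError("ragged grid: positions do not form a full raster")
    domain = DomainRect(*bounds) if bounds is not None else None
    return SpectralMap(x_coords, y_coords, axis, spectra, domain=domain)
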
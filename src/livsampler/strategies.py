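"""Sampling strategies and the autonomous acquisition loop.

Four strategies are provided:

* **UG** — uniform grid: a static, pre-defined rectangular grid measured in
  row-major raster order.
* **UR** — uniform random: points drawn i.i.d. uniformly over the domain.
* **LUR** — least unexplored region: each new point is drawn uniformly from
  the largest boundary-clipped Voronoi cell of the points measured so far
  (pure exploration).
* **LIV** — linear interpolation + Voronoi: each new point is drawn uniformly
  from the Voronoi cell of the point with the highest regularized
  leave-one-out error (exploration regularized exploitation).

The adaptive strategies start from a small scan of randomly distributed
points, then alternate measure / preprocess / model / select until the point
budget is exhausted.  Every adaptive iteration appends a record to an audit
log, which makes a run bit-reproducible from its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator, Protocol

import numpy as np

from .preprocess import (
    DEFAULT_N_COMPONENTS,
    BandRestriction,
    pca_reduce,
    restrict_band,
    rubberband_baseline,
)
from .spectral_io import (
    DomainRect,
    SampleSet,
    SpectralMap,
    Spectrum,
    WavenumberAxis,
    nearest_grid_spectrum,
)
from .surrogate import (
    ErrorTable,
    VoronoiPartition,
    loo_errors,
    voronoi_partition,
)

__all__ = [
    "Instrument",
    "SimulatedInstrument",
    "AcquisitionConfig",
    "AcquisitionError",
    "uniform_grid_points",
    "subgrids",
    "uniform_random_points",
    "lur_next_point",
    "liv_next_point",
    "run_acquisition",
    "acquisition_stream",
]

STRATEGIES = ("UG", "UR", "LUR", "LIV")

_REJECTION_CAP = 10_000


class Instrument(Protocol):
    """Abstract measurement backend: a stage position in, a spectrum out."""

    @property
    def domain(self) -> DomainRect: ...

    def measure(self, point: tuple[float, float]) -> Spectrum: ...


class SimulatedInstrument:
    """Instrument that serves spectra from a ground-truth map.

    A measurement request at a continuous position returns the spectrum of
    the spatially closest grid point, so repeated measurements of the same
    position are identical.
    """

    def __init__(self, spectral_map: SpectralMap):
        self._map = spectral_map

    @property
    def domain(self) -> DomainRect:
        return self._map.domain

    @property
    def axis(self) -> WavenumberAxis:
        return self._map.axis

    def measure(self, point: tuple[float, float]) -> Spectrum:
        return nearest_grid_spectrum(self._map, point)


@dataclass
class AcquisitionConfig:
    """Configuration of one acquisition run.

    ``budget`` is the stop criterion (total sampled points, 500 by default to
    match a practical scanning-session allowance); ``n_init`` the number of
    initial randomly distributed points for the adaptive strategies; ``band``
    an optional spectral restriction applied before baseline correction and
    PCA; ``n_components`` the PCA dimensionality the sampler operates in;
    ``k`` the grid subsampling factor used only by simulation benchmarks.
    """

    strategy: str = "LIV"
    budget: int = 500
    n_init: int = 10
    seed: int = 0
    band: BandRestriction | None = None
    n_components: int = DEFAULT_N_COMPONENTS
    baseline: bool = True
    k: int = 1

    def __post_init__(self) -> None:
        self.strategy = self.strategy.upper()
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; use one of {STRATEGIES}")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if self.strategy in ("LUR", "LIV") and not self.budget >= self.n_init >= 3:
            raise ValueError("adaptive strategies need budget >= n_init >= 3")
        if self.k < 1:
            raise ValueError("k must be >= 1")


class AcquisitionError(RuntimeError):
    """Instrument failure mid-run; carries the partial sample set."""

    def __init__(self, message: str, partial: SampleSet):
        super().__init__(message)
        self.partial = partial


def uniform_grid_points(domain: DomainRect, budget: int) -> np.ndarray:
    """Cell-centred r x c grid with r*c <= budget, maximizing the point count.

    Among factorizations with the maximal count, the grid whose aspect ratio
    (cols/rows) is closest to the domain's width/height ratio is chosen.
    Points are returned in row-major raster order.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    target = domain.width / domain.height
    best: tuple[int, float, int] | None = None  # (-count, aspect mismatch, rows)
    for rows in range(1, budget + 1):
        cols = budget // rows
        if cols < 1:
            break
        key = (-(rows * cols), abs(np.log((cols / rows) / target)), rows)
        if best is None or key < best:
            best = key
    assert best is not None
    rows = best[2]
    cols = (-best[0]) // rows
    xs = domain.x_min + (np.arange(cols) + 0.5) * domain.width / cols
    ys = domain.y_min + (np.arange(rows) + 0.5) * domain.height / rows
    xx, yy = np.meshgrid(xs, ys)
    return np.column_stack([xx.ravel(), yy.ravel()])


def subgrids(spectral_map: SpectralMap, k: int) -> list[np.ndarray]:
    """All k^2 offset subgrids of a map's raster (every k-th row and column).

    Each subgrid keeps rows ``dy::k`` and columns ``dx::k`` for one offset
    pair (dy, dx), giving roughly 1/k^2 of the original points.  Returned as
    (m, 2) position arrays, offsets enumerated row-major.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(spectral_map.n_rows, spectral_map.n_cols):
        raise ValueError("k exceeds grid: subgrid would be empty")
    out = []
    for dy in range(k):
        for dx in range(k):
            xs = spectral_map.x_coords[dx::k]
            ys = spectral_map.y_coords[dy::k]
            xx, yy = np.meshgrid(xs, ys)
            out.append(np.column_stack([xx.ravel(), yy.ravel()]))
    return out


def subgrid_indices(spectral_map: SpectralMap, k: int) -> list[np.ndarray]:
    """Row-major grid indices of each offset subgrid (companion to `subgrids`)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(spectral_map.n_rows, spectral_map.n_cols):
        raise ValueError("k exceeds grid: subgrid would be empty")
    n_cols = spectral_map.n_cols
    out = []
    for dy in range(k):
        for dx in range(k):
            rows = np.arange(dy, spectral_map.n_rows, k)
            cols = np.arange(dx, n_cols, k)
            out.append((rows[:, None] * n_cols + cols[None, :]).ravel())
    return out


def uniform_random_points(
    domain: DomainRect, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """n i.i.d. uniform points in the domain rectangle (seed-reproducible)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pts = rng.random((n, 2))
    pts[:, 0] = domain.x_min + pts[:, 0] * domain.width
    pts[:, 1] = domain.y_min + pts[:, 1] * domain.height
    return pts


def _random_point_in_cell(
    partition: VoronoiPartition, owner: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform point inside one clipped Voronoi cell.

    Rejection sampling from the cell polygon's bounding box, with membership
    decided by the nearest-owner test (which is exact for Voronoi cells and
    avoids polygon point-location).  After a fixed trial cap the cell centroid
    is returned so that selection always terminates.
    """
    cell = partition.cells[owner]
    lo = cell.min(axis=0)
    hi = cell.max(axis=0)
    pts = partition.points
    for _ in range(_REJECTION_CAP):
        cand = lo + rng.random(2) * (hi - lo)
        if not partition.domain.contains_point(cand[0], cand[1]):
            continue
        d2 = np.sum((pts - cand) ** 2, axis=1)
        if int(np.argmin(d2)) == owner:
            return cand
    return cell.mean(axis=0)


def lur_next_point(
    points: np.ndarray,
    domain: DomainRect,
    seed: int | np.random.Generator,
    partition: VoronoiPartition | None = None,
) -> np.ndarray:
    """Uniform-random point inside the largest clipped Voronoi cell.

    "Most sparsely sampled region" is operationalized as the existing point
    whose clipped Voronoi cell has maximal area; ties go to the lowest point
    index.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if partition is None:
        partition = voronoi_partition(points, domain)
    owner = int(np.argmax(partition.areas))
    return _random_point_in_cell(partition, owner, rng)


def liv_next_point(
    error_table: ErrorTable,
    partition: VoronoiPartition,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Uniform-random point inside the cell with maximal regularized LOO error.

    The owner is ``argmax eps_LIV`` with ties broken by the lowest point
    index, so the next sample lands in the region whose current model is most
    uncertain (large leave-one-out error and/or large unexplored area).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if error_table.eps_liv.shape[0] != partition.n_points:
        raise ValueError("error table and partition are not aligned")
    owner = int(np.argmax(error_table.eps_liv))
    return _random_point_in_cell(partition, owner, rng)


def _preprocess_scores(
    axis: WavenumberAxis,
    points: np.ndarray,
    spectra: np.ndarray,
    domain: DomainRect,
    config: AcquisitionConfig,
    cache: dict[int, np.ndarray],
) -> np.ndarray:
    """Band-restrict + baseline-correct every spectrum, then PCA scores.

    Baseline-corrected spectra are cached per acquisition index: the raw
    spectrum of a measured point never changes, so the correction is computed
    once.  PCA is refit on all spectra acquired so far at every iteration.
    """
    processed = []
    for i in range(spectra.shape[0]):
        if i not in cache:
            spec = Spectrum(axis, spectra[i])
            if config.band is not None:
                spec = restrict_band(spec, config.band)
            if config.baseline:
                spec = rubberband_baseline(spec)
            cache[i] = spec.intensities
        processed.append(cache[i])
    proc_axis = axis
    if config.band is not None:
        proc_axis = WavenumberAxis(axis.values[config.band.mask(axis)])
    working = SampleSet(points, np.vstack(processed), proc_axis, domain)
    return pca_reduce(working, config.n_components).scores


def acquisition_stream(
    instrument: Instrument, config: AcquisitionConfig
) -> Iterator[tuple[np.ndarray, Spectrum, dict | None]]:
    """Lazily yield (point, spectrum, audit_record) acquisition steps.

    The audit record is ``None`` for pre-planned points (UG, UR and the
    initial random scan) and a dict for each adaptive selection.  Consuming
    the stream incrementally lets a benchmark stop a strategy as soon as its
    model reaches a target without running the full budget.
    """
    domain = instrument.domain
    rng = np.random.default_rng(config.seed)

    if config.strategy == "UG":
        for pt in uniform_grid_points(domain, config.budget):
            yield pt, instrument.measure(pt), None
        return
    if config.strategy == "UR":
        for pt in uniform_random_points(domain, config.budget, rng):
            yield pt, instrument.measure(pt), None
        return

    n_init = min(config.n_init, config.budget)
    points: list[np.ndarray] = []
    spectra: list[np.ndarray] = []
    axis: WavenumberAxis | None = None
    for pt in uniform_random_points(domain, n_init, rng):
        spec = instrument.measure(pt)
        axis = spec.axis
        points.append(pt)
        spectra.append(spec.intensities)
        yield pt, spec, None

    cache: dict[int, np.ndarray] = {}
    iteration = 0
    while len(points) < config.budget:
        iteration += 1
        pts = np.asarray(points)
        partition = voronoi_partition(pts, domain)
        record: dict = {
            "iteration": iteration,
            "n_points": len(points),
            "areas": partition.areas.tolist(),
        }
        if config.strategy == "LUR":
            nxt = lur_next_point(pts, domain, rng, partition=partition)
            record["owner"] = int(np.argmax(partition.areas))
        else:  # LIV
            assert axis is not None
            scores = _preprocess_scores(
                axis, pts, np.asarray(spectra), domain, config, cache
            )
            try:
                eps = loo_errors(pts, scores, domain)
            except ValueError:
                # Too few / degenerate points for LOO: fall back to areas only.
                eps = np.zeros(len(points))
            table = ErrorTable.from_errors(eps, partition.areas)
            nxt = liv_next_point(table, partition, rng)
            record.update(table.to_dict())
            record["owner"] = int(np.argmax(table.eps_liv))
        record["next_point"] = [float(nxt[0]), float(nxt[1])]
        spec = instrument.measure((nxt[0], nxt[1]))
        points.append(nxt)
        spectra.append(spec.intensities)
        yield nxt, spec, record


def run_acquisition(
    instrument: Instrument,
    config: AcquisitionConfig,
    callback: Callable[[int, np.ndarray], None] | None = None,
) -> tuple[SampleSet, list[dict]]:
    """Run one full acquisition to the point budget.

    Returns the acquired :class:`SampleSet` (points in acquisition order) and
    the audit log, a list of per-iteration records.  An instrument failure
    raises :class:`AcquisitionError` carrying the partial sample set.
    """
    points: list[np.ndarray] = []
    spectra: list[np.ndarray] = []
    log: list[dict] = []
    axis: WavenumberAxis | None = None
    stream = acquisition_stream(instrument, config)
    while True:
        try:
            pt, spec, record = next(stream)
        except StopIteration:
            break
        except Exception as exc:
            partial_axis = axis if axis is not None else WavenumberAxis(np.array([0.0, 1.0]))
            partial = SampleSet(
                np.asarray(points).reshape(len(points), 2),
                np.asarray(spectra).reshape(len(points), partial_axis.n_features)
                if points
                else np.empty((0, partial_axis.n_features)),
                partial_axis,
                instrument.domain,
                seed=config.seed,
            )
            raise AcquisitionError(str(exc), partial) from exc
        axis = spec.axis
        points.append(pt)
        spectra.append(spec.intensities)
        if record is not None:
            log.append(record)
        if callback is not None:
            callback(len(points), pt)
    assert axis is not None
    sample_set = SampleSet(
        np.asarray(points), np.asarray(spectra), axis, instrument.domain, seed=config.seed
    )
    return sample_set, log
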
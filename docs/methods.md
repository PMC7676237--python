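# Methods

## The acquisition problem

Scanning hyperspectral microscopes (the motivating case is FTIR
spectromicroscopy of biological specimens) acquire one absorbance spectrum
per stage position. A full raster map at useful spatial resolution takes
minutes to hours, which forecloses many time-resolved experiments. The
premise of grid-less autonomous adaptive data acquisition is that most of a
mapped field is chemically bland, and that the informative regions — steep
spatiochemical gradients, interfaces, compartment boundaries — can be found
and resolved on the fly with far fewer measurements than a uniform grid
spends on them.

## The LIV strategy

LIV (barycentric **L**inear **I**nterpolation + **V**oronoi tessellation)
maintains, after every measurement, a cheap surrogate model of the mapped
field and a score for every measured point:

1. **Preprocessing.** All spectra acquired so far are band-restricted
   (optional, e.g. 900–3700 cm⁻¹), rubber-band baseline corrected (the lower
   convex hull of each spectrum is subtracted), and reduced by PCA to the
   first `n_c ≤ 5` score dimensions. PCA is refit from scratch each
   iteration — early in a run there are too few spectra to freeze a basis.
   Scores are raw (not whitened), so the L2 geometry of score space weights
   components by the spectral variance they carry.
2. **Surrogate.** A Delaunay triangulation of the sampled positions with
   barycentric (piecewise-linear) interpolation per score dimension, `U_0`.
   Outside the convex hull of the support the model returns the nearest
   support point's value, which keeps it defined on the whole rectangle.
3. **Leave-one-out errors.** For each sampled point `X_i` the model `U_{-i}`
   is rebuilt without it and evaluated at `X_i`:
   `eps_i = || U_0(X_i) − U_{-i}(X_i) ||_2 = || Y_i − U_{-i}(X_i) ||_2`.
4. **Voronoi regularization.** The domain-clipped Voronoi areas `V_i` of the
   sampled points measure local sampling sparsity. Both quantities are
   min–max normalized onto [0, 1] (`sigma(x) = (x − min)/(max − min)`; a
   constant vector maps to zeros, since a constant carries no ranking
   information) and summed:
   `eps_i^LIV = sigma(eps_i) + sigma(V_i)  in [0, 2]`.
5. **Selection.** The next measurement is a uniform-random draw inside the
   Voronoi cell of `argmax_i eps_i^LIV` (ties to the lowest index). Drawing
   is by rejection from the cell's bounding box with a nearest-owner
   membership test, capped at 10⁴ trials with a centroid fallback, so
   selection always terminates.

The loop starts from `n_init` (default 10) uniformly random points and stops
at the point budget (default 500). Model accuracy over a run is tracked by
the Voronoi-area-weighted mean LOO error
`<eps>_V = sum_i V_i eps_i / sum_i V_i`.

Baseline strategies: **UG** (cell-centred uniform grid, row-major raster
order), **UR** (i.i.d. uniform random points), and **LUR** (each new point
drawn uniformly from the largest clipped Voronoi cell — the sparsity term of
LIV alone). "Most sparsely sampled region" is operationalized as the largest
clipped cell.

## Numerical choices

* **Clipped Voronoi cells.** The point set is augmented with its mirror
  image across each domain edge before tessellating; the bisector between a
  point and its own reflection *is* the edge, and a reflected point is never
  closer than its original to any interior location, so every original
  point's cell comes out exactly clipped and finite. A Sutherland–Hodgman
  box clip handles the corner case of a point lying exactly on an edge.
  Areas always sum to the domain area (asserted to 10⁻⁶ relative).
* **Leave-one-out localization.** Removing an interior point of a Delaunay
  triangulation only re-triangulates its cavity, whose new triangles use the
  point's natural neighbours; `U_{-i}(X_i)` therefore needs only the 2-ring
  neighbourhood of `i`. A hull vertex falls outside the reduced hull by
  construction and its prediction is exactly the nearest remaining point's
  value. Ambiguous cases (local degeneracy, point outside the local hull)
  fall back to a literal full rebuild, so the localized computation is
  exact, and is verified against a brute-force rebuild oracle in the tests.
* **Degenerate supports.** Fewer than three or collinear support points
  raise on model construction; inside the LOO loop a degenerate *reduced*
  support uses the nearest-remaining-value fallback for that term.
* **PCA determinism.** Components follow a fixed sign convention (largest
  magnitude loading element positive), so reruns are bit-identical.
* **Reproducibility.** One `numpy` Generator seeded from the run
  configuration drives the initial scan and all in-cell draws; the audit log
  (one JSON record per adaptive iteration: areas, LOO errors, regularized
  errors, chosen point, `<eps>_V`) is bit-identical across reruns.

## Benchmark metrics

* **Ground-truth error** `eps_GT`: a strategy's sampled points (with spectra
  served by nearest-grid lookup from a full-resolution reference map) are
  interpolated and evaluated at every grid point of the map; the default
  `rmse` variant is `sqrt(mean_i ||U(X_i) − Y_i||²)`, and a `sum` variant
  (no division by N₀) is kept behind a flag — the two differ exactly by
  √N₀ on a fixed map, so strategy-to-strategy ratios are unaffected.
  `eps_GT` is always computed on the full (restricted) spectral
  representation for every strategy; LIV's internal PCA is used only for
  point selection, which keeps the comparison representation-identical.
* **Points-to-equal-error.** The uniform-grid baseline keeps every k-th row
  and column of the reference raster; its error, averaged over all k²
  offset subgrids (aggregation is configurable: mean or median), becomes the
  target. Each competing strategy grows its own sequence one point at a time
  until its interpolation first reaches the target; the summary statistic is
  the ratio `N_s(strategy)/N_s(UG)` and the fraction of replicates with
  ratio < 1.
* **On-target ratio (OTR).** Spectra of a noise-filtered full-resolution
  reference set (SNR = mean |signal-band intensity| / quiet-band standard
  deviation, both bands configurable) define per-peak thresholds: the mean
  intensity at each diagnostic wavenumber. A sampled spectrum is on-target
  if it reaches any threshold (inclusive OR, ≥ comparison), and
  OTR = N_on / N_total.

## The synthetic ground-truth generator

`synthgen` produces seeded raster maps whose spectra are concentration-
weighted sums of component standard spectra plus white Gaussian noise,
`Y(x,y) = Σ_c conc_c(x,y)·S_c + ε`. Standards are sums of Gaussian or
Lorentzian bands; concentration fields are sums of anisotropic
(super-)Gaussian blobs — the simplest structure with tunable gradient
steepness, plateaus and mixing zones.

Two presets emulate the experimental regimes the sampler targets:

* `two_component`: an abiotic test sample of an **ink stroke** (chain of
  flat-topped elongated blobs along a random line; diagnostic band
  1580 cm⁻¹) and a **grease smear** (broader elongated patch beside it;
  diagnostic band 798 cm⁻¹), with overlapping margins forming a mixing
  zone. Deposits cover ~20 % of the map — the regime where a uniform grid
  wastes most of its budget on bare substrate. Deposit thickness carries
  resolvable-scale texture bumps, since physical deposits are never
  uniformly thick; the default stroke half-width is two raster steps, so
  the reference map itself resolves every gradient it contains.
* `wormlike`: an elongated nematode-like body (protein background) with
  lipid- and carbohydrate-dominated internal compartments and smooth
  gradients between them.

Default axis: 650–4000 cm⁻¹ at 4 cm⁻¹ spacing, the standard mid-IR window
of a benchtop FTIR microscope. Default additive noise: 10⁻³ a.u. per
channel, typical of co-added-scan absorbance noise. Both are configurable.

What the generator deliberately does **not** model: Mie and scattering
baseline artifacts, atmospheric vapour lines, detector drift, aperture
averaging (each simulated measurement is a point sample, whereas a real
75 µm aperture averages a neighbourhood). Consequences for interpretation
are noted below.

## Standard evaluation conditions

The packaged evaluation (`reference_benchmark`, run by
`scripts/acceptance.py` and the test suite) uses 10 seeded `two_component`
maps on a 30×30 raster at 1.5 µm with the spectral axis decimated to
16 cm⁻¹ (210 channels — the comparison is spatial, and the decimation keeps
a 10-map × 20-replicate × 4-strategy evaluation inside a few CPU-minutes),
20 replicates per strategy per map, and grid subsampling factor k = 4. The
choice k = 4 makes the uniform-grid baseline ~56 of 900 points, honouring
the validity condition of nearest-grid simulated sampling (the subsample
must stay far below the reference resolution) while leaving the 6 µm grid
spacing too coarse for the ~3 µm deposit cross-sections. Under these
conditions LIV's median points-to-equal-error ratio against UG is below 1
and its outperforming fraction exceeds UR's by a wide margin.

Two caveats on what passing these conditions shows:

* With smooth isotropic features that a uniform grid resolves comfortably
  (or with targets near the additive-noise floor), no sampling strategy can
  beat a uniform grid materially — adaptive sampling pays off exactly when
  localized structure is under-resolved by the affordable grid. The
  generator's defaults encode that regime deliberately; maps outside it
  will, and should, show ratios near or above 1.
* The simulated OTR contrast (LIV ≈ 1.5–2× UG) is qualitatively, not
  numerically, comparable to an instrument experiment: a real aperture
  averages deposit margins into cores (raising margin spectra above
  threshold), and roughly a third of LIV's picks are exploration driven by
  the Voronoi term. The absolute OTR of a point-sampling simulation on a
  mostly-empty map is therefore intrinsically lower.

## Known limitations

* The nearest-grid spectral lookup attributes a grid spectrum to a
  continuous position; in steep-gradient regions this acts as irreducible
  value noise of order (gradient × step/2). Features at or below the
  reference raster's own resolution limit are therefore not meaningful
  benchmark content.
* Min–max normalization of the LOO errors is outlier-sensitive: one huge
  error squashes the scores of all other points for that iteration.
* The LOO-at-hull-vertex terms use the nearest-support fallback and do not
  vanish even for affine fields; `<eps>_V` consequently has a geometric
  floor on sloped data.
* Acquisition is strictly one point per iteration; batch selection and
  moving-stage cost models are out of scope.
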
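# Methods

`cellcompass` quantifies persistent single-cell migration from three
angles — trajectory statistics, morphodynamic (edge-velocity) maps, and
polarized-trafficking maps — and couples them to a minimal stochastic
model (the "cell compass") in which protrusion dynamics and an internal
polarity axis feed back on each other. This note documents the models,
the estimators, the calibrated constants and the design choices behind
them.

## Trajectory statistics

A track is a series of cell-centroid positions at a fixed frame
interval `dt` (5 min throughout, unless stated otherwise).

* **Step directions** are `atan2` headings of consecutive
  displacements. Zero-displacement steps produce *missing* headings
  rather than 0°, so a pausing cell cannot fake alignment.
* **Direction autocorrelation** is `AC(lag) = ⟨cos(θ(t+lag) − θ(t))⟩`
  with missing pairs skipped; `AC(0) = 1` by construction.
* **Persistence time τ** is the decay constant of a bounded nonlinear
  least-squares fit of `exp(−lag/τ)` to `AC`. The fit range is capped
  at ⅓ of the track duration and, additionally, at 3× the lag of the
  first 1/e crossing. The second cap matters for simulated tracks
  (83 h at 1000 frames): beyond a few decay times the curve is pure
  sampling noise, and fitting it inflates the per-cell τ spread by
  roughly a factor of two without changing the median. Curves that
  never decay below 1/e inside the range, or fits pinned at the upper
  bound (the track duration), are flagged *censored* and reported at
  the bound — this keeps the "superpersister" corner of the phase
  diagram well defined instead of extrapolating.
* **Directionality ratio** is net displacement over path length.
* **Axis–movement angle** is the signed angle (counterclockwise
  positive) between the nucleus→Golgi vector and the displacement
  vector, summarised by the circular mean and the circular standard
  deviation `sqrt(−2 ln r̄)`; a linear SD would overstate dispersion
  for angles near the ±180° seam.
* **Alignment index** is the mean resultant length
  `r = sqrt(⟨sin θ⟩² + ⟨cos θ⟩²)` of paired angle differences: 1 for
  perfect alignment, 0 for uniform dispersion. Note `r` is invariant
  to a *constant* angular offset; it measures dispersion, not bias.
* **Reorientation curves** wrap the angle between the nucleus→Golgi
  axis and a nucleus→target axis to `[0, 2π)`, unwrap it to a
  continuous curve, and report degrees; the cumulative fraction of
  cells whose |angle| has reached 30° gives the reorientation ECDF,
  normalised by *all* cells so non-reorienting cells keep the curve
  below 1.

## Morphodynamic maps

Each closed cell contour is resampled to `n = 100` markers equidistant
in arclength, counterclockwise, starting at the vertex with the
smallest angle from the +x axis about the centroid (a fixed, arbitrary
convention; the marker-matching step removes any residual dependence
on it). Markers of consecutive frames are paired by the circular shift
minimising the total squared displacement, searched exhaustively over
all `n` shifts with ties broken toward the smallest |shift|. The map
entry is the paired displacement magnitude divided by `dt`, signed by
the projection of the displacement on the outward normal (positive =
protrusion). Normals come from tangents of a 5-marker circular moving
average, which keeps the sign test stable on pixelated contours.
Per-frame matching shifts are composed so a map row follows the same
material point across the whole movie.

Per-column recentring rotates each column so the marker nearest a
reference direction (nucleus→Golgi axis, motion direction, …) sits on
the middle row; the shifts are stored and exactly invertible, and a
column with a missing reference is left in place and flagged. Units
are px/frame unless a pixel size and `dt` are supplied.

## Trafficking maps and the protrusion→secretion lag

The trafficking map samples mean fluorescence along the straight ray
from the Golgi centroid to each of the 100 contour markers (bilinear
interpolation at ⌈ray length⌉ points; samples inside the Golgi mask
are discarded so the organelle's own signal does not drown the vesicle
signal). Bleach correction is an affine per-frame rescaling to the
mean/SD of frame 0; since the lag estimate below is invariant to
per-frame affine intensity changes, the choice of correction scheme is
immaterial, and a pluggable hook is left for alternatives.

Protrusion and trafficking maps are cross-correlated row by row. Each
lag uses the Pearson correlation of the *overlapping* segments (means
and norms per lag): subtracting one global mean instead biases the
peak toward lag 0 by up to one frame on smooth maps, which is exactly
the scale of the effect being measured. Rows with no valid data are
dropped; the row-average gives the per-cell curve, with the sign
convention that a positive lag means protrusion precedes trafficking.
The peak is refined to sub-frame resolution by a parabola through the
maximum and its two neighbours; an edge maximum is returned unrefined
and flagged. Whether to average cross-covariances over rows or
correlate flattened maps is not determined by the procedure this
mirrors; per-row averaging was chosen (it weighs every contour sector
equally and is robust to a few dead rows).

## Segmentation and tracking

The segmentation pipeline is fixed: global threshold (Otsu, or a fixed
per-channel value) → binarise → clear border-touching structures →
remove small objects → morphological closing (disk, default radius
10 px) → fill holes → per-component centroids. Otsu is only reliable
when foreground occupies an appreciable histogram mass; on sparse,
noisy fields it splits the background, which is why a fixed threshold
override is exposed per channel. Tracking selects, each frame, the
centroid nearest the previous selection; empty frames carry the last
position forward with a gap flag. Stage-referenced coordinates are
restored as `corrected(t) = raw(t) + scale·(stage(t) − stage(0))`.
Interactive nucleus clicking is replaced by accepting external seed
points. Coordinates are 0-based pixel centres, x = column, y = row.

## The cell-compass model

State: a morphodynamic map on 100 contour markers over `t_tot = 1000`
frames of 5 min, and a polarity-axis marker `c_axis(t)`.

**Single protrusive event.** A space–time transfer function (edge
response to a point-like Cdc42 activation) sums four terms: a narrow
positive Gaussian (the protrusion, σ = 6 markers), a wide negative
Gaussian (lateral inhibition, σ = 22), a bilateral pair of narrow
Gaussians travelling at ±1 marker/frame (the wave), and a negative
Gaussian in time centred on 0 (central inhibition, σ = 15 markers);
the first three decay exponentially in time (4, 2 wait — see table
below). It is convolved circularly in space and causally in time with
a Cdc42 "puff" (spatial Gaussian σ = 5, temporal exponential
τ = 3 frames), truncated to 30 frames, forced to an exactly zero sum,
and scaled to peak speed 1. The zero sum (constant mean cell area) is
enforced by rescaling the lighter-signed part; subtracting the global
mean would smear a uniform offset over the whole contour and create
spurious background protrusion.

| parameter | value | units | fixed by |
|---|---|---|---|
| σ_narrow, σ_puff | 6, 5 | markers | footprint calibration |
| σ_wide, σ_mid | 22, 15 | markers | retraction must sit far from the core |
| A1, A2, A3, A4 | 0.25, 1, 0.08, 0.2 | – | shape calibration |
| τ_protrusion, τ_lateral, τ_wave, τ_puff | 5, 4, 2, 3 | frames | duration calibration |
| τ_central (Gaussian width) | 8 | frames | duration calibration |
| wave speed | 1 | markers/frame | – |

These numbers are **calibrated, not measured**: the constraints are
(i) the event footprint (|speed| above 10% of peak) lasts 10 ± 2
frames (50 min), matching isolated protrusion rounds in
low-persistence cells; (ii) the protrusive part spans ≲ 20 markers;
(iii) the inhibitory (retracting) mass sits far from the core. The
third constraint is mechanical: a cell that retracts exactly where it
just protruded has zero net centroid displacement per event.
Retraction concentrated beyond ~90° of contour from the protrusion —
i.e. at the cell rear — is both what migrating cells do and what lets
a single event actually displace the centroid.

**Nucleation (polarity → protrusions).** Each frame an event nucleates
with probability `p_nuc = 0.25`. With probability `p_polarized` its
centre is `round(Normal(c_axis, σ_c = 5)) mod 100`; otherwise uniform.
Events superpose linearly.

**Axis update (protrusions → polarity).**
`c_axis(t+1) = c_axis(t) + κ·g·F_prot(t) + (1 − κ)·F_basal(t)`.
`F_prot` sums the positive edge speeds weighted by the *sign* of the
shortest circular path from the axis to each marker: every protruding
portion pulls with a strength set by its speed, independently of its
distance. The literal scalar sum of speeds has no direction, so some
geometric reading is unavoidable; a speed-weighted *mean-offset*
(spring-like) variant is also implemented (`force_mode="centroid"`)
for sensitivity analysis. Retractions do not pull. The gain
`g = 0.3` converts the force to markers/frame; it is calibrated by
requiring that, at κ = 1, the axis reaches a pinned sustained
protrusion a quarter-contour away within one event duration (8 frames
at g = 0.3; g = 0.2 takes 13 and fails the bound; larger g only adds
overshoot).

**Basal axis drift.** `c_axis_natural` is an i.i.d. uniform sequence
on `[0, 10·n)` passed through a moving average of 60 frames;
`F_basal` is its discrete derivative. The window is calibrated so that the median time for the
free axis to span the full contour is ≈ 30–50 frames, inside the
48 ± 24-frame band implied by cells confined on round patterns
(reorientation in ~4 h). A much larger window makes the axis rotate
*steadily*; because the alignment index ignores constant offsets, a
steadily rotating axis paradoxically *raises* alignment at κ = 0, so
the diffusive (small-window) end of the calibration band is the
physically sensible choice.

**Trajectory.** The centroid step is the average marker velocity along
the radial directions, `(1/n)·Σ v_i(t)(cos θ_i, sin θ_i)`.

**Observables.** Persistence time (exponential AC fit as above, hours,
censored at the 83 h run length), protrusive unicity, and alignment
(`r` between axis direction `2π·c_axis/n` and motion headings) use the
same code paths as experimental data.

**Protrusive unicity.** A sliding 10-frame window is binarised at 70%
of the maximal protrusion speed and the 8-connected components
(circular in space) are counted; the index is the inverse of the mean
count over non-empty windows. The reference maximum is taken *per
window* by default: with events superposing, a map-global threshold
only passes rare chance superpositions and the index saturates near 1
everywhere, losing all sensitivity to the number of competing fronts.
The map-global variant remains available (`threshold_scope="map"`).

**Phase diagrams and inversion.** An 11 × 11 grid over
`(p_polarized, κ) ∈ [0, 1]²`, 20 realizations per node, seeds derived
deterministically from a base seed and the node/replicate indices.
`estimate_parameters` minimises
`Σ_obs ((sim − measured)/spread_obs)²` over the square, interpolating
each observable field bilinearly on a 201-point-per-axis mesh, with
`spread_obs` the across-grid standard deviation of that observable;
iso-contours of each observable at its measured value are returned for
the classic crossing-lines plot. Because the tables are Monte-Carlo
means, each field is first smoothed with a sub-node Gaussian filter
(σ = 0.6 grid cells, configurable, 0 = raw): where the objective
valley is shallow, the raw argmin rides node-level noise, and the
mild filter suppresses that jitter without displacing the broad
structure of the diagrams. Measured values outside the simulated
range clamp to the boundary and set an `extrapolated` flag; a missing
alignment (dispersed Golgi) drops that term and is recorded in
`used_observables`.

A caveat the inversion inherits from the model: along the valley where
the persistence transition happens, the three observable surfaces are
locally near-parallel, so for weakly-identifying observable triples
(e.g. those produced at `p_polarized ≈ 0.6, κ ≈ 0.5`) the κ estimate
is ill-conditioned — replicate-level noise of ±0.02 in alignment can
move it by ±0.1–0.3. The persistence-time fit-range cap above reduces
this but does not remove it; κ is simply much better determined near
the high-feedback corner than in the middle of the diagram.

## Synthetic data

The generators produce the statistical structure the analysis assumes,
with known ground truth; all are deterministic under a fixed seed.

* **Persistent random walk**: heading increments
  `Normal(0, sqrt(2·dt/τ))` at constant speed, whose direction
  autocorrelation is exactly `exp(−lag/τ)` — the recovery oracle for
  the τ estimator. `τ = ∞` gives a straight track.
* **Contour movies** displace each marker along the current outward
  normal by the prescribed map entry (explicit Euler; valid for steps
  small against the cell radius). Self-intersection truncates the
  movie with a warning. Rebuilding the map from the movie correlates
  > 0.9 with the truth on smooth maps; residual error comes from
  tangential marker slip during resampling.
* **Trafficking stacks** paint rays from a central Golgi to a circular
  contour with intensity `max(map[i, t − lag], 0)` plus Gaussian noise
  — only protrusive activity secretes. Truth rays, a Golgi mask, and
  the imposed lag are returned.
* **Blob images** place non-overlapping disks plus Gaussian noise for
  segmentation tests.

What the generators deliberately do **not** emulate: optics (PSF,
shot noise, shading), textured cell interiors, contour roughness at
pixel scale, multi-cell fields, and any feedback of the environment on
the cell. Tests passing on these fixtures therefore validate the
*estimators and bookkeeping* (signs, lags, pairings, units), not
robustness to real microscopy artefacts — thresholds in particular
will need per-dataset tuning on real images.

## Numerical notes and limitations

* The resampling start convention adds a 1e-9 epsilon before wrapping
  angles so a vertex at exactly 0° cannot flip to 2π through floating
  noise.
* Marker displacement magnitudes slightly overestimate pure radial
  motion when contours rotate sub-marker amounts between frames; the
  effect is common to all marker-pairing schemes.
* `match_contours` is O(n²) per frame pair (exhaustive by definition);
  at n = 100 this is negligible.
* The simulated cell is geometrically circular (markers keep fixed
  angular positions); shape change enters only through the map. This
  is the model's simplification, not a numerical shortcut.
* Simulated τ means are averaged with censored values at the bound;
  at the superpersister corner they are therefore lower bounds.
* The event-template amplitudes are constrained only up to the
  calibrations listed; other amplitude sets satisfying them would
  shift the phase diagrams quantitatively (the inversion results are
  stable at the ±0.1 parameter scale across base seeds).
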
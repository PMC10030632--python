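# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the tests demonstrate.

## Stimulus

The mapping stimulus is the binary contrast aperture of a bar
(3° × 14°) sweeping across a circular 7° field at 0.30°/s, rendered at
2 frames/s on a 101×101 pixel grid and averaged within each 2 s TR. Eight
sweeps run in a fixed canonical order — left→right, bottom→top, right→left,
top→bottom, then four diagonals at 45° spacing — with each diagonal sweep
traversing only half the field before being replaced by blank frames. The
published acquisition parameters (sweep speed, sweep count, run duration,
96 volumes per run) are mutually inconsistent by a few percent, so frames
are generated from the geometry and truncated (or blank-padded) to the
configured volume count. With the default speed, 96 volumes hold exactly
the four cardinal sweeps; `n_volumes=None` keeps the full 8-sweep movie
(192 volumes). The 101-pixel grid keeps overlap-integral errors below 1%
against a 201-pixel rendering (tested).

## pRF model and fitting

The forward model is linear: prediction = HRF ∗ Σ_pixels N(x, y, σ) ·
aperture(t). The HRF is a difference of two gammas with five parameters
(response delay 6 s, undershoot delay 16 s, dispersions 1 s, amplitude
ratio 1/6 — the standard double-gamma first pass), peak-normalized.
Amplitude and baseline are resolved per vertex by least squares with a
nonnegative gain.

Fitting stages: (1) brute-force grid search on data decimated by averaging
adjacent TR pairs; the grid spans x, y on an 11×11 lattice over ±1.25×
field radius and σ log-spaced over [0.1°, 6°] in 10 steps; (2) bounded
Powell refinement of (x, y, log σ) from the grid optimum (never worse than
its start by construction); (3) a bounded Powell search over the five HRF
parameters minimizing squared error averaged across vertices with pRF
parameters fixed; (4) a final per-vertex pRF refit with the HRF fixed.
Overlap time courses are cached so the HRF stage costs only convolutions.

Measured behavior: noiseless round trips recover (x, y, σ) to ~10⁻⁵; with
noise calibrated to R² ≈ 0.6, the median center error over 200 vertices is
≈0.16–0.21° and median σ error ≈19%. On pure noise the best-of-family fit
inflates R² by selection; with the full 192-volume protocol all null fits
stay below the 0.10 map threshold (max ≈ 0.06), while on a 96-volume run
roughly one in ten can exceed it — one reason map delineation thresholds at
0.10 rather than lower.

## Synthetic cortex

The generator is the package's ground-truth instrument. A flat strip is
parameterized by eccentricity E (log-spaced rows from 0.2° — a 0° apex
would collapse triangles — to the configured maximum) and a strip angle
p ∈ [−270°, 270°]: |p| ≤ 90 is V1, the next 90° on each side V2, the outer
90° V3, with the polar-angle map folding at each border so the reversal
structure matches real occipital cortex. Coordinates
u = s·ln((E+e0)/e0), v = s·(E/(E+e0))·G(p) make the area element equal
gain(θ)·(s/(E+e0))²·E dE dθ exactly, i.e. the mesh realizes the
Horton–Hoyt law (s = 17.3 mm, e0 = 0.75°) times the angular gain. Vertex
areas are barycentric thirds of triangle areas, accumulated within
visual-area compartments so border vertices carry only their own area's
share (a coarse-mesh correction that conserves total area and vanishes at
realistic densities). Pial and white areas are midgray × 1.2 and × 0.85.

The angular gain is 1 plus raised-cosine lobes (half-width 45°, a modeling
choice — the angular extent of the enlarged meridian representations is not
quantified in the literature) at the four meridians. Amplitudes are solved
in closed form so the ±25° wedge integrals reproduce any requested
HVA/VMA, under the constraint that the gain integrates to 360° (area
preserving); infeasible combinations (gain ≤ 0 somewhere) raise an error.

Default mesh density is 9000 vertices per hemisphere (~3100 in V1,
comparable to a native-resolution V1), with the angular step ≈3.2°.
Per-vertex pRF size follows σ = 0.5° + 0.25°·E; ground-truth maps carry
R² = 1.

Simulated "fitted" maps add wrapped Gaussian polar-angle noise (default SD
10°), 3% multiplicative eccentricity noise, and Beta(6, 4) R² values whose
median ≈ 0.6, matching the median variance explained of good retinotopy
data. BOLD simulation scales each vertex's prediction to unit SD and adds
Gaussian noise with SD √(1/R² − 1) for a target R². Motion traces are
step-like spikes (persistent level shifts, so each spike crosses the FD
threshold exactly once) over optional white diff-jitter.

Population variability is applied at the subject level, not in the mesh
law: a lognormal multiplier on the magnification constant (SD 0.10 in log
units; map area goes with its square, giving the ~0.2 coefficient of
variation and ~2-fold size range reported for real cohorts) plus an
independent per-hemisphere multiplier (SD 0.055, putting the left/right
area correlation near the ~0.75 seen in real data). Indices are area
ratios and are unaffected.

What the generator does **not** emulate: cortical folding (the mesh is
flat, so geodesics are exact up to the edge-graph metric), differing V1/V2/
V3 magnification (all three strips share the same law, so their areas are
equal by construction, unlike real V3 < V2 ≈ V1), nonlinear BOLD effects,
spatially correlated noise, and fixation instability. Passing tests
demonstrate the correctness of the measurement chain under the stated
noise model, not robustness to all properties of scanner data.

## Quality control

Framewise displacement is the sum of absolute framewise translation
differences plus rotation differences converted to arc length at a 50 mm
head radius. Rotations are accepted in degrees and converted with π/180
(the quotable closed form; a `rotation_units` flag handles traces already
in radians). Exceedances use a strict > 0.5 mm comparison.

## ROI delineation

On real data V1–V3 are hand-drawn at the polar-angle reversals; here the
substitute is automated: reversal ridges are vertices near a meridian that
are near-local minima of angular distance (3° slack keeps noisy ridges
contiguous) whose neighbors lie on one side of the meridian (fold
signature); V1 is the connected region between the vertical-meridian
ridges containing a smooth horizontal crossing, grown back over the cut
band. Against ground-truth labels the detected V1 differs by <5%
(noiseless) and ~13% of vertices (10° map noise), mostly at the borders.
Because border placement errors load directly on the vertical-meridian
wedges, the group pipeline defaults to ground-truth labels (the synthetic
analog of the hand-drawn ROIs) and treats detection as a validated,
optional mode; in detection mode the vertical wedge areas are biased low
at this mesh resolution and the indices should not be interpreted.

## Cortical magnification

The adaptive annulus takes, at each r in 1–7°, the smallest Δr such that
20% of the ROI's vertices (equal weight, read as ROI vertices since only
those carry in-map eccentricities) fall within r ± Δr; m(r) is their
summed area divided by π[(r+Δr)² − (r−Δr)²] × the hemifield fraction
(0.5 per hemisphere; curves from the two hemispheres are averaged).
Numerical choice: the ring boundary is placed midway between the k-th
included distance and the next distinct one, which is identical in the
continuous limit and removes a half-cell bias on discretized maps. Rings
clipped at 0° warn; group curves average subject curves rather than
pooling vertices.

## Wedge-ROIs

Meridian lines are traced from the cleaned angle map: the horizontal
meridian as the vertices of edges straddling it inside V1, the vertical
meridians as the fold ridge at the V1 border. Distance maps are
multi-source Dijkstra over the mesh edge graph with Euclidean weights
(within ~8% of true perpendicular distance on regular flat grids, exact
along edge directions; the overestimate affects iso-distances and
thresholds alike, so it largely cancels). Eccentricity bands are the 7
log-spaced intervals over [1°, 7°]; band membership uses the ground-truth
eccentricity (the analog of the template-denoised eccentricity used on
real data). Iso-angle distances are unweighted means over band vertices
within ±8° of the boundary angle with R² ≥ 0.10; missing bands are
interpolated linearly in log eccentricity; iso distances are made
nondecreasing across widths per band, which enforces monotone wedge
nesting exactly. Wedge areas sum all member vertices regardless of R².
Vertical-meridian wedges from the two hemispheres are summed before
computing indices.

Map cleaning is R²-weighted circular-mean smoothing over the one-ring
neighborhood (self included), iterated at most 10 times or until the
largest change is below 0.1°. It reduces 10° angular noise to <3° RMS and
leaves linear map regions unchanged, but rounds the fold ridges by a few
degrees (bounded, local, and side-preserving: smoothed angles never cross
a meridian). This stands in for the template-based field-sign optimization
used on real data, which is an external method.

Known systematic effects at the default density: angular grid quantization
shifts the ±8° selection window by up to half a column (~1.6°), and fold
rounding compresses the outermost angles; both effects are common to all
meridians and largely cancel in the indices. Measured end-to-end, injected
(HVA, VMA) = (80, 52) is recovered at ≈(81, 47) noiseless and the group
dissociation test recovers both indices within ±8 points with the VMA
difference at p < 10⁻⁹ and no spurious HVA difference.

## Statistics

The HVA/VMA indices use the ±25° wedges by default. Group means are
bootstrapped by resampling subjects (percentile intervals; 1000 replicates
for mean differences, 10,000 for the linear fits of area vs wedge width
with 16–84 percentile bands). Group comparisons use the pooled-variance
two-tailed t-test with df = n₁ + n₂ − 2, Cohen's d from the pooled SD, and
a t-based CI95 of the mean difference. The coefficient of variation uses
the sample SD (n − 1).

## Problem sizes

Default analyses use 9000-vertex hemispheres, 10 subjects per group, 96- or
192-volume time series, 200-vertex fitting benchmarks, and 10,000 Monte
Carlo replicates — sizes chosen so the whole suite exercises every stage at
full fidelity while a complete run stays in the minutes range on one CPU.
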
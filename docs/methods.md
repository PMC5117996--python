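# Methods

`msemstitch` reconstructs mosaics of multi-beam scanning electron
microscopy (mSEM) acquisitions.  An mSEM instrument images a specimen with
61 parallel electron beams, producing hexagonal multi-beam fields of view
(mFOVs) of 61 rectangular tiles each; the stage records an approximate
position for every tile, accurate only to the stage precision (about 2 µm,
i.e. ~200 px at 10 nm/px).  The pipeline estimates precise pairwise
translations between overlapping tiles, repairs estimates corrupted by
imaging artifacts, relaxes all tiles to a globally consistent placement,
composites them into one seamless image, and exports a tiled web-map
pyramid.

## Pairwise alignment

For every pair of tiles whose frames intersect at the stage-predicted
positions (with at least a 16×16 px intersection; smaller corner slivers
carry too little signal for correlation), the relative translation
p = x_i − x_j is estimated by Fourier phase correlation with a pure 2D
translation motion model.  The predicted overlap rectangle, expanded by a
search margin (default 150 px, chosen to exceed plausible stage error) and
clipped to each tile's frame, yields two equally sized windows.  The
inverse transform of the normalised cross-power spectrum gives a
correlation surface; the strongest N = 4 peaks within the search range are
taken, each peak's four periodic interpretations are disambiguated, and
every candidate shift is scored by the Pearson correlation of the overlap
pixels it implies.  The winning candidate defines p, and its Pearson
correlation, clipped to [0, 1], is the pair's quality coefficient R.  Ties
are broken by smaller shift magnitude, then lexicographically, so results
are deterministic.  Shifts are integer-valued: residuals are reported in
whole pixels, and a sub-pixel refinement flag is reserved but inactive.

Mean subtraction uses only valid pixels.  Zero-variance (blank) regions
return R = 0.  The candidate-verification step is what makes small
fractional overlaps workable: a 6% overlap contributes only a few percent
of the correlation surface's energy, but verification recovers the exact
shift as long as the true peak ranks among the interpreted candidates.

## Correction of unsatisfactory pairings

Topographic depressions shield secondary electrons and produce dark or
blurred tiles whose correlations are meaningless.  A pairing is rejected
when any of four criteria holds:

1. R < 0.5;
2. the initial residual r0 = (stage_i − stage_j) − p is longer than 300 px;
3. a component of the alignment adjustment exceeds the corresponding
   predicted overlap dimension (evaluated component-wise, the stricter
   deterministic reading of a scalar-ambiguous rule);
4. frames placed at relative offset p would no longer intersect.

Rejected pairs have their parameters replaced by R := 0.5 and p := the
centroid (component-wise mean) of the high-quality alignment vectors —
pairs with R > 0.9 that are themselves satisfactory — of the same overlap
type.  Overlap types group pairs by geometric relation: lateral intra-mFOV
neighbours (INTRA_1), the two diagonal-row intra relations (INTRA_2A,
INTRA_2B, split by horizontal sign so each type's vectors are tightly
clustered and the centroid is meaningful), and inter-mFOV pairs binned by
displacement direction into eight 45° sectors (INTER_0..7).

Two robustness rules guard the replacement.  Stage jitter can push a
pair's displacement across a direction-bin boundary, so the replacement
uses the centroid nearest the pair's stage-predicted offset among types of
the pair's own intra/inter character (mFOV membership is exact metadata,
and the distinct geometric relations within each character are hundreds of
pixels apart, far beyond stage error).  If even the nearest centroid lies
farther from the stage prediction than the 300 px residual cap — i.e. the
replacement would itself violate criterion 2 — the stage-predicted offset
is used instead.  For correctly labelled pairs both rules reduce to the
plain per-type table lookup.  Restricting the centroid estimate to
satisfactory pairs also makes the correction idempotent: re-running it
changes nothing.

## Global registration

Each tile is a point mass m, each overlapping pair a spring whose rest
configuration is reached when x_i − x_j = p_ij and whose stiffness is

    k_ij = k · R_ij^n ,

a power law that concentrates restoring force in well-imaged regions.  The
damped dynamics

    m ẍ + c ẋ + F_k = 0 ,   F_k(i) = Σ_j k_ij r_ij ,
    r_ij = (x_i − x_j) − p_ij

are integrated from the stage positions (velocities zero) with an adaptive
explicit Runge–Kutta 4(5) scheme.  Defaults: m = 1, k = 1, c = 0.25,
n = 5.  The centre tile of the first mFOV is anchored (its state
derivative is forced to zero), removing the global translation degeneracy;
each additional connected component, if any, receives its own anchor with
a warning.  The residual RMS is evaluated at checkpoints every 1 time
unit; integration stops when the RMS change falls below 10⁻⁶ px on two
consecutive intervals *and* the tile velocity RMS is below 10⁻⁴ px per
unit time, or at t_max = 10⁴ with a non-convergence warning.  The
velocity condition matters: RMS change alone is blind both to checkpoints
straddling an oscillation extremum of an underdamped mode and to slowly
drifting tiles whose springs are all weak (R = 0.3 gives k_ij ≈ 0.0024),
which can sit several pixels from equilibrium while barely moving the
global RMS.

The spring potential energy ½ Σ k_ij‖r_ij‖² is exactly half the weighted
least-squares objective Σ R^n‖(x_i − x_j) − p_ij‖², so the converged
relaxation must coincide with the sparse weighted LS solve; both solvers
(and an unweighted variant) are implemented, the LS path via the sparse
normal equations with one factorisation shared by x and y.  Agreement
within a small fraction of a pixel is enforced by the test suite, along
with energy dissipation at every checkpoint (tolerance 10⁻⁶ relative),
gauge equivariance under global translation, and the zero-stiffness limit
(all R = 0 leaves positions untouched).

With a damping ratio ζ = c/(2√(mk)) = 0.125 the system is underdamped for
stiff modes; the convergence time is set by the softest modes and grows
with mosaic extent.  A 549-tile grid converges in ~2000 time units
(seconds of wall time).

## Compositing and pyramid export

Registered tiles are blended with distance feathering: each tile carries a
weight map proportional to the distance to its nearest edge (strictly
positive inside, maximal at the centre), and each output pixel is
Σ w·I / Σ w over covering tiles.  This is a deliberate simplification of
published non-linear blending schemes; gain compensation is out of scope.
Placements are rounded to integer pixels, consistent with integer-shift
alignment.  The canvas is processed in chunks written to an on-disk store
(a directory of chunk arrays plus a JSON header), so peak memory is
O(chunk area) regardless of mosaic size.  Uncovered pixels take a
configurable background value (default 0; SEM voids are dark).

The pyramid partitions the full-resolution mosaic into 256×256 PNG tiles
(edges padded with background) and recursively groups 2×2 child tiles,
downsampling 512×512 → 256×256 by 2×2 block averaging until a level fits
in one tile.  Blocks straddling the valid-content boundary average only
their valid pixels, so the mean intensity over valid area is conserved to
within rounding across levels.  Tile files follow the path scheme
`(maxzoom−zoom)/y/y_x_(maxzoom−zoom).png`; a manifest JSON and a minimal
HTML stub accompany the tiles for any slippy-map viewer.

## Synthetic acquisitions

The generator produces ground-truth scenes and complete acquisitions so
every stage is testable without instrument data.

* **Scene**: band-limited Gaussian noise (autocorrelation length ≥ 4 px,
  σ = 3 px smoothing) plus a broadband fine-grain component emulating the
  shot-noise texture of SEM detection, optionally overlaid with concentric
  ring motifs evoking osteonal lamellae.  The fine grain is part of the
  scene — overlapping crops stay bit-identical — and is what anchors
  phase correlation at small fractional overlaps; a purely smooth texture
  has no energy at high frequencies and its whitened cross-power spectrum
  is dominated by noise.  Scenes are bit-reproducible from their seed.
* **Geometry**: hexagonal mFOVs with 5,6,7,8,9,8,7,6,5 tiles per row
  (61-tile default; 1/7/19/37 supported), horizontal and vertical pitch
  frame·(1 − overlap), overlap fraction within the instrument's 2.4–55%
  range (default 6%).  mFOVs sit on a grid with odd rows staggered by half
  a tile pitch so adjacent mFOVs interlock like the instrument's hexagonal
  tessellation; without the stagger, vertical adjacencies meet only in
  ~19×17 px corner slivers that no correlation method can align.  The
  emulation still leaves small uncovered notches at mFOV corners, unlike
  the seamless real tessellation; mosaic-vs-scene comparisons therefore
  mask to covered pixels.
* **Tile frame**: 322×280 px by default — a quarter of the instrument's
  1288×1120 — so full test acquisitions run in seconds; the full frame is
  a configuration choice.
* **Stage jitter**: iid integer-rounded Gaussian per tile (default
  σ = 15 px at quarter scale), plus an optional shared per-mFOV offset
  (default off) emulating correlated stage error.
* **Artifacts**: DARK scales intensities by (1 − strength) and adds
  detector noise (σ = 8·strength gray levels); BLUR convolves with a
  Gaussian of σ = 30·strength px, wide enough that a fully blurred tile's
  correlation against an untouched neighbour falls below the R = 0.5
  rejection threshold.

What passing tests on this data do **not** show: robustness to non-ideal
optics (lens distortion, rotation, scale error — the motion model is pure
translation), to per-tile independent detector noise (overlap pixels are
bit-identical by construction, so R = 1 exactly; real overlaps correlate
slightly below 1), to intensity gain differences between beams, and to
stage error correlated across tiles.  These reflect the limits of the
translation model itself, not just the generator.

## Numerical choices and degenerate inputs

* Correlation ties broken by shift magnitude then lexicographic order;
  candidate verification requires at least 256 valid overlap pixels.
* Integrator tolerances rtol = 10⁻⁸, atol = 10⁻⁹ — tight enough that the
  energy trace is monotone to 10⁻⁶ relative.
* Disconnected positive-weight graphs: the LS solvers raise (singular
  system, named component); the relaxation registers each component with
  its own anchor and logs a warning.
* Empty inputs: empty metadata yields an empty acquisition; empty pair
  lists yield empty tables; compositing an empty tile set is an error.
* Block averaging and blending are computed in float64 and rounded once at
  the uint8 boundary.

## Problem sizes used in the distributed checks

The bundled tests and the acceptance script run at reduced scale chosen to
exercise every code path with comfortable statistical margins: random
spring instances up to ~200 tiles, one 3×3-mFOV grid of 549 quarter-scale
tiles (~1150 pairs) for ground-truth recovery and for the artifact runs,
100 random shift pairs for correlation exactness, and mosaics up to
1000×700 px for pyramid conformance.
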
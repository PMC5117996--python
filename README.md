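# msemstitch

Stitching and web-map rendering of multi-beam scanning electron microscopy
(mSEM) mosaics.

mSEM instruments image macroscopic tissue samples at nanometre resolution
with 61 parallel beams, producing thousands of overlapping image tiles
grouped in hexagonal multi-beam fields of view (mFOVs).  The microscope
stage records each tile's position only to the stage precision (~2 µm,
hundreds of pixels at 10 nm/px), so the tiles must be registered before
the mosaic is usable.  `msemstitch` implements the full reconstruction
pipeline:

1. **Pairwise alignment** — for every overlapping tile pair (i, j), the
   translation **p**ᵢⱼ that best superimposes the shared content and a
   correlation coefficient Rᵢⱼ ∈ [0, 1] are estimated by Fourier phase
   correlation with multi-peak disambiguation.
2. **Correction** — pairings corrupted by imaging artifacts (dark or
   blurred regions where secondary-electron detection failed) are detected
   by four criteria (R < 0.5; initial residual ‖**r**₀‖ > 300 px;
   adjustment exceeding the predicted overlap; translation destroying the
   overlap) and reset to R = 0.5 with **p** taken from the centroid of
   high-quality (R > 0.9) alignments of the same overlap type.
3. **Global registration** — tiles become point masses connected by
   springs with stiffness kᵢⱼ = k·Rᵢⱼⁿ and rest configuration
   **r**ᵢⱼ = (**x**ᵢ − **x**ⱼ) − **p**ᵢⱼ = 0; the damped dynamics
   m**ẍ** + c**ẋ** + Σ kᵢⱼ**r**ᵢⱼ = 0 (m = 1, k = 1, c = 0.25, n = 5) are
   integrated with an adaptive Runge–Kutta scheme until the residual RMS
   settles (ΔRMS < 10⁻⁶ px), with one anchored tile fixing the gauge.
   Sparse weighted/unweighted least-squares solvers are provided as
   references — the spring equilibrium coincides with the weighted LS
   minimiser.
4. **Rendering** — distance-feathered blending composites the registered
   tiles into a chunked on-disk mosaic, exported as a web-map pyramid of
   256×256 PNG tiles under the path scheme
   `(maxzoom−zoom)/y/y_x_(maxzoom−zoom).png`.

A synthetic acquisition generator (`msemstitch.synthetic`) emulates the
instrument geometry — hexagonal 61-tile mFOVs, 2.4–55% overlaps, stage
jitter, dark/blur artifacts — with known ground truth, so the whole
pipeline is testable without instrument data.

## Worked example

Simulate one 61-tile mFOV with 15 px stage jitter and stitch it end to
end:

```python
from msemstitch import RunConfig, run_stitch
from msemstitch.synthetic import (
    AcquisitionSpec, SceneSpec, generate_scene, generate_acquisition,
    required_scene_size,
)

spec = AcquisitionSpec(mfov_grid=(1, 1), tiles_per_mfov=61,
                       jitter_sigma=15.0, seed=0)
scene = generate_scene(SceneSpec(size=required_scene_size(spec), seed=0))
acq = generate_acquisition(scene, spec, out_dir="demo/acq")

summary = run_stitch(RunConfig(out_dir="demo/run", solver="msd"),
                     tiles=acq.tiles, meta=acq.meta)
```

which prints (via `summary`):

```
n_tiles: 61
n_pairs: 122
n_corrected: 21
median_R: 1.0
rms_before: 26.75942460277115
rms_after: 0.222386815725233
reduction_pct: 99.16894021816073
converged: True
mosaic_dims: (2743, 2386)
```

Reading: the overlap graph has 122 pairs; every pair aligned exactly
(median R = 1.0 on noise-free synthetic overlaps); 21 pairs whose stage
error exceeded their narrow predicted overlap were conservatively reset by
the correction stage; relaxation shrank the residual RMS from 26.8 px (the
stage jitter) to 0.22 px, a 99.2% reduction.  The run directory contains
the pair tables, correction report, per-pair residuals, the RMS trace of
the relaxation, the chunked mosaic and the tiled pyramid
(`demo/run/pyramid/0/…` holds the full-resolution tiles plus
`manifest.json` and an HTML stub for any slippy-map viewer).

The same pipeline is scriptable from the shell:

```sh
msemstitch simulate --out demo/acq --seed 0
msemstitch run --tiles demo/acq --metadata demo/acq/metadata.csv \
    --solver msd --out demo/run
msemstitch compare-solvers --tiles demo/acq --metadata demo/acq/metadata.csv
```

`compare-solvers` runs unweighted LS, weighted LS and the mass-spring
relaxation on identical inputs and reports per-solver residual RMS and
pairwise position differences.

## Layout

```
src/msemstitch/
  model.py         tile/pair domain types, overlap graph, type taxonomy
  io.py            metadata, pair-table and position I/O
  pairwise.py      phase correlation and pair alignment
  correction.py    four-criteria rejection and centroid replacement
  registration.py  mass-spring-damper relaxation + sparse LS oracles
  render.py        feathered compositing, chunk store, tiled pyramid
  synthetic.py     ground-truth scenes, acquisitions, artifacts
  pipeline.py      end-to-end orchestration and solver comparison
  cli.py           `msemstitch` command-line interface
docs/methods.md    model, parameters, design choices, limitations
```

See `docs/methods.md` for the model details, parameter defaults and the
limits of what the synthetic benchmarks demonstrate.
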
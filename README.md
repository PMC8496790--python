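# ommap — cardiac optical-mapping analysis

`ommap` analyzes voltage-sensitive-dye movies of cardiac tissue: it turns a
fluorescence stack into local activation times (LAT), conduction-velocity
(CV) vector fields, and quantitative slow-conduction (SC) region statistics,
and provides the clustered mixed-model machinery needed when several
recordings come from each animal. It is aimed at electrophysiology groups
quantifying pro-arrhythmic substrate — for example comparing atrial tissue
from animals with a history of persistent atrial fibrillation against
controls under S1/S2 pacing.

Because raw animal recordings are rarely shareable, the package ships a
synthetic-movie generator: activation fronts are propagated through a
prescribed speed field by a fast-marching eikonal solver, each pixel gets an
action-potential-shaped trace, and drift plus noise are layered on top — so
every stage of the pipeline can be validated against known ground truth.

## Method

1. **Preprocess** — Gaussian spatial binning (kernel 3 or 5), zero-phase
   0–100 Hz band-pass, per-pixel drift correction and [0, 1] normalization,
   and an SNR mask removing low-quality pixels.
2. **Activation** — per-pixel LAT as the time of maximum dV/dt of the
   normalized trace (sub-frame parabolic refinement; a 50 %-crossing
   criterion is available).
3. **Velocity** — a local polynomial surface T(x, y) is fitted to the LAT
   map around each pixel and the velocity is the inverse gradient,
   v = ∇T/|∇T|², giving speed 1/|∇T| in m/s.
4. **Regions** — pixels with valid speed < 0.2 m/s are classified SC;
   4-connected components (no diagonals) are labeled; the outcomes are the
   percent of ROI pixels that are SC, the number of components larger than
   one pixel, and their areas (pixel count × 0.0289 mm² at the default
   0.17 mm pitch).
5. **Study statistics** — outcomes from animal × pacing-position × S1/S2
   designs are modeled with a linear mixed model (REML, random intercept per
   animal; class, train, position, class×train, class×position fixed
   effects — 9 predictor terms), with mean-centered marginal Wald contrasts,
   the intraclass correlation ICC, the design effect
   D_eff = 1 + (m − 1)·ICC, and the effective sample size n/D_eff.

## Worked example

```python
from ommap import SceneSpec, Patch, make_movie, run_pipeline, default_config

spec = SceneSpec(
    grid_rows=60, grid_cols=60, n_frames=600,
    patches=(Patch(kind="rect", speed_mps=0.1, r0=15, r1=45, c0=15, c1=45),),
    noise_sd=0.05, source="left", seed=42,
)
movie, truth = make_movie(spec)           # truth.sc_mask.mean() == 0.25
report = run_pipeline(movie, default_config()).report
print(f"percent_sc={report.percent_sc:.2f}  "
      f"n_components={report.n_components}  "
      f"mean_area_mm2={report.mean_area_mm2:.3f}")
```

prints

```
percent_sc=26.89  n_components=1  mean_area_mm2=27.975
```

A square patch conducting at 0.1 m/s covers 25 % of the 60 × 60 field; the
full pipeline classifies 26.9 % of the analyzable pixels as slow (< 0.2 m/s)
— the excess comes from smoothing at the patch border — and finds a single
connected slow region of 27.98 mm² (968 pixels × 0.0289 mm²).

The same stages are available from the shell:

```sh
ommap simulate --seed 1 --out runs/sim
ommap analyze runs/sim/movie.tif --out runs/analysis
ommap stats study_table.csv --out runs/stats
```

Each output directory archives the exact configuration and seed that
produced it.

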
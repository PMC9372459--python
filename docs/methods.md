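# Methods

## Polarity BCE loss and detection metrics

The per-sample loss is `Loss_PB(x, y) = f_p(z) · BCE(x, y)` where
`BCE(x, y) = −y log σ(x) − (1−y) log(1−σ(x))` is evaluated in log-sum-exp
form (`log(1+e^x) − x·y`), which is finite and accurate for any
representable logit — the naive `log(σ(x))` route overflows past |x| ≈ 37.
`z` is the probability assigned to the *true* class (`σ(x)` for positives,
`1−σ(x)` for negatives), and the penalty `f_p(z) = 2/(1+exp(−γ(z̄−z)))`
with `z̄ = 1−z` maps confidence to a factor in `(2/(1+e^γ), 2/(1+e^{−γ}))`:
1 at `z = 0.5`, → 2 for confident mistakes, → 0 for confident correct
predictions.  The slope γ defaults to 20, the operating value for this
detection task; it is dimensionless and trades penalty sharpness against
gradient smoothness.  The loss is pure scalar math plus `mean`/`sum`
batch reduction — integrating it into a detector's training loop (it
targets the class-probability and objectness terms; box regression is
untouched) is deliberately the caller's job, keeping the package free of
any deep-learning dependency.

Detection counts come from greedy one-to-one matching: predictions in
descending score order each claim the highest-IoU unmatched truth box at
IoU ≥ 0.5 (the standard threshold here).  Precision and recall are
reported as percentages rounded half-up to two decimals, F_β from the
textbook formula with β = 1 by default.

## Chromatic segmentation

Full-range BT.601 YCbCr is fixed as the colour convention (studio-range
would shift Cr and Cb almost equally, leaving the difference essentially
unchanged, but one convention must be chosen).  The offsets cancel in
`Cr − Cb`, leaving `0.6687·R − 0.0874·G − 0.5813·B`, clipped to [0, 255]:
strongly positive on orange, ≈0 on foliage, sky and grey bark.

Otsu's threshold maximizes the between-class variance on the 256-bin
histogram of the chroma map of the (5%-padded) box crop; ties break to the
smallest threshold.  The foreground rule is `floor(chroma) > t` so the
mask agrees exactly with the histogram classing — with float chroma, a
value like 8.07 inside bin 8 would otherwise land on the wrong side of a
threshold of 8, and those marginal background pixels then poison the depth
observations with far-background values.

Morphology order: opening (disk radius 1.5% of the larger crop side,
noise removal) → closing (radius 9% of the crop side) → hole filling →
single-component selection (largest overlap with the central third of the
crop, the fruit position a detector box implies; fallback largest area) →
convex completion.  The closing is the package's answer to branch
occluders: a bar across the fruit splits the thresholded mask in two, and
without bridging the component selection would discard half the fruit.
Its radius bridges a branch of roughly a fifth of the fruit width.  A
plausibility floor on the refined region's mean chroma (default 30)
rejects crops that contain no fruit at all: even deeply shadowed ripe
fruit exceeds ~35 while foliage and bark stay below ~25.

Convex completion computes the hull polygon of foreground pixel centers
and rasterizes by center-inclusion.  This makes the operator idempotent —
the hull of the output's centers is the same polygon — whereas
corner-based hull rasterizers grow a ring of pixels per application.

## Ordinary kriging depth restoration

Observed depths `Z(p)` at the valid fruit pixels `I_V` (inside the Otsu
region, depth > 0) are modelled as an intrinsically stationary field; each
missing pixel `s` of the completed region gets the best linear unbiased
estimate `Ẑ(s) = Σ λ_p Z(p)` with weights solving the variogram-based
saddle system under `Σ λ_p = 1`.  Ordinary (unknown-constant-mean)
kriging is the right variant: a fruit surface sits at an unknown range, so
the mean must be eliminated rather than assumed.

The variogram is estimated with the Matheron estimator over pixel-distance
bins (up to half the sampled diameter, pairs subsampled to `max_pairs`
with a seed), then fitted by pair-count-weighted least squares to an
exponential model `γ(h) = nugget + sill·(1 − e^{−h/range})` (spherical
available).  Degenerate tables fall back to a pure-sill model with range a
quarter of the region diameter, with a logged warning — for a constant
field the fill is exact regardless, because `Σλ = 1` reproduces constants.

For tractability on ~10⁴-pixel regions the production path kriges each
missing pixel from its 32 nearest observations, with the saddle systems
solved in batch; `krige_fill_dense` solves the whole system with every
observation and is the oracle route in tests (the two agree to 1e-6 mm
when the neighbourhood covers all observations).  Isotropy in pixel space
is assumed; missingness is encoded as exactly 0 mm, matching the stereo
sensor convention.

The benchmarking protocol zeroes ~50% of the fruit region under four
structured schemes — central vertical band, right half, pixel
checkerboard, central horizontal band — plus uniform random, and scores
restoration by mean absolute error (mm) and mean relative error (%).
On rendered ellipsoid depth fields all four schemes restore within 3%
mean relative error (checkerboard ~0.02%, bands ~0.3–1.6%): interleaved
missingness is easiest, contiguous blocks hardest, because extrapolation
distance grows.

## 3D localization

Pinhole model with intrinsics `fx, fy, u0, v0` (pixels; optionally derived
from focal length and pixel pitch): projection `u = fx·X/Z + u0`,
`v = fy·Y/Z + v0`, and back-projection `X = (u−u0)·Z/fx`,
`Y = (v−v0)·Z/fy` as its exact algebraic inverse.  Pixels are 0-based,
u = column, v = row, origin top-left; all distances in mm.

The silhouette's extreme points are back-projected at their restored
depths; `d_x = X_C − X_A`, `d_y = Y_D − Y_B`.  Two intrinsic biases of
this construction are quantified by the renderer: (a) tangent geometry
makes the recovered diameter `2r·sqrt(1 − (r/Z)²)` plus an inward pixel
quantization, under 1% low at Z ≥ 10·radius; (b) for off-axis fruit the
measurement is foreshortened by the cosine of the off-axis angle.  The
package therefore targets (and the generator renders) near-axis fruit,
which is exactly the harvesting scenario — the robot centres its target
before grasping.

`d_z` cannot be observed from a single view; it is predicted from the
calibrated quadratic `d_z = β₀ + β₁d_x² + β₂d_y² + β₃d_x + β₄d_y`.  The
packaged default coefficients are
(16.0728, 0.0028, 0.0018, 0.0264, 0.4133) mm-units, a caliper calibration
for mandarin-type fruit with ~4.5 mm residual scatter; `fit_dz_model`
refits the polynomial by OLS from any (d_x, d_y, d_z) table and reports
RMSE and R².

The centre `Q0` is the 2D box centre back-projected at its restored depth
(the segmented-region centroid is available as an option); if the centre
pixel falls outside the completed region the nearest region pixel's depth
is used, logged.  `d = ‖Q0‖`.  The 3D box places its front face at the
fruit surface depth `Z_q` and its back face at `Z_q + d_z`
(P1 = (X_q−d_x/2, Y_q+d_y/2, Z_q+d_z); P1–P4 back face counter-clockwise,
P5–P8 the same order on the front face).  Under perspective the projected
back face nests strictly inside the front face whenever the optical axis
passes through the box — the near-axis regime; a fully off-axis box's far
face shifts toward the principal point instead.

## Synthetic scenes

The renderer intersects each pixel ray analytically with axis-aligned
ellipsoids (semi-axes d_x/2, d_y/2, d_z/2), giving exact silhouettes,
z-buffers, bounding boxes and front-surface centre distances.  Ground
truth distance is defined to the front-surface point on the box-centre
ray — the same quantity the localizer estimates.  Defaults span the
acquisition envelope: fruit at 300–1500 mm, transverse diameters
55–90 mm, near-axis placement (≤ ~8°), three illumination modes
(well ≈ ×1.0, weak ≈ ×0.35, non-uniform = smooth bright-to-shadow
gradient ×0.55–1.3 with a saturated specular patch), leaf (disc) and
branch (bar) occluders carrying nearer depth, textured foliage
background at 2.2–4 m.

What it does *not* emulate: physically based shading (illumination is a
multiplicative field — in particular a hard half-fruit shadow step would
make the fruit's own chroma bimodal and defeat any global threshold, a
real failure mode of purely chromatic segmentation under extreme lighting),
canopy structure, stereo matching artefacts beyond zeroed pixels, motion
blur, or sensor noise.  Passing tests therefore demonstrate the geometric
and statistical machinery, not robustness to photometric extremes.

## Numerical choices and degenerate inputs

- Otsu ties → smallest threshold; constant chroma → degenerate-input error.
- Kriging needs ≥ 4 observations (configurable); the error names the count.
  Weight sums are checked to 1e-6 at runtime (solver precision is ~1e-12).
- Variogram fit failures and degenerate tables → logged fallback model.
- `estimate_dz` requires positive diameters and a positive result.
- OLS design rank is checked; collapsed dx/dy ranges are rejected.
- Per-box pipeline failures are logged and skipped; other boxes continue.
- All randomness flows through seeded `numpy` generators; rendering is
  byte-deterministic given the scene seed.

## Problem sizes used in validation

The end-to-end suite runs 50 rendered scenes at 640×480 with one fruit
each, rotating the four 50%-corruption schemes across seeds; restoration
properties use 3 scenes per scheme; oracle equivalence uses 12×12 grids
at 60% observation over 20 seeds.  These sizes make the whole suite run
in well under a minute on one core while covering the full acquisition
envelope.

## Known limitations

- One box = one fruit: no instance splitting inside a box.
- Diameters assume near-axis viewing; strongly off-axis fruit is
  foreshortened by cos θ and not corrected.
- The `d_z` polynomial is cultivar-specific; refit for other fruit.
- No lens-distortion handling; intrinsics are assumed calibrated.
- Kriging assumes isotropic, trend-free local behaviour; surfaces with a
  strong trend across a large contiguous hole restore with edge bias
  (visible as the bands-vs-checkerboard error gap).
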
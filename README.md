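# citrus3d

Detection-support losses, chromatic segmentation, kriging depth restoration
and pinhole 3D localization for orchard fruit-harvesting vision.

A harvesting robot needs more than a 2D bounding box around a mature citrus
fruit: it needs the fruit's transverse diameters `d_x`, `d_y`, the
depth-axis diameter `d_z`, the camera-frame centre `Q0 = (X_q, Y_q, Z_q)`,
the camera distance `d`, and an oriented grasp envelope (a 3D bounding
box).  Stereo depth on fruit surfaces is unreliable — specular highlights,
occluding leaves and branches, and sensor dropouts leave large holes encoded
as 0 mm — so the geometric pipeline must first recover a complete fruit
silhouette and a complete depth field.

`citrus3d` implements that pipeline as a small library plus CLI:

1. **Loss toolkit** — the polarity binary cross-entropy with logits,
   `Loss_PB(x, y) = f_p(z) · BCE(x, y)` with
   `f_p(z) = 2 / (1 + exp(−γ(z̄ − z)))`, `z` the predicted probability of
   the true class and `z̄ = 1 − z` (default γ = 20).  It inflates the loss
   of misclassified detector samples and deflates confident correct ones,
   for use on the class-probability and objectness terms of a one-stage
   detector.  Greedy IoU box matching and precision / recall / F_β
   arithmetic are included.
2. **Fruit segmentation** — the Cr−Cb chroma difference of full-range
   BT.601 YCbCr is bright on orange fruit and near zero on foliage;
   Otsu thresholding, morphological clean-up and convex-hull completion
   yield the full silhouette `I_C` even when the fruit is partly occluded,
   plus its extreme points A/B/C/D.
3. **Depth restoration** — ordinary kriging
   `Ẑ(s) = Σ λ_p(s) Z(p)`, `Σ λ_p = 1`, over the observed fruit-surface
   depths, with an exponential variogram fitted to the data; the best
   linear unbiased fill for every missing pixel inside `I_C`.
4. **3D localization** — back-project A/C and B/D at their restored depths
   to get `d_x = X_C − X_A`, `d_y = Y_D − Y_B`; estimate
   `d_z = β₀ + β₁d_x² + β₂d_y² + β₃d_x + β₄d_y` from a caliper-calibrated
   quadratic; back-project the box centre for `Q0`; report
   `d = ‖Q0‖` and the eight 3D box vertices with their image projections.
5. **Synthetic scenes** — an analytic renderer (ellipsoid fruit through the
   same pinhole model, three illumination modes, leaf/branch occluders,
   structured ~50% depth corruption) providing exact ground truth, so the
   whole pipeline is testable without captured data.

## Worked example

```bash
citrus3d simulate --seed 8 --out-dir scene/
citrus3d run --image scene/scene.png --depth scene/depth.png \
             --boxes scene/boxes.json --intrinsics scene/intrinsics.yaml \
             --out records.json
```

which prints `1 fruit(s) localized, 0 skipped`, and `records.json` holds
(abridged, this exact seed):

```json
{"dx_mm": 87.2, "dy_mm": 91.0, "dz_mm": 92.2,
 "Q0": [69.2, -19.5, 649.0], "d_mm": 653.0, ...}
```

against a rendered ground truth of diameters 89.6 × 93.7 × 86.3 mm at a
front-surface distance of 653.3 mm: the distance is recovered within a
millimetre and the transverse diameters within ~3 mm (`d_z` comes from the
calibration polynomial, whose own scatter is ~4.5 mm).  The same objects
are available in Python, including structured depth corruption and kriging
restoration in the loop:

```python
import citrus3d as c

cfg = c.sample_scene_config(seed=8)
rgb, depth, truth = c.render_scene(cfg)
depth = c.corrupt_depth(depth, truth, "checkerboard", 0.5, seed=8)
box = c.BBox2D(*truth.fruits[0].bbox)
records, skipped = c.run_pipeline_arrays(
    rgb, depth, [box], c.PipelineConfig(intrinsics=cfg.intrinsics))
print(records[0].localization.d, truth.fruits[0].d_true)
```

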
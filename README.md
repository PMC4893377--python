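# slitmosaic

Wide-field retinal mosaics from slit-lamp video.

The slit lamp is the ophthalmologist's everyday microscope, but video of the
retina taken through it is hard to use directly: only a narrow vertical slit
of the field is illuminated, illumination falls off toward the slit borders,
glare from the optical path occludes content, and the field of view of any
single frame is small. `slitmosaic` turns such a video into one large,
artifact-reduced fundus mosaic in four stages:

1. **Slit segmentation** — a gradient-boosted per-pixel classifier
   (200 rounds, shrinkage 0.1, row subsample 0.5, depth-3 trees, squared
   loss) over cheap features (RGB, CIELAB, HSV, optionally normalized x/y
   position, optionally a 3-scale x 4-direction Gabor bank) marks the
   viable, illuminated, glare-free content of each frame, which is
   downscaled 4x for speed and noise suppression.  The classic fixed color
   threshold *r − 0.7 g > 0* is included as a baseline.
2. **Pairwise registration** — frame-to-frame motion is modeled as a pure
   2-D translation.  Upright (orientation-free) blob features restricted to
   the segmented slit are matched between frame pairs and a translation is
   estimated by RANSAC (100 iterations, 3 px margin); a pair is kept only
   with at least 6 inlier correspondences.
3. **Bundle adjustment** — every accepted pair (i, j, Δ) contributes the
   constraints *x_i − x_j = Δx* and *y_i − y_j = Δy* to a sparse linear
   system *A x = b* (graph-SLAM form) solved by least squares with frame 0
   pinned at the origin.  Redundant long-range constraints remove the drift
   that plain frame-to-frame chaining accumulates.
4. **Feathering blending** — each frame's pixels are weighted by the
   Euclidean distance transform of its foreground mask, and the mosaic is
   the normalized weighted mean *I_m[p] = Σ_i w_i[p] I_i[p] / Σ_i w_i[p]*,
   so dim slit borders and small segmentation mistakes are outvoted by
   frames that see the same retinal location near their slit center.

Because no clinical slit-lamp recordings are publicly available, the package
ships a synthetic slit-lamp simulator (textured fundus, vessels, optic disc,
slit illumination with border falloff, glare blobs, sensor noise, and a
planted frame trajectory) that provides ground truth for every stage.

## Worked example

Run the full pipeline on a simulated 40-frame closed-loop scan:

```python
from slitmosaic.pipeline import PipelineConfig, run

result = run(PipelineConfig(simulate_preset="loop", n_frames=40, seed=1,
                            outdir="mosaic_out"))
print(result.report)
```

prints (elided):

```
{'n_frames': 40, 'n_registered_pairs': 780, 'n_accepted_pairs': 121,
 'n_placed_frames': 40, 'max_edge_residual_px': 0.651,
 'rms_edge_residual_px': 0.121, 'seam_gradient': 0.167,
 'coverage_px': 31346, 'fov_gain_vs_single_frame_pct': 426.6,
 'trajectory_rmse_px': 0.209, 'endpoint_drift_px': 0.089}
```

All 780 frame pairs were attempted, 121 passed the 6-inlier rule, all 40
frames were placed in one connected pose graph, and the recovered positions
deviate from the planted trajectory by 0.21 px RMS — the closed loop comes
back to its start within 0.09 px instead of accumulating drift.  The mosaic
covers about 5.3x the area of a single slit (the
`fov_gain_vs_single_frame_pct` line), and `mosaic_out/` now holds the
per-frame masks, the edge and position CSVs, the RGBA mosaic PNG and a run
log.

The same stages are scriptable from the shell:

```bash
slitmosaic simulate --preset sweep --n-frames 30 --out seq/
slitmosaic segment train --frames seq/frames --masks seq/masks --out model.joblib
slitmosaic segment predict --frames seq/frames --model model.joblib --out masks/
slitmosaic register --frames seq/frames --masks masks/ --out edges.csv
slitmosaic adjust --edges edges.csv --out positions.csv
slitmosaic blend --frames seq/frames --masks masks/ --positions positions.csv \
    --compositor feather --out mosaic.png
```

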
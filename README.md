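# spinefret

Quantitative image analysis for studies of GTPase signalling and actin
remodelling in dendritic spines: ratiometric FRET biosensor time courses
with drift, background and photobleaching correction; voxel-wise
F/G-actin fraction maps with membrane-proximal profiling; 2D
dendritic-spine morphometry and classification; cell-shape compactness;
and nested, cell-as-unit statistics. A synthetic-scene generator with
exact ground truth makes every stage testable without access to the
original microscopy data.

## Who this is for

Labs quantifying Raichu-type biosensor activity (e.g. RhoA reported by
a YPet/mTurquoise ratio) in time-lapse confocal stacks, dual-stain
F-actin/G-actin images (phalloidin / DNase I), or spine morphology in
dissociated neurons — and anyone who needs a tested reference
implementation of the associated corrections and statistics.

## The quantities it computes

* **FRET ratio** `R = F_A / F_D` pixel-wise, per-ROI over time, with
  linear photobleaching correction anchored on pre-treatment frames
  (`R'_t = R_t · a/(a + b·t)`), baseline normalisation, and responder
  calling (`mean post > 1 + 2σ̂_baseline`).
* **F-actin fraction** `FR = I_F/(I_F + I_G)` ∈ [0, 1] and ratio
  `R = I_F/I_G`, on a foreground from unimodal (background-symmetry /
  Rosin) thresholding; intensity profiles along lines perpendicular to
  the cell contour, outside → inside.
* **Spine geometry** — length (geodesic base-to-tip), neck width and
  head width in µm; the scale-free head-width/length shape parameter;
  classes by sequential rules (length > 4 µm → filopodium;
  length/neck < 2 → stubby; head > 0.75 µm → mushroom; else thin);
  log10 relative changes over time.
* **Compactness** — cell outline area over convex-hull area (0–1, 1 for
  rounded/convex cells).
* **Nested comparisons** — one-way ANOVA on per-cell means (cells as
  the statistical unit) with Newman–Keuls-style post-hoc tests and a
  permutation alternative, plus the naive spine-level test for
  comparison; Spearman correlation with permutation p-values.

See `docs/methods.md` for the models, estimators and their limits.

## Worked example

Render a synthetic FRET time-lapse with a known +30% ratio step in half
of the spine ROIs, degrade it with bleaching, stage drift and noise,
and run the full analysis chain:

```python
import numpy as np
from spinefret import synthcell, fretflow

spec = synthcell.SceneSpec(
    "fret_timelapse", shape=(200, 200), n_frames=12, baseline_frames=3,
    background_level=20.0, bleach_rate=(0.0, 0.02),   # acceptor bleaches
    drift_per_frame=(1.0, 0.0), poisson_scale=3.0, gaussian_sd=3.4,
    seed=1,
)
stack, labels, truth = synthcell.make_fret_scene(
    spec, n_rois=20, responder_fraction=0.5, step_amplitude=0.3
)
res = fretflow.fret_pipeline(stack, labels)

called = [r for r, flag in res["responders"].items() if flag]
steps = [np.nanmean(s.normalized[s.post])
         for s in res["series"] if s.roi_id in truth.responder_ids]
print("true responders:", list(truth.responder_ids))
print("called responders:", called)
m = res["bleach_model"]
print(f"recovered step: {np.mean(steps):.3f} (programmed 1.300)")
print(f"fitted ratio decay: {m.slope / m.intercept:+.4f}/frame (programmed -0.0200)")
```

Output:

```
true responders: [2, 3, 6, 7, 8, 9, 10, 11, 13, 14]
called responders: [2, 3, 6, 7, 8, 9, 10, 11, 13, 14]
recovered step: 1.300 (programmed 1.300)
fitted ratio decay: -0.0202/frame (programmed -0.0200)
```

The programmed step is recovered to 0.1% through 2%/frame bleaching,
11 px of cumulative drift and shot noise at SNR ≈ 15, and the fitted
slope matches the programmed ratio decay.

The same chain is scriptable from the shell:

```bash
spinefret simulate --spec scene.yaml --out-prefix demo
spinefret fret demo_stack.ome.tif demo_labels.tif \
    --treatment-frame 3 --out-csv demo_series.csv
spinefret actin stained.ome.tif --out-prefix actin
spinefret spines labels.tif shaft.tif --pixel-size 0.07 --out-csv spines.csv
spinefret stats nested observations.csv --out-json nested.json
```

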
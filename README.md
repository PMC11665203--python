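# pamvasc

Vessel morphometry and plaque quantification for photoacoustic microscopy
(PAM) angiograms and confocal fluorescence (CFM) frames, with a synthetic
phantom generator providing exact ground truth for every stage.

The analysis pipeline:

1. **Preprocess** — histogram equalization, background-level estimation
   (explicit ROI or automatic), optional maximum-amplitude projection of a
   raw 3-D scan via the analytic-signal envelope.
2. **Binarize** — three candidate vessel maps: a global threshold at
   1.1 × the mean background level (MAP1), and single-scale Hessian
   (Frangi-type) vesselness at a small (3 px) and a large (30 px) kernel
   scale (MAP2, MAP3), combined per pixel as
   `MAPult = (MAP1 AND MAP3) OR MAP2`.
3. **Morphometry** — topology-preserving skeletonization, segment graph
   split at branch points with spur pruning, per-segment length and
   distance-transform diameter, and vessel length density (mm/mm²) per
   diameter bin (0–10, 10–20, …, >50 µm). An edge-spread-function routine
   measures effective resolution (FWHM).
4. **Plaque quantification** — manual-annotation CSV ingest (authoritative)
   plus an automated difference-of-Gaussians bright-spot detector
   (surrogate, labeled `auto`).
5. **Statistics** — unpaired pooled-variance Student's t-tests per metric
   and diameter bin across groups, with a tidy CSV report (a Holm-adjusted
   column is emitted as a clearly labeled extension).

The **phantom** module generates branching-tree vessel scenes (known
centerlines, diameters 5–100+ µm, Gaussian PSF blur, additive noise,
hemorrhage disks), plaque spot images, and whole simulated cohorts with
per-bin effect multipliers — all deterministic per seed, with geometry and
noise on independent sub-streams.

## CLI

```bash
pamvasc phantom vessels --seed 1 --out out/            # synthetic angiogram + truth
pamvasc phantom plaques --n-plaques 25 --out out/      # synthetic CFM frame
pamvasc phantom cohort --n-per-group 5 --out study/    # two-group simulated study
pamvasc vesselmap --image out/vessels_seed1.tif --config configs/default.yaml --out maps/
pamvasc morpho    --image out/vessels_seed1.tif --out subject/
pamvasc plaque    --image out/plaques_seed0.tif --out detections.csv
pamvasc plaque    --annotations manual.csv --out ingested.csv
pamvasc study     --dir study/ --out report/
```

`configs/default.yaml` documents every parameter; defaults follow the
published workflow (threshold factor 1.1, kernel scales 3 and 30 px,
2 × 2 mm / 512 × 512 geometry), and parameters the publication leaves
unstated are marked `# paper-gap`.

## Library example

```python
import pamvasc as pv
from pamvasc import app

spec = pv.PhantomSpec(n_trees=4, capillary_fraction=0.2, seed=1)
image, truth = pv.generate_vessel_phantom(spec)

cfg = app.PipelineConfig()
maps, graph, vld = app.analyze_image(image, cfg)
print(vld.as_dict(), truth.true_vld())
```
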
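# fazkit

Semiautomated quantification of the **foveal avascular zone (FAZ)** on
3×3 mm en-face OCTA angiograms, for retina researchers working with
devices that export per-plexus en-face images but offer no built-in FAZ
measurement.

The FAZ is the capillary-free region at the center of the macula; its
area, per vascular plexus (superficial/intermediate/deep — SVP/IVP/DVP),
is a quantitative biomarker of macular microvascular change, e.g. across
cataract-surgery follow-up visits. `fazkit` implements two independent
measurement paths and the statistics to compare them:

* **Script path** — a deterministic morphological pipeline:
  8-bit → crop (127, 127, 512, 512) → resize to 270×270 (area-average) →
  Otsu binarization (vessels white) → skeletonize → dilate ×8 → erode ×4 →
  resize to 512×512 → wand flood-fill of the enclosed avascular region
  from (255, 255). The net dilate–erode margin closes the perifoveal
  capillary ring where terminal-loop flow signal fades.
* **ML path** — a trainable pixel classifier: 21 texture features per
  pixel (intensity + mean/median/variance/entropy over windows of radius
  1, 2, 4, 8, 16), a 100-tree random forest trained from a few labelled
  line strokes on one image, applied unchanged to the whole dataset; the
  FAZ is the central avascular component.

Pixel areas convert to mm² with the magnification-corrected scale
(modified Bennett ratio): scale = (3 mm / 510 px) · AL / 23.95 mm, area =
pixels · scale², where AL is the eye's axial length. Method agreement is
assessed with Pearson r (Fisher-z 95% CI) and Bland–Altman bias ± 1.96 sd
limits of agreement; longitudinal change with repeated-measures ANOVA and
Tukey-adjusted pairwise visit comparisons.

Because clinical OCTA exports carry no ground truth, the package includes
a synthetic angiogram generator (`fazkit.synthetic`) producing
768×768 angiogram-like images with an exactly known avascular region,
speckle, and a longitudinal cohort structure — every claim in the test
suite is scored against that truth. See `docs/methods.md` for the full
model description.

## Worked example

```python
from fazkit import (SyntheticSpec, simulate_angiogram,
                    run_script_pipeline, area_mm2)

angio, truth = simulate_angiogram(SyntheticSpec(faz_area_mm2=0.44, seed=11))
region = run_script_pipeline(angio)
print("truth :", truth.pixel_count, "px =", round(truth.area_mm2, 4), "mm2")
print("script:", region.pixel_count, "px =",
      round(area_mm2(region.pixel_count, 23.79), 4), "mm2")
```

prints

```
truth : 12949 px = 0.4421 mm2
script: 11903 px = 0.4064 mm2
```

i.e. the generator rasterized a 0.44 mm² avascular zone as 12,949 pixels
at the corrected scale for a 23.79 mm eye, and the script pipeline
recovered it within 8% — inside the ring excluded by the wand's
tolerance-0 convention. Training the classifier on a *different*
synthetic image (seed 1) and applying it to the same scan gives
12,754 px = 0.4354 mm², within 1.5% of truth; over a 50-image set the two
methods correlate with r > 0.95.

The same workflow runs from the shell:

```
fazkit simulate --n-eyes 5 --seed 1 --out cohort/
fazkit ml-train --image cohort/S001_OD_v1_SVP.tif --meta cohort/meta.csv \
    --annotations strokes.json --seed 7 --model faz.model
fazkit run-study --images cohort/ --meta cohort/meta.csv \
    --model faz.model --out results/
```

`run-study` quality-filters scans (quality index ≤ 15 excluded), runs
both segmenters on every kept scan, writes `measurements.csv`, one
agreement report per plexus and one longitudinal report per
plexus × method, and isolates per-scan failures instead of aborting.

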
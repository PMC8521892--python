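# hepaquant

Semi-automatic morphometry of **Masson's-trichrome (MT)**-stained liver
sections: identification and quantification of **centrilobular fibrosis**
and **sinusoidal lumen** area in fixed-size regions of interest (ROIs)
centered on a centrilobular vein.

MT staining renders collagen blue and parenchyma red/pink/purple, so both
components can be segmented by box thresholds in hue/saturation/brightness
(HSB) space. For each ROI the package reports two ratio statistics,

```
CFR% = 100 · A_fibrosis / (A_ROI − A_vein)        (centrilobular fibrosis ratio)
SLR% = 100 · A_lumen    / (A_ROI − A_vein)        (sinusoidal lumen ratio)
```

where areas are physical (pixel count × scale², default scale 4.55 µm/pixel),
and the denominator is the tissue area of the ROI after the manually
delineated centrilobular vein has been excluded (filled with white pixels).
The calibrated segmentation bands, on the 0–255-per-channel HSB scale, are

| component | hue | saturation | brightness | smoothing |
|---|---|---|---|---|
| collagen (fibrosis) | 140–190 | 0–255 | 0–248 | 3×3 mean, before threshold |
| annotated lumen (black fill) | 0–255 | 0–255 | 0–50 | none |

Sinusoidal lumens follow the reference procedure of manual extraction
(lumens pre-filled with black pixels upstream); an automated *candidate*
detector for near-white unstained space is provided as a clearly flagged
extension — it cannot distinguish lumens from fat droplets.

The package is intended for research labs quantifying congestive
hepatopathy (e.g. sinusoidal-obstruction or cardiac-congestion models) who
want the macro-style batch workflow as reviewable, tested code. A synthetic
phantom generator with exact ground-truth masks makes every pipeline stage
verifiable without slide data, and a statistics layer reproduces the
standard evaluation against an ordinal pathologist grade (the Congestive
Hepatic Fibrosis Score, CHFS 0–4): per-grade frequencies, group summaries,
a Kolmogorov–Smirnov normality check, one-way ANOVA and Tukey HSD post-hoc
comparisons.

## Worked example

Generate a phantom ROI with 10 % fibrosis, segment it, and print its row:

```bash
hepaquant phantom --out-dir demo --fibrosis-fraction 0.10 --seed 7
hepaquant segment demo/phantom_7.png --vein-mask demo/phantom_7_vein.png \
    --lumen-mode automated
```

```
roi_id: phantom_7
total_area_um2: 2407307.4
vein_area_um2: 26023.04
tissue_area_um2: 2381284.36
fibrosis_area_um2: 235076.89
lumen_area_um2: 190463.0
cfr_percent: 9.87
slr_percent: 8.0
```

The phantom was built with 10 % collagen and 8 % lumen fractions of tissue
area; the pipeline recovers CFR 9.87 % and SLR 8.0 % — segmentation error
well under one percentage point, with the small CFR deficit coming from
smoothing-blended pixels at region boundaries. The same per-ROI row is what
`hepaquant batch` writes for every image of a folder (plus a per-slide
summary CSV of mean CFR/SLR over each slide's ROIs, grouped by the
`slideID_roiN` filename convention), and `hepaquant stats` runs the cohort
comparison from a CSV of per-animal CHFS grades and ratios. Library use
mirrors the CLI:

```python
from hepaquant import (PhantomSpec, generate_phantom, ROIImage,
                       exclude_vein, segment_fibrosis)

ph = generate_phantom(PhantomSpec(fibrosis_fraction=0.10, seed=7))
roi = exclude_vein(ROIImage(ph.image), ph.truth_vein)
cfr = 100 * segment_fibrosis(roi).sum() / ph.tissue_px
```

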
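# Methods

## The measurement model

A ROI is an 8-bit RGB tile (typically 1364×1364 px at 4.55 µm/pixel)
centered on a centrilobular vein of an MT-stained liver section. The
pipeline treats segmentation as box membership in HSB color space and
morphometry as pixel counting under a physical scale:

1. **Scale.** Every area is `count × s²` with `s` the pixel scale in
   µm/pixel (default 4.55; configurable, must be positive). CFR and SLR are
   scale-free: multiplying `s` by `c` multiplies all areas by `c²` and
   cancels in the ratios.
2. **Vein exclusion.** The centrilobular vein mask is a *required manual
   input* whenever a vein is present — delineating the vessel wall is an
   editorial judgement this package deliberately does not automate. The
   masked pixels are filled with pure white (255,255,255), which places them
   above the brightness caps of both segmentation bands (248 and 50), and
   the mask is additionally subtracted from every component mask; both
   mechanisms independently guarantee vein pixels never count as tissue
   components. The vein area is also removed from the ratio denominator
   ("tissue area" = ROI − vein). The published workflow this package
   re-implements leaves the exact ratio formula to a flow diagram; the
   vein-free denominator is our reading of "tissue area" given the explicit
   vein-exclusion step, and `include_vein_in_denominator=True` restores the
   full-ROI denominator for sensitivity analysis.
3. **Fibrosis.** 3×3 unweighted mean smooth (edge pixels average their
   in-image neighborhood only), exact integer HSB conversion, box threshold
   hue 140–190, saturation 0–255, brightness 0–248 (all bounds inclusive).
   Whether the original macro thresholded the smoothed or raw image in
   batch runs is not documented; smoothing-before-threshold is the default
   here (it is how the band was tuned) and can be disabled
   (`smoothing=False`). Smoothing is applied once.
4. **Sinusoidal lumen.** Reference route: lumens are manually extracted and
   black-filled upstream; the package thresholds brightness 0–50 (no hue or
   saturation restriction, no smoothing — the fills are flat by
   construction). Automated route: `detect_lumen_candidates` selects
   near-white unstained space (brightness ≥ 230, saturation ≤ 40 by
   default) and drops 8-connected components under 4 px. It is labelled
   *candidate* quality because near-white space also includes fat droplets
   and tears; on real tissue it over-counts, which the phantom's
   fat-droplet option demonstrates.
5. **Aggregation.** Per-slide CFR/SLR are arithmetic means over the slide's
   ROIs (study design: 5 ROIs per slide, 50 slides). The batch engine
   processes files in lexicographic order, is stateless across images, and
   flags per-image failures in the output rather than skipping them, so
   row count always equals image count and reruns are byte-identical.

## HSB conventions

The band numbers are only meaningful on the 0–255-per-channel scale of the
threshold tool they were calibrated in: hue maps [0°, 360°) linearly to
[0, 255] (pure blue 240° → 170), saturation and brightness are hexcone S
and V × 255. All three channels are rounded half-up to integers.
Achromatic pixels (max = min) get hue 0 — hue is undefined there, and a
fixed value keeps thresholding deterministic; black/white pixels are
instead controlled through the brightness bound, exactly as the two bands
above do. Conversion is implemented in exact integer arithmetic
(numerator/denominator half-up) because 8-bit inputs produce exact
half-integer cases (e.g. yellow: 60° → 42.5 → 43) that binary floating
point can round either way depending on evaluation order; the test suite
checks exact agreement against an independent `fractions.Fraction`
implementation of the hexcone definition.

All six band bounds are inclusive, so boundary behavior is fully
deterministic (a pixel at brightness 248 is collagen-eligible, at 249 it is
not). A hue interval with `lo > hi` wraps around 255→0 when explicitly
enabled, for red bands; the shipped bands do not need it.

## The phantom generator

Phantoms emulate the *geometry and color contrast* of a centrilobular MT
ROI, not its stain spectra: a centered near-white vein disk, thin sinusoid
channels radiating outward, a pericentral collagen ring (optionally with
1-px perisinusoidal sleeves along the channels), red/pink parenchyma
elsewhere, optional near-white fat droplets, and i.i.d. Gaussian RGB noise.
Placement is exact-count — each component gets exactly
`round(fraction × tissue_px)` pixels — so ground-truth fractions are exact
to ≤ 0.5 percentage points and recovery tests can use sharp tolerances.

Paint coordinates (HSB, sampled per pixel): collagen hue 150–185,
S 80–200, B 120–220 — inside the fibrosis band with ≥ 5 hue units of
margin; parenchyma hue 245–10 (wrapping through red), S 60–180, B 140–230 —
far outside it; lumens/vein/droplets S ≤ 20, B 240–252. Two deliberate
idealisations follow from this design:

- **Band separation.** Real stains vary between slides and overlap the
  band edges; phantom colors do not. Passing recovery tests therefore
  demonstrates pipeline correctness (conversion, thresholding, exclusion,
  counting), not robustness to staining variability. Narrowing the margins
  ("hard mode") probes boundary behavior but is not part of the defaults.
- **Channel placement.** Sinusoid channels start 3 px outside the collagen
  ring. Where near-white touches blue, the 3×3 smooth produces pale-blue
  blends that fall *inside* the fibrosis band, so letting channels cross
  the ring would contaminate fibrosis recovery with an artefact of the
  phantom, not of the pipeline. (The perisinusoidal option intentionally
  reintroduces this contact to model delicate perisinusoidal collagen.)

Defaults: 341 px side (a quarter-scale ROI; full 1364 px works but is 16×
slower per image), vein radius 20 px, fibrosis 10 %, lumen 8 %, noise SD 5
RGB units (mild scanner/stain noise; recovery error is flat up to roughly
SD 30 because of the band margins, and grows beyond — a property the suite
checks). All randomness flows from a single integer seed; identical seeds
give bit-identical phantoms.

The cohort generator emulates a 50-animal congestive-hepatopathy design:
CHFS grade drawn per animal from frequencies (0.46, 0.32, 0.22) for grades
0/1/2, per-ROI fibrosis fraction drawn from the grade's Normal(mean, SD) =
(1.32, 1.07), (8.00, 4.45), (14.55, 6.62) percent, truncated to [0, 90) %,
5 ROIs per animal. Note the truncation at 0 raises the realized grade-0
mean above 1.32 % (≈ +0.2 pp by the truncated-normal mean); the acceptance
report shows recovered means, which include this effect plus sampling
noise.

## Statistics layer

The fixed evaluation procedure: per-grade counts/percentages; per-group
mean ± SD *and* median ± IQR (both conventions are reported because ratio
data are often summarised either way); per-group Kolmogorov–Smirnov test
against a normal with the sample's mean and SD; one-way ANOVA; Tukey-HSD
adjusted pairwise comparisons (delegated to `scipy.stats` and
`statsmodels`). Normality rejection produces a warning, never an automatic
switch to a nonparametric test — mirroring a pre-registered fixed analysis
plan. The degenerate all-identical case (zero variance everywhere) is
reported as F = 0, p = 1 rather than NaN. `anova_power` estimates
Monte-Carlo power by redrawing groups from Normal(mean, SD) at the given
sample sizes.

## Numerical and interface choices

- Bounds, ties, rounding: half-up everywhere integers are produced;
  inclusive band bounds; 8-connectivity for component filtering (the
  default of common particle-analysis tools).
- Ratios carry full float precision internally; CSVs round to 2 decimals.
  A vein filling the whole ROI makes the ratios undefined and raises,
  never returns 0.
- Masks round-trip as 8-bit PNG (0 background, 255 component) bit-exactly.
- Config files are flat `key = value` text; CLI flags override file values,
  so a run's "macro settings" are reviewable artifacts.
- Test problem sizes: unit tests use 121–241 px phantoms; the end-to-end
  suite runs one full 250-ROI cohort at 341 px. These sizes keep the suite
  fast while exercising every code path at realistic component geometry.

## Known limitations

- No color management or stain deconvolution: the thresholds assume
  scanner output comparable to the calibration material. Between-slide
  stain variation directly biases CFR.
- The automated lumen detector cannot separate lumens from steatosis; its
  output is a candidate mask, not a measurement.
- Whole-slide pyramid formats (CZI/SVS/NDPI) are out of scope; ROIs must be
  exported as flat 8-bit RGB TIFF/PNG first.
- Phantoms validate the pipeline, not biological realism (no RBC
  congestion texture, no trabecular architecture, no hepatocyte nuclei).
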
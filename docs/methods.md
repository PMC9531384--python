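# Methods

This note documents the models, parameter choices and numerical conventions
behind `cardiot1tex`, and what the synthetic experiments do and do not show.

## Phantom and cohort model

A case is an 8-slice short-axis stack of T1 maps over a circular LV
cross-section: blood-pool disk (1600 ms) inside a myocardial annulus on a zero
background. Default geometry: 128×128 px, endocardial radius 18 px, epicardial
radius 34 px, 1.4 mm/px. The middle six slices are tagged 2 basal / 2 mid /
2 apical for analysis; end slices are excluded, mirroring the usual practice of
dropping the most basal and apical slices for through-plane motion.

Pixel noise is zero-mean Gaussian in T1 (ms). Its spatial structure matters
for texture: fitted MOLLI maps are smooth in-plane, and a map whose noise is
independent per pixel is already maximum-entropy texture after 256-level
min–max normalization — no realistic lesion can then *raise* GLCM entropy,
because any added plateau stretches the intensity range and compresses the
noise in level space. The cohort generator therefore uses spatially correlated
noise (Gaussian kernel, correlation length 2 px, marginal SD preserved at
20 ms). `noise_correlation_px` defaults to 0 in `PhantomConfig` so the
slice-level contracts (noiseless phantoms exactly piecewise-constant, sample
mean within 3 SE of baseline under independence) hold as stated; the cohort
layer switches it on as a study condition.

Rejection is emulated with two components, both motivated by the patchy
character of allograft inflammation:

* **Diffuse involvement** — every myocardial pixel is elevated by
  `shift × Uniform(0.05, 1.95)` (mean exactly the group shift: +40 ms for
  group B, +80 ms for group C over a 980 ms baseline). The mean elevation
  drives mean T1 up; the pixel-scale spread makes rejection maps texturally
  heterogeneous.
* **Focal hotspots** — raised-cosine wedges with a patchy interior
  (per-pixel Uniform(1−s, 1+s) scaling, s ∈ [0.5, 0.8]). Every rejection case
  gets at least one "primary" hotspot (core 90–120°, skirt 30–50°, radial span
  ≥ 0.75 of the wall, amplitude 100–180 ms) centred near an analysed septal or
  lateral segment and spanning 2–4 contiguous analysed slices, so the 16-ROI
  protocol always sees it; further hotspots (expected counts 2/3 for B/C) are
  placed freely.

These magnitudes are calibration choices, not literature values: the source
cohort reports only group summary statistics on human data, so the defaults
were fixed once so that the documented qualitative structure holds — peak T1
of every rejection case above the 1050 ms cutoff, monotone A < B < C group
means, and rejection maps with higher GLCM entropy/variance and lower energy.
With a primary hotspot fully covering a 60° septal segment's middle third, the
worst-case segmental elevation is ≈ 40 + 0.75×100 ms over baseline, i.e. a
peak ≥ ~1085 ms against segmental noise of a few ms — hence the 100%
sensitivity of the cutoff rule is structural, not incidental.

Group labels use largest-remainder apportionment of the 74/12/14 fractions
(50 cases → 37/6/7) followed by a seeded shuffle; a cohort too small to
realize all groups generates a warning and proceeds. Biopsy grades are drawn
per group (A: 84% 0R / 16% 1R; B: 29% 0R / 71% 1R; C: 67% 1R / 33% 2R), so the
clinical and histological dichotomies disagree on part of the cohort, as in
real surveillance populations.

Graft-dysfunction markers follow `marker = mean + sd (sign·r·z + √(1−r²) ε)`
with z the standardized realized peak T1 — the population correlation equals
the target r (default 0.45, the middle of the moderate range) exactly, with
signs chosen per marker (BNP and pressures positive, ejection fraction and
volumes negative). Fibrosis percentage is drawn independently of group
(truncated normal, mean 7.6%, SD 4.7%), emulating the null finding for random
right-ventricular biopsy sampling.

All randomness flows from one `SeedSequence`: per-case image seeds are spawned
children, so any case can be regenerated independently and reruns are
bit-identical.

## Segmental protocol

Segment wedges are half-open angular sectors of the annulus (septum = 120°
arc centred at `rv_insertion_angle + 90°`, lateral arc opposite; anterior and
inferior 60° sectors never analysed). The middle-third restriction is radial
(endo + w/3 ≤ r < endo + 2w/3); an area-based variant was considered and
rejected since the radial reading is the natural one for avoiding blood-pool
and epicardial partial-volume. Abnormality is strict (`value > 1050 ms`), so a
segment at exactly 1050 ms is normal. Global mean is the unweighted mean of
the 16 segmental values, not pixel-weighted. ICC is fixed to the two-way
random-effects, absolute-agreement, single-measure form (computed via
pingouin, cross-checked against the closed-form ANOVA expression in tests);
the form is recorded in the output because "interclass correlation
coefficient" alone underdetermines it. The pipeline emulates a second reader
by re-deriving all masks under a jittered angular reference (SD 5°) and ±1 px
contour error; on phantoms this yields ICC ≈ 1 because between-case variance
dwarfs tracing error — phantom ICC validates the estimator, not human
reproducibility.

## Texture conventions

Choices the literature leaves open are explicit, recorded parameters:

* offsets: the four unit directions, pooled into one symmetric matrix;
* quantization: `floor(255 (v−min)/(max−min))` within the segmentation mask
  (whole-image scaling would let blood/background set the range); a constant
  region degenerates to level 0 with a flag;
* entropy base 2 (bits); homogeneity kernel `1/(1+|i−j|)` with the
  `1/(1+(i−j)²)` variant behind a flag;
* levels indexed 0..255, so sum average ranges over k = 0..510 — index origin
  shifts sum average and autocorrelation by constants and is recorded;
* GLCM "grand mean" μ for the variance feature is (μx+μy)/2 (= μx for
  symmetric matrices);
* pairs with either pixel outside the mask are skipped (no padding);
* texture is computed on the lower-indexed of the two mid-tagged slices
  (configurable).

Otsu thresholding maximizes between-class variance over the exact value
histogram (vectorized cumulative-moment scan; ties broken toward the lowest
cut; returned threshold is the midpoint between the adjacent classes).
Segmentation applies Otsu twice — background/body, then myocardium/blood —
keeps the largest connected myocardial component, requires an enclosed blood
pool, and erodes one pixel at the epicardial boundary only (the filled-region
erosion intersected with the annulus), mirroring careful epicardial exclusion.
A degenerate single-level mask leaves GLCM correlation undefined; it is
reported as NaN with a provenance flag rather than raising, since the other
eight features remain well-defined.

## Histology conventions

The colorimetric rule operates on raw RGB with recorded parameters
(`blue ≥ 100`, `blue−red ≥ 20`, `blue−green ≥ 20`, background = mean channel
≥ 230); an HSV hue-window rule (hue 0.5–0.75, saturation ≥ 0.15) is available
behind `mode="hsv"`. The synthetic slide palettes sit strictly inside/outside
both rules, so recovery of the constructed collagen fraction is exact, and the
only error against the *nominal* fraction is the pixel-count rounding
(< 0.1 percentage points at default slide sizes). Exclusion masks are removed
from numerator and denominator alike. Real-slide thresholds would need tuning
against expert annotation; the defaults are conventions, not clinical values.

## Statistics

Student's pooled-variance t is the default (Welch behind a flag). ROC curves
are empirical with AUC = Mann–Whitney statistic (ties half credit); the AUC
p-value uses the tie-corrected normal approximation without continuity
correction. Features where the rejection class scores lower (energy) are
negated before curve construction with the direction recorded, so reported
AUCs are ≥ 0.5 in the effect direction. Sensitivity at a cutoff uses strict
`>`, consistent with the abnormality convention. No multiple-testing
correction is applied, matching the source protocol; p-values are labelled
raw. The report also flags that cases are treated as independent although a
real surveillance cohort contains repeat encounters per patient — mirrored
deliberately, limitation noted in the output caveats. "Linear regression" of
markers on T1 is reported as supplementary slope/intercept/r² next to each
Pearson r.

## Replicated-cohort experiments and problem sizes

`experiments.null_type_i_error` runs the full generator + t-test loop on a
no-effect generator (zero shift, no hotspots, equal noise) and checks the
headline comparison rejects at the nominal 5%. `experiments.directional_recovery`
measures how often replicate cohorts reproduce the directional findings.
Replicated runs use reduced rasters chosen as the package's own scaling
defaults — 48 px / 6-slice stacks with 24 cases for the null experiment
(2000 replicates), 96 px stacks with 50 cases for directional recovery
(200 replicates) — since the quantities involved (segmental means, group-mean
directions) converge long before full resolution matters. Measured under these
conditions: type-I error 0.050–0.054, all directional recovery rates ≥ 0.97.

## What passing tests establish — and what they do not

The synthetic cohorts validate the *machinery*: exact arithmetic of the
segmental protocol, oracle-equivalence of GLCM/Otsu/ROC implementations,
exact fibrosis recovery, calibrated type-I error, and that the generator's
documented effect structure is faithfully detected. They do not establish
clinical performance: phantoms have idealized geometry (no partial volume,
motion, susceptibility artifacts, or anatomic variation), the lesion model is
a stylization of rejection pathology, markers are linear Gaussian surrogates
with nominal units, and AUCs near 1.0 on default settings reflect the chosen
effect sizes, not expected clinical discrimination. Real-data use requires
user-supplied ROI masks (the package does not contour clinical images) and
histology thresholds tuned to the staining pipeline.
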
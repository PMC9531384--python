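# cardiot1tex

Quantitative analysis of native T1 cardiac MR for pediatric heart-transplant
rejection surveillance: segmental T1 quantification, gray-level co-occurrence
matrix (GLCM) texture analysis, digital fibrosis quantification of
trichrome-stained biopsies, and the group-comparison / ROC statistics that tie
them together — exercised end to end on a synthetic phantom-cohort generator,
so the whole pipeline is testable without any clinical data.

It is written for imaging scientists who want a reproducible, scriptable
version of this analysis protocol: every stage is a plain library function
under `src/cardiot1tex/`, the numbered scripts under `analysis/` run the study
workflow, and a `cardiot1tex` CLI wraps the common entry points.

## The analysis

**Segmental native T1.** From 8 short-axis T1 maps per case, the middle six
slices (2 basal, 2 mid, 2 apical) are analysed. Per the septal/lateral
protocol, basal and mid slices contribute two septal segments (AHA 2/3, 8/9)
and one combined lateral region (5+6, 11+12); apical slices one septal (14)
and one lateral (16) region — 16 ROIs per case, each restricted to the radial
middle third of the wall, endo + w/3 ≤ r < endo + 2w/3. Global mean T1 is the
unweighted mean of the 16 segmental means, peak T1 their maximum, and a
segment is abnormal when its value strictly exceeds 1050 ms (institutional
normal range 900–1050 ms). Interobserver agreement uses ICC(2,1) (two-way
random effects, absolute agreement, single measure).

**Texture.** On one mid-ventricular slice, the LV myocardium is segmented by
two-stage Otsu thresholding (background/body, then myocardium/blood pool, with
a one-pixel epicardial erosion), min–max normalized to 256 gray levels, and a
symmetric 256×256 GLCM is accumulated over the four unit offsets
{(0,1),(1,0),(1,1),(1,−1)}, counting only pairs with both pixels in-mask.
Nine features are reduced from p(i,j):

    energy = Σ p²                 contrast = Σ p (i−j)²
    entropy = −Σ p log₂ p         homogeneity = Σ p / (1+|i−j|)
    correlation = Σ (i−μx)(j−μy) p / (σx σy)
    sum average = Σ_k k p_{x+y}(k)   variance = Σ (i−μ)² p
    dissimilarity = Σ p |i−j|        autocorrelation = Σ i j p

**Fibrosis.** Percentage tissue fibrosis of a Masson-trichrome slide is
100 × collagen / tissue pixels, where collagen is a colorimetric rule
(blue ≥ 100, blue−red ≥ 20, blue−green ≥ 20 by default; HSV variant behind a
flag) and manual exclusions are removed from both counts.

**Statistics.** Pooled-variance Student's t and ROC/AUC (Mann–Whitney, ties at
half credit, asymptotic p) under two rejection dichotomies — clinical (group A
vs B+C) and biopsy (grade 0R vs ≥1R) — one-way ANOVA across the three groups
with a monotone-trend check, Pearson correlations of mean/peak T1 against
graft-dysfunction markers (BNP, echo, catheterization and volumetric
measures), and sensitivity of the `peak T1 > 1050 ms` rule.

**Synthetic cohort.** Because no image data are deposited, `cardiot1tex.cohort`
generates cohorts with the study's structure: a 74/12/14 A/B/C split, normal
myocardium ≈980 ms with smooth (spatially correlated) map noise, rejection
cases with a diffuse pixel-scale heterogeneous elevation (mean = group shift,
+40/+80 ms) plus focal raised-cosine hotspots, markers calibrated to a target
Pearson r against realized peak T1, and fibrosis drawn independently of group.

## Worked example

```
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_segmental_t1.py   --seed 1
python analysis/03_texture_features.py --seed 1
python analysis/04_fibrosis_quantification.py --seed 1
python analysis/05_rejection_statistics.py
```

prints (seed 1):

```
groups: A=37  B=6  C=7
  group A: mean T1   980.2 ms, peak T1   993.7 ms, abnormal segments/case 0.0
  group B: mean T1  1055.7 ms, peak T1  1171.1 ms, abnormal segments/case 5.7
  group C: mean T1  1093.3 ms, peak T1  1206.7 ms, abnormal segments/case 14.3
  energy   : no-rejection 0.0001868  rejection 0.0001122
  entropy  : no-rejection 12.72  rejection 13.37
  variance : no-rejection 1730  rejection 2643
  max |measured - true| = 0.002 percentage points
  peak T1 > 1050 ms: sensitivity 100%, specificity 100%
```

Read: T1 rises monotonically with rejection severity (A < B < C); rejection
maps are texturally more heterogeneous (higher entropy and variance, lower
energy); the digital fibrosis tool recovers the constructed collagen fraction
to within rounding; and the institutional 1050 ms peak-T1 cutoff separates the
treated from the untreated cases in this cohort. Full tables land under
`results/` (`report.md`, `report.json`, per-stage CSVs, ROC figure).

`cardiot1tex demo --out demo_out` runs a 10-case miniature in seconds;
`cardiot1tex run --config config.yaml --out results/` runs a custom
configuration; `cardiot1tex texture` and `cardiot1tex fibrosis` quantify a
single study directory or slide image.

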
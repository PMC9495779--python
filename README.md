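# pdfftexture

Texture analysis of proton-density fat-fraction (PDFF) maps from chemical
shift encoding-based water–fat MRI, for quantifying fat *distribution* — not
just fat amount — in lumbar muscle and vertebral bone marrow.

Mean PDFF tells you how much fat a compartment holds; it says nothing about
whether that fat is diffusely spread or concentrated in streaks and islands.
`pdfftexture` computes, per segmented compartment (erector spinae **ES**,
psoas **PS**, lumbar vertebral bone marrow L1–L4 **LS**):

* **first-order features** from the ROI intensity histogram —
  Variance(global), Skewness(global), Kurtosis(global) — with the bin count
  chosen as the median of Sturges', Scott's and the Freedman–Diaconis rules;
* **second-order features** from 3D gray-level co-occurrence matrices
  (GLCM): Energy, Entropy, Contrast, Homogeneity, Correlation, Variance,
  Sum Average and Dissimilarity, after 200-level quantization of the fixed
  0–100 % PDFF domain, over the 13 unique displacement directions of the
  26-neighborhood, averaged (inverse-offset-length weighted) into
  rotation-invariant values;
* **cohort statistics**: Mann–Whitney tests for demographics, per-feature
  logistic regression of sex adjusted for age and BMI (Wald tests, with a
  Firth-penalized fallback under separation), and partial correlations
  between spine and muscle features adjusted for age and BMI.

For a symmetric co-occurrence matrix p(i,j) over gray levels i,j ∈ 1..N_g
with marginal mean μ_x and SD σ_x, the implemented definitions are

    Energy   = Σ p(i,j)²               Entropy       = −Σ p(i,j) log₂ p(i,j)
    Contrast = Σ (i−j)² p(i,j)         Homogeneity   = Σ p(i,j) / (1+|i−j|)
    Variance = Σ (i−μ_x)² p(i,j)       Dissimilarity = Σ |i−j| p(i,j)
    Correlation = Σ (i−μ_x)(j−μ_y) p(i,j) / (σ_x σ_y)
    Sum Average = Σ_k k · p_{x+y}(k),  p_{x+y}(k) = Σ_{i+j=k} p(i,j)

Because no imaging cohort is bundled, the package ships a synthetic
generator: smoothed, skew-warped Gaussian random fields fill a phantom with
two bilateral muscle ROIs of unequal volume and four vertebral ROIs, with
per-sex compartment targets, truncated-normal demographics, and a latent
factor that controls how strongly heterogeneity co-varies between spine and
muscle. See `docs/methods.md` for the model details and its limits.

## Worked example

Simulate a default cohort (13 male, 31 female), extract features, analyze:

```sh
pdfftexture simulate --out cohort/ --seed 5
pdfftexture extract  --cohort cohort/ --out features/
pdfftexture analyze  --features features/features.csv --out results/
```

The analyze step prints a report (and writes `table1.csv`, `table2.csv`):

```
Cohort texture-feature analysis
subjects: 44 (13 male, 31 female)
alpha = 0.05 (two-sided)

Sex differences (logistic regression adjusted for age and BMI):
   ES pdff_mean          p = 0.0315
   ES sum_average        p = 0.0315
   LS skewness_global    p = 0.0030

Partial correlations LS vs muscles (adjusted for age and BMI):
  LS_vs_ES  variance_global    r = +0.44, p = 0.0036
  LS_vs_ES  skewness_global    r = -0.42, p = 0.0060
  LS_vs_ES  contrast           r = +0.55, p = 0.0002
  LS_vs_ES  variance_glcm      r = +0.46, p = 0.0024
  LS_vs_PS  variance_global    r = +0.58, p = 0.0001
  LS_vs_PS  contrast           r = +0.60, p = 0.0000
  LS_vs_PS  variance_glcm      r = +0.58, p = 0.0001

KS normality screen: 67% of feature distributions consistent with normality
```

Reading it: mean erector-spinae PDFF separates the sexes even after
adjusting for the cohort's age and BMI imbalance (males are older on
average), and the heterogeneity of the vertebral marrow's fat distribution —
Variance(global) — tracks the heterogeneity of muscle fat infiltration
across subjects (partial r ≈ 0.5–0.6 in this realization), the planted
cross-compartment association the generator is calibrated to; the
variance-coupled co-occurrence features (Contrast, GLCM Variance) move with
it. Each `table1.csv` row carries the per-sex mean ± SD and the adjusted p;
each `table2.csv` row one spine–muscle partial correlation.

The same API is available in Python:

```python
from pdfftexture import (CohortSpec, simulate_cohort,
                         extract_compartment_features, run_cohort_analysis)

subjects = simulate_cohort(CohortSpec(seed=5))
features = extract_compartment_features(subjects[0].volume, subjects[0].mask)
print(features["ES"].features["contrast"])
```

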
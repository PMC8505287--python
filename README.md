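# ihcspatial

Quantitative mapping of how immunostained inflammatory cells are arranged in
tumor tissue.

Pathology studies of the tumor microenvironment routinely report *how many*
marker-positive immune cells (T cells, macrophages, mast cells, …) a tissue
contains, but two tissues with the same cell density can organise those cells
very differently — diffusely scattered versus packed into clusters — and that
architecture carries biological meaning. `ihcspatial` turns brightfield
H-DAB immunohistochemistry field images (or pre-extracted cell-coordinate
tables) into spatial statistics of the positive-cell pattern, and compares
two patient cohorts parameter by parameter. It was built around the study
design of two diffuse large B-cell lymphoma subgroups (15 samples per arm,
10 equal-area fields per sample), but nothing in it is specific to that
setting.

## What it computes

**Imaging path.** An RGB field is converted to optical density
(OD<sub>c</sub> = −log₁₀(I<sub>c</sub>/I₀); Beer–Lambert absorption makes
stain amounts additive in OD) and unmixed through the 3×3 stain matrix of
hematoxylin, DAB and a residual completion vector (colour deconvolution,
published H-DAB signatures by default). Thresholding the DAB channel (Otsu
by default) gives the immunoreactive-area mask and **Area%** (percent of
field pixels covered); thresholding the hematoxylin channel gives the nuclei
mask; nuclei whose area overlaps the immunoreactive mask by ≥ 50% are called
positive and reduced to centroids (x = column, y = row, origin top-left).

**Statistical path.** For the point pattern of each field:

* **Ripley's K-function** — K(d) = |W|/(n(n−1)) · Σ<sub>i≠j</sub>
  **1**(‖p<sub>i</sub>−p<sub>j</sub>‖ ≤ d), compared against a Monte-Carlo
  null of 100 CSR (complete spatial randomness) patterns with the *same*
  point count in the *same* window. Pointwise 95% envelopes are the 3rd
  smallest/largest simulated K at each distance. L(d) = K(d) − K₀(d) above
  the upper envelope over a sustained run of distances ⇒ **clustered**;
  below the lower envelope ⇒ **avoidance** (regularity); neither ⇒
  **random**.
* **Uniformity index** ∈ [0, 1] — normalised Clark–Evans ratio
  R = mean NN distance / (0.5/√λ) scaled by its hexagonal-lattice maximum
  R<sub>hex</sub> = 2√(2/√3) ≈ 2.1491: 0 at maximal clustering (all points
  coincident), 1 for an ideal regular array.

**Cohort path.** Field values are averaged per sample; groups are compared
per parameter with a two-sample Student t-test (equal-variance, two-sided,
α = 0.05; Welch optional).

A synthetic-data module generates ground-truth patterns across the
clustered → random → regular spectrum, Beer–Lambert-rendered two-stain
fields with exact masks, and full two-arm cohorts, so the whole pipeline is
testable without slide data.

## Worked example

```python
from ihcspatial import (PatternSpec, Window, generate_pattern,
                        RipleyKAnalysis, uniformity_index)

window = Window(1000, 1000)
clustered = generate_pattern(
    PatternSpec("thomas_cluster", 150, parent_intensity=8e-6,
                offspring_spread=30.0, seed=7), window)

result = RipleyKAnalysis(clustered).fit(n_sim=100, seed=1)
print(result.summary())
ui = uniformity_index(clustered)
print(f"uniformity index: {ui.index:.3f}")
```

prints

```
Ripley K Monte-Carlo envelope test
==================================
points:            150
window:            1000 x 1000
CSR simulations:   100
estimator:         naive
grid:              50 distances in (5, 250]
above envelope:    100.0% of distances
below envelope:    0.0% of distances
verdict:           clustered
uniformity index: 0.130
```

The observed K sits above the CSR envelope across the whole distance grid —
cells are closer together than chance at every scale examined — and the
uniformity index is far below the CSR reference value 1/R<sub>hex</sub> ≈
0.465. `result.plot()` draws the L(d) curve with dashed envelopes.

A full two-arm comparison, from generation to t-test:

```python
from ihcspatial import PipelineConfig, generate_cohort, run_cohort

cohort = generate_cohort(
    PatternSpec("thomas_cluster", 150, parent_intensity=8e-6, offspring_spread=30.0),
    PatternSpec("csr", 150),
    window, n_samples_per_group=15, n_fields_per_sample=10, seed=0)
report = run_cohort(cohort, PipelineConfig(seed=0, n_sim=50))
print(report.summary())
```

```
Two-sample Student t-test — uniformity_index (synthetic)
------------------------------------------------
A: n=15  mean=0.1533  SD=0.007967  SEM=0.002057
B: n=15  mean=0.4817  SD=0.006535  SEM=0.001687
t = -123.4573  (df = 28)   p = 7.268e-40   significant at alpha = 0.05
```

The CSR arm (B) shows the significantly higher uniformity index, i.e. a more
even cell distribution than the clustered arm.

The same pipeline runs from the shell:

```bash
ihc-spatial simulate --out cohort/ --seed 1            # points + manifest
ihc-spatial analyze-cohort --input cohort/manifest.json --out results/
ihc-spatial report --input results/ --out figures/     # bar charts
ihc-spatial analyze-cohort --simulate --out results/   # one-shot variant
```

## Documentation

`docs/methods.md` describes the model, estimators, defaults and their
rationale, what the synthetic generator does and does not emulate, and known
limitations.
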
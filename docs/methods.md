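# Methods

This note documents the statistical and numerical choices behind
`ihcspatial`: what each stage assumes, which knobs matter, and what the
synthetic-data tests do and do not demonstrate about real tissue.

## 1. Stain model and colour deconvolution

Brightfield immunohistochemistry is modelled as Beer–Lambert absorption:
per channel c, transmitted intensity I_c = I0 · 10^(−A_c), so stain amounts
add linearly in optical density OD_c = log10(I0 / I_c). A pixel's OD vector
is a non-negative combination of unit "signature" vectors S_H (hematoxylin)
and S_D (DAB); unmixing inverts the 3×3 matrix whose rows are S_H, S_D and
their normalised cross product S_R (the standard orthogonal completion,
which also makes the matrix well conditioned for any non-collinear pair).

* **Stain vectors** — defaults are the published H-DAB signatures
  H ≈ (0.650, 0.704, 0.286), DAB ≈ (0.269, 0.568, 0.778), re-normalised.
  They are calibration constants and are configurable
  (`StainSystem(hematoxylin=…, dab=…)`, or `stains.*` keys in a config
  file). No automatic stain estimation (Macenko-style) is attempted.
* **OD clamp** — OD = log10(I0 / max(I, ε)) with ε = 1 grey level, bounding
  OD at log10(255) ≈ 2.407 and keeping fully absorbed pixels finite.
* **Negative concentrations** — unmixing can return slightly negative
  values on noisy pixels; the named channels are clipped at zero for
  thresholding while `UnmixedImage.raw` keeps the signed solution, so
  `compose(raw)` reconstructs OD exactly.
* **Shading** — an optional white-balance (scale each channel so its 99th
  percentile maps to I0) stands in for shading correction on real scans. It
  is off by default; synthetic renders need none, and contrast enhancement
  is treated as cosmetic and not reproduced.
* **Float vs 8-bit** — files on disk are 8-bit RGB; rendered fields stay
  float in memory (optional quantisation) because 8-bit rounding alone
  injects up to ~1% error into unmixed concentrations, which would mask
  true round-trip accuracy.

## 2. Cell detection and Area%

The DAB concentration channel is thresholded (Otsu by default — the
between-class-variance maximiser; a fixed threshold is available for
strict reproducibility across batches), opened with a radius-1 disc and
stripped of components below `min_area` = 20 px. The same is done to the
hematoxylin channel to obtain the nuclei mask. A nuclear connected
component is called marker-positive when ≥ `min_overlap_fraction` = 0.5 of
its pixels lie in the immunoreactive mask ("co-localised"); its centroid is
emitted with x = column, y = row, pixel centers at integer coordinates,
origin top-left. Area% = 100 · (immunoreactive pixels) / (field pixels).

Otsu on a constant channel is a degeneracy, raised as
`DegenerateHistogramError` so callers can fall back to a fixed threshold.
Watershed splitting of touching nuclei is available
(`split_touching=True`) but off by default; at the densities studied the
hard-core placement of nuclei makes merging rare, and on real tissue the
choice deserves explicit review rather than a silent default.

## 3. Ripley's K with a matched Monte-Carlo null

K̂(d) = |W| / (n(n−1)) · Σ_{i≠j} 1(‖p_i − p_j‖ ≤ d), the naive
(uncorrected) estimator, evaluated on a grid of 50 equal steps from
d_max/50 to d_max = ¼ of the shorter window side. The null is 100 CSR
patterns with exactly the observed n in the same window; envelopes are
pointwise rank envelopes — with k = ceil(0.025 · n_sim), the k-th smallest
and k-th largest simulated value per distance (k = 3 at n_sim = 100), with
exact pointwise exceedance probability 2k/(n_sim+1) = 5.94%.

**Why naive?** The inference is purely relative: the same estimator is
applied to the observed and simulated patterns in the same window at the
same n, so the boundary bias cancels from the comparison. The bias is real
— under CSR in the unit square the naive mean falls below πd² by
approximately (8/3)d³ (measured −4.4% at d = 0.05, −8.3% at d = 0.10
at n = 500) — so users needing absolute K should pass
`edge_correction="translation"`, which weights each pair by
|W| / ((w−|Δx|)(h−|Δy|)) and is exactly unbiased for a homogeneous
process; the test suite verifies its mean against the closed form
E[K(d)] = πd².

**Classification.** A field is called *clustered* when K̂ exceeds the upper
envelope over a contiguous run of at least `min_run_fraction` = 0.2 of the
grid, *avoidance* symmetrically below, *mixed* when both, *random*
otherwise. The run requirement exists because a pointwise 95% envelope is
expected to be crossed at ~6% of isolated distances by chance; requiring a
sustained excursion ("a large interval of cell-to-cell distances") makes
single-distance noise non-actionable. 0.2 is a judgement call, configurable,
and validated by the regime fixtures (20/20 Thomas-cluster seeds called
clustered, 20/20 jittered-lattice seeds called avoidance at the default
study conditions).

## 4. Uniformity index

Defined here as the normalised Clark–Evans nearest-neighbour ratio:
R = mean observed NN distance / (0.5/√λ), λ = n/|W|, and
index = min(R / R_hex, 1) with R_hex = 2√(2/√3) ≈ 2.1491, the maximum of R,
attained by the hexagonal (triangular) lattice. The index is 0 exactly when
all points coincide and 1 for the ideal regular array; CSR sits at
1/R_hex ≈ 0.465. This normalisation is adopted *as the package's
definition* because it provably has the required endpoints; it is a
substitute for, not a restatement of, earlier "morphological approach"
procedures whose exact formula is not public. No NN edge correction is
applied by default (the CSR-expectation denominator and the index are
defined against the uncorrected quantity); Donnelly's boundary adjustment
is available via `nn_correction="donnelly"`. Patterns with n < 2 return a
flagged undefined result and are excluded (with a logged warning) from
sample-level means rather than raising.

## 5. Synthetic data: what it emulates, what it does not

Generators are fixed-n (a binomial process rather than Poisson) because the
Monte-Carlo null conditions on the observed count; Thomas offspring are
assigned multinomially to Poisson-number parents and resampled until inside
the window (keeping n and the within-cluster spread exact; the
offspring-per-parent rate is implied by n, the parent intensity and the
window, so it is not a separate knob). Jittered lattices perturb a
triangular lattice by uniform jitter of fraction j of the spacing;
`hexagonal_lattice` builds the exactly tiling array used for the
uniformity-index endpoint. `coincident` is the degenerate
maximal-clustering case.

Default study conditions mirror the two-arm design: 2 groups × 15 samples ×
10 fields, per-field counts Poisson with mean 150 (within a realistic
50–400 cells/field range for dense immune infiltrates) in a 1000×1000
window; the clustered arm uses ~8 expected parents per field with offspring
SD = 3% of the window side. Cohort streams are keyed per field as
(master seed, group, sample, field), so any field is independently
replayable.

Rendering places hard-disc nuclei (radius 5 px) that sum in OD where they
overlap; all nuclei carry hematoxylin (amplitude 0.6), positives
additionally carry DAB (amplitude 0.8); optional zero-mean Gaussian noise is
clipped to [0, 255]. This reproduces the *optical* structure the pipeline
consumes — not chromatin texture, stroma, folds, uneven illumination or
out-of-focus blur. Passing the imaging round trip therefore certifies the
deconvolution/threshold/centroid machinery, not robustness to real-slide
artefacts; on real material the stain vectors, thresholds and morphology
parameters need case-by-case review.

## 6. Cohort statistics

Per-sample values are arithmetic means over usable fields (n ≥ 2 cells);
a sample with zero usable fields is flagged and excluded listwise per
parameter. Groups are compared with the classical equal-variance two-sample
t-test (df = n_A + n_B − 2), two-sided, α = 0.05; `equal_var=False`
switches to Welch. Zero-pooled-variance degeneracies are resolved
explicitly (equal means → t = 0, p = 1; unequal → infinite t, p = 0).
Both SD and SEM are reported. No multiple-testing correction is applied
across markers or parameters — a deliberate caveat: with five markers and
two parameters, a 5% per-test level implies a materially higher familywise
rate.

Calibration at the default study conditions, verified in the test suite:
identical-spec arms reject at ≈ 5% over 200 replicate cohorts; a
clustered-vs-CSR contrast at the default effect size separates with power
> 0.9 (in practice ≈ 1) with the CSR arm scoring higher.

## 7. Determinism and problem sizes

Every stochastic step takes a seed or a `numpy.random.Generator`; per-field
envelope streams are keyed by (config seed, CRC32 of the field id), so
results are independent of processing order and identical runs produce
byte-identical JSON (sorted keys). The test suite's simulation sizes —
100-seed closed-form averages, 200-replicate coverage and type-I runs,
20-seed classification sweeps, 15×10 cohorts — were chosen as the smallest
designs whose Monte-Carlo error is well inside the asserted tolerances.

## 8. Known limitations

* Area% is defined by this package's own masks; it is not a reimplementation
  of any scanner vendor's positive-pixel metric, and the two will differ in
  absolute value.
* The envelope test is pointwise, not a global rank/MAD envelope; with the
  run-length rule this is adequate for classification, but global envelopes
  would give exact familywise control over d.
* Only univariate K is provided — no cross-type K between markers, no
  pair-correlation g(r), no inhomogeneous K; tissues with strong density
  gradients will register as "clustered" against a homogeneous null.
* The uniformity index summarises first-order NN structure only; patterns
  can share an index yet differ at larger scales (which is why K is
  reported alongside).
* Field selection is upstream of the package: fields are taken as given,
  and no whole-slide (pyramidal) reading is implemented.
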
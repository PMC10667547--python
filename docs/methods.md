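# Methods

## Problem setting

An AI system scores each screening image for malignancy and, through a saliency
method, assigns each pixel a relevance value.  Ground truth is a radiologist's
binary lesion mask on case images.  The package quantifies two properties per
system — detection (can the scores separate case from control images?) and
localization (does the saliency concentrate on the lesion?) — deliberately as
separate measurements, because the empirical point of the analysis is that they
can diverge.

## Saliency normalization and the optimal-threshold area of interest

Saliency values are min-max rescaled to [0, 1] per image (v′ = (v − min)/(max −
min)); a constant map normalizes to all zeros and is flagged degenerate.
Normalization over the full image, before any cropping, is a fixed convention of
this package.

The area of interest at threshold τ is A(τ) = {p : s(p) ≥ τ}.  The "≥"
convention resolves the ambiguity of "above a threshold" at equality: it
guarantees the maximum-saliency pixel is always selectable and makes the
candidate thresholds exactly the distinct saliency values.  Pixels sharing a
value enter or leave A together — a threshold cannot split a value level.

The per-image threshold τ\* maximizes DSC(A(τ), B) = 2|A∩B|/(|A|+|B|).  The
search is exact, not grid-based: sort pixels by descending saliency; with k
pixels above a cut and TP(k) of them in B, the Dice score of the prefix is
2·TP(k)/(k+|B|); admissible cuts are the boundaries between distinct values, so
a single O(P log P) sweep evaluates every distinct threshold.  Tests assert
exact agreement with brute-force evaluation at every distinct value, including
tie-heavy quantized maps.  Ties in DSC resolve to the largest τ (the smallest,
most specific area of interest) — a deterministic choice.  Because τ\* is
optimized against the ground truth, the reported DSC is an upper bound on
apparent localization; this is intentional and makes low values conclusive.

Degenerate inputs: DSC with |A|+|B| = 0 raises rather than returning a number;
an empty or absent mask excludes the image from overlap analysis (counted and
logged, never silently dropped) while the image still contributes to detection
evaluation.  Summaries use the median and IQR (Q3 − Q1) with
linear-interpolation quantiles; the quantile rule is stated because no single
convention is universal.

## Detection evaluation

AUC is the Mann–Whitney rank statistic (ties ½), computed from midranks;
property tests confirm equality with trapezoidal ROC integration to 1e−12 and
invariance under strictly increasing score transforms.  The confidence interval
is a percentile bootstrap — the simplest defensible choice, stated explicitly —
with stratified resampling preserving the case and control counts, as the
case–control design fixes them; no replicate can lose a class.  Default 2000
replicates; the seed is mandatory and logged.  Significance versus chance is
operationalized as the 95% interval strictly excluding 0.5 (two-sided, α =
0.05).  The analysis unit is the image.  Four images per woman induce
within-woman correlation that independent resampling ignores; a cluster
bootstrap by woman and a per-woman max-score aggregation are provided as
options, both off by default.

## Matching

Cases are paired 1:1 to control candidates sharing the exact key (birth year,
screening year, mammographic system) — no caliper, since the design matches on
years, not age bands.  Among candidates at a key, selection follows a seeded
random permutation of the canonically sorted candidate list, and cases are
processed in sorted order, so the output is deterministic given the seed and
invariant to input ordering.  Unmatched cases are reported.  Age is
screening_year − birth_year (only years are available), banded as <55, 55–59,
60–64, >64 with inclusive lower bounds.

## Synthetic data

The generators produce the statistical structure the analysis consumes, not
radiological realism — the pipeline sees only masks, saliency and scores, so
texture realism is irrelevant to its correctness surface.

* **Phantoms** (default 128×128, small enough for brute-force oracles): a
  half-ellipse breast of blurred seeded noise, plus an additive bright
  elliptical lesion; the mask is exactly the discrete lesion ellipse,
  independent of contrast.  A lesion outside the breast is a parameter error.
* **Saliency fields**: λ·K_lesion + (1−λ)·K_diffuse + noise, then normalized.
  K_lesion is a Gaussian bump (width 8 px) on the lesion centroid; K_diffuse a
  broad bump (width 48 px) at a uniform-random center, placed independently of
  the lesion rather than anti-correlated, so no artificial negative association
  is built in.  λ = 1 yields lesion-concentrated saliency, λ = 0 saliency
  statistically independent of the lesion; the median optimal-threshold DSC is
  empirically monotone in λ.
* **Scores**: binormal — controls N(0, 1), cases N(μ, 1) — giving the closed
  form true AUC Φ(μ/√2), used for recovery and CI-coverage checks.
* **Cohorts**: screening years 2015–2017, ages uniform on 50–69 (birth year
  derived as screening year − age within 1946–1967), systems PH/GE at 22/78%,
  cancer types DCIS/ductal/lobular/other at 17/64/13/6%.  The candidate pool
  copies the case keys for its first n_cases entries so a full matching exists
  by construction.
* **Dataset writer**: 191 cases + 191 controls by default, four images per
  woman (left/right × CC/MLO), lesions on both views of one affected breast,
  and 12 lesion images stripped of their mask (at most one view per case),
  emulating lesions conspicuous in a single view; masks as 8-bit PNG, saliency
  as 16-bit PNG, scores and tables as CSV.

What passing tests on these phantoms do **not** show: performance on real
parenchymal texture, lesion morphology (spiculation, calcifications), scanner
effects, or saliency methods' behaviour on real networks.  They do show that
the measurement pipeline — thresholding, Dice, bootstrap, matching, accounting
— is exact, calibrated and deterministic.

## Reproducibility and numerical choices

One master seed drives a run; every stage derives a named sub-seed
(CRC32-salted SeedSequence), recorded in `run_metadata.json` together with the
threshold rule, quantile rule and bootstrap type.  Reports contain no
timestamps, so identical config and fixtures give byte-identical outputs.
Report CSVs round to 3 decimals and render CIs with an en-dash; JSON carries
raw floats.  DSC is reported both as a proportion and as a percent.

## Problem sizes

Defaults chosen for the package's own test and demonstration runs: acceptance
reruns the full pipeline at 191/191 women (1528 images, 370 scored lesion
images) with 2000 bootstrap replicates; calibration checks use 200 random 16×16
sweep instances, 2000/2000 binormal scores, and 200 simulated datasets of
100/100 for CI coverage.

## Known limitations

* Exact-key matching can leave cases unmatched in sparse pools; no caliper or
  distance matching is offered by design.
* The percentile bootstrap can undercover for AUCs near 1 with small samples;
  BCa or DeLong intervals are out of scope.
* The optimal-threshold DSC depends on the mask's scale: very small lesions cap
  the achievable Dice of any smooth saliency field.
* Detection pools both mammographic systems; a per-system breakdown is
  available by filtering the cohort, not as a built-in stratified analysis.
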
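# Methods

This note documents the models, conventions and numerical choices behind
`stenella`, in the order the pipeline runs them. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`;
nothing is quoted from external datasets.

## Contours and acoustic parameters

A whistle contour is a strictly time-ordered trace of the fundamental
frequency (times in ms, frequencies in Hz internally; durations are
reported in seconds and frequencies in kHz). Selection rules mirror common
field practice: whistles must exceed 4 dB SNR (SNR is an input column, not
measured from audio), be separated by at least 200 ms from the previous
kept whistle in the same recording, and stay below 22.05 kHz so recordings
digitized at different rates remain comparable.

Seven parameters are extracted per contour: duration and minimum, maximum,
start, end, delta (max − min) and peak frequency. Peak frequency is the
frequency at the sample of maximum amplitude; when no amplitude track
exists the median trace frequency is substituted (a trace alone carries no
energy information). Synthetic contours always carry an amplitude track so
peak frequency is well defined.

Ecotype comparisons use the Mann–Whitney U test with mid-ranks and tie
correction; the exact null distribution is used when both groups have
n ≤ 8 without ties, the tie-corrected normal approximation otherwise.
Bonferroni correction multiplies raw p-values by the number of parameters
(7). An exhaustive label-permutation oracle pins the exact branch in the
tests.

## The synthetic generator

The generator emulates the two-ecotype structure the analysis assumes; its
defaults are the study conditions and are not tuned per experiment.

* **Contour-type mixtures** — coastal: ascending (upsweep) 45%, sine 28%,
  descending 8%, convex 8%, concave 6%, constant 5%; offshore: sine 44%,
  ascending 20%, convex 20%, descending 6%, concave 6%, constant 4%.
* **Durations** — log-normal, median 0.45 s (coastal) vs 1.10 s (offshore),
  σ = 0.45 on the log scale, so the distributions overlap but coastal
  whistles are typically at or below ~0.6 s and offshore at or above ~1 s.
* **Frequency band** — the band floor is ecotype specific (truncated
  normal, coastal 5.0 ± 1.2 kHz, offshore 8.5 ± 1.6 kHz); the bandwidth
  distribution (4.5 ± 1.5 kHz) is shared, so band ceilings overlap more
  than floors. All frequencies are clipped below the 22.05 kHz cap.
* **Peak frequency** — a per-whistle target is drawn (coastal 7.0 ± 1.2
  kHz, offshore 11.5 ± 1.5 kHz) and the unimodal amplitude envelope is
  centered on the contour point closest to it, placing coastal peaks mostly
  below 10 kHz and offshore peaks mostly above.
* **Shapes** — parametric templates: monotone ramps, single-extremum
  parabolas, ≥2-inflection sinusoids (with an optional 0.15 kHz fast
  vibrato), and flat contours confined within 1 kHz; plus 0.1 kHz Gaussian
  jitter per point.
* **Group structure** — each ecotype is split into groups whose presets are
  the ecotype preset with random ≤10% parameter offsets, so between-ecotype
  contrasts exceed within-ecotype ones in the MRPP/dispersion tests.

What the generator does *not* emulate: ocean noise, clicks and burst
pulses, recording-chain artifacts, signature-whistle repetition structure,
or realistic category abundance tails. Passing tests therefore demonstrate
that the estimators recover structure the generator encodes, not that the
field values of any statistic are reproduced; published field quantities
(category counts, field Hill estimates, field Horn/Morisita–Horn values)
are explicitly out of reach without the recordings.

An optional round trip synthesizes a tone along the contour, computes a
spectrogram (Hann window of 512 samples zero-padded to a 2048-point FFT,
87% overlap, 44.1 kHz), and re-extracts the per-frame peak frequency;
tests require a pure tone to survive within one frequency bin and a linear
sweep within two.

## DTW dissimilarity

Contours are linearly resampled to a uniform grid (1 ms by default; the
shipped analyses use 20–25 ms, which changes scores only marginally while
cutting cost quadratically). Each point carries four parameters: elapsed
time from contour onset, f₀, the central-difference slope (kHz/ms), and
vibrato amplitude — half the local peak-to-trough excursion of the residual
after removing a 50 ms moving-average trend, measured in a 50 ms window.
Parameters are divided by their pooled dataset standard deviations and
multiplied by the weights (time 10.0, f₀ 3.513, Δf₀ 2.413, vibrato 1.973).

The local cost between aligned points is the Euclidean norm of the weighted
parameter differences; DTW uses steps {(1,0),(0,1),(1,1)} and the score is
the accumulated cost divided by the warping-path length, making contours of
different durations comparable. Ties in accumulated cost resolve toward
shorter paths, a convention shared by the exhaustive-path oracle so the
dynamic program is testable to machine precision on tiny contours. The
cost convention is recorded in the matrix metadata. Consequences asserted
as properties: identity zero, symmetry, homogeneity of degree one in the
weights, and invariance to common time shifts.

## Ordination and group statistics

* **NMMDS** — non-metric SMACOF with monotone regression (scikit-learn),
  best of several random restarts, Kruskal stress-1 reported.
* **k-medoids** — PAM (greedy BUILD, steepest-descent SWAP, ties to the
  lowest index) on the dissimilarity matrix; for two classes the accuracy
  is the better of the two cluster-to-label mappings and the confusion
  matrix is reported as rows = prediction, columns = reference, classes
  alphabetical.
* **MRPP** — empirical δ = Σ_g (n_g/N) · (mean within-group dissimilarity);
  the group weighting n_g/N is the common convention. E[δ] and the p-value
  come from label permutations with p = (count ≤ δ + 1)/(n_perm + 1);
  effect size A = 1 − δ/E[δ].
* **Dispersion** — principal-coordinate embedding with the Anderson-style
  correction (squared distances along negative-eigenvalue axes are
  subtracted, clipped at zero); each point's dispersion is its distance to
  its group centroid, compared by a one-way ANOVA F. Significance permutes
  the group labels and *recomputes* centroids and distances per
  permutation. The classical variant that permutes fixed residual
  distances measured anticonservative at small n (rejection ≈ 0.07 at
  nominal 0.05 with 8 points per group); the recomputing scheme is exact
  under exchangeability and calibrates to 0.05 ± 0.02 in the suite's
  500-simulation check (n = 8 per group, 199 permutations per test —
  sizes chosen to keep the calibration cheap while leaving the binomial
  error well inside the band). scikit-bio's PERMDISP is used as an
  independent cross-check on a Euclidean example, where the two
  negative-eigenvalue conventions coincide.

## ART2 categorization

Whistles are presented in a seed-fixed random order and compared by DTW to
every category's reference contour with local similarity
100·(1 − |f_a − f_b| / max(f_a, f_b)), averaged along the optimal path; an
input joins the best category if similarity ≥ vigilance (default 96%) and
founds a new one otherwise. The reference is updated by warping the member
onto it (averaging member points aligned to each reference index) and
taking a running mean with weight 1/(category size); a fixed learning rate
can be set instead. Passes repeat until none of the whistles changes
category (converged) or `max_iterations` is hit, in which case the result
is returned flagged unconverged. Properties pinned by tests: a partition is
always produced, duplicates collapse to one category, category count is
non-decreasing in vigilance, and two constructed families with
intra-similarity ≈ 99.5% and inter-similarity ≈ 67% resolve to exactly two
categories at 96% vigilance across presentation orders.

Reference contours are assigned to the six-class taxonomy: constant if the
total excursion is ≤ 1 kHz; otherwise direction reversals of the smoothed
trace (moving average over 10% of the length) are counted with a 0.5 kHz
hysteresis so jitter does not create inflections — none: ascending or
descending by net slope; one: convex (up-then-down) or concave; two or
more: sine. "Ascending" and "upsweep" are synonyms, as are "descending"
and "downsweep". A category is *shared* between ecotypes iff it contains
at least one whistle of each.

## Random-forest classification

The forest is scikit-learn's (300 trees); everything reported is computed
natively so each number's definition is explicit. The split takes
⌈0.67·n⌉ whistles of each ecotype for training. mtry is tuned by mean ROC
AUC over 10-fold × 3-repeat stratified CV (ties to the smaller mtry); a
single-value grid skips CV. Evaluation: test confusion matrix (rows =
prediction, columns = reference), accuracy with the exact Clopper–Pearson
interval, Cohen's κ from the marginals (with balanced references κ reduces
to 2·accuracy − 1, asserted as a consistency check), OOB error, MDA as the
mean per-tree decrease in out-of-bag accuracy when a predictor is permuted
(tree bootstrap indices reconstructed from each tree's random state; a
test guards the reconstruction by checking the OOB fraction ≈ e⁻¹), MDG as
impurity importance, and partial dependence on a 50-point grid of each
predictor over the test set, on the coastal-probability scale. The Pearson
correlation screen flags |r| > 0.8 pairs but never drops features
silently.

## Diversity and repertoire similarity

Hill numbers: ⁰D = richness, ¹D = exp(Shannon entropy), ²D = inverse
Simpson. Asymptotic estimates: Chao1 for q = 0 (bias-corrected form
f₁(f₁−1)/2 when f₂ = 0), the Chao–Jost entropy estimator exponentiated for
q = 1, and the minimum-variance unbiased Simpson estimator inverted for
q = 2. An assemblage of only singletons is flagged unreliable. Coverage
and its rarefied/extrapolated forms use the standard f₁/f₂ formulas.

Rarefaction is exact: richness by the hypergeometric expectation, Shannon
by the exact expectation of subsample entropy (summing the hypergeometric
pmf per category — validated against exhaustive subsample enumeration at
n ≤ 12), and q = 2 by the closed form valid at any m. Extrapolation uses
the Chao1-based unseen-richness formula for q = 0, blends observed and
asymptotic entropy by sample fractions for q = 1, and the same closed form
for q = 2. Bootstrap CIs (default 200 replicates, 84% level — the
non-overlap convention approximating a pairwise 5% test) resample from the
coverage-adjusted bootstrap assemblage with the unseen mass spread over
the estimated number of unseen categories. Diversity at a target coverage
(e.g. 90.25%) inverts the coverage-size relation by bisection and errors
if the target exceeds the attainable extrapolated coverage.

Similarity: Morisita–Horn = 2Σp_iq_i/(Σp_i² + Σq_i²) (invariant to scaling
either count vector) and Horn = 1 − [H((p+q)/2) − (H(p)+H(q))/2]/ln 2 with
equal pooling weights, both in [0, 1].

The ecotype-specificity test permutes whistle ecotype labels while
preserving category sizes and per-ecotype totals (both margins of the
observed table fixed); the statistic is the fraction of single-ecotype
categories, and the two-tailed p counts permutations at least as far from
the permuted mean as the observed value, with the (count+1)/(n_perm+1)
correction. A quantile rule (doubled one-sided tail) is available behind a
flag; the distance-from-mean rule is the default.

## Pipeline and reproducibility

Stages run in the order simulate → features → dtw → ordinate → mrpp →
categorize → classify → diversity, each writing its artifact and a block
of `summary.json`; a stage can be skipped when its artifact exists, and a
missing upstream artifact is reported by name. One top-level seed expands
to per-stage seeds as (seed·1009 + stage index) mod 2³¹, so stages rerun in
isolation reproduce. Identical configurations produce byte-identical
summaries (floats are rounded to six decimals on serialization).

Problem sizes in the shipped runs: the analysis drivers use 100 whistles
per ecotype with 20 ms DTW/ART grids and a full 1–7 mtry grid; the
acceptance script uses the full 466 per ecotype for feature-level
analyses and 60 per ecotype (20 ms grids, fixed mtry = 2) for the
DTW/ART-bound pipeline block. These sizes are the package's default
desk-scale configuration; all estimators accept arbitrary n.

## Known limitations

* Luscinia's and ARTwarp's exact internal cost functions are not public;
  the DTW and similarity conventions here are fully specified alternatives,
  recorded in output metadata, and pinned by property tests rather than by
  comparison to those programs' scores.
* The q = 1 extrapolation is a smooth interpolant between the observed and
  asymptotic entropy, accurate near the sample and at the asymptote but
  heuristic in between.
* The synthetic generator's abundance structure is richer in rare
  categories than a field repertoire need be; asymptotic estimators are
  validated on their own terms (oracles, saturated samples, Zipf
  recovery), not against field tables.
* MDA relies on reconstructing scikit-learn's per-tree bootstrap indices
  from private helpers; a dedicated test fails loudly if that contract
  changes.
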
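# stenella

Whistle-repertoire analysis for pantropical spotted dolphin (*Stenella
attenuata*) ecotypes: from fundamental-frequency contours to repertoire
diversity.

Pantropical spotted dolphins in the Eastern Tropical Pacific occur as two
diverged ecotypes, coastal and offshore, whose habitats differ acoustically.
This package implements the full comparative pipeline used to ask whether
their whistle repertoires have diverged: acoustic feature extraction from
frequency contours, multi-feature dynamic-time-warping (DTW) dissimilarity,
ordination and permutation tests of group structure, unsupervised ART2
categorization of contours, random-forest ecotype classification, and
Hill-number repertoire diversity with coverage-based rarefaction and
extrapolation. Because the field recordings are available only on request,
a first-class synthetic contour generator reproduces the statistical
structure the analysis assumes (contour-type mixtures, duration and
frequency shifts, group structure), so every stage is testable end to end.

It is written for bioacousticians and quantitative ecologists who want the
individual estimators (they are all importable functions) or the whole
pipeline (a `stenella` CLI and numbered drivers under `analysis/`).

## Methods at a glance

* **Acoustic parameters** per whistle: duration *D* (s) and, in kHz, minimum
  (MF), maximum (MXF), start (SF), end (EF), delta (DF = MXF − MF) and peak
  (PF, frequency at maximum amplitude). Ecotypes are compared per parameter
  by Mann–Whitney U with Bonferroni correction.
* **DTW dissimilarity**: contours resampled to a common grid are described
  per point by time, fundamental frequency f₀, slope df₀/dt, and vibrato
  amplitude; parameters are scaled by their dataset standard deviations,
  weighted (time 10.0, f₀ 3.513, Δf₀ 2.413, vibrato 1.973), and aligned by
  classic DTW; the score is the accumulated weighted-Euclidean cost per
  warping step.
* **Group structure**: non-metric MDS (Kruskal stress-1), PAM k-medoids
  (k = 2) scored against ecotype labels, MRPP with effect size
  A = 1 − δ/E[δ], and a PERMDISP-style dispersion test (Levene-type F on
  distances to group centroids in principal-coordinate space).
* **Categorization**: an ART2 network with DTW similarity
  100·(1 − mean |f_a − f_b| / max(f_a, f_b)) and 96% vigilance; category
  references are warped running means, and reference contours are assigned
  to the six-class taxonomy (ascending, descending, convex, concave, sine,
  constant).
* **Classification**: a 300-tree random forest on the seven parameters
  (67/33 stratified split, mtry by repeated-CV ROC AUC), evaluated natively:
  confusion matrix, exact Clopper–Pearson CI, Cohen's κ, out-of-bag
  permutation importance (MDA), impurity importance (MDG), and partial
  dependence.
* **Diversity**: Hill numbers ^qD for q = 0, 1, 2 (observed, Chao-type
  asymptotic), sample coverage Ĉ = 1 − (f₁/n)·(n−1)f₁/((n−1)f₁+2f₂),
  coverage-based rarefaction/extrapolation with bootstrap CIs, Horn and
  Morisita–Horn similarity, and a permutation test for ecotype-specific
  categories.

## Worked example

```sh
stenella run --outdir results/demo --seed 7 --n-per 100
stenella report results/demo/summary.json
```

or equivalently `python analysis/01_simulate.py` … `06_diversity.py`. With
the shipped `analysis/config.yaml` (100 whistles per ecotype, seed 7) the
report reads:

```
k-medoids clustering (rows = prediction, cols = reference ['coastal', 'offshore']): accuracy 82.50%
    coastal: [97, 32]
   offshore: [3, 68]

Random forest: accuracy 96.97% (95% CI 89.48-99.63%), kappa 0.94, OOB error 5.22%, mtry 5
    coastal: [32, 1]
   offshore: [1, 32]

ART categorization: 55 categories (converged: True in 7 passes)
  sharing: {'shared': 11, 'unique_coastal': 30, 'unique_offshore': 14}

Hill diversity (observed / asymptotic):
    coastal: q0 41.0/65.0  q1 26.2/37.7  q2 16.2/19.2  coverage 78.2%
   offshore: q0 25.0/35.0  q1 17.0/20.5  q2 13.1/14.9  coverage 91.1%
  Horn 39.19%, Morisita-Horn 38.84%
  ecotype-specific categories: 80.00% observed vs 57.01% permuted mean (p = 0.0010)
```

Reading it: blind k-medoids recovers the ecotypes imperfectly (82.5%) while
the supervised forest does much better — the repertoires overlap but are
separable, and the most informative predictors are peak frequency, duration
and minimum frequency. At 96% vigilance the 200 whistles fall into 55
contour categories, most specific to one ecotype (80% observed vs 57%
expected under label permutation, p ≈ 0.001): the synthetic coastal
repertoire is dominated by ascending contours and the offshore one by sine
contours, mirroring the field pattern.

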
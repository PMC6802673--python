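# Methods

## The modelling problem

The package classifies fetal skeletal development performance — whether a
bone measurement (femur/humerus weight, length, diameter: Fw, Fl, Fd, Hw,
Hl, Hd) is *low* or *high* — from a six-protein serum bone-turnover panel
(PTH, BALP, BGLAP, TRAP, INTP, CTX-I) measured in pregnant goats and their
fetuses under a 2×2×2 factorial design of experimental conditions (ECs):
animal type (fetus/mother), maternal nutrition (control vs. restricted
intake), and gestation period (middle/late). The data are small (tens of
animals), so the pipeline is built around leave-one-out cross-validation
(LOOCV) and an exhaustive comparison of feature encodings rather than a
single model fit.

## Output binarisation

Bone measurements of fetuses and mothers differ by orders of magnitude. Each
output is therefore robust-scaled *within each animal type* —
(x − median)/IQR, quartiles by linear interpolation — and thresholded at 0
(the image of the median). A pooled scaling would make the classes encode
fetus-vs-mother rather than low-vs-high. Ties at the median fall to class 0:
deterministic, and consistent with the median mapping to 0 under the robust
transform. A zero IQR yields all-zero scaled values; an output constant
within an animal type is an error (classes undefined).

## Experiment-centered (MA) features

For record *j*, protein *p* and an EC grouping *i* (any non-empty subset of
the three axes; all three jointly is the "mixed"/`experim` grouping):

    MA_ij = mean_{k in group i(j)} p_k  −  p_j

The record itself is included in its group mean, so MA values sum to zero
within every group — a property the test suite asserts to 1e−9. The sign is
mean − value. Blocks: `MAmix` (6 columns, mixed grouping), `MAi` (18
columns, one per protein × single axis), alongside `Metab` (the 6 raw
proteins), `OneHot` (6 binary EC columns, both columns per axis retained),
`ProbECs`/`ProbMix` (empirical per-record frequencies of the record's EC
category/cell).

MA and probability features are computed on the **full table before
cross-validation**. This replicates the original analysis scripts' order of
operations and means group means leak across CV folds; it is the documented
default. `ExperimentCenteredEncoder(strict=True)` instead learns group
means on training rows only (unseen groups fall back to the fitted global
mean) for leakage-free experiments. In-pipeline robust scaling, by
contrast, is always fit on training rows only.

## Datasets, classifiers, evaluation

Twelve block combinations × six outputs give 72 datasets: the seven
non-empty subsets of {Metab, MAmix, MAi}; three probability-augmented
combinations (Metab+Probs, MAmix+Probs, MAmix+Metab+Probs); and the two
one-hot arms (OneHot+Metab, OneHot) for the encoding comparison. The
combination list is configuration — any list of block combinations can be
supplied — with the chosen default documented here because the original
enumeration is not recoverable in full.

Seven classifier families are evaluated per dataset, every hyperparameter
pinned (library "defaults" drift across versions): k-nearest-neighbours
(k=5, uniform), linear-kernel SVM (C=1), RBF-kernel SVM (C=1,
gamma=1/(n_features·Var(X))), L2 logistic regression (C=1, lbfgs),
decision tree (Gini, unlimited depth), random forest (100 trees), XGBoost
(100 rounds, learning rate 0.1, depth 3). Stochastic families take an
explicit seed (default 42); XGBoost runs single-threaded for bitwise
reproducibility. Each fit is a pipeline: robust scaler (training rows only)
then classifier.

LOOCV is scored as pooled accuracy over the n held-out predictions —
per-fold balanced accuracy is degenerate for single-record folds. k-fold CV
(k ∈ {2,3,5,10}, stratified, seeded shuffle) is scored as mean per-fold
balanced accuracy = (sensitivity + specificity)/2; a fold missing a class
contributes that class's recall as 0, with a warning, rather than silently
averaging over present classes. A single-class *training* set (possible
when a class has one member) predicts that class, with a warning. Best
models are the per-output argmax, ties broken by fewer input columns, then
by the fixed family order above.

Two LOOCV behaviours worth knowing on small balanced data: (1) a
majority-vote baseline on perfectly balanced labels scores exactly 0 (the
held-out label is always the training minority — the "flip" property), and
(2) near-chance classifiers consequently score slightly *below* 0.5.
Single-feature models under a label-permutation null inherit this strongly
(simulated mean ≈ 0.2, not 0.5); multi-feature null models sit near 0.46.

## Feature importance

For each best model, every input feature is removed in turn and LOOCV
recomputed; delta = new − pool score. Negative delta marks an important
feature, positive delta marks noise; ranking is by ascending delta. Only
single-feature removals are performed. One-feature models rebuild the same
classifier on each single input column. `refine_best` adopts the reduced
model of the single removal with the largest strictly positive delta, else
keeps the pool model.

## Synthetic data

The generator emulates the study's shape so the pipeline is fully testable
without the animal records. Per design cell, proteins are drawn from
normals truncated at 0 (rejection sampling) with cell means taken from the
study's descriptive group summaries and SD = SEm·√7 (√ of a typical cell
size; actual cells held 4–10 animals). Normality is a declared assumption —
only means and standard errors are known. Bone outputs follow *planted
links*: output = intercept(animal) + β·z + N(0, σ), where z is a chosen
protein centred within a chosen EC grouping and scaled to unit SD. Because
the effect lives in within-group deviations, the MA encoding is the correct
representation by construction, and the one-hot arm's disadvantage on
interaction effects is reproducible as a testable property. Defaults: one
link per output, each from a distinct protein, mixed-EC grouping, β=1,
σ=1/3 (signal/noise 3 — strong but not trivial). A `threshold` link kind
reassigns the planted protein to exactly two levels per cell (cell mean ±
cell SD, balanced, odd record low), giving noiseless two-cluster
separability when σ=0 — a diagnostic configuration; it is cleanest for
proteins whose cell SDs are of comparable magnitude (e.g. TRAP).

`generate_study_standin` draws a table with the study's unbalanced cell
sizes (fetus 10/10/6/8, mother 9/6/4/5 across treatment×period; two records
then dropped at random, landing on the 56 integrated records). It is a
synthetic stand-in: it reproduces the design shape and measurement
magnitudes, **not** the original measurements, so accuracies computed from
it are properties of the synthetic draw. The end-to-end tests that compare
against the originally reported accuracies run on this stand-in and
document that caveat.

What the synthetic data does not emulate: within-animal correlation between
the six proteins beyond the planted link, litter effects (several fetuses
per mother), longitudinal structure, assay floor/ceiling artefacts, and
abortion/dropout. Passing tests on synthetic data therefore demonstrate
the pipeline's correctness and the encodings' relative behaviour, not
biological conclusions about real goats.

## Problem sizes and numerical choices

Default verification sizes: 56-record tables (n=7 per cell or the study's
cell sizes), 20 seeded replicates for recovery/null simulations, full
72×7 = 504-model grids for end-to-end runs. The MA zero-sum tolerance is
1e−9 absolute; robust-scale agreement with its brute-force oracle is
asserted to 1e−12. All randomness descends from explicit integer seeds;
identical configuration and input give byte-identical CSV outputs.

## Known limitations

* Full-table MA computation leaks group means across CV folds by design
  (matching the original procedure); use strict mode to quantify the
  effect.
* LOOCV pooled accuracy has high variance at n=56; one fold is ±0.018.
* The probability features are constants per EC category and nearly
  constant across records in a balanced design; they mostly matter for
  unbalanced tables.
* Removal importance is single-step; correlated features can mask each
  other.
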
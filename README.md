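# bonemetab

Classification of fetal skeletal development performance from serum
bone-turnover biomarkers, for researchers modelling small factorial animal
studies. The package reimplements, as a tested reusable pipeline, a
goat-gestation analysis in which six serum proteins (PTH, BALP, BGLAP,
TRAP, INTP, CTX-I) measured under a 2×2×2 design — animal type
(fetus/mother) × maternal nutrition (control/restricted) × gestation period
(middle/late) — are used to predict whether six bone outputs (femur and
humerus weight, length, diameter) are low or high.

## The method

The central feature-engineering device is the *experiment-centered* ("moving
average", MA) encoding, which mixes the categorical experimental conditions
(ECs) into the continuous inputs. For record *j*, protein *p* and an EC
grouping *i*:

    MA_ij = Avg_i(p_j) − p_j

i.e. the mean of the protein over all records sharing *j*'s EC values on
the grouping's axes, minus the record's own value. `MAmix` centres within
the joint grouping of all three axes (6 features), `MAi` within each single
axis (18 features). These compete against raw inputs (`Metab`), one-hot EC
encoding (`OneHot`) and EC frequency features (`ProbECs`, `ProbMix`) across
a default enumeration of 12 block combinations × 6 outputs = 72 datasets,
each evaluated with 7 pinned classifier families (kNN, linear/RBF SVM,
logistic regression, decision tree, random forest, XGBoost) under
leave-one-out cross-validation (pooled accuracy) or stratified k-fold
(balanced accuracy). Outputs are binarised by robust scaling within each
animal type with a cutoff at 0. Best models per output are then probed by
removal-based feature importance (delta = accuracy without the feature −
pool accuracy; negative = important, positive = noise) and by one-feature
models. A synthetic-data generator with planted protein→bone links at the
study's measurement magnitudes makes every stage verifiable without the
animal data.

## Worked example

```python
from bonemetab import (SyntheticConfig, generate_synthetic_study, DatasetSpec,
                       assemble, loocv_accuracy, importance_by_removal)

table = generate_synthetic_study(SyntheticConfig(seed=7))
print(f"records: {len(table)}")

dataset = assemble(table, DatasetSpec("Hw", ("MAmix",)))
pool = loocv_accuracy(dataset, "SVM linear")
print(f"pool LOOCV accuracy (Hw ~ MAmix): {pool.score:.3f}")

for r in importance_by_removal(dataset, "SVM linear", pool_score=pool.score)[:3]:
    print(f"removed {r.removed_feature:>18}: acc {r.score:.3f} (delta {r.delta:+.3f})")
```

prints

```
records: 56
pool LOOCV accuracy (Hw ~ MAmix): 0.804
removed    MA-INTP-experim: acc 0.554 (delta -0.250)
removed   MA-CTX-I-experim: acc 0.732 (delta -0.071)
removed     MA-PTH-experim: acc 0.821 (delta +0.018)
```

The synthetic table plants INTP (centred within the mixed EC grouping) as
the driver of humerus weight at signal/noise 3: the pool model classifies
low/high Hw at 0.804, removing the planted feature costs 0.250 accuracy
(most important by the removal ranking), and removing MA-PTH-experim
slightly *improves* the model — that feature is noise here, so the refined
best model would drop it.

The same stages run from the shell via the `bonemetab` CLI
(`simulate`, `integrate`, `encode`, `list-datasets`, `grid`, `best`,
`importance`, `onefeature`, `report`); `bonemetab report --input table.csv
-o outdir` executes everything and writes the CSV report bundle.

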
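# medsup — median-supplement balancing for imbalanced binary classification

Binary classifiers trained on imbalanced data — 86 receptor-negative vs 14
receptor-positive breast-cancer samples, 1589 plasma-membrane vs 1046
nuclear proteins — inherit the imbalance as a bias toward the majority
class. `medsup` implements the *median-supplement* correction for such
two-class tabular problems: instead of resampling or interpolating existing
minority instances, it manufactures the missing instances from the
per-attribute medians of the training set.

Given a training set with class counts n₁ > n₂ and n attributes:

1. compute the median **m**ⱼ of each attribute j over all instances;
2. draw an m × n matrix **U** of uniform random numbers on [0, 1), where
   m = n₁ − n₂, and form the supplement S with Sᵢⱼ = mⱼ · Uᵢⱼ;
3. append S, labelled with the minority class, to the training set — the
   result is exactly balanced;
4. fit an ordinary classifier to the balanced set.

Two backends are provided, selected by a method switch:

- **MSNaiveBayes** — Gaussian naive Bayes on the balanced set. The class
  posterior is P(Cⱼ|G) ∝ P(Cⱼ) ∏ᵢ P(gᵢ|Cⱼ) with each P(gᵢ|Cⱼ) a univariate
  Gaussian; the evidence P(G) cancels between classes.
- **MSRandomForest** (the default) — a random forest on the balanced set:
  B trees on bootstrap resamples, ⌊√n⌋ random candidate attributes per
  Gini split, prediction by majority vote C_B(x) = majority{C_b(x)}.

The plain variants (`NaiveBayes`, `RandomForest`) skip balancing, enabling
the four-way comparisons of the evaluation protocol: classification rate
(correct / total), confusion matrices, repeated stratified k-fold
cross-validation with balancing applied *inside* each training fold, and
Mann–Whitney U comparison of per-fold rate samples.

## Worked example

Train on an imbalanced expression-like table and classify a labelled test
set (both generated by the built-in fixture module):

```python
import medsup

train, test = medsup.her2_like_pair(seed=4)    # 86/14 train, 51/11 test
print(train.class_counts())

balanced = medsup.balance(train, seed=3)
print(balanced.class_counts(), int(balanced.is_synthetic.sum()))

report = medsup.independent_test(train, test, "MSNaiveBayes", seed=3)
print(f"classification rate: {report.rate:.4f}")
print(report.confusion)
```

prints

```
{'Negative': 86, 'Positive': 14}
{'Negative': 86, 'Positive': 86} 72
classification rate: 0.9839
predicted   Negative   Positive
Negative          51          1
Positive           0         10
```

The 86/14 training set needs m = 86 − 14 = 72 synthetic minority rows to
balance; the fitted model then classifies 61 of the 62 test instances
correctly, calling one positive sample negative. The same run from the
shell:

```sh
medsup --train train.csv --test test.csv --method MSNaiveBayes --seed 3 \
       --out-predictions pred.csv --report report.tsv
```

Training files are delimited text with a header, instances in rows,
attributes in columns and the class label in the last column; test files
carry the same attribute columns, with the label column optional (when
present, the report adds the confusion matrix and classification rate).
Omitting `--test` writes only the fitted model, and omitting `--method`
applies the median-supplement random forest.

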
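# Methods

## The balancing model

`medsup` addresses two-class classification of numeric tabular data when
the class counts n₁ > n₂ are unequal. The median-supplement scheme makes
the training set exactly balanced by appending m = n₁ − n₂ synthetic
instances:

- the per-attribute medians mⱼ are taken over **all** training instances
  (the literal recipe; `median_scope="minority"` restricts them to
  minority-class instances, a plausible variant that is also shipped and
  tested — both behave identically on the supplement's defining property,
  values in [0, mⱼ]);
- a fresh m × n matrix of uniform draws on the half-open interval [0, 1)
  scales each median column-wise. The endpoints of "between 0 and 1" are
  a convention choice; [0, 1) is the native range of the generator and the
  probability of hitting an endpoint is zero anyway;
- the synthetic rows carry the **minority** label. No other labelling
  yields a balanced set, which is the point of step 3;
- a single supplement is generated per model fit (not, e.g., per forest
  tree): balancing is a data-preparation step that precedes model
  inference;
- negative attribute values are legal; the formula is applied verbatim, so
  a negative median yields supplement values in [mⱼ, 0].

Implications worth knowing: a median-scaled uniform has mean mⱼ/2 and
standard deviation mⱼ/√12 ≈ 0.29 mⱼ, independently across attributes. The
supplement therefore represents the minority class faithfully only when
that class genuinely occupies the low half of each attribute's range with
a comparable spread. When it does not, the supplement distorts the
minority class-conditional distribution — visible in this package as the
plain naive Bayes beating its median-supplement variant on the
localization-like fixture, and reported for the real localization data in
the study this method comes from.

## Classifier backends

**Gaussian naive Bayes.** Class-conditional attribute independence with
univariate Gaussian densities. The source method leaves P(gᵢ|Cⱼ)
distribution-free; Gaussian is this package's declared choice for
continuous attributes (and the convention of the R packages the method
was originally compared against). Priors are empirical class frequencies
— hence exactly (0.5, 0.5) after balancing. Scale estimates use the
unbiased n−1 divisor and are floored at
`scale_floor = 1e-9 · (pooled attribute variance + 1)` so constant
attributes cannot produce infinite densities. All computation is in log
space; the evidence term is never formed; normalized posteriors use
log-sum-exp. Exact posterior ties resolve to the lexicographically first
class level, purely for determinism.

**Random forest.** CART-style trees on bootstrap resamples (with
replacement, original size). At each node `mtry` candidate attributes are
drawn without replacement; thresholds are tested at midpoints between
consecutive distinct sorted values; the split minimizes the children's
weighted Gini impurity, with ties broken by (lowest attribute index,
lowest threshold). Nodes stop at purity or at `min_node_size` (default 1);
an unsplittable mixed node becomes a majority leaf, ties again to the
first level. Defaults: 500 trees, mtry = ⌊√n⌋ — the customary
classification-forest subset size; the source text's "m = n" line
contradicts its own feature-subset step and is not followed (both values
are configurable). Vote ties across trees resolve to the first class
level. With one tree, no bootstrap and mtry = n the forest reproduces the
single deterministic tree exactly, which the tests exploit as an oracle.

## Evaluation protocol

The sole performance measure is the classification rate (correct/total);
confusion matrices are reported predicted × true. Cross-validation is
stratified (per-class shuffle, round-robin deal): with a 14-instance
minority class, unstratified 10-fold CV can produce minority-free folds.
Balancing runs *inside* each training split, after fold assignment, so a
held-out fold can never contain synthetic instances; `kfold_cv` can
retain per-fold records so tests audit this directly. Rate samples for
the Mann–Whitney comparison are per-fold rates pooled over repeats
(default 10). The U statistic counts pairs where the first sample exceeds
the second; p-values are two-sided, exact by enumeration when
min(n₁, n₂) ≤ 8 and the pooled sample is tie-free, otherwise the normal
approximation with tie and continuity corrections (scipy's
implementation stands behind this operation; an independent enumeration
oracle checks the exact branch in the tests).

## Synthetic fixture families

No real datasets ship with the package; two generated families emulate
the study data's shape so everything is testable offline.

**Expression-like pair** (`her2_like_pair`): 86/14 training and 51/11
test tables, 10 positive continuous features. Per-feature majority means
are drawn uniformly from [100, 400]; minority means are 0.48× the
majority mean and the shared within-class standard deviation is 0.35× —
i.e. a within-class coefficient of variation of 35%, a realistic order
for expression panels. These two ratios are deliberate: the pooled
per-feature median sits near the majority mean, so a median-scaled
uniform supplement centres at ~half the majority level with spread
0.29×, closely matching the minority class-conditional distribution.
That is the regime in which the median-supplement mechanism is coherent
(supplements land in minority territory), and it makes the direction
property — balanced-prior naive Bayes recovering minority sensitivity
that the 0.86/0.14 empirical priors suppress — a property of the model,
not of a tuned seed. Draws are clipped below at 0, mimicking
floor-censored expression values.

**Localization-like table** (`subcellular_like`): 2635 instances split
1589 (plasma-membrane) / 1046 (nucleus), 126 bounded positive features on
a percent-composition scale (majority means uniform on [2, 30], minority
0.8×, sd 0.6×). Here the minority class is *not* centred at half-median,
so the supplement mismatches it — intentionally mirroring the data regime
in which the median-supplement naive Bayes was observed to trail the
plain one while the two forests stay statistically indistinguishable.
An `n_instances` argument scales the table down proportionally (keeping
the 1589:1046 ratio) for desk-scale runs.

What the fixtures do **not** model: feature covariance, heavy tails,
batch effects, or any biological structure. Passing tests demonstrate the
mechanics and the direction of the balancing effect under the generative
assumptions, not performance on real expression or proteome data.

## Numerical and interface choices

- Class levels are ordered lexicographically everywhere (matching R
  factor semantics); all tie-breaks point to the first level.
- File I/O: delimiter auto-detection between comma and tab (overridable);
  floats written to 10 significant digits, so read∘write is the identity
  at that precision; missing values are a hard error — the method has no
  imputation story.
- Test-set label detection: a trailing column is treated as truth labels
  when its name matches the training label column or all its entries are
  known class levels; detection is deterministic and order-independent.
- Seeds: every stochastic step (supplement, bootstrap, feature draws,
  fold shuffles) derives from one user seed via `numpy` seed sequences.
  The CLI draws and logs a seed when none is given, since the
  augmentation is otherwise unreproducible. For a fixed seed, a
  median-supplement method on already-balanced input is bit-identical to
  its plain counterpart (the m = 0 fixed point).
- The CLI exposes the plain methods alongside the median-supplement ones
  although the original tool surfaced only the latter: the published
  evaluation is a four-way comparison and reproducing it requires all
  four.

## Problem sizes in the shipped scripts

`scripts/acceptance.py` uses 200-tree forests and scales the
localization-like family to 600 instances for its 5-fold CV block; the
expression-like blocks run at the fixture's native 100/62 sizes with
10-fold CV × 10 repeats. These sizes keep the full recomputation at a
couple of minutes on one core while leaving every reported quantity
well-resolved; tree count and instance count are ordinary accuracy/cost
knobs, and the defaults in the library itself remain 500 trees and the
native 2635-instance table.

## Known limitations

- Binary problems only; multi-class imbalance is out of scope.
- The supplement ignores attribute covariance: synthetic instances are
  axis-independent even when the minority class is correlated.
- Gaussian class-conditionals make the naive Bayes backend sensitive to
  the floor-censoring spike at 0 in heavily clipped data.
- The published accuracies on the archived real datasets are not
  reproducible without downloading them; with those files supplied, the
  evaluation module supports the same protocol (10-fold / 5-fold CV,
  Mann–Whitney comparisons) for an integration-style check.
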
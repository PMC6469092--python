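# Methods

## Model family and fitting procedure

For a numeric, two-class or K-class response measured on N samples with p
features, the package fits one elastic-net GLM per mixing parameter α and
assesses each against permutation nulls.  The penalized objective follows
the glmnet parametrization: loss averaged over in-bag samples plus
λ(α‖β‖₁ + (1−α)/2‖β‖₂²).  Coordinate descent (scikit-learn `enet_path`)
solves the linear family for α > 0; at α = 0 the ridge solution is computed
in closed form from the SVD of the standardized in-bag design, which is
exact and avoids coordinate descent's unreliability at vanishing L1 weight.
Binomial and multinomial fits use the saga solver with warm starts along
the descending λ path, with the penalty mapped via C = 1/(n_ib·λ).

Features are standardized to zero mean and unit (population) variance using
**in-bag statistics only**; out-of-bag rows never influence training, and
reported coefficients are transformed back to the original feature scale so
κ is comparable across folds.  The λ path is computed once per α from the
full data: λ_max = max_j |⟨x_j, r⟩| / (N·max(α, 0.001)) with r the
null-model residual, descending geometrically over `n_lambda` points to
λ_max·`lambda_min_ratio` (10⁻⁴ when N > p, else 10⁻²).  Sharing one grid
across runs, folds and permutations makes QF(λ) curves directly comparable.
The optional symmetric extension keeps the log-spacing constant and gives
the odd extra point to the small-λ side — the informative end for dense
models; a fixed rule is needed for reproducibility.

λ\* maximizes the unweighted mean over runs of the OOB quality function;
an exact tie picks the larger (more regularized) λ for parsimony.  A λ
whose QF is undefined in any run (e.g. zero-variance predictions at the
path top) is treated as worst possible.  A flat profile or a boundary
maximum triggers a warning, since it suggests the λ range should be
extended.  λ\* is family-level: the same λ\* serves every run, and the
per-run QF values at that single λ\* feed the significance comparison.

## Quality functions

Defaults per family: correlation for linear (Pearson, Spearman or Kendall),
accuracy for binomial, average accuracy for multinomial.  Average accuracy
is the macro-average over classes of the one-vs-rest binary accuracies
(tp+tn)/m — like plain accuracy it is invariant under simultaneous
relabelings of the classes, which matters because permutation nulls must
not be an artifact of label identity.  Precision, recall, F1, specificity
(macro-averaged variants for K > 2) and Mann–Whitney AUC (ties credited ½,
computed from midranks) are offered but are not label-permutation
invariant.  Binomial class prediction thresholds the positive-class
probability at 0.5, ties going to the first class in sorted label order;
the positive class is the second sorted label, matching the reference-level
convention of GLM software.  An undefined QF value (zero variance, empty
confusion-matrix denominator, single-class AUC) is a NaN sentinel: worst
possible during λ\* selection, dropped with a logged count from
significance comparisons — counting it as 0 would bias p-values.

## Feature statistics

Within a run, ν is the fraction of folds assigning the feature a non-zero
coefficient and κ the mean of its non-zero coefficients; κ is missing when
the feature is never selected in the run.  Across runs, frequency uses the
plain mean and sample (ddof = 1) standard deviation; the coefficient uses
ν-weighted mean and the population-form weighted standard deviation, which
stays well-defined even when a single run carries all the weight.  For
multinomial models every statistic is computed per class; a feature can be
significant for one class only.  Intercepts are excluded throughout.

## Permutation nulls and empirical significance

Each of the n_r × n_p null models permutes the response's sample labels
uniformly at random (feature matrix untouched), refits the cross-validation
models at the model's λ\* using the **same fold assignments** as the model
arm, and records QF, ν and κ.  Nulls are deliberately not re-tuned per
permutation: λ\* is part of the fitted model being tested, and re-tuning
would answer a different question; this choice affects conservativeness and
is the main reason null selection frequencies can be substantial at weakly
sparse α.  The empirical p-value is
(1 + #{(r,p): null ≥ model_r}) / (1 + n_r·n_p): ties count against the
model, so p is bounded below by 1/(1 + n_r·n_p) and the estimate is
conservative under sampling permutations with replacement.  Feature
p-values substitute ν or |κ| (missing κ enters as 0 — an unselected feature
has no effect size, conservative for the model arm).  Undefined entries are
dropped from numerator and denominator with a logged count; more than 20%
undefined is a hard error.  Annotations follow the conventional scheme:
··· p<0.1, * p<0.05, ** p<0.01, *** p<0.001, all strict inequalities.

A known ceiling of the frequency statistic: once ν_model = 1 (always true
for ridge, and typical for strong features at lasso λ\*), a feature's
minimal attainable frequency p equals the fraction of null models that also
select it in every fold, plus the 1/(1+n_r·n_p) offset.  Because one
permutation's spurious correlations persist across all folds of that null
model, this fraction is not negligible at moderate λ\*; the |κ|-based
p-value does not saturate and is the sharper feature test in that regime.

## Randomness and determinism

All randomness derives from one master seed through named `SeedSequence`
streams: fold assignments from (seed, run) — hence shared across α, keeping
QF(α) curves comparable — and permutations from (seed, α-index, run,
permutation), so ensembles are independent across α but fully reproducible.
Identical inputs, configuration and seed give byte-identical archives
(floats written at 12 significant digits); archives therefore carry seed
and package version but no timestamps.

## Synthetic data generator

Designs are multivariate normal with independent, equicorrelated-block
(ρ within blocks of `block_size`) or AR-decay (ρ^|i−j|) covariance — the
canonical structures spanning ridge-favoring (many correlated weak signals)
and lasso-favoring (few independent strong signals) regimes.  Linear
responses are y = Xβ + ε with β = ±effect_size on the first
`n_true_features` (alternating signs) and Gaussian noise, giving the closed
form R² = s·b²/(s·b² + σ²) for independent features; categorical responses
draw labels from a softmax over K linear scores with disjoint true-feature
blocks per class.  The generator emulates the covariance-vs-sparsity
structure the method is designed to explore, not the heavy tails, batch
effects, missingness or feature-count scales of real omics data — passing
tests demonstrate correct mechanics and calibration of the procedure, not
performance guarantees on any particular biological dataset.

Study conditions used by the test suite and acceptance script, chosen once
as representative regimes: sparse-signal recovery at N=100, p=50, 5 true
features of effect 1.0 in unit noise (n_r=10, n_f=5, n_p=10, lasso); null
calibration at N=60, p=30, zero effect, 100 replicates (n_r=5, n_p=10,
lasso); multinomial at N=120, p=30, 3 classes × 3 true features of effect
2.0 (α=0.2, n_lambda=20).  The categorical path uses a shorter λ grid than
the linear default because each grid point is a full saga fit rather than
one coordinate-descent path.

## Numerical choices and edge cases

- Non-zero means exactly ≠ 0: coordinate descent and saga produce exact
  zeros via soft thresholding, so no threshold parameter is needed; the SVD
  ridge solution is generically dense, giving ν ≡ 1 at α = 0.
- A constant feature column standardizes to zeros and simply never enters.
- Solver failure at a λ is retried once with 10× tolerance, then that entry
  is marked undefined and logged.
- Validation rejects missing values outright rather than imputing: no
  imputation policy is defined, and silent imputation would corrupt the
  permutation nulls.  Sample alignment across datasets is by ID, never row
  order; duplicate feature names after aggregation get deterministic
  `_2`, `_3`… suffixes.
- Multi-dataset aggregation requires identical sample-ID sets and is
  associative; stratified folds require every class to have at least
  `n_folds` members.

## Limitations

Poisson and survival (Cox) families are not implemented.  No per-run λ
selection or one-standard-error rule.  Feature p-values carry no
multiple-testing correction — the framework is exploratory, ranking
features for hypothesis generation rather than confirmatory inference.
Sparse input formats and categorical predictor encoding are out of scope
(encode before input).  The permutation scheme assumes exchangeable
samples; grouped or longitudinal designs would need restricted permutations
that are not provided.
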
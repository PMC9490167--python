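# Methods

`crossimpute` implements two-step cross-survey imputation of a latent
binary legal status: a deterministic *logical-edit* pass that proves
documented status from responses logically incompatible with being
undocumented, followed by *statistical imputation* of the residual
"possibly undocumented" pool using a model trained on a donor survey that
carries a status proxy. This note describes the models, the synthetic
data-generating process used throughout the tests, the numerical choices,
and what the package's validation does and does not establish.

## The two-step model

**Step one (logical edits).** An ordered but order-invariant disjunction of
exclusion rules — by default citizenship, Medicare coverage, veteran or
active-duty military status, and receipt of public assistance — labels a
record `doc_logical` if any rule fires. Missing values never fire a rule:
a record with unknown Medicare status stays in the pool. This conservatism
is what gives the step its defining guarantee, sensitivity exactly one — no
truly undocumented record is ever excluded — at the cost of very low
specificity (the pool retains many documented records). Medicaid is
deliberately *not* an exclusion rule: a small number of undocumented
respondents genuinely report Medicaid (state provisions for pregnant women
and children, emergency coverage, misreporting), and excluding on it would
both break the guarantee and select on poverty. Medicaid remains available
as a predictor.

**Donor truth proxy.** On the donor side, a record is treated as truly
undocumented iff it is a non-citizen that entered the country strictly
after a cutoff year (default 1981) without entering as — or later
adjusting to — lawful permanent resident status, and no exclusion rule
fires. The cutoff and rule list live in configuration, not code.

**Step two (statistical imputation).** Four backends share one interface
(fit on the donor pool, classify the target pool):

- `logit` — additive logistic regression; classify undocumented iff the
  predicted probability strictly exceeds the threshold (default 0.5).
- `mi_logit` — multiple imputation. The donor pool and target pool are
  stacked with the target status missing. After the missing-as-category
  encoding the status is the only incomplete variable, so the
  chained-equations scheme reduces exactly to its single logistic
  conditional: fit the status model on the complete rows, then for each of
  M (default 10) imputations draw a coefficient vector from the
  approximate sampling posterior N(b̂, (XᵀWX + λI)⁻¹) and draw Bernoulli
  labels from the implied probabilities. Analyses run per completed
  dataset are pooled with Rubin's rules; correlations are pooled on the
  Fisher-z scale.
- `knn` — k-nearest neighbours, Euclidean distance on min-max-scaled
  numerics and one-hot categoricals (scaling fit on training data only);
  majority vote with default k = 31, optionally tuned over a grid by
  repeated stratified cross-validated accuracy.
- `rf` — random forest of 500 trees (bootstrap rows, a random predictor
  subset per split, square-root rule by default, optionally CV-tuned),
  classified by vote share at the same strict threshold.

Survey weights are never used in model fitting; they enter only in
weighted tabulation. All tuning runs strictly inside the training sample.

**Missing data.** Categorical predictors encode missingness as a reserved
extra level (`__MISSING__`), because non-response — especially to
immigration-related items — cannot be assumed missing at random, and the
pattern itself may be predictive. Numeric and binary predictors gain a
paired 0/1 `…__was_missing` indicator and a training-sample median fill
(distance- and tree-based methods need complete inputs; the median is
scale-robust).

**Propensity-score harmonization.** When donor and target are sampled
differently on observables, a logistic donor-membership model is fit on
the stacked pools using the shared predictors plus harmonization-only
covariates (default: region of residence and occupation, which are not in
the imputation predictor set), and its fitted probability is appended to
both tables as exactly one extra predictor.

## Evaluation framework

Confusion metrics use the standard definitions (sensitivity tp/(tp+fn),
specificity tn/(tn+fp), PPV tp/(tp+fp), accuracy); the false-positive rate
is additionally exposed as `fpr` because some descriptions of "specificity"
in this literature actually refer to it. Metrics are reported on two
denominators — the possibly-undocumented pool and the full sample including
the logically documented — because headline accuracy figures in this
setting are typically computed on the full sample while sensitivity and
PPV are pool-level quantities. Undefined ratios are NaN with an explicit
flag, never silently zero.

Bias diagnostics are Pearson correlations between imputed status and
binary health outcomes (for 0/1 data this equals the phi coefficient of
the 2×2 table), with Fisher-z confidence intervals, compared against the
same correlation computed with the true status on the held-out half. The
simulation study repeats random 80/20 splits (default 10) of the donor:
splits are drawn on the *initial* sample, before logical edits, and both
halves are then edited. One master seed spawns per-(split, method) child
seeds through a fixed method registry, so results for one method never
depend on which other methods were requested.

## The synthetic data-generating process

Real inputs for this problem are restricted-access-scale survey microdata,
so the package ships a generator whose defaults define the study
conditions for every test:

- ~13 socio-demographic predictors (four categorical, five binary, four
  numeric) with configurable missingness (notably ~25% on spousal
  citizenship), plus two harmonization-only covariates.
- A hidden binary status driven by a logistic model in the predictors,
  calibrated by root-finding the intercept so that the expected prevalence
  *in the post-logical-edit pool* equals the configured value (default
  0.33). A pure two-way interaction (sign +γ when Hispanic ethnicity and
  English difficulty agree, −γ when they differ; default γ = 2) injects
  non-additivity that an additive logit cannot represent but a tree
  ensemble can.
- Exclusion flags and truth-proxy components generated *consistently with
  the status*: no undocumented record ever carries a flag, and every
  documented non-citizen holds LPR status or entered before the cutoff, so
  the proxy recovers the hidden status exactly.
- Two binary outcomes. Private insurance depends negatively on the status
  and strongly positively on citizenship, so the logically excluded
  (mostly citizens) are markedly better insured than pool-retained
  documented records — this is the mechanism by which logical-only
  imputation *overstates* the negative status–insurance correlation.
  Poor/fair self-rated health carries a weak negative status effect (a
  "healthy migrant" pattern), yielding a small, usually insignificant
  correlation.
- Donor/target selection with configurable log-odds differentials on
  observables (default: English difficulty and region of residence);
  target weights are inverse selection probabilities normalized to mean
  one.

Two named variants pin down the extreme conditions. `strong_signal()`
concentrates large quantized effects on the discrete predictors so almost
every covariate cell is pure, uses a balanced pool, removes missingness,
and disables the entry-year bookkeeping that would otherwise rewrite
years-in-US — under it every method recovers the status with sensitivity
and PPV above 0.9 at n_train = 10,000. `null()` removes *every* structural
channel linking covariates to status: zero effects, covariate-free flag
probabilities, no pre-cutoff entries, years-in-US bounded below the cap,
and a pool prevalence of 0.5 so threshold classifiers still emit positives
whose precision can be compared with the prevalence. These switches exist
because the two-step design itself induces covariate signal (pool
membership depends on years-in-US through the citizenship flag) even when
all status effects are zero.

What the generator does **not** emulate: complex sample designs (strata,
PSUs, panel rotation and attrition), measurement error in the truth proxy,
item non-response that is informative beyond the missing-category encoding,
and real covariate joint distributions. Passing tests therefore establish
the internal correctness and the qualitative behaviour of the method —
ordering of methods by bias, the direction of the logical-imputation bias,
the effect of harmonization — not performance figures for any real survey.

## Numerical choices

- Logistic fits use a fixed, very small ridge penalty (C = 10⁴ in
  scikit-learn's parameterization), which coincides with maximum
  likelihood away from separation and keeps coefficients finite under it;
  a suspicion of separation (|coef| > 15) is recorded in the tuning trace.
  An empty predictor set degrades to the intercept-only model.
- KNN vote ties classify as documented (the strict > 0.5 convention);
  neighbours tied with the k-th distance are all included (relative
  tolerance 10⁻¹², order-independent).
- CV tuning uses repeated stratified k-fold accuracy (default 10 folds,
  2 repeats); grid ties resolve to the smaller candidate. Default grids
  are singletons (k = 31, square-root mtry), so tuning only runs when a
  grid is supplied; with multi-entry grids each simulation split re-tunes
  inside its own training pool.
- Rubin's rules: T = W + (1 + 1/M)B with the usual degrees of freedom
  (M−1)(1 + W/((1+1/M)B))²; B = 0 collapses to the normal single-dataset
  interval. Correlation pooling happens on the Fisher-z scale (within
  variance 1/(n−3)).
- Constant vectors make correlations an error, not zero; undefined
  confusion ratios are flagged NaN.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; identical seeds give byte-identical tables
  and metrics.

## Problem sizes

The shipped validation uses donor sizes of 10,000 for the parameter
recovery and bias-ordering studies (20 master seeds for the stochastic
orderings), 8,000 for the null-precision check, and 6,000 per side for the
harmonization comparison; the acceptance script runs three 80/20 splits of
a 10,000-record donor with all five methods. These sizes were chosen so
the Monte-Carlo error of each checked quantity is small relative to the
effect being asserted.

## Known limitations

- The MI implementation draws coefficients from the asymptotic sampling
  posterior rather than a fully Bayesian or bootstrap posterior; with
  small pools the approximation understates uncertainty.
- The propensity score enters as a single extra predictor; weighting-based
  harmonization alternatives are out of scope.
- Cross-survey application requires a definitive classifier; multiple
  imputation is not accepted there because it does not assign one label
  per record.
- The logical-edit engine evaluates rules as a pure disjunction of
  per-variable predicates; conjunctive rules would need a new rule type.
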
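# Methods

## Problem and model

The package addresses a recurring situation in early clinical risk
prediction: many recorded indicators are partially redundant, so there is
rarely a single "best" predictor set. Formally, a **Markov boundary** (MB)
of a binary outcome Y is a minimal set **M** of features such that every
other feature is conditionally independent of Y given some subset of
**M** — the smallest maximally predictive set. When two features are
*information equivalent* (each is an invertible recoding of the other, or
of a shared signal), Y has many Markov boundaries, all equally predictive
and mutually interchangeable. The pipeline enumerates all of them and
quantifies their shared predictive accuracy.

The procedure runs in five stages:

1. **Tabular input** (`tabular_io`): CSV + sidecar YAML schema
   (continuous / ordinal / binary per column). Missing predictors are
   imputed deterministically (median for continuous, mode with
   smaller-value tie-break for discrete); continuous columns are
   discretized by equal-frequency binning (default 3 bins) for
   contingency-based testing only.
2. **Conditional independence testing** (`independence`): the
   likelihood-ratio G² test on contingency tables, stratified by the
   conditioning set, with degrees of freedom accumulated per stratum from
   realized level counts; or the Fisher-z partial-correlation test for
   continuous pipelines. A G² test is *reliable* only when the average
   sample count per contingency cell reaches `min_avg_cell` (default 5);
   an unreliable test never removes a candidate feature (conservative
   policy — sparse strata cannot fabricate independence). One deliberate
   refinement: when a feature varies overall but is constant within every
   stratum of the conditioning set, that is in-sample functional
   determinism, which *does* certify conditional independence provided
   the strata are well populated; without this rule an exact duplicate of
   a selected feature could never be eliminated.
3. **MB induction** (`mb_induction`): a semi-interleaved HITON-PC-style
   learner. Candidates enter in order of univariate association strength
   (p ascending, statistic descending, name ascending — fully
   deterministic); each newcomer is challenged by conditioning subsets of
   the current set up to size `max_k` (default 3), and a full backward
   pass re-challenges every survivor. The parents/children set is used as
   the boundary: the synthetic generating structures place the outcome as
   a sink with direct parents only, so no spouse-recovery phase is
   needed. This is a known limitation for data with colliders.
4. **Equivalence enumeration** (`tie_star`): induce a reference boundary,
   score it by internal stratified cross-validation on the training data
   (never on held-out data), then process a removal agenda: exclusion
   sets are seeded with each single reference-boundary feature and grown
   as unions of previously processed exclusions with single features of
   newly admitted boundaries — smallest first, never revisited, bounded
   by a budget (default 5000). A re-induced boundary joins the pool iff
   its feature set is new and its accuracy passes the equivalence
   criterion against the reference. Two criteria are provided, because
   "as accurate as the original" admits two readings: a deterministic AUC
   margin (default 0.01) and a two-sided paired permutation test of the
   AUC difference (default 2000 swaps at alpha 0.05). The margin form is
   the default; the permutation form is preferable when score vectors are
   noisy and a calibrated error rate is wanted.
5. **Evaluation** (`classifier_eval`, `cross_validation`): a support
   vector machine (default linear kernel, cost grid {0.01, 0.1, 1, 10}
   selected by internal CV, class weights balanced for minority-outcome
   data) scored by AUC in the Mann–Whitney formulation (ties get half
   credit; identical to trapezoidal ROC area). The outer loop is
   stratified k-fold cross-validation repeated `repeats` times (defaults
   10×10 = 100 train/test runs): boundaries are enumerated on each
   training partition and every pooled boundary is scored on the held-out
   fold. Per-boundary test AUCs are pooled across runs; the "95% range"
   is the empirical 2.5th/97.5th percentile interval of that pool (an
   asymmetric percentile range, not a normal CI). Feature robustness is
   the fraction of all discovered boundaries containing the feature, with
   a strict `> threshold` cut (default 0.75).

## Ordinal coding in the classifier

Ordinal and binary features enter the SVM as level codes (their rank
within the schema's declared levels); continuous features enter raw, and
all columns are standardized by training-partition location and scale.
The numeric labels of an ordinal clinical item are arbitrary, and a
linear SVM is not invariant to that arbitrary spacing: two boundaries
built from differently coded but information-identical members would
otherwise show small systematic AUC gaps that the equivalence criterion
would faithfully — and misleadingly — detect. Rank coding makes the
evaluation invariant to any monotone relabelling, so information
equivalence implies score equivalence by construction. Schema levels are
static metadata, so no information flows from test rows.

## Synthetic data generator

The generator emulates the structural shape of an early-risk cohort
study, not any particular dataset's marginals:

- **Latent sources**: independent 3-level discrete uniforms, one per
  equivalence group. Three levels keep every CI test exact on small
  tables and make the Bayes AUC computable by enumeration of the finite
  support.
- **Outcome**: logistic in the sources. The intercept is calibrated by
  deterministic root bracketing so the expected outcome rate equals the
  target prevalence (default 0.17, a typical minority rate for
  non-remitting post-traumatic symptom trajectories).
- **Equivalent members**: each group member is an invertible transform of
  its source (`copy`, `monotone_relabel` with strictly increasing maps,
  `sign_flip`), optionally corrupted independently with probability
  `equivalence_noise` (default 0, i.e. exact equivalence). Implementing
  equivalence by invertible transforms rather than correlated draws
  guarantees the true boundary set exactly: it is the Cartesian product
  of one-member-per-group choices over nonzero-weight groups.
- **Noise features**: independent of everything, cycling ordinal /
  binary / continuous kinds to exercise the mixed-type path.
- **Defaults**: the demo configuration uses groups of sizes 2 and 3 with
  log-odds weights (1.0, 0.8) per source level, which puts the exact
  Bayes AUC at ≈ 0.754 — the moderate-accuracy regime where this class
  of early-prediction model typically operates — with 10 noise features
  at n = 2000.

What the generator does **not** emulate: realistic marginal
distributions of clinical instruments, item-level missingness patterns,
measurement error correlated across items, or confounded/collider
structures. Passing tests on this generator therefore demonstrate the
machinery (enumeration completeness, calibration, leakage-freedom,
determinism) — not that any particular clinical dataset contains a given
number of boundaries.

## Numerical choices and degenerate inputs

- All tie-breaks (candidate ranking, agenda ordering, mode imputation,
  cost-grid selection) resolve deterministically, lexicographically or
  toward the smaller value; every random draw flows from an explicit
  seed through `numpy.random.default_rng`, so every stage reproduces
  byte-identically.
- Fold assignment is within-class shuffle + round robin, which makes the
  per-fold case and control counts differ by at most one by construction.
- `pd.qcut` with `duplicates="drop"` implements equal-frequency binning;
  a column with fewer distinct values than bins collapses with a warning,
  a constant column collapses to a single level.
- A globally constant feature, an empty candidate list, or a dataset in
  which no feature is dependent on the outcome yields an empty boundary
  and an empty pool with a logged warning rather than an error.
- Internal CV fold counts are clipped to the minority-class count; a
  training split whose minority class is too small for even 2 folds is
  an error.
- The Fisher-z partial correlation is read off the inverse correlation
  matrix; perfect correlation is treated as the r = ±1 boundary (p = 0),
  any other singular structure as an unreliable non-result.

## Problem sizes in the shipped tests and acceptance script

Unit and acceptance tests run the study conditions at n = 150–5000
subjects with 5–16 features, 10×10 stratified CV on the small
configuration and 2×5 on the n = 2000 demo configuration; the brute-force
boundary oracle enumerates all 2^p subsets at p = 8. These sizes were
chosen so that each statistical check has the power it needs (e.g.
±0.03 Bayes-AUC recovery needs n = 5000; type-I calibration uses 500
null replicates) while the complete suite stays fast enough to run
routinely.

## Known limitations

- No spouse recovery: boundaries are parents/children sets, correct for
  outcome-as-sink structures only.
- No permutation-exact or kernel CI tests; G² relies on the chi-square
  asymptotics guarded by the cell-count heuristic.
- The SVM scores are rank-quality only (as AUC requires); no probability
  calibration is attempted.
- The agenda-growth strategy is complete for the generator's equivalence
  structures; for arbitrary dependence structures completeness of TIE*-
  style search depends on the removal-set generator, and the budget can
  truncate enumeration (flagged on the returned pool).
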
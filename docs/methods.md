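# Methods

## The problem this package addresses

Small discovery cohorts profiled on qPCR panels invite overfitting: with
~80 serum samples and >12,000 candidate expression-ratio features, a lasso
model tuned and evaluated on the same resamples reports optimistic
accuracy, and the selected feature set changes with every random fold
split. `stavarsel` implements a stabilised, three-stage nested
cross-validation (StaVarSel) that addresses both problems at once: an
outer leave-one-out loop supplies honest held-out predictions, and the
variable set is stabilised by collating lasso selections across many
resampled fits and keeping only features selected at high frequency.

## Data model

Input is a Ct matrix (assays x samples, PCR cycles; "Undetermined" =
not amplified) with cohort labels (control, GORD, cancer); modelling is
binary, cancer vs the pooled non-cancer cohorts. Relative expression is
anchored at the instrument's 40-cycle limit, `2^(40 - Ct)`, so one cycle
earlier doubles expression. Non-amplified measurements are imputed at
Ct = 40 (expression 1) *after* the detectability filter; the cycle limit
is the natural censoring point, and the imputation value is configurable
(`undetected_ct`). Per-feature sample dropping was the alternative; it was
rejected because it makes the feature matrix ragged and the lasso design
sample-dependent.

The feature space is every **ordered** pair of assays,
`expr(a)/expr(b) = 2^(Ct_b - Ct_a)` — `m(m-1)` features for `m` assays.
Within-sample ratios cancel per-sample global scale (input amount,
extraction efficiency), so the classifier arm needs no between-sample
normalization. Reciprocal pairs are statistically redundant for rank
tests but not for CoV filtering or lasso scaling on raw ratios, so both
orientations are kept (a `dedupe_reciprocals` helper exists for users who
want one orientation).

Prefilters, applied once on the full data before the nested CV (the
Methods-order reading; the leakage implication is discussed under
*Limitations*):

* detectability — assay kept if detected in >= 50% of samples in at
  least one class;
* CoV filter — ratio removed only if its per-class coefficient of
  variation (sd/mean, raw ratios) exceeds 300% in **both** classes;
* Mann–Whitney prefilter — two-sided p < 0.05. Exact enumeration of rank
  assignments (midranks for ties) when both groups have <= 8 samples,
  normal approximation with tie correction otherwise.

Modelling uses raw ratios by default; a `log2` flag is available because
raw ratios are heavy-tailed, but the default mirrors the original design.

## Penalized logistic regression and lambda selection

The path solver minimises `(1/n)·binomial deviance + lambda·||beta||_1`
with an unpenalized intercept on internally standardized features
(population-SD scaling), via IRLS with cyclic coordinate descent on an
active set, warm-started down a geometric 100-point grid from
`lambda_max` (the smallest penalty with an all-zero solution) to
`lambda_min_ratio·lambda_max` (0.01 when n < p, 1e-4 otherwise).
Numerical choices:

* convergence tolerance 1e-11 on the weighted squared coefficient change,
  which keeps the maximum KKT subgradient violation below 1e-6 on every
  reported path point (checked in the tests by an independent subgradient
  oracle and against an unpenalized Newton fit in the lambda -> 0 limit);
* fold fits inside cross-validation use a looser 1e-8 tolerance — the CV
  deviance curve is insensitive at that scale and the inner loop performs
  thousands of path fits;
* the path stops once >99.9% of the null deviance is explained (the model
  is saturated); by default the returned grid is truncated there, while
  CV fold fits keep the full grid with the last solution carried forward
  so fold curves stay aligned;
* IRLS weights are floored at 1e-6.

Lambda is estimated by stratified 10-fold CV of held-out binomial
deviance: `lambda.min` minimises the mean curve; `lambda.1se` is the
largest lambda within one standard error of that minimum (the
more-stringent, sparser choice). Stratification is a deliberate deviation
from plain random folds: with ~78 samples and leave-one-out outer
training sets, unstratified 10-fold splits produce single-class folds
often enough to matter. The CV is repeated (50 fold-splits by default;
10 in the desk-scale profile) and the arithmetic mean of the repeat
estimates is the lambda used downstream. The repeat distribution also
yields a stability diagnostic: estimates are "stable" when the
normal-theory 95% CI half-width (1.96·SD/sqrt(R)) is below 15% of the
mean; instability triggers a warning but does not abort, matching the
intended workflow.

## Nested cross-validation

**Two-stage baseline.** Outer loop: leave-one-out. For each training set,
repeated 10-fold CV estimates lambda; one lasso fitted at the mean
estimate (lambda.min or lambda.1se rule) predicts the held-out sample.

**StaVarSel (three-stage).** For each outer training set and each CV
repeat, the lasso fitted on the full training set at that repeat's
lambda.min contributes one selection event per nonzero feature. Pooling
over (training set x repeat) fits — 780 fits at the desk scale — gives
each feature a percent selection frequency. This pooling choice makes the
repeats informative (they differ through their lambda estimates) and
stabilises selection against fold randomness within training sets and
sample variance across them. A step-down search over percent cutoffs
(100% downward in 5% steps; descent stops when the feature set would
exceed `p_max = n/4`, a guard against p > n refits) evaluates each
candidate set by repeated stratified 10-fold CV misclassification (at
probability 0.5) of an unpenalized logistic model; the cutoff with the
lowest inner error wins, ties going to the higher cutoff (smaller model).
The cutoff evaluation is global (full data), consistent with the stable
set itself being a global object; the leakage this global choice entails
is inherent to the design (see *Limitations*), and a strictly-nested
variant (`nested_selection=True`) that re-derives the stable set inside
each outer training set is provided for leakage-sensitivity analysis.
Finally the stable
feature set is refitted by plain logistic regression on every outer
training set — the held-out sample's row is excluded from each fit, which
the tests assert — to produce one cross-validated probability per sample.

Unpenalized logistic fits use Newton's method with step halving and a
fixed tiny ridge (1e-8 on standardized coefficients), escalated up to
1e-2 only if the iteration fails; quasi-separation is routine with ~20
features on ~78 samples and the ridge keeps refits defined without
materially changing coefficients.

## Evaluation

ROC thresholds are the midpoints between sorted unique scores with +-inf
sentinels ("positive" = score strictly above threshold). AUC is the
Mann–Whitney statistic `U/(n1·n2)` with ties counted half. 95% CIs for
sensitivity and specificity at each threshold come from stratified
bootstrap resampling (class counts preserved; 2000 replicates by default,
500 at desk scale), percentile 2.5/97.5, clipped to contain the
full-sample point estimate. Operating points: the Youden-index maximiser
(ties to the higher specificity) and a high-specificity point (maximum
sensitivity subject to specificity >= 0.95, configurable; if unreachable
the maximum-specificity point is returned with a warning).

The permutation null shuffles the class labels and reruns the **entire**
pipeline — the label-dependent CoV and Mann–Whitney prefilters included,
and the stable set re-derived, the conservative reading — measuring each
run's accuracy at its own Youden threshold, mirroring how the observed
model is reported. p = (1 + #{permuted >= observed}) / (n_perm + 1), so
it is never zero. Per-permutation seeds are counter-based
(`SeedSequence([seed, i])`): the null distribution is identical for any
worker count and a partial run can be resumed by permutation index.

## Housekeeping panel and differential expression

The DE arm asks a different question — which individual assays shift —
and therefore needs between-sample normalization. Housekeeping criteria:
(i) amplified in all samples, median Ct < 30; (ii) no class difference
(Mann–Whitney p > 0.1); (iii) not highly variable — the assay's
expression CoV must lie within 2 SD above the mean CoV of the candidate
assays (the printed form of this criterion is dimensionally ambiguous;
this outlier-screen reading is ours and the multiplier is configurable) —
and no sample outside fivefold of the assay mean; (iv) Pearson
correlation (log2 scale) with the panel geometric mean > 0.7, applied
**iteratively** (drop, recompute the reference, repeat) until the panel
is stable — the self-consistent reading, since the reference moves when
members leave. The panel geometric mean includes the assay being tested;
with >= 10 panel members the self-inclusion bias in r is small. A final
panel below 3 assays raises an error advising manual review. Expression
is then divided per sample by the panel's geometric mean, which makes
normalized values invariant to any global rescaling of a sample (tested
exactly).

Testing uses two-sided Mann–Whitney per assay with Storey FDR:
`pi0 = #{p > 0.5} / (0.5·m)` capped at 1 (single fixed lambda0 = 0.5
rather than the smoother — simpler and configurable; with m < 5 pi0 is
forced to 1 with a warning, and an all-small-p degenerate estimate of 0
is floored at the smallest attainable nonzero value), and
`q_(i) = min_{j>=i} pi0·m·p_(j)/j`. Fold changes are ratios of class
geometric means (the mean type is unstated in the original description;
geometric is the coherent choice next to a geometric-mean reference) and
the 1.3-fold criterion is direction-symmetric.

One deliberate reordering: q-values are estimated over **all** assays
passing the detectability and variability screens, and the 1.3-fold
criterion is applied as part of the final DE call rather than as a
pre-test filter. Filtering on the observed fold change first selects
assays whose test statistics are extreme under the null, drags the pi0
estimate toward zero and destroys FDR calibration — implemented literally
it produced double-digit false positives per null dataset, versus zero
under the calibrated ordering. `de_prefilter` still exposes the literal
criteria (including the fold filter) for users who want them.

## Synthetic data generator

`Ct(a, s) = baseline(a) + offset(s) + effect(a)·is_cancer(s) + noise`,
with missingness from `logistic((Ct - dropout_ct50)/scale)` plus hard
censoring at 40 cycles. Defaults and what they emulate:

| parameter | default | meaning |
|---|---|---|
| cohorts | 19 / 20 / 39 | control / GORD / cancer sample counts |
| `n_assays` | 112 | panel size (15 housekeeping, 2 spike-ins) |
| `n_informative` | 5 | assays with planted cancer-vs-rest shifts |
| `effect_ct` | 1.5 cycles | planted shift; fold change `2^1.5 ≈ 2.8`, signs alternate |
| `sample_offset_sd` | 0.5 cycles | pre-analytic global variation; cancels in ratios and under normalization, so both arms are genuinely exercised |
| `noise_sd` | 1.0 cycles | per-measurement noise, target assays |
| `hkg_noise_sd` | 0.3 cycles | housekeeping/spike-in assays; their stability is a planted property — an assay whose total cross-sample SD exceeds ~0.7 cycles cannot pass a fivefold-outlier screen over 78 samples, so "stable housekeepers" must actually be stable |
| `dropout_ct50` / scale | 38 / 1 cycle | Ct of 50% amplification failure |
| baselines | U(24,34) targets, U(22,28) HKG/spike-in | abundance ranges |

Effects are planted in Ct space because the downstream transform is
exponential (`effect_ct = -log2(fold)`). What the generator does **not**
emulate: plate/batch structure, probe-specific amplification efficiency,
correlated biological co-regulation among target assays, and
non-Gaussian heavy-tailed measurement error. Passing tests therefore
demonstrate that the machinery recovers planted structure and stays
calibrated under this generative model, not that real serum data meet
its assumptions.

## Problem sizes used by the test suite and acceptance script

The full design (50 repeats, 2000 permutations, 2000 bootstrap
replicates) is the package default. The shipped checks use the
documented desk-scale profile: 10 inner repeats on the 112 x 78
benchmark; and for the permutation/null-calibration runs — which rerun
the entire pipeline per permutation — a reduced generative profile of
16 assays x 24 samples (6/6/12), 3 repeats, 5 folds, 100 permutations.
These are the package's own desk-scale choices and are recorded so
results are interpretable, not tunable knobs of the method.

## Known limitations

* The prefilters and the stable set are derived once on the full data
  (the published design); outer LOO predictions therefore carry some
  optimism. The permutation null inherits the same structure under each
  permutation, which is exactly why it is the honest significance check.
* Raw-ratio modelling is heavy-tailed; the `log2` option is provided but
  changes the estimator.
* The cutoff grid floor (`p_max = n/4`) and 5% step are our defaults; the
  original grid is not recorded anywhere recoverable.
* Exact Mann–Whitney enumeration is only engaged for per-group n <= 8;
  between that and the asymptotic regime there is no mid-size exact path.
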
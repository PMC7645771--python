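# Methods

## The analysis problem

Each subject contributes one FAIMS run: a positive- and a negative-ion
dispersion plot of 51 dispersion-field steps (0–100 %) × 512
compensation-voltage steps (+6 V → −6 V), i.e. 52,224 ion-current values
against cohorts of 57 SAM children (38 discharged, 19 dead within six days
of admission) and 7 healthy sibling controls. With ~10³ times more
features than subjects, the pipeline's job is to estimate out-of-sample
discrimination without optimistic bias, and every design choice below
serves that goal.

## Pipeline

1. **Replicate selection.** Each sample is measured three times; the
   second run is analysed (configurable, `replicate=2`). The generator
   models the empirical motivation: replicates 1 and 3 carry larger
   run-to-run gain jitter.
2. **Polarity combination.** The two planes are concatenated into one flat
   vector — positive block first, row-major (dispersion field outer, CV
   inner). The layout is a bijection, so any selected feature back-maps to
   (polarity, field %, CV volts) exactly.
3. **Background masking.** Pixels whose across-sample standard deviation
   is at or below the median SD are dropped (≈50 % of pixels). The
   statistic never sees class labels, so fitting the mask once on all
   samples cannot leak outcome information; a per-fold refit
   (`refit_mask_per_fold=True`) exists for strictness. An intensity-based
   statistic (`mean_abs`) is available as the alternative interpretation
   of "thresholding the background"; variability is the default because a
   constant pixel cannot discriminate anything.
4. **In-fold feature selection.** Stratified tenfold CV; within each 90 %
   training split every retained pixel is scored by a two-sided two-sample
   rank-sum test and the k smallest p-values are kept (k ∈ {100, 50, 20};
   ties broken by ascending flat index for reproducibility). Ranking by
   p ascending equals ranking by extremity of U for equal group sizes and
   is well-defined otherwise. p-values are exact — the full null
   distribution of U by dynamic programming — when both classes have ≤ 10
   members and the feature is tie-free, else a tie-corrected,
   continuity-corrected normal approximation (cohort arm sizes here,
   7–38, straddle the exactness limit). Constant features get p = 1.
5. **Classification.** Four scikit-learn families behind one declarative
   spec: random forest (1000 trees), Gaussian process (RBF), SVM (RBF,
   probability-calibrated), and sparse logistic regression (L1 path,
   penalty chosen by inner 5-fold CV). Kernel and linear models sit
   behind a StandardScaler fitted on the training fold. All stochastic
   components are seeded; a fixed config reproduces a run byte-for-byte.
6. **Pooled evaluation.** Each subject is scored exactly once, by the
   model of the fold that held it out; the pooled scores give one ROC per
   (comparison, family, k). AUC is computed as Mann–Whitney concordance
   (identical to the trapezoidal ROC integral — a tested invariant). The
   95 % CI is a stratified percentile bootstrap (default 2000 resamples;
   DeLong available), the p-value a one-sided label-permutation test
   against AUC = 0.5 (default 10,000 permutations, +1 correction). The
   operating point maximises Youden's J with ties resolved towards higher
   sensitivity; PPV/NPV use the cohort prevalence.

## Clinical comparisons

Eleven contrasts: mortality ≤ 6 d vs discharge, early mortality (day 1–3)
vs discharge, late mortality (day 4–6) vs discharge, early vs late
mortality, SAM vs healthy controls (method validation), and six morbidity
splits of the SAM cohort (WAZ ≤ −3, oedema, diarrhoea, pneumonia, HIV
status with unknowns excluded, age ≤ 2 years). Arms are defined as
predicates over the metadata table; arms are checked disjoint, exclusions
are logged, and an empty arm raises rather than silently shrinking a
comparison. Baseline characteristics use a pooled-variance (Student)
t-test for continuous variables — from raw data or printed mean/SD/n
summaries, which are algebraically identical — and a two-proportion z-test
for binary rows; the pooled variant is the default because it reproduces
the study's printed baseline p-values (0.04 for age, 0.03 for MUAC),
where Welch gives 0.03/0.02. Subjects missing a variable drop out of that
row only, so each row carries its own denominators.

Published rounded sensitivity/specificity pairs can be inverted to integer
confusion matrices (`reconstruct_confusion`): both class orientations are
searched for TP/TN counts whose rates round (half-up, 2 dp) to the printed
values. Orientation is resolved per table row because the published table
implies different positive classes in different rows.

## Synthetic cohorts

The generator emulates instrument geometry, not chemistry: a reactant-ion
background ridge whose CV position drifts with the dispersion field and
whose amplitude decays with it; sparse 2D Gaussian analyte peaks with
their own CV-vs-field drift; per-pixel Gaussian noise (SD 1 a.u. — the
intensity unit of the simulation); per-sample lognormal gain jitter
(σ = 0.05) and larger jitter on replicates 1 and 3 (σ = 0.10 vs 0.02).
Metadata marginals mirror the study's admission table per arm (age, MUAC,
anthropometric z-scores, comorbidity rates, HIV and site distributions),
with arm sizes 38/19 (9 early + 10 late deaths)/7 by default.

Class structure is planted as peak-amplitude increments expressed in noise
SDs (so the increment is a per-pixel Cohen's d at the peak centre) and/or
CV shifts, for subjects matching a predicate. The default configuration
plants d = 1.5 on two peaks for children who died and d = 4 on three peaks
for healthy controls — one-time realism choices that echo the reported
ordering (fair mortality discrimination, near-perfect control separation).
The exact affected-pixel set (|noiseless difference| ≥ 20 % of its
maximum) is emitted as ground truth.

What passing tests on these cohorts do **not** show: robustness to real
VOC chemistry, instrument drift between sessions, correlated
clinical-volatilome confounding, or batch effects — none of which the
generator models.

## Validation experiments

- **Leakage guard.** On 50 signal-free cohorts the honest pipeline's
  median pooled AUC must lie in [0.40, 0.60]; the deliberately leaky
  variant (selection on all data before CV) must exceed 0.65 — it
  empirically sits near 1.0, which is the size of the bias in-fold
  selection removes at this dimensionality.
- **Signal recovery.** With d = 2 planted on ~200 pixels (two peaks), the
  median pooled AUC over 20 cohorts must reach 0.9 and at least half of
  all in-fold top-100 selections must be planted pixels.
- **Inference calibration.** On null scores, permutation p-values pass a
  uniformity KS test (α = 0.01) and the bootstrap CI covers 0.5 at its
  nominal rate. The tie-inclusive permutation p is slightly conservative
  (mean marginally above 0.5), which is the standard, valid convention.

These experiments run at 51 × 128 CV resolution — the problem-size choice
that makes many-cohort replication practical on a single CPU while
preserving the feature-to-sample ratio regime (13,056 features for 57
subjects); single-run analyses use the full 51 × 512 geometry.

## Numerical conventions and edge cases

- Matrix CSVs store floats with 17 significant digits: write∘read is
  value-exact. Malformed files report file, row and column.
- Scores are probability-like in [0, 1], oriented towards the comparison's
  declared positive arm; every report states the orientation.
- A fold whose training split degenerates (e.g. loses a class) is
  recorded and skipped; its samples are excluded from the pooled ROC and
  the result is flagged incomplete.
- Zero-denominator PPV/NPV are NaN (flagged), never silently clamped.
- Stratification falls back to plain folds, with a warning, when a class
  is smaller than the fold count.
- Display rounding is decimal half-up to 2 dp; JSON keeps full precision.

## Known limitations

- FAIMS features are pixels, not identified compounds; the pipeline ranks
  locations on the dispersion plot and cannot name chemistry.
- The exact-p path assumes tie-free data; tied features inside the exact
  regime fall back to the corrected normal approximation.
- The reproduction of the original study's AUCs depends on its raw export
  plus fold seeds and hyperparameters that were never published; the
  reproduction script therefore reports deltas rather than asserting
  equality.
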
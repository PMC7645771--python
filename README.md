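# faimsvoc

Cross-validated classification of faecal volatile-organic-compound (VOC)
profiles measured by field asymmetric ion mobility spectrometry (FAIMS),
built for the proof-of-concept question: can the faecal volatilome of
children hospitalised with severe acute malnutrition (SAM) separate those
who die within six days of admission from those discharged alive?

A FAIMS instrument reports, per sample and per ion polarity, a dispersion
plot: an ion-current matrix over 51 dispersion-field steps (0–100 % of the
maximum field) × 512 compensation-voltage steps (+6 V → −6 V). Combining
the positive- and negative-ion planes gives 2 × 51 × 512 = 52,224 data
points per sample — far more features than subjects, so the analysis
lives or dies by leakage control.

## What the package does

- **Data model & I/O** (`faimsvoc.io`): validated scan/run/sample types, a
  plain-text matrix-CSV dialect, replicate selection (the second of three
  instrument runs by default), and a typed admission-metadata table.
- **Preprocessing** (`faimsvoc.preprocess`): polarity combination into one
  flat feature vector and a label-blind background mask (drop pixels whose
  across-sample SD is below the median).
- **Feature selection** (`faimsvoc.select`): two-sample Wilcoxon rank-sum
  scoring of every retained pixel — exact p-values for small classes, a
  tie-corrected normal approximation otherwise — and top-*k* selection
  (k ∈ {100, 50, 20}) with deterministic tie-breaking.
- **Cross-validation** (`faimsvoc.crossval`): stratified tenfold CV with
  the rank-sum selection nested *inside* each training fold, four
  classifier families (random forest, Gaussian process, RBF SVM, sparse
  L1 logistic regression), and pooled out-of-fold probability scores.
- **Performance** (`faimsvoc.performance`): AUC as Mann–Whitney
  concordance, stratified-bootstrap CIs, label-permutation p-values,
  Youden operating points, PPV/NPV, and reconstruction of integer
  confusion matrices from published rounded sensitivity/specificity.
- **Comparisons** (`faimsvoc.comparisons`): the study's eleven clinical
  contrasts (mortality within 6 days, early/late mortality, SAM vs healthy
  sibling controls, and six morbidity splits) plus baseline-characteristic
  tables with pooled t-tests.
- **Simulation** (`faimsvoc.simulate`): a synthetic cohort generator —
  background ridge, drifting Gaussian analyte peaks, replicate/gain noise,
  study-like metadata marginals (38 discharged / 19 died / 7 controls) —
  with planted class effects and exact ground-truth pixel sets.
- **Orchestration** (`faimsvoc.pipeline`, `faimsvoc` CLI): YAML-configured
  `simulate` / `analyze` / `report` runs producing CSV/JSON tables,
  feature-map TSV/PNGs and ROC plots.

The statistic at the core is the pooled out-of-fold AUC. For scores
s and labels y it is the concordance probability
P(s⁺ > s⁻) + ½ P(s⁺ = s⁻), computed over every (positive, negative) pair;
its null is tested by label permutation and its uncertainty by per-class
bootstrap resampling.

## Worked example

`examples/03_cross_validated_classification.py` simulates a cohort at
reduced CV resolution (51 × 128) with the default planted mortality
effect, runs the honest pipeline for the mortality comparison, and prints:

```
pooled AUC          0.92 (95% CI 0.83-0.98)
permutation p       0.0004998
sensitivity         1.00
specificity         0.76
PPV / NPV           0.68 / 1.00
```

Every subject was scored exactly once while held out, so the AUC estimates
out-of-sample discrimination between the 19 children who died and the 38
discharged. `examples/04_leakage_demo.py` shows why the fold-nesting
matters — on signal-free cohorts the honest pipeline stays at chance
(median AUC 0.43 over five cohorts) while selecting features before the
split yields a spurious 0.99:

```
per-cohort AUC, honest (in-fold selection):  [0.43 0.49 0.37 0.58 0.38]
per-cohort AUC, leaky (selection before CV): [1.   0.99 1.   0.95 0.98]
```

The other examples cover simulation/ground truth, feature mapping, and
auditing published summary tables back to integer confusion matrices.

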
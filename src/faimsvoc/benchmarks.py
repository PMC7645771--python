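"""Calibration and recovery benchmarks run on simulated cohorts.

Three study-condition experiments, used both by the test suite and the
reproducibility script:

- :func:`null_leakage_benchmark` - the leakage guard.  On cohorts with no
  class effect the honest pipeline (selection inside each training fold)
  must stay at chance, while the deliberately leaky variant (selection on
  the full data before CV) inflates far above it.
- :func:`signal_recovery_benchmark` - with a planted effect of known
  location and size, the pipeline must both discriminate and select the
  planted pixels.
- :func:`inference_calibration` - permutation p-values must be uniform and
  bootstrap CIs must cover 0.5 at their nominal rate when there is nothing
  to find.

All benchmarks run at a reduced compensation-voltage resolution (51 x 128
by default) to keep many-cohort replication tractable on one CPU; the
mortality arm sizes (19 vs 38) and the rest of the generative model match
the full-geometry defaults.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from faimsvoc.layout import Geometry
from faimsvoc.performance import auc_inference, mann_whitney_auc
from faimsvoc.pipeline import classify, sample_vectors
from faimsvoc.simulate import (
    ClassEffect,
    SyntheticConfig,
    simulate_cohort,
    simulate_null_cohort,
)

REDUCED_GEOMETRY = Geometry(51, 128)

# d = 2 amplitude effects on one positive- and one negative-polarity peak:
# ~200 planted pixels at the reduced geometry
RECOVERY_EFFECTS = (
    ClassEffect("died", 0, amplitude_d=2.0),
    ClassEffect("died", 3, amplitude_d=2.0),
)


def _mortality_vectors(cohort):
    vecs = sample_vectors(cohort.samples)
    t = cohort.metadata.table
    sam = t["group"] == "SAM"
    ids = t.loc[sam, "sample_id"]
    y = (t.loc[sam, "outcome"] == "died").to_numpy()
    return [vecs[i] for i in ids], y


def null_leakage_benchmark(
    n_cohorts: int = 50,
    seed: int = 0,
    geometry: Geometry = REDUCED_GEOMETRY,
    family: str = "sparse_logistic_regression",
    k: int = 100,
) -> dict:
    """Pooled mortality-comparison AUC on effect-free cohorts.

    Returns per-cohort AUCs for the honest (in-fold selection) and leaky
    (pre-CV selection) pipelines, fitted on identical data.
    """
    rng = np.random.default_rng(seed)
    fair, leaky = [], []
    for i in range(n_cohorts):
        cohort_seed = int(rng.integers(0, 2**31 - 1))
        cohort = simulate_null_cohort(
            SyntheticConfig(geometry=geometry, seed=cohort_seed)
        )
        vecs, y = _mortality_vectors(cohort)
        for variant, sink in ((True, fair), (False, leaky)):
            res = classify(
                vecs, y, family=family, k=k, seed=cohort_seed % 10007,
                in_fold_selection=variant,
            )
            sink.append(mann_whitney_auc(res.scores, res.labels))
    return {
        "fair_aucs": np.array(fair),
        "leaky_aucs": np.array(leaky),
        "fair_median": float(np.median(fair)),
        "leaky_median": float(np.median(leaky)),
    }


def signal_recovery_benchmark(
    n_cohorts: int = 20,
    seed: int = 0,
    geometry: Geometry = REDUCED_GEOMETRY,
    family: str = "sparse_logistic_regression",
    k: int = 100,
    effects=RECOVERY_EFFECTS,
) -> dict:
    """Planted-effect discrimination and feature recovery.

    Per cohort: the pooled AUC of the mortality comparison, and the
    fraction of all in-fold top-k selections that fall inside the planted
    ground-truth pixel set.
    """
    rng = np.random.default_rng(seed)
    aucs, fractions = [], []
    n_planted = None
    for i in range(n_cohorts):
        cohort_seed = int(rng.integers(0, 2**31 - 1))
        cohort = simulate_cohort(
            SyntheticConfig(geometry=geometry, seed=cohort_seed, class_effects=effects)
        )
        planted = cohort.ground_truth["died"]
        n_planted = planted.size
        vecs, y = _mortality_vectors(cohort)
        res = classify(vecs, y, family=family, k=k, seed=cohort_seed % 10007)
        aucs.append(mann_whitney_auc(res.scores, res.labels))
        selected = np.concatenate(list(res.selected_per_fold.values()))
        fractions.append(float(np.isin(selected, planted).mean()))
    return {
        "aucs": np.array(aucs),
        "recovery_fractions": np.array(fractions),
        "median_auc": float(np.median(aucs)),
        "median_recovery": float(np.median(fractions)),
        "n_planted_pixels": int(n_planted),
    }


def inference_calibration(
    n_replicates: int = 200,
    n_pos: int = 19,
    n_neg: int = 38,
    n_perm: int = 499,
    n_boot: int = 400,
    seed: int = 0,
) -> dict:
    """Null calibration of the AUC permutation test and bootstrap CI.

    Scores are iid noise, so the true AUC is 0.5: permutation p-values
    should be uniform, and the 95% CI should cover 0.5 at its nominal rate.
    """
    rng = np.random.default_rng(seed)
    y = np.r_[np.ones(n_pos), np.zeros(n_neg)].astype(bool)
    p_values, covered = [], 0
    for i in range(n_replicates):
        s = rng.normal(size=y.size)
        (lo, hi), p = auc_inference(
            s, y, n_boot=n_boot, n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1))
        )
        p_values.append(p)
        covered += lo <= 0.5 <= hi
    ks = stats.kstest(p_values, "uniform")
    return {
        "p_values": np.array(p_values),
        "ks_pvalue": float(ks.pvalue),
        "coverage": covered / n_replicates,
    }
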
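"""Tenfold cross-validation with in-fold feature selection.

The design point of this engine is leakage control: the rank-sum feature
ranking (and, optionally, the background mask) is recomputed on each 90%
training split only, and the resulting classifier is applied to the held-out
10%.  After ten folds every sample has been scored exactly once as a test
sample; scores are pooled into a single ROC.  Selecting features on the full
data set before splitting is a classic source of optimistic bias in
high-dimensional (52,224-feature) problems; that deliberately leaky variant
is available only to demonstrate the bias it causes.

Four classifier families are supported as pluggable scikit-learn backends:
random forest, Gaussian process (RBF kernel), support vector machine (RBF,
probability-calibrated) and sparse (L1) logistic regression with the penalty
chosen by inner 5-fold CV.  Kernel and linear models sit behind a
standardisation step fitted on the training fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from faimsvoc.preprocess import FeatureMask, FeatureVector, apply_mask, fit_background_mask
from faimsvoc.select import rank_sum_feature_scores, top_k_features

CLASSIFIER_FAMILIES = (
    "random_forest",
    "gaussian_process",
    "support_vector_machine",
    "sparse_logistic_regression",
)


@dataclass(frozen=True)
class ClassifierSpec:
    """Declarative description of one classifier family + hyperparameters."""

    family: str
    hyperparameters: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(
                f"family must be one of {CLASSIFIER_FAMILIES}, got {self.family!r}"
            )

    def with_seed(self, seed: int) -> "ClassifierSpec":
        return ClassifierSpec(self.family, self.hyperparameters, seed)

    def build(self):
        hp = dict(self.hyperparameters)
        if self.family == "random_forest":
            return RandomForestClassifier(
                n_estimators=hp.pop("n_estimators", 1000),
                random_state=self.seed,
                **hp,
            )
        if self.family == "gaussian_process":
            kernel = ConstantKernel(1.0) * RBF(hp.pop("length_scale", 1.0))
            return make_pipeline(
                StandardScaler(),
                GaussianProcessClassifier(kernel=kernel, random_state=self.seed, **hp),
            )
        if self.family == "support_vector_machine":
            return make_pipeline(
                StandardScaler(),
                SVC(
                    kernel=hp.pop("kernel", "rbf"),
                    probability=True,
                    random_state=self.seed,
                    **hp,
                ),
            )
        # sparse_logistic_regression: L1 path, penalty picked by inner CV
        return make_pipeline(
            StandardScaler(),
            LogisticRegressionCV(
                l1_ratios=(1.0,),
                solver="liblinear",
                cv=hp.pop("inner_cv", 5),
                Cs=hp.pop("Cs", 10),
                scoring="neg_log_loss",
                use_legacy_attributes=False,
                random_state=self.seed,
                max_iter=hp.pop("max_iter", 1000),
                **hp,
            ),
        )


@dataclass
class FoldAssignment:
    """Per-sample fold ids for k-fold CV."""

    fold_id: np.ndarray
    n_folds: int
    stratified: bool
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_id == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_id != fold)


def make_folds(labels, n_folds: int = 10, seed: int = 0, stratified: bool = True) -> FoldAssignment:
    """Deterministic (seeded) fold assignment, stratified by default.

    Stratification keeps each fold's class ratio within one sample of the
    cohort ratio - important here because one arm can be as small as 7
    subjects and an event-free test fold contributes nothing to the ROC.
    Falls back to plain folds (with a warning) when a class is smaller than
    the fold count.
    """
    y = np.asarray(labels)
    n = y.size
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds the {n} samples")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes to fold")
    used_strat = stratified
    if stratified and counts.min() < n_folds:
        warnings.warn(
            f"smallest class ({counts.min()}) < n_folds ({n_folds}); "
            "falling back to unstratified folds",
            stacklevel=2,
        )
        used_strat = False
    splitter = (
        StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        if used_strat
        else KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    )
    fold_id = np.empty(n, dtype=int)
    for f, (_, test) in enumerate(splitter.split(np.zeros((n, 1)), y)):
        fold_id[test] = f
    return FoldAssignment(fold_id=fold_id, n_folds=n_folds, stratified=used_strat, seed=seed)


@dataclass
class CrossValResult:
    """Pooled out-of-fold scores with per-fold provenance.

    ``scores`` are probability-like in [0, 1], oriented so that higher
    means more like the positive (True-label) class.  Every sample is
    scored exactly once, by the model of the fold in which it was held out.
    """

    comparison_id: str
    family: str
    k: int
    sample_ids: list[str]
    scores: np.ndarray
    labels: np.ndarray
    fold_id: np.ndarray
    selected_per_fold: dict[int, np.ndarray] = field(default_factory=dict)
    failed_folds: list[int] = field(default_factory=list)
    in_fold_selection: bool = True

    @property
    def complete(self) -> bool:
        return not self.failed_folds


def _check_no_leak(provenance: Sequence[str], test_ids: Sequence[str], what: str) -> None:
    leaked = set(provenance) & set(test_ids)
    if leaked:  # pragma: no cover - internal invariant
        raise RuntimeError(f"{what} fitted on test-fold samples: {sorted(leaked)}")


def run_cv(
    vectors: list[FeatureVector],
    labels,
    spec: ClassifierSpec,
    k: int = 100,
    folds: FoldAssignment | None = None,
    comparison_id: str = "",
    n_folds: int = 10,
    seed: int = 0,
    refit_mask_per_fold: bool = False,
    mask_rule: dict | None = None,
    in_fold_selection: bool = True,
) -> CrossValResult:
    """Cross-validate one classifier on pre-masked feature vectors.

    Per fold: rank-sum selection on the training split only (unless
    ``in_fold_selection=False``, the leaky variant kept for demonstrating
    selection bias), classifier fit on the selected features, and
    probability scores for the held-out split.  With
    ``refit_mask_per_fold=True`` the background mask is also refitted per
    training split (vectors must then be unmasked).
    """
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("need two classes")
    if k < 1:
        raise ValueError("k must be >= 1")
    if folds is None:
        folds = make_folds(y, n_folds=n_folds, seed=seed)
    ids = [v.sample_id for v in vectors]

    pre_ranking = None
    if not in_fold_selection:
        pre_ranking = rank_sum_feature_scores(vectors, y)

    scores = np.full(y.size, np.nan)
    selected_per_fold: dict[int, np.ndarray] = {}
    failed: list[int] = []
    for f in range(folds.n_folds):
        tr, te = folds.train_indices(f), folds.test_indices(f)
        train_vecs = [vectors[i] for i in tr]
        test_vecs = [vectors[i] for i in te]
        test_ids = [ids[i] for i in te]
        try:
            if refit_mask_per_fold:
                mask = fit_background_mask(train_vecs, **(mask_rule or {}))
                _check_no_leak(mask.provenance, test_ids, "background mask")
                train_vecs = [apply_mask(v, mask) for v in train_vecs]
                test_vecs = [apply_mask(v, mask) for v in test_vecs]
            if in_fold_selection:
                ranking = rank_sum_feature_scores(train_vecs, y[tr])
                _check_no_leak(ranking.provenance, test_ids, "feature ranking")
            else:
                ranking = pre_ranking
            sel = top_k_features(ranking, k)
            selected_per_fold[f] = sel
            pos = np.searchsorted(train_vecs[0].flat_indices, sel)
            Xtr = np.vstack([v.values for v in train_vecs])[:, pos]
            Xte = np.vstack([v.values for v in test_vecs])[:, pos]
            est = spec.build()
            est.fit(Xtr, y[tr])
            proba = est.predict_proba(Xte)
            pos_col = int(np.flatnonzero(est.classes_ == True)[0])
            scores[te] = proba[:, pos_col]
        except Exception as e:  # fit failure: record and continue
            warnings.warn(f"fold {f} failed: {e}", stacklevel=2)
            failed.append(f)
    return CrossValResult(
        comparison_id=comparison_id,
        family=spec.family,
        k=k,
        sample_ids=ids,
        scores=scores,
        labels=y,
        fold_id=folds.fold_id.copy(),
        selected_per_fold=selected_per_fold,
        failed_folds=failed,
        in_fold_selection=in_fold_selection,
    )


def run_all(
    vectors_by_id: dict[str, FeatureVector],
    metadata,
    comparisons,
    families: Sequence[str] = CLASSIFIER_FAMILIES,
    ks: Sequence[int] = (100, 50, 20),
    n_folds: int = 10,
    seed: int = 0,
    log=None,
) -> list[CrossValResult]:
    """Run every (comparison, classifier family, k) combination.

    ``comparisons`` are :class:`faimsvoc.comparisons.ComparisonSpec`;
    comparisons with an empty arm are skipped with a log entry.  Returns one
    :class:`CrossValResult` per combination; the best performer per
    comparison is flagged downstream (by AUC) when building reports.
    """
    from faimsvoc.comparisons import resolve

    results: list[CrossValResult] = []
    for comp in comparisons:
        try:
            res = resolve(comp, metadata)
        except ValueError as e:
            if log is not None:
                log.append(f"skipped {comp.id}: {e}")
            continue
        ids = res.arm_a_ids + res.arm_b_ids
        missing = [i for i in ids if i not in vectors_by_id]
        if missing:
            raise KeyError(f"no feature vector for samples {missing[:5]}...")
        vecs = [vectors_by_id[i] for i in ids]
        y = np.array([i in set(res.arm_a_ids) for i in ids])
        folds = make_folds(y, n_folds=min(n_folds, len(ids)), seed=seed)
        for fam in families:
            for k in ks:
                results.append(
                    run_cv(
                        vecs,
                        y,
                        ClassifierSpec(fam, seed=seed),
                        k=k,
                        folds=folds,
                        comparison_id=comp.id,
                    )
                )
    return results
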
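"""ROC/AUC inference and report statistics for pooled out-of-fold scores.

The AUC is computed as the Mann-Whitney concordance probability (ties count
half), which is identical to the trapezoidal integral of the empirical ROC
curve.  Confidence intervals come from a stratified (per-class) percentile
bootstrap by default, or DeLong's asymptotic variance; the p-value is the
one-sided probability, under label permutation, of an AUC at least as large
as observed (i.e. a test against AUC = 0.5).  The single operating point is
the Youden-optimal threshold (maximal sensitivity + specificity - 1, ties
resolved towards higher sensitivity), and predictive values are computed at
the cohort's class prevalence.

``reconstruct_confusion`` inverts a published (rounded) sensitivity/
specificity pair back to the integer confusion matrix consistent with the
stated group sizes, trying both class orientations - useful for auditing
printed summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, as used for display tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RocCurve:
    """Empirical ROC curve: (FPR, TPR) points with their thresholds.

    Starts at (0, 0) and ends at (1, 1); both coordinates non-decreasing.
    A point's score threshold classifies ``score >= threshold`` as positive.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass
class PerformanceReport:
    """One summary-table row for one comparison x classifier x k."""

    comparison_id: str
    family: str
    k: int
    auc: float
    auc_ci_95: tuple[float, float]
    p_value: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    threshold: float
    positive_class: str
    n_pos: int
    n_neg: int
    best: bool = False

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["auc_ci_95"] = list(self.auc_ci_95)
        return d


def _validate_scores(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores contain NaN/Inf")
    if y.all() or not y.any():
        raise ValueError("AUC undefined with a single class present")
    return s, y


def mann_whitney_auc(scores, labels) -> float:
    """AUC as concordance: P(score+ > score-) + 0.5 P(tie)."""
    s, y = _validate_scores(scores, labels)
    n1, n0 = int(y.sum()), int((~y).sum())
    ranks = stats.rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_auc(scores, labels) -> tuple[RocCurve, float]:
    """Empirical ROC curve plus its AUC.

    The returned AUC is the Mann-Whitney concordance; the curve's
    trapezoidal integral equals it (a tested invariant).
    """
    s, y = _validate_scores(scores, labels)
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # one ROC vertex per distinct score value
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted) != 0), s_sorted.size - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(~y_sorted)[distinct]
    n1, n0 = int(y.sum()), int((~y).sum())
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    curve = RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds)
    return curve, mann_whitney_auc(s, y)


def _auc_from_ranks(ranks: np.ndarray, pos_mask: np.ndarray, n1: int, n0: int) -> float:
    return (ranks[pos_mask].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _delong_ci(s: np.ndarray, y: np.ndarray, level: float) -> tuple[float, float]:
    """DeLong's asymptotic CI via placement values."""
    pos, neg = s[y], s[~y]
    m, n = pos.size, neg.size
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = v10.mean()
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half))


def auc_inference(
    scores,
    labels,
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[tuple[float, float], float]:
    """95% CI and permutation p-value for the AUC.

    CI: stratified percentile bootstrap (resampling within each class) or
    DeLong.  p: one-sided P(AUC_perm >= AUC_obs) under random label
    permutation, with the +1 small-sample correction.
    """
    s, y = _validate_scores(scores, labels)
    n1, n0 = int(y.sum()), int((~y).sum())
    n = n1 + n0
    if min(n1, n0) < 2:
        raise ValueError("need >= 2 samples per class for AUC inference")
    rng = np.random.default_rng(seed)
    obs = mann_whitney_auc(s, y)

    if ci_method == "bootstrap":
        pos, neg = s[y], s[~y]
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            bs = np.concatenate(
                [rng.choice(pos, n1, replace=True), rng.choice(neg, n0, replace=True)]
            )
            ranks = stats.rankdata(bs)
            aucs[b] = (ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
        ci = (float(np.quantile(aucs, 0.025)), float(np.quantile(aucs, 0.975)))
    elif ci_method == "delong":
        ci = _delong_ci(s, y, 0.95)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    # permutation p: rank vector is fixed; only the positive set changes
    ranks = stats.rankdata(s)
    perm_auc = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.permutation(n)[:n1]
        perm_auc[b] = (ranks[idx].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    p = float((1 + np.sum(perm_auc >= obs - 1e-12)) / (n_perm + 1))
    return ci, p


def operating_point(curve: RocCurve) -> tuple[float, float, float]:
    """Youden-optimal threshold: (threshold, sensitivity, specificity).

    Maximises J = TPR - FPR; among ties prefers the higher sensitivity.
    """
    j = curve.tpr - curve.fpr
    best = np.flatnonzero(j >= j.max() - 1e-12)
    pick = best[np.argmax(curve.tpr[best])]
    return (
        float(curve.thresholds[pick]),
        float(curve.tpr[pick]),
        float(1.0 - curve.fpr[pick]),
    )


def predictive_values(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> tuple[float, float]:
    """PPV and NPV at the cohort prevalence n_pos / (n_pos + n_neg)."""
    for r, name in ((sensitivity, "sensitivity"), (specificity, "specificity")):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class counts must be >= 1")
    tp = sensitivity * n_pos
    fp = (1.0 - specificity) * n_neg
    tn = specificity * n_neg
    fn = (1.0 - sensitivity) * n_pos
    ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
    npv = tn / (tn + fn) if tn + fn > 0 else float("nan")
    return ppv, npv


@dataclass
class ConfusionCandidate:
    """One integer confusion matrix consistent with printed rates."""

    positive_arm: str  # "a" or "b": which group size acts as the positive class
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


def reconstruct_confusion(
    printed_sens: float, printed_spec: float, n_a: int, n_b: int
) -> list[ConfusionCandidate]:
    """Invert printed (2-dp) sensitivity/specificity to integer counts.

    Tries both orientations (arm a or arm b as the positive class) and
    returns every integer TP/TN whose rates round (half-up, 2 dp) to the
    printed values.  An empty list means no integer solution exists - the
    printed row is internally inconsistent with the stated group sizes.
    """
    out: list[ConfusionCandidate] = []
    seen: set[tuple[int, int, int, int]] = set()
    for arm, n_pos, n_neg in (("a", n_a, n_b), ("b", n_b, n_a)):
        tps = [
            tp
            for tp in range(n_pos + 1)
            if round_half_up(tp / n_pos) == round_half_up(printed_sens)
        ]
        tns = [
            tn
            for tn in range(n_neg + 1)
            if round_half_up(tn / n_neg) == round_half_up(printed_spec)
        ]
        for tp in tps:
            for tn in tns:
                key = (tp, n_pos - tp, tn, n_neg - tn)
                if key in seen:
                    continue  # symmetric duplicate (e.g. n_a == n_b, perfect rates)
                seen.add(key)
                out.append(
                    ConfusionCandidate(
                        positive_arm=arm, tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn
                    )
                )
    return out


def build_report(
    result,
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    n_perm: int = 10000,
    seed: int = 0,
    positive_class: str = "arm_a",
) -> PerformanceReport:
    """Full summary-row statistics from one :class:`CrossValResult`.

    Samples from failed folds (unscored, NaN) are dropped from the pooled
    ROC; the result's ``failed_folds`` list records the incompleteness.
    """
    scored = np.isfinite(np.asarray(result.scores, dtype=float))
    s, y = _validate_scores(
        np.asarray(result.scores, dtype=float)[scored],
        np.asarray(result.labels)[scored],
    )
    curve, auc = roc_auc(s, y)
    ci, p = auc_inference(
        s, y, ci_method=ci_method, n_boot=n_boot, n_perm=n_perm, seed=seed
    )
    thr, sens, spec = operating_point(curve)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    ppv, npv = predictive_values(sens, spec, n_pos, n_neg)
    return PerformanceReport(
        comparison_id=result.comparison_id,
        family=result.family,
        k=result.k,
        auc=auc,
        auc_ci_95=ci,
        p_value=p,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        threshold=thr,
        positive_class=positive_class,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def plot_roc(curve: RocCurve, auc: float, title: str, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(curve.fpr, curve.tpr, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.set_title(f"{title} (AUC = {auc:.2f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
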
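"""The study's eleven clinical group comparisons and baseline tables.

Primary comparisons: SAM vs healthy sibling controls (a validation of the
method), mortality within 6 days of admission vs discharge, early mortality
(death on day 1-3) vs discharge, late mortality (day 4-6) vs discharge, and
early vs late mortality.  Secondary comparisons stratify the SAM cohort by
known mortality risk factors: weight-for-age z-score <= -3, oedema,
diarrhoea, pneumonia, HIV status (unknowns excluded) and age <= 2 years.

Baseline characteristics are compared arm-vs-arm with a pooled-variance
(Student) two-sample t-test for continuous variables and a two-proportion
z-test for binary ones; subjects missing a variable drop out of that
variable's row only, so each row carries its own denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from faimsvoc.io import CohortMetadata

Predicate = Callable[[pd.DataFrame], pd.Series]


@dataclass(frozen=True)
class ComparisonSpec:
    """Two disjoint arms defined by predicates over the metadata table.

    ``arm_a`` is the reference/positive arm for score orientation (the
    rendered report states the orientation explicitly).  Subjects matching
    neither predicate are excluded, with counts logged by :func:`resolve`.
    """

    id: str
    label: str
    arm_a_name: str
    arm_b_name: str
    arm_a: Predicate
    arm_b: Predicate
    orientation_note: str = ""


@dataclass
class Resolution:
    spec: ComparisonSpec
    arm_a_ids: list[str]
    arm_b_ids: list[str]
    excluded_ids: list[str]

    @property
    def arm_sizes(self) -> tuple[int, int]:
        return len(self.arm_a_ids), len(self.arm_b_ids)


def _sam(t: pd.DataFrame) -> pd.Series:
    return t["group"] == "SAM"


def _died_between(t: pd.DataFrame, lo: int, hi: int) -> pd.Series:
    return (
        _sam(t)
        & (t["outcome"] == "died")
        & t["day_of_death"].between(lo, hi)
    )


def _discharged(t: pd.DataFrame) -> pd.Series:
    return _sam(t) & (t["outcome"] == "discharged")


def _bool_arm(col: str, value: bool) -> Predicate:
    def pred(t: pd.DataFrame) -> pd.Series:
        return _sam(t) & (t[col] == value).fillna(False)

    return pred


def builtin_comparisons() -> list[ComparisonSpec]:
    """The study's eleven comparisons (4 mortality + 7 morbidity rows)."""
    specs = [
        ComparisonSpec(
            "mortality_vs_survival",
            "Mortality vs. survival",
            "died",
            "discharged",
            lambda t: _died_between(t, 1, 6),
            _discharged,
            "positive arm: died within 6 days of admission",
        ),
        ComparisonSpec(
            "early_mortality_vs_survival",
            "Early mortality vs. survival",
            "died_early",
            "discharged",
            lambda t: _died_between(t, 1, 3),
            _discharged,
            "positive arm: died within 3 days (early mortality)",
        ),
        ComparisonSpec(
            "late_mortality_vs_survival",
            "Late mortality vs. survival",
            "died_late",
            "discharged",
            lambda t: _died_between(t, 4, 6),
            _discharged,
            "positive arm: died on day 4-6 (late mortality)",
        ),
        ComparisonSpec(
            "early_vs_late_mortality",
            "Early vs. late mortality",
            "died_early",
            "died_late",
            lambda t: _died_between(t, 1, 3),
            lambda t: _died_between(t, 4, 6),
            "positive arm: early mortality",
        ),
        ComparisonSpec(
            "sam_vs_healthy_controls",
            "SAM vs. healthy controls",
            "SAM",
            "healthy_control",
            _sam,
            lambda t: t["group"] == "healthy_control",
            "positive arm: SAM (method validation comparison)",
        ),
        ComparisonSpec(
            "waz_le_minus3",
            "WAZ <= -3 vs. WAZ > -3",
            "waz_le_-3",
            "waz_gt_-3",
            lambda t: _sam(t) & (t["waz"] <= -3),
            lambda t: _sam(t) & (t["waz"] > -3),
            "positive arm: weight-for-age z-score <= -3 SD",
        ),
        ComparisonSpec(
            "oedema_vs_no_oedema",
            "Oedema vs. no oedema",
            "oedema",
            "no_oedema",
            _bool_arm("oedema", True),
            _bool_arm("oedema", False),
            "positive arm: oedematous (kwashiorkor phenotype)",
        ),
        ComparisonSpec(
            "diarrhoea_vs_no_diarrhoea",
            "Diarrhoea vs. no diarrhoea",
            "diarrhoea",
            "no_diarrhoea",
            _bool_arm("diarrhoea", True),
            _bool_arm("diarrhoea", False),
            "positive arm: diarrhoea at admission",
        ),
        ComparisonSpec(
            "pneumonia_vs_no_pneumonia",
            "Pneumonia vs. no pneumonia",
            "pneumonia",
            "no_pneumonia",
            _bool_arm("pneumonia", True),
            _bool_arm("pneumonia", False),
            "positive arm: severe pneumonia at admission",
        ),
        ComparisonSpec(
            "hiv_pos_vs_neg",
            "HIV+ vs. HIV-",
            "hiv_positive",
            "hiv_negative",
            lambda t: _sam(t) & (t["hiv"] == "positive"),
            lambda t: _sam(t) & (t["hiv"] == "negative"),
            "positive arm: HIV positive; unknown HIV status excluded",
        ),
        ComparisonSpec(
            "age_le_2y_vs_gt_2y",
            "Age <= 2 yrs vs. age > 2 yrs",
            "age_le_2y",
            "age_gt_2y",
            lambda t: _sam(t) & (t["age_months"] <= 24),
            lambda t: _sam(t) & (t["age_months"] > 24),
            "positive arm: age <= 2 years",
        ),
    ]
    return specs


def resolve(spec: ComparisonSpec, metadata: CohortMetadata) -> Resolution:
    """Apply a comparison's predicates; error on an empty arm."""
    t = metadata.table
    a = spec.arm_a(t).to_numpy(dtype=bool)
    b = spec.arm_b(t).to_numpy(dtype=bool)
    if (a & b).any():
        both = t.loc[a & b, "sample_id"].tolist()
        raise ValueError(f"{spec.id}: arms overlap on {both}")
    if not a.any():
        raise ValueError(f"{spec.id}: arm '{spec.arm_a_name}' is empty on this cohort")
    if not b.any():
        raise ValueError(f"{spec.id}: arm '{spec.arm_b_name}' is empty on this cohort")
    ids = t["sample_id"]
    return Resolution(
        spec=spec,
        arm_a_ids=ids[a].tolist(),
        arm_b_ids=ids[b].tolist(),
        excluded_ids=ids[~(a | b)].tolist(),
    )


# ---------------------------------------------------------------------------
# baseline characteristics


def pooled_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance two-sample t-test from summary statistics.

    Equivalent to the raw-data Student t-test on any data realising these
    summaries (SDs taken with ddof=1).  Returns (t, two-sided p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per arm")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        return 0.0, 1.0
    t = (mean1 - mean2) / se
    return float(t), float(2.0 * stats.t.sf(abs(t), df))


def two_proportion_p(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided two-proportion z-test (pooled SE, no continuity corr.)."""
    if n1 < 1 or n2 < 1:
        raise ValueError("need n >= 1 per arm")
    p1, p2 = x1 / n1, x2 / n2
    pool = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pool * (1 - pool) * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        return 1.0
    z = (p1 - p2) / se
    return float(2.0 * stats.norm.sf(abs(z)))


CONTINUOUS_VARS = ("age_months", "muac_cm", "waz", "whz", "haz")
BINARY_VARS = ("oedema", "diarrhoea", "vomiting", "fever", "pneumonia", "danger_signs")


def baseline_table(
    metadata: CohortMetadata,
    grouping: ComparisonSpec | None = None,
    test: str = "pooled",
) -> pd.DataFrame:
    """Admission-characteristics table by arm, with per-variable p-values.

    Continuous rows: mean (SD) per arm, Student (pooled) or Welch t-test.
    Binary rows: n (%) per arm, two-proportion z-test.  Subjects with the
    variable missing are dropped from that row only.
    """
    if grouping is None:
        grouping = builtin_comparisons()[0]  # mortality vs survival
    res = resolve(grouping, metadata)
    t = metadata.table.set_index("sample_id")
    a, b = t.loc[res.arm_a_ids], t.loc[res.arm_b_ids]
    rows = []
    for var in CONTINUOUS_VARS:
        if var not in t.columns:
            continue
        va, vb = a[var].dropna(), b[var].dropna()
        if len(va) < 2 or len(vb) < 2:
            continue
        if test == "pooled":
            _, p = pooled_t_from_summary(
                va.mean(), va.std(ddof=1), len(va), vb.mean(), vb.std(ddof=1), len(vb)
            )
        elif test == "welch":
            p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {
                "variable": var,
                "type": "continuous",
                f"{grouping.arm_a_name}_summary": f"{va.mean():.1f} ({va.std(ddof=1):.1f})",
                f"{grouping.arm_b_name}_summary": f"{vb.mean():.1f} ({vb.std(ddof=1):.1f})",
                f"{grouping.arm_a_name}_n": len(va),
                f"{grouping.arm_b_name}_n": len(vb),
                "p": p,
            }
        )
    for var in BINARY_VARS:
        if var not in t.columns:
            continue
        va, vb = a[var].dropna(), b[var].dropna()
        if len(va) < 1 or len(vb) < 1:
            continue
        xa, xb = int(va.sum()), int(vb.sum())
        rows.append(
            {
                "variable": var,
                "type": "binary",
                f"{grouping.arm_a_name}_summary": f"{xa} ({100 * xa / len(va):.1f}%)",
                f"{grouping.arm_b_name}_summary": f"{xb} ({100 * xb / len(vb):.1f}%)",
                f"{grouping.arm_a_name}_n": len(va),
                f"{grouping.arm_b_name}_n": len(vb),
                "p": two_proportion_p(xa, len(va), xb, len(vb)),
            }
        )
    return pd.DataFrame(rows)
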
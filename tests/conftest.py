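import numpy as np
import pandas as pd
import pytest

from faimsvoc.io import CohortMetadata
from faimsvoc.layout import Geometry
from faimsvoc.simulate import SyntheticConfig, simulate_cohort

SMALL_GEOM = Geometry(11, 16)
REDUCED_GEOM = Geometry(51, 128)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny but complete synthetic cohort for fast structural tests."""
    from faimsvoc.simulate import CohortConfig

    cfg = SyntheticConfig(
        geometry=SMALL_GEOM,
        cohort=CohortConfig(n_discharged=8, n_died_early=3, n_died_late=3, n_controls=3),
        seed=42,
    )
    return simulate_cohort(cfg)


def study_metadata() -> CohortMetadata:
    """Deterministic 57+7-subject metadata table realising the study's
    admission-table counts exactly: 38 discharged / 19 died (9 early, 10
    late), oedema 22 (17/5), diarrhoea 23 (12/11), HIV 14+/38-/5 unknown,
    pneumonia 17 (10/7), plus 7 healthy controls."""
    rows = []

    def mk(sid, outcome, dod, oedema, diarrhoea, hiv, pneumonia, age, waz, group="SAM"):
        rows.append(
            dict(
                sample_id=sid,
                site="QECH",
                age_months=age,
                sex="male",
                muac_cm=11.0,
                waz=waz,
                whz=-3.0,
                haz=-3.0,
                oedema=oedema,
                diarrhoea=diarrhoea,
                vomiting=False,
                fever=False,
                pneumonia=pneumonia,
                hiv=hiv,
                danger_signs=False,
                group=group,
                outcome=outcome,
                day_of_death=dod,
            )
        )

    for i in range(38):  # discharged: 17 oedema, 12 diarrhoea, 7 HIV+, 3 unknown, 10 pneumonia
        hiv = "positive" if i < 7 else ("unknown" if i < 10 else "negative")
        mk(
            f"D{i:02d}", "discharged", None,
            i < 17, i < 12, hiv, i < 10,
            age=30.0 if i < 19 else 20.0, waz=-4.0 if i < 20 else -2.0,
        )
    for i in range(19):  # died: 9 early / 10 late; 5 oedema, 11 diarrhoea, 7 HIV+, 2 unknown
        hiv = "positive" if i < 7 else ("unknown" if i < 9 else "negative")
        mk(
            f"M{i:02d}", "died", 2.0 if i < 9 else 5.0,
            i < 5, i < 11, hiv, i < 7,
            age=15.0, waz=-4.5 if i < 12 else -2.5,
        )
    for i in range(7):
        mk(f"H{i:02d}", "discharged", None, False, False, "negative", False,
           age=52.0, waz=-0.5, group="healthy_control")
    t = pd.DataFrame(rows)
    for col in ("oedema", "diarrhoea", "vomiting", "fever", "pneumonia", "danger_signs"):
        t[col] = pd.array(t[col], dtype="boolean")
    return CohortMetadata(t)


@pytest.fixture(scope="session")
def table1_metadata():
    return study_metadata()
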
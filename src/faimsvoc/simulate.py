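"""Synthetic FAIMS cohort generator with planted, ground-truthed effects.

Emulates what a Lonestar-style instrument produces for a faecal headspace
cohort: per subject, three replicate runs of paired positive/negative
51 x 512 dispersion plots consisting of

- a smooth reactant-ion background ridge whose compensation-voltage
  position drifts with the dispersion field and whose amplitude decays
  with it;
- sparse 2D Gaussian analyte peaks that likewise drift along a trajectory
  in (dispersion field, CV) space;
- per-pixel Gaussian instrument noise, per-sample multiplicative gain
  jitter, and extra run-to-run jitter on replicates 1 and 3 (the
  motivation for analysing the second replicate);

plus an admission-metadata table whose marginals (arm sizes, age, MUAC,
anthropometry, comorbidity rates, HIV distribution) mirror the study
cohort: 38 SAM children discharged alive, 19 who died within 6 days of
admission (9 on days 1-3, 10 on days 4-6) and 7 healthy sibling controls.

Class structure is planted as amplitude increments (in units of the pixel
noise SD, i.e. Cohen's d at the peak centre) and/or CV shifts on chosen
peaks for subjects matching a predicate ("died", "healthy_control", ...).
The exact set of affected pixels is emitted as ground truth, so feature-
recovery rates are first-class outputs rather than guesswork.  What the
generator does NOT model: real VOC chemistry, inter-instrument alignment,
or correlated biological covariation between clinical variables and the
volatilome beyond the planted effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from faimsvoc.io import (
    CohortMetadata,
    DispersionScan,
    FaimsSample,
    InstrumentRun,
    select_replicate,
)
from faimsvoc.layout import Geometry, POLARITIES


@dataclass(frozen=True)
class Peak:
    """A 2D Gaussian analyte peak; its CV centre drifts with the field."""

    polarity: str
    df_center: float  # % dispersion field
    cv_center: float  # volts at df_center
    width_df: float  # SD, % units
    width_cv: float  # SD, volts
    amplitude: float  # a.u.
    cv_slope: float = -0.03  # volts per % of dispersion field


@dataclass(frozen=True)
class ClassEffect:
    """Planted difference for subjects matching ``where``.

    ``amplitude_d`` is the peak-centre intensity increment in units of the
    per-pixel noise SD (an effect size d); ``cv_shift`` moves the peak in
    volts.
    """

    where: str
    peak_index: int
    amplitude_d: float = 0.0
    cv_shift: float = 0.0


# predicates over a metadata row for ClassEffect.where
_EFFECT_PREDICATES = {
    "died": lambda r: r["outcome"] == "died",
    "died_early": lambda r: r["outcome"] == "died" and r["day_of_death"] <= 3,
    "died_late": lambda r: r["outcome"] == "died" and r["day_of_death"] >= 4,
    "healthy_control": lambda r: r["group"] == "healthy_control",
    "oedema": lambda r: pd.notna(r["oedema"]) and bool(r["oedema"]),
    "diarrhoea": lambda r: pd.notna(r["diarrhoea"]) and bool(r["diarrhoea"]),
    "pneumonia": lambda r: pd.notna(r["pneumonia"]) and bool(r["pneumonia"]),
    "hiv_positive": lambda r: r["hiv"] == "positive",
}


def default_peaks() -> tuple[Peak, ...]:
    return (
        Peak("positive", 30.0, 2.2, 4.0, 0.35, 9.0),
        Peak("positive", 55.0, 0.8, 5.0, 0.45, 7.0),
        Peak("positive", 70.0, -1.5, 4.5, 0.40, 6.0),
        Peak("negative", 40.0, 1.2, 4.5, 0.40, 8.0),
        Peak("negative", 65.0, -0.8, 5.0, 0.45, 6.5),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Arm sizes and per-arm metadata marginals (study-cohort defaults)."""

    n_discharged: int = 38
    n_died_early: int = 9
    n_died_late: int = 10
    n_controls: int = 7


@dataclass(frozen=True)
class SyntheticConfig:
    geometry: Geometry = Geometry(51, 512)
    background_amplitude: float = 20.0
    background_cv0: float = 1.0  # ridge CV position at 0% field
    background_drift: float = -3.0  # ridge CV drift over the full field, volts
    background_width: float = 0.8  # ridge SD, volts
    peaks: tuple[Peak, ...] = field(default_factory=default_peaks)
    class_effects: tuple[ClassEffect, ...] = (
        # mortality signal on two peaks; strong multi-peak control signature
        ClassEffect("died", 1, amplitude_d=1.5),
        ClassEffect("died", 4, amplitude_d=1.5, cv_shift=0.1),
        ClassEffect("healthy_control", 0, amplitude_d=4.0),
        ClassEffect("healthy_control", 2, amplitude_d=4.0, cv_shift=0.2),
        ClassEffect("healthy_control", 3, amplitude_d=4.0),
    )
    noise_sd: float = 1.0
    gain_jitter: float = 0.05  # lognormal sigma of per-sample gain
    replicate_jitter: tuple[float, float, float] = (0.10, 0.02, 0.10)
    cohort: CohortConfig = CohortConfig()
    n_replicates: int = 3
    ground_truth_rel_threshold: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for p in self.peaks:
            if p.width_df <= 0 or p.width_cv <= 0 or p.amplitude <= 0:
                raise ValueError("peak widths and amplitudes must be positive")
        for e in self.class_effects:
            if not 0 <= e.peak_index < len(self.peaks):
                raise ValueError(
                    f"class effect refers to non-existent peak {e.peak_index}"
                )
            if e.where not in _EFFECT_PREDICATES:
                raise ValueError(f"unknown effect predicate {e.where!r}")
        c = self.cohort
        if min(c.n_discharged, c.n_died_early + c.n_died_late, c.n_controls) < 2:
            raise ValueError("every cohort arm needs >= 2 subjects")


@dataclass
class SimulatedCohort:
    samples: list[FaimsSample]
    runs: dict[str, list[InstrumentRun]]
    metadata: CohortMetadata
    ground_truth: dict[str, np.ndarray]  # effect key -> planted flat indices
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# metadata


def _norm(rng, mean, sd, n, lo, hi):
    return np.clip(rng.normal(mean, sd, n), lo, hi).round(1)


def _simulate_metadata(rng: np.random.Generator, c: CohortConfig) -> CohortMetadata:
    """Draw per-arm marginals mirroring the study's admission table."""
    rows = []

    def arm(n, prefix, site_p, age, muac, waz, whz, haz, rates, hiv_p, male_p):
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{prefix}{i + 1:03d}",
                    "site": rng.choice(["CPGH", "KCH", "QECH"], p=site_p),
                    "age_months": float(_norm(rng, *age, 1, 6, 70)[0]),
                    "sex": "male" if rng.random() < male_p else "female",
                    "muac_cm": float(_norm(rng, *muac, 1, 7, 18)[0]),
                    "waz": float(_norm(rng, *waz, 1, -8, 2)[0]),
                    "whz": float(_norm(rng, *whz, 1, -8, 2)[0]),
                    "haz": float(_norm(rng, *haz, 1, -8, 2)[0]),
                    "oedema": bool(rng.random() < rates["oedema"]),
                    "diarrhoea": bool(rng.random() < rates["diarrhoea"]),
                    "vomiting": bool(rng.random() < rates["vomiting"]),
                    "fever": bool(rng.random() < rates["fever"]),
                    "pneumonia": bool(rng.random() < rates["pneumonia"]),
                    "hiv": rng.choice(["negative", "positive", "unknown"], p=hiv_p),
                    "danger_signs": bool(rng.random() < rates["danger"]),
                }
            )

    # discharged SAM arm (study means/SDs and rates for survivors)
    arm(
        c.n_discharged,
        "D",
        [15 / 38, 4 / 38, 19 / 38],
        (25.9, 16.1),
        (11.5, 1.6),
        (-3.8, 1.3),
        (-3.1, 1.4),
        (-3.2, 1.5),
        dict(oedema=17 / 38, diarrhoea=12 / 38, vomiting=7 / 38, fever=9 / 38,
             pneumonia=10 / 38, danger=2 / 38),
        [28 / 38, 7 / 38, 3 / 38],
        23 / 38,
    )
    n_died = c.n_died_early + c.n_died_late
    arm(
        n_died,
        "M",
        [10 / 19, 1 / 19, 8 / 19],
        (16.8, 13.3),
        (10.5, 1.5),
        (-4.3, 1.6),
        (-3.7, 1.4),
        (-3.1, 2.3),
        dict(oedema=5 / 19, diarrhoea=11 / 19, vomiting=7 / 19, fever=10 / 19,
             pneumonia=7 / 19, danger=6 / 19),
        [10 / 19, 7 / 19, 2 / 19],
        12 / 19,
    )
    arm(
        c.n_controls,
        "H",
        [0.0, 0.0, 1.0],
        (52.9, 22.1),
        (15.1, 2.0),
        (-0.5, 1.0),
        (-0.5, 1.0),
        (-0.5, 1.0),
        dict(oedema=0, diarrhoea=0, vomiting=0, fever=0, pneumonia=0, danger=0),
        [1.0, 0.0, 0.0],
        4 / 7,
    )
    t = pd.DataFrame(rows)
    t["group"] = ["SAM"] * (c.n_discharged + n_died) + ["healthy_control"] * c.n_controls
    t["outcome"] = (
        ["discharged"] * c.n_discharged
        + ["died"] * n_died
        + ["discharged"] * c.n_controls
    )
    dod = np.full(len(t), np.nan)
    died0 = c.n_discharged
    dod[died0 : died0 + c.n_died_early] = rng.integers(1, 4, c.n_died_early)
    dod[died0 + c.n_died_early : died0 + n_died] = rng.integers(4, 7, c.n_died_late)
    t["day_of_death"] = dod
    for col in ("oedema", "diarrhoea", "vomiting", "fever", "pneumonia", "danger_signs"):
        t[col] = pd.array(t[col], dtype="boolean")
    return CohortMetadata(t)


# ---------------------------------------------------------------------------
# matrices


def _peak_field(geom: Geometry, p: Peak, cv_shift: float = 0.0) -> np.ndarray:
    """Noiseless unit-amplitude image of one peak on its polarity plane."""
    df = geom.default_df_axis()[:, None]
    cv = geom.default_cv_axis()[None, :]
    center = p.cv_center + cv_shift + p.cv_slope * (df - p.df_center)
    return np.exp(
        -0.5 * (((df - p.df_center) / p.width_df) ** 2 + ((cv - center) / p.width_cv) ** 2)
    )


def _background(cfg: SyntheticConfig) -> np.ndarray:
    geom = cfg.geometry
    df = geom.default_df_axis()[:, None]
    cv = geom.default_cv_axis()[None, :]
    ridge_cv = cfg.background_cv0 + cfg.background_drift * df / 100.0
    amp = cfg.background_amplitude * (1.0 - 0.6 * df / 100.0)
    return amp * np.exp(-0.5 * ((cv - ridge_cv) / cfg.background_width) ** 2)


def _subject_effects(cfg: SyntheticConfig, row: pd.Series) -> list[ClassEffect]:
    return [e for e in cfg.class_effects if _EFFECT_PREDICATES[e.where](row)]


def _noiseless_planes(cfg: SyntheticConfig, effects: list[ClassEffect]) -> dict[str, np.ndarray]:
    """Background + peaks per polarity, with the given effects applied."""
    by_peak: dict[int, tuple[float, float]] = {}
    for e in effects:
        d, s = by_peak.get(e.peak_index, (0.0, 0.0))
        by_peak[e.peak_index] = (d + e.amplitude_d, s + e.cv_shift)
    bg = _background(cfg)
    planes = {pol: bg.copy() for pol in POLARITIES}
    for i, p in enumerate(cfg.peaks):
        d, shift = by_peak.get(i, (0.0, 0.0))
        amp = p.amplitude + d * cfg.noise_sd
        planes[p.polarity] += amp * _peak_field(cfg.geometry, p, cv_shift=shift)
    return planes


def _ground_truth(cfg: SyntheticConfig) -> dict[str, np.ndarray]:
    """Flat pixel indices materially changed by each effect group."""
    base = _noiseless_planes(cfg, [])
    out: dict[str, np.ndarray] = {}
    for where in sorted({e.where for e in cfg.class_effects}):
        effects = [e for e in cfg.class_effects if e.where == where]
        affected = _noiseless_planes(cfg, effects)
        delta = np.concatenate(
            [np.abs(affected[pol] - base[pol]).ravel() for pol in POLARITIES]
        )
        if delta.max() == 0:
            out[where] = np.empty(0, dtype=np.intp)
        else:
            out[where] = np.flatnonzero(
                delta >= cfg.ground_truth_rel_threshold * delta.max()
            ).astype(np.intp)
    return out


def simulate_cohort(config: SyntheticConfig | None = None) -> SimulatedCohort:
    """Generate a full cohort: metadata, 3 runs per subject, ground truth.

    Deterministic given ``config.seed``; byte-identical on re-run.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    metadata = _simulate_metadata(rng, cfg.cohort)
    geom = cfg.geometry
    df_axis, cv_axis = geom.default_df_axis(), geom.default_cv_axis()

    runs: dict[str, list[InstrumentRun]] = {}
    samples: list[FaimsSample] = []
    for _, row in metadata.table.iterrows():
        sid = row["sample_id"]
        planes = _noiseless_planes(cfg, _subject_effects(cfg, row))
        gain = float(np.exp(rng.normal(0.0, cfg.gain_jitter)))
        subject_runs = []
        for rep in range(1, cfg.n_replicates + 1):
            rep_gain = gain * float(
                np.exp(rng.normal(0.0, cfg.replicate_jitter[rep - 1]))
            )
            scans = {}
            for pol in POLARITIES:
                mat = planes[pol] * rep_gain + rng.normal(
                    0.0, cfg.noise_sd, (geom.n_df, geom.n_cv)
                )
                scans[pol] = DispersionScan(pol, mat, df_axis, cv_axis)
            subject_runs.append(
                InstrumentRun(sid, rep, scans["positive"], scans["negative"])
            )
        runs[sid] = subject_runs
        samples.append(
            FaimsSample(
                sample_id=sid,
                selected_run=select_replicate(subject_runs, 2),
                metadata=row,
            )
        )
    return SimulatedCohort(
        samples=samples,
        runs=runs,
        metadata=metadata,
        ground_truth=_ground_truth(cfg),
        config=cfg,
    )


def simulate_null_cohort(config: SyntheticConfig | None = None) -> SimulatedCohort:
    """Same generative model with every class effect removed: the labels
    carry no information about the matrices (leakage-guard fixture)."""
    cfg = config or SyntheticConfig()
    return simulate_cohort(replace(cfg, class_effects=()))


def write_cohort(cohort: SimulatedCohort, outdir) -> None:
    """Write metadata + per-run matrix CSVs in the package dialects."""
    from pathlib import Path

    from faimsvoc.io import write_metadata, write_scan

    outdir = Path(outdir)
    scans = outdir / "scans"
    scans.mkdir(parents=True, exist_ok=True)
    write_metadata(outdir / "metadata.csv", cohort.metadata)
    for sid, subject_runs in cohort.runs.items():
        for run in subject_runs:
            for pol in POLARITIES:
                write_scan(
                    scans / f"{sid}_r{run.replicate_index}_{pol}.csv",
                    getattr(run, pol),
                )
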
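"""Data model and plain-text I/O for FAIMS scans and cohort metadata.

Matrix-CSV dialect (one file per sample x replicate x polarity): the first
row holds the compensation-voltage axis (volts, descending +6 -> -6) after
an empty corner cell; the first column holds the dispersion-field axis
(percent, ascending 0 -> 100); every other cell is an ion-current intensity
in arbitrary units (negative values allowed - the instrument baseline may
undershoot).  Floats are written with 17 significant digits so a
write/read round-trip is value-exact.

Metadata CSV: one row per subject, header fixed by
:data:`METADATA_COLUMNS`.  Booleans are ``1``/``0``; missing numeric or
boolean cells are empty; HIV status ``unknown`` (refused or died before
testing) is a real category, distinct from an empty cell.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from faimsvoc.layout import DEFAULT_GEOMETRY, POLARITIES, Geometry


class FaimsIOError(ValueError):
    """Malformed scan or metadata file."""


@dataclass
class DispersionScan:
    """One polarity's ion-current matrix for one instrument run.

    ``intensities`` has shape (n_df, n_cv); ``df_axis`` is the dispersion
    field in percent (ascending), ``cv_axis`` the compensation voltage in
    volts (descending).
    """

    polarity: str
    intensities: np.ndarray
    df_axis: np.ndarray
    cv_axis: np.ndarray

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}, got {self.polarity!r}")
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.df_axis = np.asarray(self.df_axis, dtype=float)
        self.cv_axis = np.asarray(self.cv_axis, dtype=float)
        n_df, n_cv = self.intensities.shape
        if self.df_axis.shape != (n_df,) or self.cv_axis.shape != (n_cv,):
            raise ValueError(
                f"axis lengths ({self.df_axis.size}, {self.cv_axis.size}) do not match "
                f"matrix shape {self.intensities.shape}"
            )
        if not np.all(np.diff(self.df_axis) > 0):
            raise ValueError("df_axis must be strictly ascending")
        if not np.all(np.diff(self.cv_axis) < 0):
            raise ValueError("cv_axis must be strictly descending")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain NaN/Inf")

    @property
    def geometry(self) -> Geometry:
        return Geometry(*self.intensities.shape)


@dataclass
class InstrumentRun:
    """A single instrument run: paired positive and negative scans."""

    sample_id: str
    replicate_index: int
    positive: DispersionScan
    negative: DispersionScan

    def __post_init__(self) -> None:
        if self.positive.polarity != "positive" or self.negative.polarity != "negative":
            raise ValueError("scan polarities do not match their slots")
        if self.positive.geometry != self.negative.geometry:
            raise ValueError(
                f"polarity geometries differ: {self.positive.geometry} vs {self.negative.geometry}"
            )

    @property
    def geometry(self) -> Geometry:
        return self.positive.geometry


@dataclass
class FaimsSample:
    """A subject's selected instrument run plus its metadata row."""

    sample_id: str
    selected_run: InstrumentRun
    metadata: "pd.Series | None" = None
    replicate_choice: int = 2

    def __post_init__(self) -> None:
        if self.selected_run.replicate_index != self.replicate_choice:
            raise ValueError(
                f"selected run is replicate {self.selected_run.replicate_index}, "
                f"configured choice is {self.replicate_choice}"
            )


METADATA_COLUMNS = [
    "sample_id",
    "site",
    "age_months",
    "sex",
    "muac_cm",
    "waz",
    "whz",
    "haz",
    "oedema",
    "diarrhoea",
    "vomiting",
    "fever",
    "pneumonia",
    "hiv",
    "danger_signs",
    "group",
    "outcome",
    "day_of_death",
]

SITES = ("CPGH", "KCH", "QECH")
_BOOL_COLUMNS = ("oedema", "diarrhoea", "vomiting", "fever", "pneumonia", "danger_signs")
_FLOAT_COLUMNS = ("age_months", "muac_cm", "waz", "whz", "haz")


@dataclass
class CohortMetadata:
    """Validated per-subject clinical table (one row per subject).

    Boolean columns are pandas nullable booleans so a missing flag excludes
    the subject only from comparisons needing that flag.  ``day_of_death``
    is present iff ``outcome == "died"`` and lies in 1..6 (deaths beyond
    day 6 are outside the study window).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in METADATA_COLUMNS if c not in t.columns]
        if missing:
            raise FaimsIOError(f"metadata missing mandatory columns: {missing}")
        if len(t) == 0:
            raise FaimsIOError("metadata table is empty")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise FaimsIOError(f"duplicate sample_id values: {dup}")
        bad_site = set(t["site"].dropna()) - set(SITES)
        if bad_site:
            raise FaimsIOError(f"unknown site codes: {sorted(bad_site)}")
        if not set(t["group"]) <= {"SAM", "healthy_control"}:
            raise FaimsIOError("group must be SAM or healthy_control")
        if not set(t["outcome"]) <= {"discharged", "died"}:
            raise FaimsIOError("outcome must be discharged or died")
        if not set(t["hiv"].dropna()) <= {"negative", "positive", "unknown"}:
            raise FaimsIOError("hiv must be negative/positive/unknown (or missing)")
        died = t["outcome"] == "died"
        if ((t["group"] == "healthy_control") & died).any():
            raise FaimsIOError("healthy controls cannot have outcome 'died'")
        dod = t["day_of_death"]
        if died.any():
            bad = died & (dod.isna() | (dod < 1) | (dod > 6))
            if bad.any():
                ids = t.loc[bad, "sample_id"].tolist()
                raise FaimsIOError(
                    f"subjects died without day_of_death in 1..6 (study window is 6 days): {ids}"
                )
        if (~died & dod.notna()).any():
            ids = t.loc[~died & dod.notna(), "sample_id"].tolist()
            raise FaimsIOError(f"day_of_death present for non-died subjects: {ids}")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def group_counts(self) -> dict[str, int]:
        """Counts of the disjoint strata SAM-died / SAM-discharged / control."""
        t = self.table
        sam = t["group"] == "SAM"
        return {
            "sam_died": int((sam & (t["outcome"] == "died")).sum()),
            "sam_discharged": int((sam & (t["outcome"] == "discharged")).sum()),
            "healthy_control": int((~sam).sum()),
        }

    def row(self, sample_id: str) -> pd.Series:
        hit = self.table[self.table["sample_id"] == sample_id]
        if len(hit) != 1:
            raise KeyError(sample_id)
        return hit.iloc[0]


# ---------------------------------------------------------------------------
# scan I/O


def write_scan(path, scan: DispersionScan) -> None:
    """Write a scan in the matrix-CSV dialect (17 significant digits)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([""] + [format(v, ".17g") for v in scan.cv_axis])
        for i, df_val in enumerate(scan.df_axis):
            w.writerow(
                [format(df_val, ".17g")]
                + [format(v, ".17g") for v in scan.intensities[i]]
            )


def read_scan(path, polarity: str, geometry: Geometry | None = None) -> DispersionScan:
    """Read a matrix-CSV file into a validated :class:`DispersionScan`.

    If ``geometry`` is given, the file's dimensions must match it.
    Errors name the file, row and column of the first offending cell.
    """
    path = Path(path)
    if not path.exists():
        raise FaimsIOError(f"{path}: no such file")
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or len(rows) < 2:
        raise FaimsIOError(f"{path}: empty or header-only matrix CSV")
    header = rows[0]
    if header[0].strip() != "":
        raise FaimsIOError(f"{path}: row 1, column 1 must be an empty corner cell")

    def _num(cell: str, r: int, c: int) -> float:
        try:
            return float(cell)
        except ValueError:
            raise FaimsIOError(
                f"{path}: non-numeric cell at row {r}, column {c}: {cell!r}"
            ) from None

    cv_axis = [_num(c, 1, j + 2) for j, c in enumerate(header[1:])]
    df_axis, intensities = [], []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FaimsIOError(
                f"{path}: row {i} has {len(row)} cells, expected {len(header)}"
            )
        df_axis.append(_num(row[0], i, 1))
        intensities.append([_num(c, i, j + 2) for j, c in enumerate(row[1:])])
    mat = np.asarray(intensities, dtype=float)
    if geometry is not None and mat.shape != (geometry.n_df, geometry.n_cv):
        raise FaimsIOError(
            f"{path}: geometry mismatch - file is {mat.shape[0]}x{mat.shape[1]}, "
            f"expected {geometry.n_df}x{geometry.n_cv}"
        )
    try:
        return DispersionScan(polarity, mat, np.asarray(df_axis), np.asarray(cv_axis))
    except ValueError as e:
        raise FaimsIOError(f"{path}: {e}") from None


def select_replicate(runs: list[InstrumentRun], which: int = 2) -> InstrumentRun:
    """Pick the configured replicate (default: the second instrument run,
    which previous work with this instrument found most discriminatory)."""
    if not runs:
        raise ValueError("no runs supplied")
    indices = [r.replicate_index for r in runs]
    if len(set(indices)) != len(indices):
        raise ValueError(f"replicate indices not unique: {indices}")
    for r in runs:
        if r.replicate_index == which:
            return r
    raise ValueError(
        f"replicate {which} absent; available replicate indices: {sorted(indices)}"
    )


# ---------------------------------------------------------------------------
# metadata I/O


def read_metadata(path) -> CohortMetadata:
    """Load and validate the cohort metadata CSV."""
    path = Path(path)
    if not path.exists():
        raise FaimsIOError(f"{path}: no such file")
    if path.stat().st_size == 0:
        raise FaimsIOError(f"{path}: empty metadata file")
    try:
        t = pd.read_csv(path, dtype={"sample_id": str})
    except pd.errors.EmptyDataError:
        raise FaimsIOError(f"{path}: empty metadata file") from None
    missing = [c for c in METADATA_COLUMNS if c not in t.columns]
    if missing:
        raise FaimsIOError(f"{path}: metadata missing mandatory columns: {missing}")
    for c in _FLOAT_COLUMNS + ("day_of_death",):
        t[c] = pd.to_numeric(t[c], errors="coerce")
    for c in _BOOL_COLUMNS:
        t[c] = pd.array(
            [None if pd.isna(v) else bool(int(v)) for v in t[c]], dtype="boolean"
        )
    try:
        return CohortMetadata(t[METADATA_COLUMNS])
    except FaimsIOError as e:
        raise FaimsIOError(f"{path}: {e}") from None


def write_metadata(path, metadata: CohortMetadata) -> None:
    t = metadata.table.copy()
    for c in _BOOL_COLUMNS:
        t[c] = t[c].map({True: 1, False: 0}, na_action="ignore")
    t.to_csv(path, index=False)
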
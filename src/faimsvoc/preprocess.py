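"""Polarity combination and label-blind background masking.

Most of a dispersion plot is background: the reactant-ion ridge plus empty
regions that carry no analyte information.  Masking those pixels before
feature ranking halves the compute without touching class labels, so the
mask cannot leak outcome information.  The retention statistic is, by
default, the across-sample standard deviation of each pixel: a pixel that
never varies between samples cannot discriminate anything.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from faimsvoc.io import InstrumentRun
from faimsvoc.layout import Geometry


@dataclass
class FeatureVector:
    """Flattened per-sample intensities, possibly masked.

    ``flat_indices`` maps each position in ``values`` back to the flat
    layout index (see :mod:`faimsvoc.layout`); for a full vector it is
    simply 0..n_features-1.
    """

    sample_id: str
    values: np.ndarray
    geometry: Geometry
    flat_indices: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.flat_indices = np.asarray(self.flat_indices, dtype=np.intp)
        if self.values.shape != self.flat_indices.shape:
            raise ValueError("values and flat_indices lengths differ")

    @property
    def is_full(self) -> bool:
        return self.values.size == self.geometry.n_features


@dataclass
class FeatureMask:
    """Retained flat indices plus the rule and data provenance that made it.

    ``provenance`` records which samples the mask was fitted on; the
    cross-validation engine asserts that a mask refitted inside a fold never
    saw that fold's test samples.
    """

    retained: np.ndarray
    rule: dict
    geometry: Geometry
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.retained = np.asarray(np.sort(np.unique(self.retained)), dtype=np.intp)
        if self.retained.size and (
            self.retained[0] < 0 or self.retained[-1] >= self.geometry.n_features
        ):
            raise ValueError("mask indices out of range")

    def __len__(self) -> int:
        return self.retained.size


def combine_polarities(run: InstrumentRun) -> FeatureVector:
    """Concatenate both polarity matrices into one flat feature vector.

    Positive block first, then negative; each block row-major (dispersion
    field outer, CV inner).  At default geometry the result has
    2 * 51 * 512 = 52,224 entries.
    """
    geom = run.geometry  # InstrumentRun already enforces matching geometries
    values = np.concatenate([run.positive.intensities.ravel(), run.negative.intensities.ravel()])
    return FeatureVector(
        sample_id=run.sample_id,
        values=values,
        geometry=geom,
        flat_indices=np.arange(geom.n_features),
    )


def _stack(vectors: list[FeatureVector]) -> np.ndarray:
    lengths = {v.values.size for v in vectors}
    if len(lengths) != 1:
        raise ValueError(f"feature vectors have differing lengths: {sorted(lengths)}")
    return np.vstack([v.values for v in vectors])


def fit_background_mask(
    vectors: list[FeatureVector],
    statistic: str = "sd",
    quantile: float = 0.5,
    provenance: tuple[str, ...] | None = None,
) -> FeatureMask:
    """Fit a background mask on (training) vectors.

    Retains pixels whose ``statistic`` across samples strictly exceeds the
    given quantile of that statistic.  ``statistic`` is ``"sd"`` (default:
    across-sample standard deviation; a constant pixel is pure background)
    or ``"mean_abs"`` (mean absolute intensity, for thresholding on signal
    level instead of variability).  Label-blind by construction.
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 training vectors to fit a mask")
    if not 0.0 <= quantile < 1.0:
        raise ValueError("quantile must be in [0, 1)")
    X = _stack(vectors)
    if statistic == "sd":
        stat = X.std(axis=0, ddof=0)
    elif statistic == "mean_abs":
        stat = np.abs(X).mean(axis=0)
    else:
        raise ValueError(f"unknown mask statistic {statistic!r}")
    geom = vectors[0].geometry
    if np.all(stat == 0):
        warnings.warn(
            "all training vectors identical: background mask retains nothing",
            stacklevel=2,
        )
        retained = np.empty(0, dtype=np.intp)
    else:
        threshold = float(np.quantile(stat, quantile))
        retained = vectors[0].flat_indices[stat > threshold]
    return FeatureMask(
        retained=retained,
        rule={"statistic": statistic, "quantile": quantile},
        geometry=geom,
        provenance=tuple(provenance) if provenance is not None else tuple(v.sample_id for v in vectors),
    )


def apply_mask(vector: FeatureVector, mask: FeatureMask) -> FeatureVector:
    """Reduce a vector to the mask's retained pixels (order preserved)."""
    pos = np.searchsorted(vector.flat_indices, mask.retained)
    if np.any(pos >= vector.flat_indices.size) or np.any(
        vector.flat_indices[np.minimum(pos, vector.flat_indices.size - 1)] != mask.retained
    ):
        raise IndexError("mask contains indices absent from the vector")
    return FeatureVector(
        sample_id=vector.sample_id,
        values=vector.values[pos],
        geometry=vector.geometry,
        flat_indices=mask.retained.copy(),
    )
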
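"""Matrix geometry and the flat feature-index layout.

The flattened per-sample feature vector concatenates the positive-polarity
matrix followed by the negative-polarity matrix, each in row-major order
(dispersion field outer, compensation voltage inner):

    flat = polarity_block * n_df * n_cv + df_index * n_cv + cv_index

with ``polarity_block`` 0 for positive and 1 for negative.  At the default
51 x 512 geometry the vector has 2 * 51 * 512 = 52,224 entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

POLARITIES = ("positive", "negative")


@dataclass(frozen=True)
class Geometry:
    """Dispersion-plot dimensions: dispersion-field steps x CV steps."""

    n_df: int = 51
    n_cv: int = 512

    @property
    def pixels_per_polarity(self) -> int:
        return self.n_df * self.n_cv

    @property
    def n_features(self) -> int:
        """Total flattened length over both polarities."""
        return 2 * self.n_df * self.n_cv

    def default_df_axis(self) -> np.ndarray:
        """Dispersion field in %, ascending 0 -> 100."""
        return np.linspace(0.0, 100.0, self.n_df)

    def default_cv_axis(self) -> np.ndarray:
        """Compensation voltage in volts, descending +6 -> -6."""
        return np.linspace(6.0, -6.0, self.n_cv)


DEFAULT_GEOMETRY = Geometry()


def flat_index(polarity: str, df_index, cv_index, geometry: Geometry = DEFAULT_GEOMETRY):
    """Map (polarity, df_index, cv_index) to the flat feature index."""
    block = POLARITIES.index(polarity)
    df_index = np.asarray(df_index)
    cv_index = np.asarray(cv_index)
    if np.any(df_index < 0) or np.any(df_index >= geometry.n_df):
        raise IndexError(f"df_index out of range [0, {geometry.n_df})")
    if np.any(cv_index < 0) or np.any(cv_index >= geometry.n_cv):
        raise IndexError(f"cv_index out of range [0, {geometry.n_cv})")
    return block * geometry.pixels_per_polarity + df_index * geometry.n_cv + cv_index


def unflatten_index(flat, geometry: Geometry = DEFAULT_GEOMETRY):
    """Inverse of :func:`flat_index`: flat -> (polarity, df_index, cv_index)."""
    flat = np.asarray(flat)
    if np.any(flat < 0) or np.any(flat >= geometry.n_features):
        raise IndexError(f"flat index out of range [0, {geometry.n_features})")
    block, rem = np.divmod(flat, geometry.pixels_per_polarity)
    df_index, cv_index = np.divmod(rem, geometry.n_cv)
    return block, df_index, cv_index
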
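"""Rank-sum (Mann-Whitney/Wilcoxon) feature ranking and top-k selection.

Every retained pixel is scored with a two-sample rank-sum test between the
two class arms of the training data; the k pixels with the smallest
two-sided p-values are kept.  Because the test uses ranks, selection is
invariant to any strictly monotone transform of a pixel's intensities.

p-values are exact (full null distribution of U by dynamic programming)
when both class sizes are at most 10 and the feature is tie-free;
otherwise a tie-corrected normal approximation with continuity correction
is used.  A feature constant across all samples gets p = 1 by convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from faimsvoc.layout import DEFAULT_GEOMETRY, POLARITIES, Geometry, unflatten_index
from faimsvoc.preprocess import FeatureVector

EXACT_MAX_CLASS_SIZE = 10


@dataclass
class FeatureRanking:
    """Per-feature U statistic and p-value, with the sort order.

    ``order`` sorts ascending by p-value, ties broken by ascending flat
    index, so a re-run on identical data reproduces the same selection.
    ``provenance`` names the samples the ranking was computed from.
    """

    flat_indices: np.ndarray
    u_statistic: np.ndarray
    p_value: np.ndarray
    order: np.ndarray
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return self.flat_indices.size


@lru_cache(maxsize=64)
def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U as counts over u = 0..n1*n2 (no ties).

    Recurrence f(m,n)[u] = f(m-1,n)[u-n] + f(m,n-1)[u]; total sums to
    C(n1+n2, n1).
    """
    table: dict[tuple[int, int], np.ndarray] = {}
    for m in range(n1 + 1):
        for n in range(n2 + 1):
            if m == 0 or n == 0:
                table[m, n] = np.ones(1)
                continue
            a = np.zeros(m * n + 1)
            prev_m = table[m - 1, n]
            a[n : n + prev_m.size] += prev_m
            prev_n = table[m, n - 1]
            a[: prev_n.size] += prev_n
            table[m, n] = a
    return table[n1, n2]


def _exact_two_sided_p(u: np.ndarray, n1: int, n2: int) -> np.ndarray:
    counts = _exact_u_counts(n1, n2)
    cdf = np.cumsum(counts) / counts.sum()
    sf_incl = 1.0 - np.concatenate([[0.0], cdf[:-1]])  # P(U >= u)
    u = np.asarray(u, dtype=np.intp)
    return np.minimum(1.0, 2.0 * np.minimum(cdf[u], sf_incl[u]))


def _tie_term(col: np.ndarray) -> float:
    """sum(t^3 - t) over tied groups of one feature column."""
    _, t = np.unique(col, return_counts=True)
    return float(np.sum(t**3 - t))


def _as_matrix(vectors, labels):
    if isinstance(vectors, np.ndarray):
        X = np.asarray(vectors, dtype=float)
        flat = np.arange(X.shape[1])
        prov = tuple(str(i) for i in range(X.shape[0]))
    else:
        X = np.vstack([v.values for v in vectors])
        flats = {tuple(v.flat_indices) for v in vectors}
        if len(flats) != 1:
            raise ValueError("feature vectors carry inconsistent flat index maps")
        flat = vectors[0].flat_indices
        prov = tuple(v.sample_id for v in vectors)
    y = np.asarray(labels).astype(bool)
    if y.shape != (X.shape[0],):
        raise ValueError("labels length does not match number of vectors")
    if y.all() or not y.any():
        raise ValueError("rank-sum ranking needs two non-empty classes")
    return X, flat, y, prov


def rank_sum_feature_scores(vectors, labels, provenance=None) -> FeatureRanking:
    """Score every feature with a two-sample rank-sum test.

    ``vectors`` is a list of :class:`FeatureVector` (sharing one index map)
    or an (n_samples, n_features) array; ``labels`` is boolean with the
    True group taken as the U statistic's reference class.
    """
    X, flat, y, prov = _as_matrix(vectors, labels)
    if provenance is not None:
        prov = tuple(provenance)
    n1, n2 = int(y.sum()), int((~y).sum())
    n = n1 + n2

    ranks = stats.rankdata(X, axis=0)
    u1 = ranks[y].sum(axis=0) - n1 * (n1 + 1) / 2.0

    has_tie = _has_tie_fast(X)

    p = np.empty(X.shape[1])
    exact_ok = (n1 <= EXACT_MAX_CLASS_SIZE and n2 <= EXACT_MAX_CLASS_SIZE)
    if exact_ok:
        tie_free = ~has_tie
        if tie_free.any():
            p[tie_free] = _exact_two_sided_p(
                np.rint(u1[tie_free]).astype(np.intp), n1, n2
            )
        approx = has_tie
    else:
        approx = np.ones(X.shape[1], dtype=bool)
    if approx.any():
        mu = n1 * n2 / 2.0
        cols = np.flatnonzero(approx)
        tie_sum = np.zeros(cols.size)
        for i, j in enumerate(cols):
            if has_tie[j]:
                tie_sum[i] = _tie_term(X[:, j])
        var = n1 * n2 / 12.0 * ((n + 1) - tie_sum / (n * (n - 1)))
        sd = np.sqrt(var)
        d = u1[cols] - mu
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (np.abs(d) - 0.5) / sd  # continuity correction
        pa = 2.0 * stats.norm.sf(z)
        pa = np.where(sd == 0, 1.0, np.minimum(pa, 1.0))
        pa = np.where(np.abs(d) < 0.5, 1.0, pa)  # |z|<0 after correction
        p[cols] = pa

    order = np.lexsort((flat, p))
    return FeatureRanking(
        flat_indices=np.asarray(flat, dtype=np.intp),
        u_statistic=u1,
        p_value=p,
        order=order,
        provenance=prov,
    )


def _has_tie_fast(X: np.ndarray) -> np.ndarray:
    S = np.sort(X, axis=0)
    return (np.diff(S, axis=0) == 0).any(axis=0)


def top_k_features(ranking: FeatureRanking, k: int) -> np.ndarray:
    """Flat indices of the k best-ranked features (smallest p first)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ranking):
        warnings.warn(
            f"k={k} exceeds the {len(ranking)} retained features; returning all",
            stacklevel=2,
        )
        k = len(ranking)
    return ranking.flat_indices[ranking.order[:k]]


def feature_map_coordinates(
    selected: np.ndarray,
    geometry: Geometry = DEFAULT_GEOMETRY,
    df_axis: np.ndarray | None = None,
    cv_axis: np.ndarray | None = None,
) -> pd.DataFrame:
    """Back-map flat feature indices to instrument coordinates.

    Returns a frame with columns flat_index, polarity, df_percent,
    cv_volts, ready for TSV export or plotting.
    """
    selected = np.asarray(selected, dtype=np.intp)
    block, df_idx, cv_idx = unflatten_index(selected, geometry)
    if df_axis is None:
        df_axis = geometry.default_df_axis()
    if cv_axis is None:
        cv_axis = geometry.default_cv_axis()
    return pd.DataFrame(
        {
            "flat_index": selected,
            "polarity": [POLARITIES[b] for b in block],
            "df_percent": np.asarray(df_axis)[df_idx],
            "cv_volts": np.asarray(cv_axis)[cv_idx],
        }
    )


def write_feature_map(path, coords: pd.DataFrame) -> None:
    coords.to_csv(path, sep="\t", index=False)


def plot_feature_map(coords: pd.DataFrame, path) -> None:
    """Render the selected-feature locations as two polarity panels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, pol in zip(axes, POLARITIES):
        sub = coords[coords["polarity"] == pol]
        ax.scatter(sub["cv_volts"], sub["df_percent"], s=8)
        ax.set_title(f"{pol.capitalize()} feature locations")
        ax.set_xlabel("Compensation voltage (V)")
        ax.invert_xaxis()
    axes[0].set_ylabel("Dispersion field (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
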
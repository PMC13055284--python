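"""Resolution-vs-homogenization diagnostics across embedding dimensions.

In high-dimensional embeddings nearest- and farthest-neighbor distances
converge ("distance homogenization"), washing out cluster structure; in very
low dimensions, structure is distorted by compression.  Three seeded,
deterministic diagnostics quantify the balance at each dimensionality:

* treatment SNR — mean between-treatment distance over mean within-treatment
  distance, both restricted to same-soil same-day pairs;
* kNN statistics — mean distance to the k nearest neighbors and its
  coefficient of variation across points (k = 5 by default);
* Hopkins statistic (Lawson & Jurs sampling scheme, 50 real + 50 uniform
  probe points by default) — near 0.5 for spatial randomness, toward 1 for
  clustered data.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.neighbors import NearestNeighbors

from ._seeding import substream
from .ordination import Embedding

__all__ = ["snr", "knn_stats", "hopkins", "sweep_diagnostics"]


def _coords(E: Embedding | np.ndarray) -> np.ndarray:
    return E.coordinates if isinstance(E, Embedding) else np.asarray(E, float)


def snr(
    E: Embedding,
    metadata: pd.DataFrame,
    per_soil: bool = False,
) -> float | pd.Series:
    """Between-treatment / within-treatment mean distance ratio.

    Between-treatment pairs share soil and day but differ in treatment;
    within-treatment pairs share soil, day, and treatment.  By default one
    global mean is taken over each pair set (pooled across soils); with
    ``per_soil`` a per-soil Series is returned instead.
    """
    X = _coords(E)
    meta = metadata.loc[[str(i) for i in E.sample_ids]]
    dist = squareform(pdist(X))
    soil = meta["soil"].to_numpy()
    day = meta["day"].to_numpy()
    treat = meta["treatment"].to_numpy()
    iu = np.triu_indices(len(meta), 1)
    same_soil = soil[iu[0]] == soil[iu[1]]
    same_day = day[iu[0]] == day[iu[1]]
    same_treat = treat[iu[0]] == treat[iu[1]]
    d = dist[iu]

    def _ratio(mask):
        between = d[mask & ~same_treat]
        within = d[mask & same_treat]
        if len(between) == 0 or len(within) == 0:
            raise ValueError("no qualifying between/within-treatment pairs")
        w = within.mean()
        if w == 0:
            raise ValueError("zero within-treatment mean distance (coincident replicates)")
        return float(between.mean() / w)

    if not per_soil:
        return _ratio(same_soil & same_day)
    return pd.Series(
        {s: _ratio(same_soil & same_day & (soil[iu[0]] == s))
         for s in np.unique(soil)},
        name="snr",
    )


def knn_stats(
    E: Embedding | np.ndarray, k: int = 5, mode: str = "mean"
) -> tuple[float, float]:
    """(mean, CV) of per-point k-nearest-neighbor distances (self excluded).

    ``mode='mean'``: each point contributes the mean distance to its k
    nearest neighbors; ``mode='kth'``: the distance to the k-th neighbor
    only.  CV is population SD / mean across points.
    """
    X = _coords(E)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    if mode not in ("mean", "kth"):
        raise ValueError(f"unknown mode {mode!r}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dists, _ = nn.kneighbors(X)
    per_point = dists[:, 1:].mean(axis=1) if mode == "mean" else dists[:, k]
    m = float(per_point.mean())
    if m == 0:
        warnings.warn("all kNN distances are zero; CV defined as 0")
        return 0.0, 0.0
    return m, float(per_point.std() / m)


def hopkins(E: Embedding | np.ndarray, m: int = 50, seed: int = 0) -> float:
    """Hopkins clustering-tendency statistic H = sum(u) / (sum(u) + sum(w)).

    m real points are sampled without replacement and m uniform probe points
    are drawn in the axis-aligned bounding box of the data; u are probe-to-
    nearest-real distances, w are sampled-real-to-nearest-other-real
    distances.  H near 0.5 indicates spatial randomness, near 1 clustering.
    """
    X = _coords(E)
    n = X.shape[0]
    if m > n - 1:
        raise ValueError(f"m={m} must be <= n-1={n - 1}")
    lo, hi = X.min(axis=0), X.max(axis=0)
    if np.all(hi == lo):
        raise ValueError("degenerate bounding box: all points coincident")
    rng = substream(seed, "hopkins")
    real_idx = rng.choice(n, size=m, replace=False)
    probes = rng.uniform(lo, hi, size=(m, X.shape[1]))
    nn_probe = NearestNeighbors(n_neighbors=1).fit(X)
    u = nn_probe.kneighbors(probes)[0][:, 0]
    nn_real = NearestNeighbors(n_neighbors=2).fit(X)
    w = nn_real.kneighbors(X[real_idx])[0][:, 1]  # nearest *other* real point
    return float(u.sum() / (u.sum() + w.sum()))


def sweep_diagnostics(
    embeddings: Sequence[Embedding],
    metadata: pd.DataFrame,
    k: int = 5,
    m: int = 50,
    seed: int = 0,
    knn_mode: str = "mean",
) -> pd.DataFrame:
    """SNR, kNN mean/CV, and Hopkins per embedding dimension.

    Returns a DataFrame with one row per dimension and columns
    dimension, snr, mean_knn, cv_knn, hopkins, k, m, seed, error.
    Per-dimension failures are recorded in ``error`` rather than raised.
    """
    if not embeddings:
        raise ValueError("no embeddings supplied")
    id_sets = {tuple(e.sample_ids) for e in embeddings}
    if len(id_sets) != 1:
        raise ValueError("embeddings do not share an identical sample set")
    rows = []
    for E in embeddings:
        row = dict(dimension=E.dimension, snr=np.nan, mean_knn=np.nan,
                   cv_knn=np.nan, hopkins=np.nan, k=k, m=m, seed=seed,
                   error="")
        try:
            row["snr"] = snr(E, metadata)
            row["mean_knn"], row["cv_knn"] = knn_stats(E, k=k, mode=knn_mode)
            row["hopkins"] = hopkins(E, m=m, seed=seed)
        except ValueError as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
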
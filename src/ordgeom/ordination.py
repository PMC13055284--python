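"""Embeddings of dissimilarity matrices / rCLR tables at arbitrary dimension.

Four routes, matching the study design this package emulates:

* :func:`pcoa` — classical (Torgerson) scaling: exact metric embedding of the
  double-centered squared-distance matrix.
* :func:`sammon` — Sammon mapping: metric stress weighted by 1/d_ij, which
  privileges small-scale distance structure; gradient descent with step
  halving so the stress trace is non-increasing.
* :func:`nmds` — non-metric MDS minimizing Kruskal stress-1 (rank-order
  preservation only), multi-start with one PCoA start plus random restarts.
* :func:`rpca_embed` — robust-Aitchison PCA: rCLR transform with zeros as
  missing, completed by alternating rank-d truncated SVD.

All coordinates are column-centered and sign-fixed (largest-magnitude entry
of each axis positive) so runs are directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS
from skbio import DistanceMatrix

from ._seeding import substream, substream_seed
from .distances import rclr_transform

__all__ = [
    "Embedding",
    "EmbeddingSweep",
    "DEFAULT_DIMENSIONS",
    "pcoa",
    "sammon",
    "nmds",
    "complete_low_rank",
    "rpca_embed",
    "reconstruct_distance",
    "sweep_embeddings",
    "kruskal_stress",
]

#: the nine-dimensionality sweep used throughout
DEFAULT_DIMENSIONS: tuple[int, ...] = (2, 3, 4, 7, 10, 15, 20, 30, 70)


@dataclass
class Embedding:
    """samples x d coordinates tagged with method and dimensionality."""

    sample_ids: list[str]
    coordinates: np.ndarray
    method: str
    dimension: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2:
            raise ValueError("coordinates must be 2-D")
        if self.coordinates.shape != (len(self.sample_ids), self.dimension):
            raise ValueError(
                f"coordinate shape {self.coordinates.shape} does not match "
                f"({len(self.sample_ids)}, {self.dimension})"
            )
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.dimension)]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


@dataclass
class EmbeddingSweep:
    """Embeddings per requested dimension, plus per-dimension skip reasons."""

    embeddings: list[Embedding]
    skipped: dict[int, str] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.embeddings)

    def dimensions(self) -> list[int]:
        return [e.dimension for e in self.embeddings]


def _finalize(coords: np.ndarray) -> np.ndarray:
    """Center columns and fix signs (largest-|entry| of each axis positive)."""
    coords = coords - coords.mean(axis=0, keepdims=True)
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return coords


def _as_array(D: DistanceMatrix) -> tuple[np.ndarray, list[str]]:
    return np.asarray(D.data, dtype=float), list(D.ids)


# ---------------------------------------------------------------------------
# PCoA

def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * J @ d2 @ J


def pcoa(D: DistanceMatrix, d: int) -> Embedding:
    """Classical scaling onto the ``d`` largest positive eigenvalue axes.

    Raises if fewer than ``d`` positive eigenvalues exist (no Cailliez or
    Lingoes correction is applied): requesting more axes than the matrix
    supports is an explicit error rather than fabricated coordinates.
    """
    dist, ids = _as_array(D)
    n = dist.shape[0]
    if d > n - 1:
        raise ValueError(f"d={d} exceeds n-1={n - 1}")
    B = _gower_center(dist**2)
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(np.abs(eigvals).max(), 1.0) * 1e-12
    n_pos = int(np.sum(eigvals > tol))
    if n_pos < d:
        raise ValueError(
            f"only {n_pos} positive eigenvalues available, cannot embed at d={d}"
        )
    coords = eigvecs[:, :d] * np.sqrt(eigvals[:d])
    pos_sum = eigvals[eigvals > tol].sum()
    diag = {
        "eigenvalues": eigvals,
        "n_positive": n_pos,
        "proportion_explained": float(eigvals[:d].sum() / pos_sum),
    }
    return Embedding(ids, _finalize(coords), "pcoa", d, diag)


# ---------------------------------------------------------------------------
# Sammon mapping

def _sammon_stress_grad(Y: np.ndarray, dist: np.ndarray, c: float, eps: float):
    delta = squareform(pdist(Y))
    np.fill_diagonal(delta, 1.0)  # diagonal never used
    dsafe = np.maximum(delta, eps)
    diff = dist - delta
    np.fill_diagonal(diff, 0.0)
    stress = float(np.sum(np.triu(diff**2 / np.maximum(dist, eps), 1)) / c)
    W = diff / (np.maximum(dist, eps) * dsafe)
    np.fill_diagonal(W, 0.0)
    # grad_i = (-2/c) * sum_j W_ij (y_i - y_j)
    grad = (-2.0 / c) * (W.sum(axis=1, keepdims=True) * Y - W @ Y)
    return stress, grad


def sammon(
    D: DistanceMatrix,
    d: int,
    init: Embedding | np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-9,
    seed: int = 0,
) -> Embedding:
    """Sammon mapping by gradient descent with step halving.

    Stress E = (sum d_ij)^-1 * sum (d_ij - delta_ij)^2 / d_ij over i<j.
    The step is halved until the stress decreases, so the recorded trace is
    non-increasing; iteration stops when |dE| < tol or ``max_iter``.
    Initialization defaults to PCoA (padded with small seeded noise if PCoA
    cannot supply d positive axes).
    """
    dist, ids = _as_array(D)
    n = dist.shape[0]
    offdiag = dist[np.triu_indices(n, 1)]
    if np.any(offdiag == 0):
        raise ValueError(
            "zero off-diagonal distance: Sammon weights 1/d_ij are undefined; "
            "jitter the data or deduplicate identical samples"
        )
    Y = _initial_config(D, d, init, seed, "sammon-init")
    c = float(offdiag.sum())
    eps = 1e-12
    step = 0.3
    stress, grad = _sammon_stress_grad(Y, dist, c, eps)
    trace = [stress]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        gnorm = np.linalg.norm(grad)
        if gnorm == 0:
            break
        improved = False
        for _ in range(40):
            Y_new = Y - step * grad
            s_new, g_new = _sammon_stress_grad(Y_new, dist, c, eps)
            if s_new <= stress:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        delta_s = stress - s_new
        Y, stress, grad = Y_new, s_new, g_new
        trace.append(stress)
        step *= 1.2  # cautious re-growth after successful step
        if delta_s < tol:
            break
    diag = {"stress": stress, "iterations": n_iter, "stress_trace": np.array(trace)}
    return Embedding(ids, _finalize(Y), "sammon", d, diag)


def _initial_config(D, d, init, seed, stream) -> np.ndarray:
    n = len(D.ids)
    if init is not None:
        Y = init.coordinates if isinstance(init, Embedding) else np.asarray(init, float)
        if Y.shape != (n, d):
            raise ValueError(f"init shape {Y.shape} != ({n}, {d})")
        return Y.copy()
    rng = substream(seed, stream)
    try:
        E = pcoa(D, d)
        return E.coordinates.copy()
    except ValueError:
        pass
    # pad available PCoA axes with small noise
    dist, _ = _as_array(D)
    B = _gower_center(dist**2)
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(np.abs(eigvals).max(), 1.0) * 1e-12
    n_pos = int(np.sum(eigvals > tol))
    k = min(n_pos, d)
    scale = np.sqrt(np.maximum(eigvals[:k], 0)).mean() if k else 1.0
    Y = rng.normal(scale=0.01 * max(scale, 1e-6), size=(n, d))
    if k:
        Y[:, :k] += eigvecs[:, :k] * np.sqrt(eigvals[:k])
    return Y


# ---------------------------------------------------------------------------
# NMDS

def kruskal_stress(dissim: np.ndarray, Y: np.ndarray) -> float:
    """Kruskal stress-1 of configuration ``Y`` against ``dissim``.

    Monotone (isotonic) regression of the embedded distances on the
    dissimilarities gives the fitted d-hats; stress-1 is
    sqrt(sum (delta - dhat)^2 / sum delta^2) over pairs.
    """
    iu = np.triu_indices(dissim.shape[0], 1)
    d_obs = dissim[iu]
    delta = squareform(pdist(Y))[iu]
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    dhat = iso.fit_transform(d_obs, delta)
    denom = float(np.sum(delta**2))
    if denom == 0:
        return np.inf
    return float(np.sqrt(np.sum((delta - dhat) ** 2) / denom))


def nmds(
    D: DistanceMatrix,
    d: int,
    n_starts: int = 20,
    max_iter: int = 300,
    seed: int = 0,
) -> Embedding:
    """Non-metric MDS (Kruskal stress-1) with multi-start selection.

    One start from PCoA plus ``n_starts - 1`` random starts; SMACOF with
    monotone regression optimizes each, and the configuration with the
    lowest stress-1 is returned.  Deterministic given ``seed``.
    """
    dist, ids = _as_array(D)
    n = dist.shape[0]
    if n < d + 1:
        raise ValueError(f"need at least d+1={d + 1} samples, have {n}")
    offdiag = dist[np.triu_indices(n, 1)]
    if np.allclose(offdiag, offdiag[0]):
        raise ValueError("degenerate distance matrix: all dissimilarities equal")
    rng = substream(seed, "nmds-starts")
    scale = offdiag.mean()
    inits = [_initial_config(D, d, None, seed, "nmds-init")]
    for _ in range(max(0, n_starts - 1)):
        inits.append(rng.normal(scale=scale, size=(n, d)))
    best_Y, best_stress = None, np.inf
    for k, Y0 in enumerate(inits):
        model = MDS(
            n_components=d,
            metric_mds=False,
            metric="precomputed",
            n_init=1,
            max_iter=max_iter,
            normalized_stress=True,
            random_state=substream_seed(seed, f"nmds-run{k}"),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Y = model.fit_transform(dist, init=Y0)
        s = kruskal_stress(dist, Y)
        if s < best_stress:
            best_Y, best_stress = Y, s
    diag = {"stress": best_stress, "n_starts": len(inits), "max_iter": max_iter}
    return Embedding(ids, _finalize(best_Y), "nmds", d, diag)


# ---------------------------------------------------------------------------
# RPCA (rCLR + masked low-rank completion)

def complete_low_rank(
    X: np.ndarray, d: int, max_iter: int = 500, tol: float = 1e-6
) -> tuple[np.ndarray, dict]:
    """Rank-``d`` completion of a matrix with NaN-marked missing entries.

    Alternating truncated SVD: missing entries start at 0 and are refilled
    from the current rank-d reconstruction until the relative Frobenius
    change of the imputed matrix falls below ``tol``.  Returns the completed
    matrix and an info dict (converged flag, iterations, singular values).
    """
    X = np.asarray(X, dtype=float)
    missing = np.isnan(X)
    filled = np.where(missing, 0.0, X)
    converged = False
    n_iter = 0
    s = None
    for n_iter in range(1, max_iter + 1):
        U, s, Vt = np.linalg.svd(filled, full_matrices=False)
        recon = (U[:, :d] * s[:d]) @ Vt[:d]
        new = np.where(missing, recon, X)
        change = np.linalg.norm(new - filled)
        filled = new
        if change < tol * max(1.0, np.linalg.norm(filled)):
            converged = True
            break
    return filled, {"converged": converged, "iterations": n_iter,
                    "singular_values": s}


def rpca_embed(
    table: pd.DataFrame,
    d: int,
    min_feature_count: int = 8,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> Embedding:
    """Robust-Aitchison PCA: rank-``d`` completion of the masked rCLR matrix.

    The rCLR transform treats zero counts as missing; the masked matrix is
    completed by :func:`complete_low_rank` and sample coordinates are
    U_d * s_d of the completed matrix, under the package-wide sign
    convention.  Deterministic (``seed`` is accepted for interface symmetry
    with the other embedding methods).
    """
    M = rclr_transform(table, min_feature_count)
    X = M.to_numpy()
    n, p = X.shape
    if d >= min(n, p):
        raise ValueError(f"d={d} must be < min(n_samples, n_features)={min(n, p)}")
    filled, info = complete_low_rank(X, d, max_iter=max_iter, tol=tol)
    U, s, Vt = np.linalg.svd(filled, full_matrices=False)
    coords = U[:, :d] * s[:d]
    diag = {
        "converged": info["converged"],
        "iterations": info["iterations"],
        "singular_values": s[:d],
        "feature_ids": list(M.columns),
        "feature_loadings": Vt[:d].T,
    }
    return Embedding(list(map(str, M.index)), _finalize(coords), "rpca", d, diag)


# ---------------------------------------------------------------------------
# reconstruction and sweeping

def reconstruct_distance(E: Embedding) -> DistanceMatrix:
    """Pairwise Euclidean distances between embedding coordinates."""
    vals = squareform(pdist(E.coordinates))
    return DistanceMatrix(vals, ids=E.sample_ids)


_DISTANCE_METHODS = {"pcoa": pcoa, "sammon": sammon, "nmds": nmds}


def sweep_embeddings(
    source: DistanceMatrix | pd.DataFrame,
    method: str,
    dimensions: Sequence[int] = DEFAULT_DIMENSIONS,
    **params,
) -> EmbeddingSweep:
    """Embed ``source`` at every dimension in ``dimensions``.

    ``method`` is one of pcoa/sammon/nmds (DistanceMatrix input), rpca
    (CountTable input), or umap (optional adapter; requires umap-learn).
    Dimensions at which the method raises are recorded in ``skipped`` with
    the error message rather than aborting the sweep.
    """
    dims = list(dimensions)
    if not dims:
        raise ValueError("empty dimension sweep")
    if any(b <= a for a, b in zip(dims, dims[1:])):
        raise ValueError("dimensions must be strictly increasing")
    out, skipped = [], {}
    for d in dims:
        try:
            if method in _DISTANCE_METHODS:
                if not isinstance(source, DistanceMatrix):
                    raise TypeError(f"{method} requires a DistanceMatrix input")
                emb = _DISTANCE_METHODS[method](source, d, **params)
            elif method == "rpca":
                if not isinstance(source, pd.DataFrame):
                    raise TypeError("rpca requires a CountTable (DataFrame) input")
                emb = rpca_embed(source, d, **params)
            elif method == "umap":
                emb = _umap_adapter(source, d, **params)
            else:
                raise ValueError(f"unknown embedding method: {method!r}")
        except (ValueError,) as exc:
            skipped[d] = str(exc)
            continue
        out.append(emb)
    return EmbeddingSweep(out, skipped)


def _umap_adapter(D: DistanceMatrix, d: int, n_neighbors: int = 15,
                  min_dist: float = 0.1, seed: int = 0) -> Embedding:
    """Optional UMAP adapter over a precomputed distance matrix (external
    implementation; not part of the core contract)."""
    try:
        import umap
    except ImportError as exc:  # pragma: no cover
        raise ValueError("umap-learn is not installed") from exc
    dist, ids = _as_array(D)
    reducer = umap.UMAP(
        n_components=d, n_neighbors=n_neighbors, min_dist=min_dist,
        metric="precomputed", random_state=substream_seed(seed, "umap"),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Y = reducer.fit_transform(dist)
    return Embedding(ids, _finalize(np.asarray(Y, float)), "umap", d, {})
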
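"""Permutation-based multivariate inference on dissimilarity matrices.

The centerpiece is a multi-term PERMANOVA in the adonis2 tradition: the
distance matrix is Gower-centered, sums of squares are partitioned
sequentially (Type I) over an ordered list of categorical factors via
projection (hat) matrices, and each term's pseudo-F is referred to its
permutation distribution under free relabeling of samples.  Companions:
pairwise PERMANOVA with Benjamini–Hochberg adjustment, beta-dispersion
(distance to group centroid), alpha diversity (Shannon, Chao1), and the
feature-exclusion reanalysis used to attribute treatment variance to a
single inoculant feature.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control
from skbio import DistanceMatrix

from ._seeding import substream
from .ordination import Embedding

__all__ = [
    "PermanovaResult",
    "permanova",
    "permanova_sweep",
    "pairwise_permanova",
    "beta_dispersion",
    "exclude_feature_and_renormalize",
    "shannon",
    "chao1",
    "alpha_diversity_table",
]


@dataclass
class PermanovaResult:
    """Sequential variance partition of a distance matrix over factors.

    ``table`` has one row per term plus Residual and Total, with columns
    df, SumOfSqs, R2, F, p.  R2 entries (terms + residual) sum to 1.
    """

    table: pd.DataFrame
    terms: list[str]
    n_permutations: int
    seed: int | None
    method: str = "sequential"
    extras: dict = field(default_factory=dict)

    def r2(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def f(self, term: str) -> float:
        return float(self.table.loc[term, "F"])


def _gower(dist: np.ndarray) -> np.ndarray:
    n = dist.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * J @ (dist**2) @ J


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def _model_matrices(meta: pd.DataFrame, terms: Sequence[str]):
    """Cumulative hat matrices and dfs for intercept + terms (sequential)."""
    n = len(meta)
    blocks = [np.ones((n, 1))]
    hats = []
    dfs = []
    for term in terms:
        levels = meta[term].astype(str)
        uniq = sorted(levels.unique())
        if len(uniq) < 2:
            raise ValueError(f"factor {term!r} is constant among samples")
        dummies = pd.get_dummies(levels, drop_first=True).to_numpy(float)
        blocks.append(dummies)
        X = np.hstack(blocks)
        hats.append(_hat(X))
        dfs.append(len(uniq) - 1)
    return hats, dfs


def permanova(
    D: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: Sequence[str],
    n_perm: int | str = 999,
    seed: int | None = 0,
) -> PermanovaResult:
    """PERMANOVA with sequential (Type I) sums of squares.

    ``terms`` is the ordered factor list (e.g. ["soil", "day", "treatment"]).
    P-values use the +1 correction (1 + #{F* >= F}) / (1 + n_perm) under
    free permutation of sample labels.  ``n_perm='exhaustive'`` enumerates
    every non-identity permutation (tiny n only).  Seeded.
    """
    ids = list(D.ids)
    meta = metadata.loc[[str(i) for i in ids]]
    dist = np.asarray(D.data, dtype=float)
    n = dist.shape[0]
    if isinstance(n_perm, int) and n_perm < 99 and n_perm != 0:
        raise ValueError("n_perm must be >= 99 (or 0 to skip the test)")
    hats, dfs = _model_matrices(meta, terms)
    H0 = np.full((n, n), 1.0 / n)  # intercept-only hat
    H_full = hats[-1]
    R_full = np.eye(n) - H_full
    df_res = n - 1 - sum(dfs)
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    G = _gower(dist)
    ss_total = float(np.trace(G))

    def term_stats(Gm):
        prev = H0
        ss_terms = np.empty(len(terms))
        for k, H in enumerate(hats):
            ss_terms[k] = np.sum((H - prev) * Gm)
            prev = H
        ss_res = np.sum(R_full * Gm)
        F = (ss_terms / np.asarray(dfs)) / (ss_res / df_res)
        return ss_terms, ss_res, F

    ss_terms, ss_res, F_obs = term_stats(G)

    exceed = np.zeros(len(terms))
    if n_perm == "exhaustive":
        perms = [p for p in itertools.permutations(range(n))
                 if p != tuple(range(n))]
        n_done = len(perms)
        for p in perms:
            idx = np.asarray(p)
            exceed += term_stats(G[np.ix_(idx, idx)])[2] >= F_obs - 1e-12
    elif n_perm:
        rng = substream(seed if seed is not None else 0, "permanova")
        n_done = int(n_perm)
        for _ in range(n_done):
            idx = rng.permutation(n)
            exceed += term_stats(G[np.ix_(idx, idx)])[2] >= F_obs - 1e-12
    else:
        n_done = 0
    p_vals = (1.0 + exceed) / (1.0 + n_done) if n_done else np.full(len(terms), np.nan)

    rows = []
    for k, term in enumerate(terms):
        rows.append((term, dfs[k], ss_terms[k], ss_terms[k] / ss_total,
                     F_obs[k], p_vals[k]))
    rows.append(("Residual", df_res, ss_res, ss_res / ss_total, np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["term", "df", "SumOfSqs", "R2", "F", "p"]
    ).set_index("term")
    return PermanovaResult(table, list(terms), n_done, seed)


def permanova_sweep(
    embeddings: Sequence[Embedding],
    metadata: pd.DataFrame,
    global_terms: Sequence[str] = ("soil", "day", "treatment"),
    soil_term: str = "treatment",
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Dimension-swept PERMANOVA on distances reconstructed from embeddings.

    For every embedding: the global sequential model over ``global_terms``
    and, per soil, a soil-wise model with ``soil_term`` only (time points
    pooled).  Long-format output with columns dimension, scope, term, R2,
    F, p (plus error for dimensions that failed).
    """
    from .ordination import reconstruct_distance

    if not embeddings:
        raise ValueError("no embeddings supplied")
    rows = []
    for E in embeddings:
        D = reconstruct_distance(E)
        meta = metadata.loc[[str(i) for i in E.sample_ids]]
        try:
            res = permanova(D, meta, global_terms, n_perm=n_perm, seed=seed)
            for term in global_terms:
                rows.append(dict(dimension=E.dimension, scope="global",
                                 term=term, R2=res.r2(term), F=res.f(term),
                                 p=res.p_value(term), error=""))
            for soil, grp in meta.groupby("soil", sort=True):
                sub = D.filter(grp.index.tolist())
                r = permanova(sub, grp, [soil_term], n_perm=n_perm, seed=seed)
                rows.append(dict(dimension=E.dimension, scope=str(soil),
                                 term=soil_term, R2=r.r2(soil_term),
                                 F=r.f(soil_term), p=r.p_value(soil_term),
                                 error=""))
        except ValueError as exc:
            rows.append(dict(dimension=E.dimension, scope="global", term="",
                             R2=np.nan, F=np.nan, p=np.nan, error=str(exc)))
    return pd.DataFrame(rows)


def pairwise_permanova(
    D: DistanceMatrix,
    metadata: pd.DataFrame,
    factor: str,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """One PERMANOVA per level pair of ``factor``, BH-adjusted q-values."""
    meta = metadata.loc[[str(i) for i in D.ids]]
    levels = sorted(meta[factor].astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    usable = []
    for lev in levels:
        if (meta[factor].astype(str) == lev).sum() < 2:
            warnings.warn(f"level {lev!r} has < 2 samples; skipped")
        else:
            usable.append(lev)
    rows = []
    for a, b in itertools.combinations(usable, 2):
        keep = meta.index[meta[factor].astype(str).isin([a, b])].tolist()
        res = permanova(D.filter(keep), meta.loc[keep], [factor],
                        n_perm=n_perm, seed=seed)
        rows.append(dict(level_a=a, level_b=b, R2=res.r2(factor),
                         F=res.f(factor), p=res.p_value(factor)))
    out = pd.DataFrame(rows)
    out["q"] = false_discovery_control(out["p"].to_numpy(), method="bh")
    return out


def beta_dispersion(
    source: Embedding | DistanceMatrix, groups: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Distance of each sample to its group centroid, plus per-group means.

    For a DistanceMatrix input the centroids are taken in its full-rank
    PCoA space (positive-eigenvalue axes).
    """
    if isinstance(source, DistanceMatrix):
        dist = np.asarray(source.data, float)
        # full-rank classical scaling on positive axes
        Bc = _gower(dist)
        eigvals, eigvecs = np.linalg.eigh(Bc)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        tol = max(np.abs(eigvals).max(), 1.0) * 1e-12
        k = int(np.sum(eigvals > tol))
        X = eigvecs[:, :k] * np.sqrt(eigvals[:k])
        ids = [str(i) for i in source.ids]
    else:
        X = source.coordinates
        ids = [str(i) for i in source.sample_ids]
    groups = groups.loc[ids]
    counts = groups.value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValueError(f"singleton group(s): {singletons.index.tolist()}")
    dist_to_centroid = np.empty(len(ids))
    pos = {s: i for i, s in enumerate(ids)}
    for g, members in groups.groupby(groups):
        idx = [pos[s] for s in members.index]
        centroid = X[idx].mean(axis=0)
        dist_to_centroid[idx] = np.linalg.norm(X[idx] - centroid, axis=1)
    per_sample = pd.DataFrame(
        {"group": groups.to_numpy(), "distance_to_centroid": dist_to_centroid},
        index=ids,
    )
    per_group = per_sample.groupby("group")["distance_to_centroid"].mean()
    return per_sample, per_group


def exclude_feature_and_renormalize(
    table: pd.DataFrame, feature_ids: Sequence[str] | set
) -> pd.DataFrame:
    """Remove features (e.g. the inoculant OTU) for the exclusion reanalysis.

    The remaining features are rescaled to 100% of each sample: every row is
    multiplied by its pre-exclusion total over its post-exclusion total, so
    abundance-based distances see only compositional differences among the
    surviving features, not the bulk removed with the excluded ones.
    Samples whose total drops to zero are flagged with a warning (they break
    distance computation downstream) and left unscaled.
    """
    feats = list(feature_ids)
    missing = [f for f in feats if f not in table.columns]
    if missing:
        raise ValueError(f"feature(s) not in table: {missing}")
    if len(feats) >= table.shape[1]:
        raise ValueError("cannot remove all features")
    out = table.drop(columns=feats).astype(float)
    old_totals = table.sum(axis=1).astype(float)
    new_totals = out.sum(axis=1)
    zero = out.index[new_totals == 0].tolist()
    if zero:
        warnings.warn(f"sample(s) left with zero total after exclusion: {zero}")
    factor = np.where(new_totals > 0, old_totals / new_totals.where(new_totals > 0, 1.0), 1.0)
    return out.mul(factor, axis=0)


def shannon(counts: np.ndarray | pd.Series) -> float:
    """Shannon diversity, natural log, over nonzero features."""
    x = np.asarray(counts, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("empty sample")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def chao1(counts: np.ndarray | pd.Series) -> float:
    """Chao1 richness: S_obs + F1^2 / (2 F2), with the F2 = 0 correction
    F1 (F1 - 1) / 2 substituted for F1^2 / (2 F2)."""
    x = np.asarray(counts)
    if x.sum() <= 0:
        raise ValueError("empty sample")
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f2 > 0:
        return s_obs + f1**2 / (2 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def alpha_diversity_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Shannon and Chao1 for a count table."""
    return pd.DataFrame(
        {
            "shannon": [shannon(row) for _, row in table.iterrows()],
            "chao1": [chao1(row.to_numpy()) for _, row in table.iterrows()],
        },
        index=table.index,
    )
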
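"""Community dissimilarities: Bray–Curtis, weighted UniFrac, and the robust
centered log-ratio (rCLR) transform that feeds robust-Aitchison PCA.

Distances are computed on raw (unrarefied) counts.  Weighted UniFrac
defaults to the normalized variant; the raw form is exposed via a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

from .synthetic import apply_min_count_filter

__all__ = ["bray_curtis", "weighted_unifrac", "rclr_transform"]


def _check_table(table: pd.DataFrame) -> None:
    if table.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    totals = table.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"all-zero sample(s): {', '.join(map(str, zero.index.tolist()))}"
        )


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray–Curtis dissimilarity on raw counts.

    BC(x, y) = 1 - 2 * sum_f min(x_f, y_f) / sum_f (x_f + y_f).
    """
    _check_table(table)
    vals = squareform(pdist(table.to_numpy(dtype=float), metric="braycurtis"))
    return DistanceMatrix(vals, ids=[str(i) for i in table.index])


def weighted_unifrac(
    table: pd.DataFrame, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """Weighted UniFrac between all sample pairs.

    Raw form: sum over branches of length * |p_b - q_b| where p_b, q_b are the
    relative-abundance masses of each sample descending from the branch;
    the normalized form divides by sum of length * (p_b + q_b).  Every feature
    carrying a nonzero count must be a leaf of ``tree``; zero-total features
    missing from the tree are silently dropped.
    """
    _check_table(table)
    tips = {t.name for t in tree.tips()}
    nonzero = table.columns[(table.sum(axis=0) > 0).to_numpy()]
    missing = [f for f in nonzero if f not in tips]
    if missing:
        raise ValueError(
            "feature(s) with nonzero counts absent from tree: "
            + ", ".join(map(str, missing[:10]))
            + ("..." if len(missing) > 10 else "")
        )
    sub = table.loc[:, [c for c in table.columns if c in tips]]
    return beta_diversity(
        "weighted_unifrac",
        sub.to_numpy(dtype=float),
        ids=[str(i) for i in table.index],
        taxa=list(sub.columns),
        tree=tree,
        normalized=normalized,
        validate=True,
    )


def rclr_transform(table: pd.DataFrame, min_feature_count: int = 8) -> pd.DataFrame:
    """Robust CLR: log counts centered per sample over *observed* entries only.

    Zeros are treated as missing (NaN), never imputed.  Features with a total
    count below ``min_feature_count`` are removed first.  Each observed entry
    becomes log(count) minus the mean log over that sample's observed
    entries, so observed entries of a row sum to zero.
    """
    filtered = apply_min_count_filter(table, min_feature_count)
    if filtered.shape[1] == 0:
        raise ValueError("no features survive the minimum-count filter")
    x = filtered.to_numpy(dtype=float)
    empty = (x > 0).sum(axis=1) == 0
    if empty.any():
        bad = filtered.index[empty].tolist()
        raise ValueError(
            f"sample(s) with no observed features after filtering: {bad}"
        )
    logx = np.full_like(x, np.nan)
    np.log(x, out=logx, where=x > 0)
    row_means = np.nanmean(logx, axis=1, keepdims=True)
    return pd.DataFrame(
        logx - row_means, index=filtered.index, columns=filtered.columns
    )
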
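"""Trajectory geometry in embedding space.

Each replicate microcosm traces a path through ordination space over the
sampling days.  Three descriptors quantify that path:

* cos(theta) between trajectory vectors — directional alignment between the
  control and inoculated arms (1 identical orientation, 0 orthogonal,
  -1 opposite);
* smoothness — mean cos(theta) between successive segments, local
  directional consistency;
* linearity — net displacement divided by cumulative path length, in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ordination import Embedding

__all__ = [
    "Trajectory",
    "TrajectoryComparison",
    "build_trajectories",
    "trajectory_vector",
    "cos_theta",
    "compare_treatment_trajectories",
    "smoothness",
    "linearity",
    "sweep_trajectory_metrics",
]

_CLAMP_TOL = 1e-12


@dataclass
class Trajectory:
    soil: str
    treatment: str
    replicate: int
    days: np.ndarray          # strictly increasing
    coordinates: np.ndarray   # len(days) x d

    def __post_init__(self):
        self.days = np.asarray(self.days)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if len(self.days) < 2:
            raise ValueError(
                f"trajectory {self.key} has fewer than 2 time points"
            )
        if np.any(np.diff(self.days) <= 0):
            raise ValueError(f"days not strictly increasing for {self.key}")
        if self.coordinates.shape[0] != len(self.days):
            raise ValueError("coordinate rows must match days")

    @property
    def key(self) -> tuple:
        return (self.soil, self.treatment, self.replicate)

    def at(self, day: int) -> np.ndarray:
        idx = np.nonzero(self.days == day)[0]
        if len(idx) == 0:
            raise KeyError(f"day {day} not present in trajectory {self.key}")
        return self.coordinates[idx[0]]

    def has_day(self, day: int) -> bool:
        return bool(np.any(self.days == day))


@dataclass
class TrajectoryComparison:
    soil: str
    interval: tuple[int, int]
    pairs: list[tuple[int, int]]       # (control replicate, inoculated replicate)
    cos_theta_values: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def mean(self) -> float:
        return float(np.mean(self.cos_theta_values))

    @property
    def sd(self) -> float:
        return float(np.std(self.cos_theta_values))  # population SD (ddof=0)


def build_trajectories(E: Embedding, metadata: pd.DataFrame) -> list[Trajectory]:
    """One trajectory per (soil, treatment, replicate), days ascending."""
    coords = pd.DataFrame(E.coordinates, index=E.sample_ids)
    meta = metadata.loc[[str(i) for i in E.sample_ids]]
    trajectories = []
    for (soil, treatment, rep), grp in meta.groupby(
        ["soil", "treatment", "replicate"], sort=True
    ):
        days = grp["day"].to_numpy()
        if len(np.unique(days)) != len(days):
            raise ValueError(
                f"duplicate (replicate, day) for ({soil}, {treatment}, {rep})"
            )
        order = np.argsort(days)
        ids = grp.index.to_numpy()[order]
        trajectories.append(
            Trajectory(soil, treatment, int(rep), days[order],
                       coords.loc[ids].to_numpy())
        )
    return trajectories


def trajectory_vector(t: Trajectory, from_day: int, to_day: int) -> np.ndarray:
    """Displacement vector coordinate(to_day) - coordinate(from_day)."""
    return t.at(to_day) - t.at(from_day)


def cos_theta(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors, clamped into [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cos_theta undefined for a zero-norm vector")
    c = float(u @ v / (nu * nv))
    # rounding can push |c| across (or just short of) 1; clamp/snap at 1e-12
    if c > 1.0 - _CLAMP_TOL:
        return 1.0
    if c < -1.0 + _CLAMP_TOL:
        return -1.0
    return c


def compare_treatment_trajectories(
    trajectories: Sequence[Trajectory],
    soil: str,
    from_day: int,
    to_day: int,
    control_label: str = "control",
) -> TrajectoryComparison:
    """Pairwise cos(theta) between every control and inoculated replicate.

    Replicates missing either endpoint day are excluded with a warning; the
    mean and (population) SD summarize the |control| x |inoculated| pairs.
    """
    controls, inoculated = [], []
    for t in trajectories:
        if t.soil != soil:
            continue
        if not (t.has_day(from_day) and t.has_day(to_day)):
            warnings.warn(
                f"replicate {t.key} lacks day {from_day} or {to_day}; excluded"
            )
            continue
        (controls if t.treatment == control_label else inoculated).append(t)
    if not controls or not inoculated:
        raise ValueError(
            f"no usable control/inoculated pair for soil {soil!r} on "
            f"interval {from_day}-{to_day}"
        )
    pairs, values = [], []
    for c in controls:
        u = trajectory_vector(c, from_day, to_day)
        for i in inoculated:
            v = trajectory_vector(i, from_day, to_day)
            pairs.append((c.replicate, i.replicate))
            values.append(cos_theta(u, v))
    return TrajectoryComparison(soil, (from_day, to_day), pairs, np.array(values))


def _segments(t: Trajectory) -> np.ndarray:
    return np.diff(t.coordinates, axis=0)


def smoothness(t: Trajectory) -> float:
    """Mean cos(theta) between successive trajectory segments."""
    if len(t.days) < 3:
        raise ValueError("smoothness needs at least 3 time points")
    segs = _segments(t)
    lens = np.linalg.norm(segs, axis=1)
    if np.any(lens == 0):
        raise ValueError(f"zero-length segment in trajectory {t.key}")
    return float(np.mean([cos_theta(segs[i], segs[i + 1])
                          for i in range(len(segs) - 1)]))


def linearity(t: Trajectory) -> float:
    """Net start-to-end displacement over cumulative path length, in [0, 1]."""
    segs = _segments(t)
    path = float(np.linalg.norm(segs, axis=1).sum())
    if path == 0:
        raise ValueError(f"zero path length for trajectory {t.key}")
    net = float(np.linalg.norm(t.coordinates[-1] - t.coordinates[0]))
    return min(1.0, net / path)


def sweep_trajectory_metrics(
    embeddings: Sequence[Embedding],
    metadata: pd.DataFrame,
    intervals: Sequence[tuple[int, int]] | None = None,
    control_label: str = "control",
) -> pd.DataFrame:
    """Trajectory metrics for every embedding dimension in long format.

    Rows: per dimension x soil x interval the mean/SD pairwise cos(theta)
    (metric ``cos_theta``), and per dimension x trajectory the smoothness and
    linearity (over the full day range).  Columns: dimension, method, soil,
    interval, metric, unit, value, sd.
    """
    if not embeddings:
        raise ValueError("no embeddings supplied")
    id_sets = {tuple(e.sample_ids) for e in embeddings}
    if len(id_sets) != 1:
        raise ValueError("embeddings do not share an identical sample set")
    rows = []
    for E in embeddings:
        trajs = build_trajectories(E, metadata)
        days = sorted({int(d) for t in trajs for d in t.days})
        ivals = intervals if intervals is not None else [(days[0], days[-1])]
        soils = sorted({t.soil for t in trajs})
        for soil in soils:
            for a, b in ivals:
                cmp_res = compare_treatment_trajectories(
                    trajs, soil, a, b, control_label=control_label
                )
                rows.append(dict(
                    dimension=E.dimension, method=E.method, soil=soil,
                    interval=f"{a}-{b}", metric="cos_theta",
                    unit="treatment-pairs", value=cmp_res.mean, sd=cmp_res.sd,
                ))
        for t in trajs:
            unit = f"{t.treatment}.r{t.replicate}"
            rows.append(dict(
                dimension=E.dimension, method=E.method, soil=t.soil,
                interval=f"{t.days[0]}-{t.days[-1]}", metric="smoothness",
                unit=unit, value=smoothness(t), sd=np.nan,
            ))
            rows.append(dict(
                dimension=E.dimension, method=E.method, soil=t.soil,
                interval=f"{t.days[0]}-{t.days[-1]}", metric="linearity",
                unit=unit, value=linearity(t), sd=np.nan,
            ))
    return pd.DataFrame(rows)
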
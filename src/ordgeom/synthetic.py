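"""Synthetic soil-microcosm data generator.

Emulates a bioaugmentation microcosm study: three soils with strongly
distinct baseline communities, a control and an inoculated treatment arm,
replicate microcosms destructively sampled on a fixed day grid, and a single
inoculant feature that spikes at Day 0 in the inoculated arm and decays
log-linearly to a soil-specific residual relative abundance by the final day.

The generative model works in log-composition space.  For sample with soil
``s``, treatment ``t``, day ``d`` the expected composition is

    softmax( log(baseline_s) + m(d) * drift_s + [t == inoculated] * shift_s )

after which the inoculant feature's relative abundance is pinned to the
decay curve (inoculated arm) or to exactly zero (control arm), the other
features being rescaled to fill the remainder.  Counts are then drawn from a
Dirichlet-multinomial: library size ~ Poisson(library_size), composition
jittered as Dirichlet(overdispersion * expected composition).

The "divergence angle" rotates the inoculated arm's drift direction within
the plane spanned by drift and treatment-shift directions, so a soil can be
made to respond to inoculation by *changing direction* of its temporal
trajectory rather than merely shifting — the geometry the trajectory-cosine
analysis is designed to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._seeding import substream

__all__ = [
    "DesignSpec",
    "EffectSpec",
    "generate_metadata",
    "generate_tree",
    "generate_counts",
    "apply_min_count_filter",
    "default_design",
    "default_effects",
]

#: factor levels of the emulated study design
DEFAULT_SOILS = ("ANT", "AT", "G")
DEFAULT_TREATMENTS = ("control", "inoculated")
DEFAULT_DAYS = (0, 14, 28, 57, 249)


@dataclass(frozen=True)
class DesignSpec:
    """Factorial design: soils x treatments x replicates x days."""

    soils: tuple[str, ...] = DEFAULT_SOILS
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    replicates: int = 3
    days: tuple[int, ...] = DEFAULT_DAYS
    n_features: int = 500
    library_size: int = 100_000
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "soils", tuple(self.soils))
        object.__setattr__(self, "treatments", tuple(self.treatments))
        object.__setattr__(self, "days", tuple(int(d) for d in self.days))
        if len(set(self.soils)) != len(self.soils):
            raise ValueError(f"duplicate soil labels in design: {self.soils}")
        if len(set(self.treatments)) != len(self.treatments):
            raise ValueError(f"duplicate treatment labels: {self.treatments}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError(f"days must be strictly increasing: {self.days}")
        if self.n_features < 2:
            raise ValueError("n_features must be >= 2")
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")

    @property
    def feature_ids(self) -> list[str]:
        width = max(4, len(str(self.n_features)))
        return [f"OTU{i + 1:0{width}d}" for i in range(self.n_features)]

    @property
    def n_samples(self) -> int:
        return (
            len(self.soils) * len(self.treatments) * self.replicates * len(self.days)
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "DesignSpec":
        return cls(**d)


@dataclass(frozen=True)
class EffectSpec:
    """Effect-size block controlling soil, time, and inoculation structure.

    Per-soil entries default (for soils without an explicit entry) to:
    baseline Dirichlet concentration 0.3 per feature, drift magnitude 1.0,
    treatment shift 0.25, divergence angle 0, residual fraction 0.001.
    """

    soil_baseline_concentration: Mapping[str, float] = field(default_factory=dict)
    drift_scale: Mapping[str, float] = field(default_factory=dict)
    treatment_shift: Mapping[str, float] = field(
        default_factory=lambda: {"ANT": 0.25, "AT": 0.25, "G": 0.25}
    )
    divergence_angle: Mapping[str, float] = field(
        default_factory=lambda: {"ANT": 0.0, "AT": 0.0, "G": 1.25}
    )
    inoculant_feature_id: str = "OTU0001"
    inoculant_initial_fraction: float = 0.05
    inoculant_residual_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"G": 0.0033, "AT": 0.0017, "ANT": 0.0005}
    )
    overdispersion: float = 200.0

    def __post_init__(self):
        if not 0.0 <= self.inoculant_initial_fraction <= 1.0:
            raise ValueError("inoculant_initial_fraction must lie in [0, 1]")
        for soil, frac in self.inoculant_residual_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"residual fraction for {soil} must lie in [0, 1]")
            if frac > self.inoculant_initial_fraction:
                raise ValueError(
                    f"residual fraction for {soil} ({frac}) exceeds initial "
                    f"fraction ({self.inoculant_initial_fraction})"
                )
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be > 0")

    # per-soil lookups with defaults
    def baseline_concentration(self, soil: str) -> float:
        return float(self.soil_baseline_concentration.get(soil, 0.3))

    def drift(self, soil: str) -> float:
        return float(self.drift_scale.get(soil, 1.0))

    def shift(self, soil: str) -> float:
        return float(self.treatment_shift.get(soil, 0.25))

    def angle(self, soil: str) -> float:
        return float(self.divergence_angle.get(soil, 0.0))

    def residual(self, soil: str) -> float:
        return float(self.inoculant_residual_fraction.get(soil, 0.001))

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in (
            "soil_baseline_concentration",
            "drift_scale",
            "treatment_shift",
            "divergence_angle",
            "inoculant_residual_fraction",
        ):
            d[key] = dict(d[key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "EffectSpec":
        return cls(**d)


def default_design(**overrides) -> DesignSpec:
    return DesignSpec(**overrides)


def default_effects(**overrides) -> EffectSpec:
    return EffectSpec(**overrides)


# ---------------------------------------------------------------------------
# metadata

def generate_metadata(design: DesignSpec) -> pd.DataFrame:
    """One record per soil x treatment x replicate x day, deterministic order.

    Returns a DataFrame indexed by sample_id with columns
    ``soil, treatment, day, replicate``.
    """
    records = []
    for soil in design.soils:
        for treatment in design.treatments:
            for rep in range(1, design.replicates + 1):
                for day in design.days:
                    sid = f"{soil}.{treatment}.r{rep}.d{day}"
                    records.append((sid, soil, treatment, day, rep))
    meta = pd.DataFrame(
        records, columns=["sample_id", "soil", "treatment", "day", "replicate"]
    ).set_index("sample_id")
    return meta


# ---------------------------------------------------------------------------
# phylogeny

def generate_tree(n_features: int, seed: int = 0) -> TreeNode:
    """Random coalescent-style rooted binary tree over the feature labels.

    Lineages are merged pairwise at exponentially distributed waiting times
    with rate k(k-1)/2 for k extant lineages; branch lengths are the height
    differences, so the tree is ultrametric.  Deterministic given ``seed``.
    """
    if n_features < 2:
        raise ValueError("need at least 2 features for a tree")
    rng = substream(seed, "tree")
    width = max(4, len(str(n_features)))
    nodes = [TreeNode(name=f"OTU{i + 1:0{width}d}", length=None) for i in range(n_features)]
    heights = [0.0] * n_features
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = nodes[i], nodes[j]
        ha, hb = heights[i], heights[j]
        a.length = t - ha
        b.length = t - hb
        parent = TreeNode(children=[a, b])
        # replace i with parent, drop j
        nodes[i] = parent
        heights[i] = t
        del nodes[j]
        del heights[j]
    root = nodes[0]
    root.length = None
    return root


# ---------------------------------------------------------------------------
# counts

def _softmax(logp: np.ndarray) -> np.ndarray:
    z = np.exp(logp - logp.max())
    return z / z.sum()


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-norm direction vector")
    return v / n


def expected_inoculant_fraction(
    day: int, days: Sequence[int], initial: float, residual: float
) -> float:
    """Log-linear interpolation of the inoculant fraction from Day 0 to the
    final sampling day; constant if initial == 0 or residual == 0 handled
    by linear fallback on the zero endpoint."""
    d0, d1 = days[0], days[-1]
    if d1 == d0:
        return initial
    w = (day - d0) / (d1 - d0)
    if initial <= 0.0:
        return 0.0
    if residual <= 0.0:
        # log-linear undefined at 0: decay linearly in log down to a floor
        return initial * (1.0 - w) if w < 1.0 else 0.0
    return float(math.exp((1 - w) * math.log(initial) + w * math.log(residual)))


def generate_counts(design: DesignSpec, effects: EffectSpec) -> pd.DataFrame:
    """Draw the full count table for ``design`` under ``effects``.

    Returns a samples x features DataFrame of non-negative integers whose
    row/column order matches :func:`generate_metadata` / ``design.feature_ids``.
    """
    feature_ids = design.feature_ids
    if effects.inoculant_feature_id not in feature_ids:
        raise ValueError(
            f"inoculant feature {effects.inoculant_feature_id!r} not among the "
            f"{design.n_features} design features"
        )
    ino = feature_ids.index(effects.inoculant_feature_id)
    p = design.n_features
    meta = generate_metadata(design)
    inoculated_label = design.treatments[-1] if len(design.treatments) > 1 else None

    # per-soil structural parameters (each from its own named substream)
    soil_params = {}
    for soil in design.soils:
        rng = substream(design.seed, f"soil:{soil}")
        alpha = np.full(p, effects.baseline_concentration(soil))
        baseline = rng.dirichlet(alpha)
        baseline = np.maximum(baseline, 1e-12)
        # drift/shift magnitudes are per-feature log-abundance SDs
        drift_dir = rng.normal(size=p) * effects.drift(soil)
        shift_dir = rng.normal(size=p)
        if np.linalg.norm(drift_dir) > 0:
            # orthogonalize the treatment direction against the drift direction
            drift_unit = _unit(drift_dir)
            shift_dir = shift_dir - (shift_dir @ drift_unit) * drift_unit
        shift_dir = shift_dir * effects.shift(soil)
        soil_params[soil] = (baseline, drift_dir, shift_dir)

    last_day = design.days[-1]
    denom = math.log1p(last_day) if last_day > 0 else 1.0
    rng_counts = substream(design.seed, "counts")

    counts = np.zeros((len(meta), p), dtype=np.int64)
    for row, (sid, rec) in enumerate(meta.iterrows()):
        soil, treatment, day = rec["soil"], rec["treatment"], int(rec["day"])
        baseline, drift_dir, shift_dir = soil_params[soil]
        inoculated = treatment == inoculated_label
        m = math.log1p(day) / denom  # drift magnitude grows sublinearly in time
        drift = drift_dir
        if inoculated and effects.angle(soil) != 0.0 and np.linalg.norm(drift_dir) > 0:
            # rotate the inoculated drift within span(drift, shift) by the
            # divergence angle — inoculation bends the trajectory
            u = _unit(drift_dir)
            v = shift_dir - (shift_dir @ u) * u
            if np.linalg.norm(v) > 0:
                v = _unit(v)
                phi = effects.angle(soil)
                drift = (u * math.cos(phi) + v * math.sin(phi)) * np.linalg.norm(drift_dir)
        logp = np.log(baseline) + m * drift
        if inoculated:
            logp = logp + shift_dir
        comp = _softmax(logp)
        # pin the inoculant fraction
        if inoculated:
            phi_frac = expected_inoculant_fraction(
                day, design.days, effects.inoculant_initial_fraction,
                effects.residual(soil),
            )
        else:
            phi_frac = 0.0
        comp[ino] = 0.0
        s = comp.sum()
        comp = comp / s * (1.0 - phi_frac)
        comp[ino] = phi_frac

        n_reads = rng_counts.poisson(design.library_size)
        if n_reads == 0:
            continue
        pos = comp > 0
        alpha = effects.overdispersion * comp[pos]
        probs = rng_counts.dirichlet(alpha)
        draw = rng_counts.multinomial(n_reads, probs)
        counts[row, pos] = draw

    return pd.DataFrame(counts, index=meta.index.copy(), columns=feature_ids)


# ---------------------------------------------------------------------------
# filtering

def apply_min_count_filter(table: pd.DataFrame, threshold: int) -> pd.DataFrame:
    """Drop features whose total count across samples is < ``threshold``.

    Mirrors both the <10-UMI discard applied to the raw table and the
    minimum-feature-count 8 pre-filter of the rCLR/RPCA route.  Samples and
    the surviving feature order are unchanged; threshold 0 is the identity.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = table.sum(axis=0) >= threshold
    return table.loc[:, keep]
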
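"""Spatial clonal architecture: genet convex hulls, hull-overlap counts with
leave-one-genet-out (jackknife) confidence intervals, clonal identity as a
function of distance, and stem density from sub-quadrat counts.

Ramet positions are grid-cell centres; hull areas therefore measure the
extent of occupied cell centres, not cell outlines.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from shapely.geometry import MultiPoint, Point
from shapely.geometry.base import BaseGeometry

from .clones import MLGPartition, MLLPartition
from .io import SampleSet, Stage


@dataclass
class GenetGeometry:
    """One genet's ramet positions and its minimum convex polygon."""

    genet_id: int
    positions: tuple[tuple[float, float], ...]
    hull: BaseGeometry
    area: float

    @property
    def n_ramets(self) -> int:
        return len(self.positions)

    @property
    def is_degenerate(self) -> bool:
        """True for point or segment hulls (fewer than 3 non-collinear positions)."""
        return self.area == 0.0


@dataclass
class OverlapStats:
    """Genet-pair hull overlaps with jackknife uncertainty."""

    quadrat_id: str
    n_genets: int
    total_overlaps: int
    jackknife_values: tuple[int, ...]
    jk_mean: float
    jk_ci_low: float
    jk_ci_high: float
    ci_method: str = "normal"


@dataclass
class DistanceIdentityCurve:
    """Fraction of ramet pairs sharing a genet, binned by pair distance."""

    quadrat_id: str
    bin_edges: tuple[float, ...]          # len = n_bins + 1, half-open [lo, hi)
    fractions: tuple[Optional[float], ...]  # None for empty bins
    pair_counts: tuple[int, ...]


@dataclass
class StemDensitySample:
    """Stem counts from the random 1 m^2 sub-quadrats of one quadrat."""

    quadrat_id: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("stem counts must be non-negative")
        if not self.counts:
            raise ValueError("need at least one sub-quadrat count")

    @property
    def mean_density(self) -> float:
        """Mean stems per square metre (sub-quadrats are 1 m^2)."""
        return float(np.mean(self.counts))


# ---------------------------------------------------------------------------


def genet_hull(
    positions: Sequence[tuple[float, float]], genet_id: int = 0
) -> GenetGeometry:
    """Minimum convex polygon enclosing the positions.

    One or two points, or a collinear set, give a degenerate hull of area 0.
    """
    if not positions:
        raise ValueError("need at least one position")
    hull = MultiPoint([Point(p) for p in positions]).convex_hull
    return GenetGeometry(
        genet_id=genet_id,
        positions=tuple((float(x), float(y)) for x, y in positions),
        hull=hull,
        area=float(hull.area),
    )


def hulls_overlap(a: GenetGeometry, b: GenetGeometry) -> bool:
    """Overlap rule: positive-area intersection for two polygons; a degenerate
    hull counts if it intersects the other polygon's closure; two degenerate
    hulls never count (measure-zero contact is not intermingling)."""
    if a.is_degenerate and b.is_degenerate:
        return False
    if a.is_degenerate or b.is_degenerate:
        return bool(a.hull.intersects(b.hull))
    return a.hull.intersection(b.hull).area > 0.0


def count_overlaps(geometries: Sequence[GenetGeometry]) -> int:
    """Number of unordered genet pairs whose hulls overlap."""
    if not geometries:
        raise ValueError("need at least one genet")
    return sum(
        1 for a, b in itertools.combinations(geometries, 2) if hulls_overlap(a, b)
    )


def jackknife_overlaps(
    geometries: Sequence[GenetGeometry],
    quadrat_id: str = "",
    ci_method: str = "normal",
) -> OverlapStats:
    """Leave-one-genet-out totals with a 95% CI on the overlap count.

    ``normal`` uses mean +/- 1.96 * sqrt(Var_jack) with the standard jackknife
    variance estimator Var = (G-1)/G * sum (theta_i - mean)^2; ``percentile``
    takes the 2.5/97.5 percentiles of the leave-one-out values.
    """
    G = len(geometries)
    if G < 2:
        raise ValueError("jackknife requires at least two genets")
    total = count_overlaps(geometries)
    loo: list[int] = []
    for i in range(G):
        rest = [g for j, g in enumerate(geometries) if j != i]
        loo.append(count_overlaps(rest) if len(rest) >= 1 else 0)
    values = np.asarray(loo, dtype=float)
    mean = float(values.mean())
    if ci_method == "normal":
        var_jack = (G - 1) / G * float(np.sum((values - mean) ** 2))
        half = 1.96 * math.sqrt(var_jack)
        lo, hi = mean - half, mean + half
    elif ci_method == "percentile":
        lo, hi = (float(v) for v in np.percentile(values, [2.5, 97.5]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return OverlapStats(
        quadrat_id=quadrat_id,
        n_genets=G,
        total_overlaps=total,
        jackknife_values=tuple(loo),
        jk_mean=mean,
        jk_ci_low=lo,
        jk_ci_high=hi,
        ci_method=ci_method,
    )


def cis_disjoint(a: OverlapStats, b: OverlapStats) -> bool:
    """Non-overlap decision rule between two quadrats' 95% CIs."""
    return a.jk_ci_high < b.jk_ci_low or b.jk_ci_high < a.jk_ci_low


def genet_geometries(
    mll_partition: MLLPartition,
    mlg_partition: MLGPartition,
    sample_set: SampleSet,
    quadrat_id: str,
    stage: Optional[Stage] = None,
) -> list[GenetGeometry]:
    """Per-genet hull geometries for one quadrat (both stages pooled by default)."""
    layout = sample_set.layouts[quadrat_id]
    genet_of_sample = mll_partition.genet_of_sample(mlg_partition)
    positions: dict[int, list[tuple[float, float]]] = {}
    for rec in sample_set.records:
        if rec.quadrat_id != quadrat_id:
            continue
        if stage is not None and rec.stage is not stage:
            continue
        positions.setdefault(genet_of_sample[rec.sample_id], []).append(
            rec.position(layout)
        )
    return [genet_hull(pos, genet_id=g) for g, pos in sorted(positions.items())]


def identity_by_distance(
    mll_partition: MLLPartition,
    mlg_partition: MLGPartition,
    sample_set: SampleSet,
    quadrat_id: str,
    bin_width: float = 1.0,
    max_distance: Optional[float] = None,
) -> DistanceIdentityCurve:
    """Per-distance-bin fraction of ramet pairs that share a genet.

    All C(N, 2) pairs are binned by Euclidean cell-centre distance into
    half-open bins [k*w, (k+1)*w).  With the default ``max_distance=None``
    bins extend to cover every pair; an explicit ``max_distance`` truncates
    the curve (pairs beyond it are dropped).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    layout = sample_set.layouts[quadrat_id]
    genet_of_sample = mll_partition.genet_of_sample(mlg_partition)
    recs = [r for r in sample_set.records if r.quadrat_id == quadrat_id]
    if len(recs) < 2:
        raise ValueError("need at least two ramets")
    pts = np.array([r.position(layout) for r in recs])
    genets = np.array([genet_of_sample[r.sample_id] for r in recs])
    iu = np.triu_indices(len(recs), k=1)
    dists = np.hypot(pts[iu[0], 0] - pts[iu[1], 0], pts[iu[0], 1] - pts[iu[1], 1])
    same = genets[iu[0]] == genets[iu[1]]
    limit = float(dists.max()) if max_distance is None else float(max_distance)
    n_bins = max(1, math.floor(limit / bin_width) + 1)
    edges = [k * bin_width for k in range(n_bins + 1)]
    which = np.floor(dists / bin_width).astype(int)
    keep = which < n_bins
    counts = np.bincount(which[keep], minlength=n_bins)
    same_counts = np.bincount(which[keep], weights=same[keep].astype(float),
                              minlength=n_bins)
    fractions = tuple(
        float(same_counts[k] / counts[k]) if counts[k] > 0 else None
        for k in range(n_bins)
    )
    return DistanceIdentityCurve(
        quadrat_id=quadrat_id,
        bin_edges=tuple(edges),
        fractions=fractions,
        pair_counts=tuple(int(c) for c in counts),
    )


def stem_density(samples: Sequence[StemDensitySample]) -> dict[str, float]:
    """Mean stems per square metre for each quadrat."""
    return {s.quadrat_id: s.mean_density for s in samples}


def density_vectors_by_group(
    samples: Sequence[StemDensitySample],
    forest_of_quadrat: Mapping[str, str],
) -> dict[str, list[int]]:
    """Pool raw sub-quadrat counts per forest type for downstream tests."""
    out: dict[str, list[int]] = {}
    for s in samples:
        out.setdefault(forest_of_quadrat[s.quadrat_id], []).extend(s.counts)
    return out
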
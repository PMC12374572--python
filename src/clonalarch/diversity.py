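"""Per-quadrat clonal diversity statistics.

Implements clonal richness R = (G-1)/(N-1), the range-standardized Simpson
evenness V, the Pareto index (negative log-log slope of the reverse
cumulative clone-size distribution), the clonal-ramet percentage, and
cross-quadrat mean +/- SD summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .clones import MLGPartition, MLLPartition
from .io import SampleSet, Stage


@dataclass
class ClonalCensus:
    """Ramet/genet bookkeeping for one quadrat."""

    quadrat_id: str
    n_ramets: int
    n_genets: int
    clone_sizes: tuple[int, ...]
    n_multi_ramet_genets: int
    max_clone_size: int
    n_on_floor: int
    n_on_tree: int
    occupied_cells_on_floor: int
    occupied_cells_on_tree: int

    @property
    def clonal_ramet_pct(self) -> float:
        """Percent of ramets in multi-ramet genets: 100 * (1 - G/N)."""
        return 100.0 * (1.0 - self.n_genets / self.n_ramets)


@dataclass
class DiversityReport:
    """Clonal diversity indices of one quadrat (None marks 'not calculated')."""

    quadrat_id: str
    n_ramets: int
    n_genets: int
    richness: float
    simpson_d: float
    simpson_d_min: float
    simpson_d_max: float
    evenness: Optional[float]
    pareto_beta: Optional[float]
    pareto_p: Optional[float]
    clonal_ramet_pct: float


def census(
    mll_partition: MLLPartition,
    mlg_partition: MLGPartition,
    sample_set: SampleSet,
    quadrat_id: str,
) -> ClonalCensus:
    """Exact clone-size and stage counts for the records of one quadrat."""
    if quadrat_id not in sample_set.layouts:
        raise KeyError(f"unknown quadrat {quadrat_id!r}")
    genet_of_sample = mll_partition.genet_of_sample(mlg_partition)
    recs = [r for r in sample_set.records if r.quadrat_id == quadrat_id]
    if not recs:
        raise ValueError(f"quadrat {quadrat_id!r} has no genotyped ramets")
    sizes: dict[int, int] = {}
    floor = tree = 0
    cells_floor: set[tuple[int, int]] = set()
    cells_tree: set[tuple[int, int]] = set()
    for rec in recs:
        g = genet_of_sample[rec.sample_id]
        sizes[g] = sizes.get(g, 0) + 1
        if rec.stage is Stage.ON_FLOOR:
            floor += 1
            cells_floor.add(rec.cell)
        else:
            tree += 1
            cells_tree.add(rec.cell)
    clone_sizes = tuple(sorted(sizes.values(), reverse=True))
    return ClonalCensus(
        quadrat_id=quadrat_id,
        n_ramets=len(recs),
        n_genets=len(clone_sizes),
        clone_sizes=clone_sizes,
        n_multi_ramet_genets=sum(1 for s in clone_sizes if s >= 2),
        max_clone_size=max(clone_sizes),
        n_on_floor=floor,
        n_on_tree=tree,
        occupied_cells_on_floor=len(cells_floor),
        occupied_cells_on_tree=len(cells_tree),
    )


def clonal_richness(N: int, G: int) -> float:
    """Clonal (genotypic) richness R = (G - 1) / (N - 1)."""
    if N < 2:
        raise ValueError("clonal richness requires N >= 2")
    if not 1 <= G <= N:
        raise ValueError("need 1 <= G <= N")
    return (G - 1) / (N - 1)


def simpson_evenness(
    clone_sizes: Sequence[int], N: Optional[int] = None
) -> tuple[float, float, float, Optional[float]]:
    """Simpson index D with its range bounds and the evenness V.

    D     = 1 - sum n_i (n_i - 1) / (N (N - 1))
    D_min = [(2N - G)(G - 1) / N^2] * [N / (N - 1)]
    D_max = [(G - 1) / G] * [N / (N - 1)]
    V     = (D - D_min) / (D_max - D_min); undefined (None) when the range
    degenerates (G == 1, and the all-singletons case G == N).
    """
    sizes = list(clone_sizes)
    total = sum(sizes)
    if N is None:
        N = total
    elif total != N:
        raise ValueError(f"clone sizes sum to {total}, expected N = {N}")
    if N < 2:
        raise ValueError("Simpson evenness requires N >= 2")
    G = len(sizes)
    D = 1.0 - sum(n * (n - 1) for n in sizes) / (N * (N - 1))
    D_min = ((2 * N - G) * (G - 1) / N**2) * (N / (N - 1))
    D_max = ((G - 1) / G) * (N / (N - 1))
    if D_max - D_min == 0.0:
        return D, D_min, D_max, None
    V = (D - D_min) / (D_max - D_min)
    return D, D_min, D_max, V


def pareto_index(
    clone_sizes: Sequence[int], x_grid: str = "observed"
) -> Optional[tuple[float, float]]:
    """Pareto index beta: negative slope of log10 N_{>=X} on log10 X.

    X values are the sorted distinct clone sizes (``x_grid="observed"``,
    default) or every integer 1..max (``x_grid="integer"``); N_{>=X} counts
    genets with at least X ramets.  Returns ``(beta, p_value)`` with the
    two-sided t-test p-value of the OLS slope, or None when fewer than three
    distinct sizes are available (fit not calculated).
    """
    sizes = list(clone_sizes)
    if not sizes:
        raise ValueError("empty clone-size multiset")
    if x_grid == "observed":
        xs = sorted(set(sizes))
    elif x_grid == "integer":
        xs = list(range(1, max(sizes) + 1))
    else:
        raise ValueError(f"unknown x_grid {x_grid!r}")
    ys = [sum(1 for s in sizes if s >= x) for x in xs]
    pts = [(x, y) for x, y in zip(xs, ys) if y > 0]
    if len({x for x, _ in pts}) < 3:
        return None
    log_x = np.log10([x for x, _ in pts])
    log_y = np.log10([y for _, y in pts])
    fit = sps.linregress(log_x, log_y)
    return -float(fit.slope), float(fit.pvalue)


def diversity_report(census_: ClonalCensus) -> DiversityReport:
    """Bundle every quadrat-level diversity index from a census."""
    D, D_min, D_max, V = simpson_evenness(census_.clone_sizes, census_.n_ramets)
    pareto = pareto_index(census_.clone_sizes)
    beta, p = pareto if pareto is not None else (None, None)
    return DiversityReport(
        quadrat_id=census_.quadrat_id,
        n_ramets=census_.n_ramets,
        n_genets=census_.n_genets,
        richness=clonal_richness(census_.n_ramets, census_.n_genets),
        simpson_d=D,
        simpson_d_min=D_min,
        simpson_d_max=D_max,
        evenness=V,
        pareto_beta=beta,
        pareto_p=p,
        clonal_ramet_pct=census_.clonal_ramet_pct,
    )


def mean_sd(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n - 1 denominator; SD 0 for n == 1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no values")
    if arr.size == 1:
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1))


def summarize_forest_type(
    values_by_quadrat: Mapping[str, float],
    forest_of_quadrat: Mapping[str, str],
) -> dict[str, tuple[float, float]]:
    """Mean +/- sample SD of a per-quadrat statistic within each forest type."""
    groups: dict[str, list[float]] = {}
    for qid, value in values_by_quadrat.items():
        groups.setdefault(forest_of_quadrat[qid], []).append(value)
    return {ft: mean_sd(vals) for ft, vals in groups.items()}
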
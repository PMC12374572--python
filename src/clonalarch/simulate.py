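"""Spatially explicit simulator of clonal populations with known ground truth.

Founder genets are placed uniformly in a gridded quadrat with Hardy-Weinberg
genotypes drawn from Dirichlet population allele frequencies.  Each founder
spreads by a branching stolon random walk (exponential step lengths, uniform
turning, reflecting quadrat walls); ramets inherit the founder genotype with
optional stepwise somatic mutation (+/- one repeat unit) and genotyping
error (allele re-drawn from the locus pool).  Sampling mirrors the field
protocol: one ramet per grid cell per life stage, chosen uniformly among the
cell's occupants.

Two presets bracket the study regimes: ``young`` (2-5 founders, ~10 stems
per m^2, large exclusive clones) and ``old_growth`` (14-30 founders, ~145
stems per m^2, intermingled clones).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .clones import genotype_distance, AlleleFreqTable
from .io import (
    ForestType,
    LocusGenotype,
    MarkerPanel,
    QuadratLayout,
    RametRecord,
    SampleSet,
    Stage,
)

PRESET_NAMES = ("young", "old_growth")


@dataclass(frozen=True)
class SimScenario:
    """Full parameterization of one simulated quadrat."""

    quadrat_id: str = "SIM1"
    forest_type: Optional[ForestType] = None
    grid_rows: int = 10
    grid_cols: int = 10
    cell_size: float = 1.0
    #: fixed count, or inclusive (lo, hi) range drawn per run
    n_founders: Union[int, tuple[int, int]] = 3
    n_loci: int = 11
    alleles_per_locus: int = 8
    dirichlet_concentration: float = 1.0
    motif_bp: int = 2
    #: mean ramets per founder (negative binomial, includes the founder itself)
    ramets_per_founder: float = 100.0
    nb_dispersion: float = 10.0
    min_ramets_per_founder: int = 1
    stolon_step_mean: float = 0.5
    branch_prob: float = 0.2
    on_tree_probability: float = 0.2
    somatic_mutation_rate: float = 0.0
    genotyping_error_rate: float = 0.0
    #: redraw founder genotypes until all pairwise distances reach this
    min_founder_distance: int = 1
    #: hard-core spacing (m) between founder points (0 = plain uniform)
    founder_min_spacing: float = 0.0
    n_sub_quadrats: int = 10

    def __post_init__(self) -> None:
        lo, hi = self.founder_range
        if lo < 1 or hi < lo:
            raise ValueError("n_founders must be >= 1 (or a valid range)")
        for p in (self.branch_prob, self.on_tree_probability,
                  self.somatic_mutation_rate, self.genotyping_error_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_loci < 1 or self.alleles_per_locus < 2:
            raise ValueError("need n_loci >= 1 and alleles_per_locus >= 2")

    @property
    def founder_range(self) -> tuple[int, int]:
        if isinstance(self.n_founders, int):
            return (self.n_founders, self.n_founders)
        lo, hi = self.n_founders
        return (int(lo), int(hi))

    @property
    def panel(self) -> MarkerPanel:
        loci = tuple(f"L{i + 1:02d}" for i in range(self.n_loci))
        return MarkerPanel(loci, motif_bp={l: self.motif_bp for l in loci})

    @property
    def layout(self) -> QuadratLayout:
        return QuadratLayout(
            self.quadrat_id, self.forest_type, self.grid_rows, self.grid_cols,
            self.cell_size,
        )

    def allele_pool(self, locus_index: int) -> np.ndarray:
        """Allele fragment sizes available at one locus."""
        base = 100 + 50 * locus_index
        return base + self.motif_bp * np.arange(self.alleles_per_locus)


@dataclass
class SimTruth:
    """Ground truth retained alongside the sampled records."""

    scenario: SimScenario
    seed: int
    n_founders: int
    founder_positions: np.ndarray            # (F, 2) metres
    founder_genotypes: list[tuple[LocusGenotype, ...]]
    ramet_positions: np.ndarray               # (n, 2) all pre-sampling ramets
    ramet_genet: np.ndarray                   # (n,) founder ids 1..F
    true_genet_of_sample: dict[str, int]      # sampled ramets only
    cell_counts: np.ndarray                   # (rows, cols) true stems per cell

    @property
    def true_stem_density(self) -> float:
        return float(self.cell_counts.mean()) / (self.scenario.cell_size ** 2)


def preset(name: str) -> SimScenario:
    """Documented parameter bundles for the two forest regimes."""
    if name == "young":
        return SimScenario(
            quadrat_id="SIM-Y",
            forest_type=ForestType.YOUNG,
            n_founders=(2, 5),
            ramets_per_founder=280.0,
            min_ramets_per_founder=50,
            stolon_step_mean=0.6,
            branch_prob=0.25,
            min_founder_distance=7,
        )
    if name == "old_growth":
        return SimScenario(
            quadrat_id="SIM-O",
            forest_type=ForestType.OLD_GROWTH,
            n_founders=(14, 30),
            ramets_per_founder=620.0,
            nb_dispersion=50.0,
            min_ramets_per_founder=200,
            stolon_step_mean=0.22,
            branch_prob=0.25,
            min_founder_distance=7,
            founder_min_spacing=1.5,
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def draw_population_freqs(
    scenario: SimScenario, rng: np.random.Generator
) -> AlleleFreqTable:
    """Per-locus population allele frequencies from a symmetric Dirichlet."""
    freqs: dict[str, dict[int, float]] = {}
    for i, locus in enumerate(scenario.panel.loci):
        pool = scenario.allele_pool(i)
        p = rng.dirichlet(np.full(len(pool), scenario.dirichlet_concentration))
        p = p / p.sum()
        freqs[locus] = {int(a): float(f) for a, f in zip(pool, p)}
    return AlleleFreqTable(scenario.panel.loci, freqs, "population")


def _draw_founder_genotypes(
    scenario: SimScenario,
    freqs: AlleleFreqTable,
    n_founders: int,
    rng: np.random.Generator,
) -> list[tuple[LocusGenotype, ...]]:
    """HWE founder genotypes, redrawn until pairwise distances reach the floor."""
    pools = [scenario.allele_pool(i) for i in range(scenario.n_loci)]
    probs = [
        np.array([freqs.freqs[l][int(a)] for a in pools[i]])
        for i, l in enumerate(scenario.panel.loci)
    ]

    def draw_one() -> tuple[LocusGenotype, ...]:
        return tuple(
            LocusGenotype(*(int(a) for a in rng.choice(pools[i], size=2, p=probs[i])))
            for i in range(scenario.n_loci)
        )

    for _ in range(500):
        founders = [draw_one() for _ in range(n_founders)]
        ok = all(
            genotype_distance(founders[i], founders[j]) >= scenario.min_founder_distance
            for i in range(n_founders)
            for j in range(i + 1, n_founders)
        )
        if ok:
            return founders
    raise RuntimeError(
        "could not draw founders satisfying min_founder_distance; "
        "increase loci/alleles or lower the floor"
    )


def _place_founders(
    n: int,
    width: float,
    height: float,
    min_spacing: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform founder points, optionally thinned to a hard-core spacing.

    With ``min_spacing > 0`` candidates closer than the spacing to an accepted
    point are rejected (up to a try budget, after which the spacing is
    relaxed by 10% and retried) — keeps founder territories from coinciding.
    """
    if min_spacing <= 0.0:
        return np.column_stack(
            [rng.uniform(0.0, width, n), rng.uniform(0.0, height, n)]
        )
    spacing = min_spacing
    while True:
        accepted: list[tuple[float, float]] = []
        for _ in range(2000 * n):
            x, y = rng.uniform(0.0, width), rng.uniform(0.0, height)
            if all((x - px) ** 2 + (y - py) ** 2 >= spacing**2
                   for px, py in accepted):
                accepted.append((x, y))
                if len(accepted) == n:
                    return np.array(accepted)
        spacing *= 0.9


def _reflect(value: float, limit: float) -> float:
    """Fold a coordinate back into [0, limit] (reflecting boundary)."""
    period = 2.0 * limit
    v = value % period
    return period - v if v > limit else v


def _stolon_walk(
    origin: tuple[float, float],
    n_ramets: int,
    scenario: SimScenario,
    rng: np.random.Generator,
) -> np.ndarray:
    """Branching random walk from the founder; returns (n_ramets, 2) positions.

    The founder point is the first ramet.  Tips advance breadth-first; each
    new node becomes one tip, or two with probability ``branch_prob``.
    """
    width = scenario.grid_cols * scenario.cell_size
    height = scenario.grid_rows * scenario.cell_size
    nodes = [origin]
    tips = [origin]
    while len(nodes) < n_ramets:
        tip = tips.pop(0) if tips else nodes[-1]
        step = rng.exponential(scenario.stolon_step_mean)
        angle = rng.uniform(0.0, 2.0 * math.pi)
        x = _reflect(tip[0] + step * math.cos(angle), width)
        y = _reflect(tip[1] + step * math.sin(angle), height)
        nodes.append((x, y))
        tips.append((x, y))
        if rng.random() < scenario.branch_prob:
            tips.append((x, y))
    return np.array(nodes)


def _apply_noise(
    genotype: tuple[LocusGenotype, ...],
    scenario: SimScenario,
    rng: np.random.Generator,
) -> tuple[LocusGenotype, ...]:
    mu, err = scenario.somatic_mutation_rate, scenario.genotyping_error_rate
    if mu == 0.0 and err == 0.0:
        return genotype
    out: list[LocusGenotype] = []
    for i, g in enumerate(genotype):
        alleles = list(g.alleles)
        for k in range(2):
            if mu > 0.0 and rng.random() < mu:
                alleles[k] += scenario.motif_bp * (1 if rng.random() < 0.5 else -1)
            if err > 0.0 and rng.random() < err:
                alleles[k] = int(rng.choice(scenario.allele_pool(i)))
        out.append(LocusGenotype(alleles[0], alleles[1]))
    return tuple(out)


def simulate_quadrat(
    scenario: SimScenario, seed: int
) -> tuple[SampleSet, SimTruth]:
    """Generate one quadrat and apply the field sampling protocol.

    Returns the sampled records as a :class:`SampleSet` (at most
    rows x cols x 2 of them) together with the full ground truth.
    Deterministic for a fixed (scenario, seed).
    """
    rng = np.random.default_rng(seed)
    lo, hi = scenario.founder_range
    n_founders = int(rng.integers(lo, hi + 1))
    freqs = draw_population_freqs(scenario, rng)
    founder_genotypes = _draw_founder_genotypes(scenario, freqs, n_founders, rng)

    width = scenario.grid_cols * scenario.cell_size
    height = scenario.grid_rows * scenario.cell_size
    founder_positions = _place_founders(n_founders, width, height,
                                        scenario.founder_min_spacing, rng)

    all_positions: list[np.ndarray] = []
    all_genets: list[np.ndarray] = []
    mean = scenario.ramets_per_founder
    k = scenario.nb_dispersion
    for f in range(n_founders):
        count = int(rng.negative_binomial(k, k / (k + mean)))
        count = max(count, scenario.min_ramets_per_founder, 1)
        walk = _stolon_walk(tuple(founder_positions[f]), count, scenario, rng)
        all_positions.append(walk)
        all_genets.append(np.full(len(walk), f + 1))
    positions = np.concatenate(all_positions)
    genets = np.concatenate(all_genets)
    if len(positions) == 0:
        raise RuntimeError("no ramets generated; increase ramets_per_founder")

    # stage per ramet, grid cell per ramet
    stages = rng.random(len(positions)) < scenario.on_tree_probability  # True = on_tree
    cols = np.clip((positions[:, 0] / scenario.cell_size).astype(int) + 1,
                   1, scenario.grid_cols)
    rows = np.clip((positions[:, 1] / scenario.cell_size).astype(int) + 1,
                   1, scenario.grid_rows)
    cell_counts = np.zeros((scenario.grid_rows, scenario.grid_cols), dtype=int)
    np.add.at(cell_counts, (rows - 1, cols - 1), 1)

    # one ramet per (cell, stage), uniform among occupants, deterministic order
    occupants: dict[tuple[int, int, bool], list[int]] = {}
    for idx in range(len(positions)):
        occupants.setdefault((int(rows[idx]), int(cols[idx]), bool(stages[idx])), []
                             ).append(idx)
    records: list[RametRecord] = []
    true_genet_of_sample: dict[str, int] = {}
    for r in range(1, scenario.grid_rows + 1):
        for c in range(1, scenario.grid_cols + 1):
            for on_tree in (False, True):
                members = occupants.get((r, c, on_tree))
                if not members:
                    continue
                idx = int(members[rng.integers(0, len(members))])
                stage = Stage.ON_TREE if on_tree else Stage.ON_FLOOR
                sample_id = f"{scenario.quadrat_id}-r{r:02d}c{c:02d}{'T' if on_tree else 'F'}"
                genotype = _apply_noise(
                    founder_genotypes[int(genets[idx]) - 1], scenario, rng
                )
                records.append(
                    RametRecord(sample_id, scenario.quadrat_id, r, c, stage, genotype)
                )
                true_genet_of_sample[sample_id] = int(genets[idx])

    sample_set = SampleSet(
        scenario.panel, {scenario.quadrat_id: scenario.layout}, records
    )
    truth = SimTruth(
        scenario=scenario,
        seed=seed,
        n_founders=n_founders,
        founder_positions=founder_positions,
        founder_genotypes=founder_genotypes,
        ramet_positions=positions,
        ramet_genet=genets,
        true_genet_of_sample=true_genet_of_sample,
        cell_counts=cell_counts,
    )
    return sample_set, truth


def draw_sub_quadrat_counts(
    truth: SimTruth, rng: np.random.Generator
) -> list[int]:
    """Stem counts of ``n_sub_quadrats`` distinct random cells (density protocol)."""
    sc = truth.scenario
    n_cells = sc.grid_rows * sc.grid_cols
    chosen = rng.choice(n_cells, size=min(sc.n_sub_quadrats, n_cells), replace=False)
    flat = truth.cell_counts.ravel()
    return [int(flat[i]) for i in chosen]


def truth_to_json_dict(truth: SimTruth) -> dict:
    """JSON-serializable ground-truth summary (for the CLI --truth output)."""
    return {
        "seed": truth.seed,
        "quadrat_id": truth.scenario.quadrat_id,
        "n_founders": truth.n_founders,
        "founder_positions": truth.ramet_positions[:0].tolist()
        if truth.founder_positions is None else truth.founder_positions.tolist(),
        "founder_genotypes": [
            [list(g.alleles) for g in geno] for geno in truth.founder_genotypes
        ],
        "true_genet_of_sample": truth.true_genet_of_sample,
        "cell_counts": truth.cell_counts.tolist(),
        "n_ramets_total": int(len(truth.ramet_positions)),
        "true_stem_density": truth.true_stem_density,
    }
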
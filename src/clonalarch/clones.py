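"""Clone discrimination: MLG collapsing, marker resolution, P_gen / P_sex,
and distance-threshold clustering of MLGs into multilocus lineages (genets).

An MLG (multilocus genotype) groups samples with identical allele calls at
every scored locus.  MLGs within a small pairwise genetic distance of each
other are then merged into MLLs (multilocus lineages), absorbing slightly
different genotypes produced by somatic mutation or scoring error; MLLs are
the operational genets.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .io import LocusGenotype, SampleSet


class Linkage(str, Enum):
    """Inter-cluster distance rule for MLL agglomeration."""

    FARTHEST = "farthest"  # complete linkage (conservative, default)
    NEAREST = "nearest"    # single linkage


@dataclass
class MLGPartition:
    """Exact-match partition of samples into multilocus genotypes.

    MLG ids are dense integers ``1..n_mlgs`` assigned by first occurrence in
    sample order.
    """

    mlg_of_sample: dict[str, int]
    representative_genotype: dict[int, tuple[LocusGenotype, ...]]
    loci_used: tuple[int, ...]

    @property
    def n_samples(self) -> int:
        return len(self.mlg_of_sample)

    @property
    def n_mlgs(self) -> int:
        return len(self.representative_genotype)

    @property
    def mlg_ids(self) -> list[int]:
        return sorted(self.representative_genotype)

    def samples_of_mlg(self, mlg_id: int) -> list[str]:
        return [s for s, m in self.mlg_of_sample.items() if m == mlg_id]

    def counts(self) -> dict[int, int]:
        out: dict[int, int] = {m: 0 for m in self.mlg_ids}
        for m in self.mlg_of_sample.values():
            out[m] += 1
        return out


@dataclass
class MLLPartition:
    """MLG -> genet assignment produced by threshold agglomeration."""

    genet_of_mlg: dict[int, int]
    threshold: float
    linkage: Linkage

    @property
    def n_genets(self) -> int:
        return len(set(self.genet_of_mlg.values()))

    def genet_of_sample(self, mlg_partition: MLGPartition) -> dict[str, int]:
        return {
            s: self.genet_of_mlg[m] for s, m in mlg_partition.mlg_of_sample.items()
        }


@dataclass
class AlleleFreqTable:
    """Per-locus allele frequency estimates.

    ``freqs[locus]`` maps allele size -> frequency; frequencies at each locus
    sum to 1.
    """

    loci: tuple[str, ...]
    freqs: dict[str, dict[int, float]]
    estimation_mode: str = "round_robin"

    def __post_init__(self) -> None:
        for locus in self.loci:
            total = sum(self.freqs[locus].values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"locus {locus!r}: frequencies sum to {total}, not 1")

    def frequency(self, locus: str, allele: int) -> float:
        try:
            return self.freqs[locus][allele]
        except KeyError:
            raise KeyError(
                f"allele {allele} at locus {locus!r} absent from frequency table "
                "(frequency table and genotype data disagree)"
            ) from None


@dataclass
class AccumulationCurve:
    """MLG counts over locus subsets of each size k = 1..L."""

    subset_sizes: list[int]
    counts: dict[int, list[int]]          # k -> MLG count per evaluated subset
    enumeration_mode: dict[int, str]      # k -> "exhaustive" | "sampled"
    n_mlgs_full: int

    def max_counts(self) -> dict[int, int]:
        return {k: max(v) for k, v in self.counts.items()}

    @property
    def plateau_k(self) -> int:
        """Smallest subset size whose best subset already finds every MLG."""
        for k in self.subset_sizes:
            if max(self.counts[k]) == self.n_mlgs_full:
                return k
        return self.subset_sizes[-1]


# ---------------------------------------------------------------------------
# MLG collapsing and marker resolution


def _genotype_key(
    genotype: Sequence[LocusGenotype], loci_idx: Sequence[int]
) -> tuple[tuple[int, int], ...]:
    return tuple(genotype[i].alleles for i in loci_idx)


def collapse_mlgs(
    sample_set: SampleSet, loci_subset: Optional[Sequence[int]] = None
) -> MLGPartition:
    """Partition samples into MLGs by exact genotype match on the chosen loci.

    ``loci_subset`` holds 0-based locus indices; default is all loci.  Ids are
    assigned by first occurrence in sample order.
    """
    if sample_set.n_samples == 0:
        raise ValueError("cannot collapse an empty sample set")
    loci_idx = tuple(loci_subset) if loci_subset is not None else tuple(
        range(sample_set.panel.n_loci)
    )
    mlg_of_sample: dict[str, int] = {}
    key_to_id: dict[tuple, int] = {}
    representative: dict[int, tuple[LocusGenotype, ...]] = {}
    for rec in sample_set.records:
        key = _genotype_key(rec.genotype, loci_idx)
        if key not in key_to_id:
            key_to_id[key] = len(key_to_id) + 1
            representative[key_to_id[key]] = rec.genotype
        mlg_of_sample[rec.sample_id] = key_to_id[key]
    return MLGPartition(mlg_of_sample, representative, loci_idx)


def accumulation_curve(
    sample_set: SampleSet,
    max_exhaustive: int = 200,
    rng_seed: int = 0,
) -> AccumulationCurve:
    """Genotype accumulation curve: MLG counts for locus subsets of size 1..L.

    Subsets of size k are enumerated exhaustively while C(L, k) does not
    exceed ``max_exhaustive``; otherwise ``max_exhaustive`` distinct subsets
    are drawn uniformly without replacement with ``rng_seed``.
    """
    L = sample_set.panel.n_loci
    rng = np.random.default_rng(rng_seed)
    full = collapse_mlgs(sample_set).n_mlgs
    counts: dict[int, list[int]] = {}
    mode: dict[int, str] = {}
    for k in range(1, L + 1):
        n_total = math.comb(L, k)
        if n_total <= max_exhaustive:
            subsets: Iterable[tuple[int, ...]] = itertools.combinations(range(L), k)
            mode[k] = "exhaustive"
        else:
            chosen: set[tuple[int, ...]] = set()
            while len(chosen) < max_exhaustive:
                chosen.add(tuple(sorted(rng.choice(L, size=k, replace=False).tolist())))
            subsets = sorted(chosen)
            mode[k] = "sampled"
        counts[k] = [collapse_mlgs(sample_set, s).n_mlgs for s in subsets]
    return AccumulationCurve(list(range(1, L + 1)), counts, mode, full)


# ---------------------------------------------------------------------------
# allele frequencies and clonal-identity probabilities


def plain_freqs(sample_set: SampleSet) -> AlleleFreqTable:
    """Allele frequencies counted over every sample (2 alleles per sample)."""
    freqs: dict[str, dict[int, float]] = {}
    for i, locus in enumerate(sample_set.panel.loci):
        counts: dict[int, int] = {}
        for rec in sample_set.records:
            g = rec.genotype[i]
            if g.is_missing:
                continue
            for allele in g.alleles:
                counts[allele] = counts.get(allele, 0) + 1
        total = sum(counts.values())
        if total == 0:
            raise ValueError(f"locus {locus!r}: no scored alleles")
        freqs[locus] = {a: c / total for a, c in sorted(counts.items())}
    return AlleleFreqTable(sample_set.panel.loci, freqs, "plain")


def round_robin_freqs(sample_set: SampleSet) -> AlleleFreqTable:
    """Round-robin allele frequencies.

    For locus i, samples are collapsed to MLGs using all loci *except* i; one
    representative per MLG (first in sample order) contributes its two
    alleles at locus i.  This removes the inflation of common-clone alleles
    without conditioning on the focal locus itself.  Falls back to plain
    frequencies (with a warning) when only one locus is available.
    """
    L = sample_set.panel.n_loci
    if L == 1:
        warnings.warn(
            "round-robin frequencies undefined for a single locus; using plain frequencies",
            stacklevel=2,
        )
        table = plain_freqs(sample_set)
        return AlleleFreqTable(table.loci, table.freqs, "plain")
    freqs: dict[str, dict[int, float]] = {}
    for i, locus in enumerate(sample_set.panel.loci):
        others = [j for j in range(L) if j != i]
        partition = collapse_mlgs(sample_set, others)
        first_of_mlg: dict[int, str] = {}
        for rec in sample_set.records:
            m = partition.mlg_of_sample[rec.sample_id]
            first_of_mlg.setdefault(m, rec.sample_id)
        counts: dict[int, int] = {}
        for sample_id in first_of_mlg.values():
            g = sample_set.record_by_id(sample_id).genotype[i]
            if g.is_missing:
                continue
            for allele in g.alleles:
                counts[allele] = counts.get(allele, 0) + 1
        total = sum(counts.values())
        if total == 0:
            raise ValueError(f"locus {locus!r}: no scored alleles among representatives")
        freqs[locus] = {a: c / total for a, c in sorted(counts.items())}
    return AlleleFreqTable(sample_set.panel.loci, freqs, "round_robin")


def pgen(
    genotype: Sequence[LocusGenotype],
    freqs: AlleleFreqTable,
) -> float:
    """Probability of drawing this multilocus genotype under Hardy-Weinberg.

    ``P_gen = (prod over loci of f_a * f_b) * 2**h`` with h the number of
    heterozygous loci (Parks & Werth estimator).  Computed in log space.
    """
    if len(genotype) != len(freqs.loci):
        raise ValueError("genotype length does not match frequency table")
    log_p = 0.0
    h = 0
    for locus, g in zip(freqs.loci, genotype):
        if g.is_missing:
            raise ValueError(f"missing genotype at locus {locus!r}")
        fa = freqs.frequency(locus, g.allele_a)
        fb = freqs.frequency(locus, g.allele_b)
        if fa <= 0 or fb <= 0:
            raise ValueError(f"zero frequency at locus {locus!r}")
        log_p += math.log(fa) + math.log(fb)
        if g.is_heterozygous:
            h += 1
    return math.exp(log_p + h * math.log(2.0))


def psex(p_gen: float, n: int, N: int, convention: str = "inclusive") -> float:
    """Probability of observing >= n copies of an MLG among N samples by chance.

    ``inclusive`` (default) is the upper binomial tail from i = n; the
    ``conditional`` alternative conditions on the first observation (tail from
    n-1 successes among N-1 trials).  Evaluated with the binomial survival
    function for numerical stability at tiny ``p_gen``.
    """
    if not 0.0 <= p_gen <= 1.0:
        raise ValueError("p_gen must be in [0, 1]")
    if n < 1 or n > N:
        raise ValueError("need 1 <= n <= N")
    if convention == "inclusive":
        return float(sps.binom.sf(n - 1, N, p_gen))
    if convention == "conditional":
        if n == 1:
            return 1.0
        return float(sps.binom.sf(n - 2, N - 1, p_gen))
    raise ValueError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# genetic distances and MLL clustering


def locus_distance(a: LocusGenotype, b: LocusGenotype) -> int:
    """Allele mismatches between two diploid calls under optimal pairing (0-2)."""
    if a.is_missing or b.is_missing:
        raise ValueError("cannot compute a distance with missing calls")
    shared = 0
    bs = list(b.alleles)
    for allele in a.alleles:
        if allele in bs:
            bs.remove(allele)
            shared += 1
    return 2 - shared


def genotype_distance(
    ga: Sequence[LocusGenotype], gb: Sequence[LocusGenotype], skip_missing: bool = False
) -> int:
    """Total allele-mismatch count across loci."""
    total = 0
    for a, b in zip(ga, gb):
        if skip_missing and (a.is_missing or b.is_missing):
            continue
        total += locus_distance(a, b)
    return total


def pairwise_mlg_distances(
    sample_set: SampleSet,
    partition: MLGPartition,
    skip_missing: bool = False,
) -> np.ndarray:
    """Symmetric (n_mlgs x n_mlgs) allele-mismatch distance matrix.

    Row/column order follows MLG id (first-occurrence order); the diagonal is
    zero.
    """
    ids = partition.mlg_ids
    n = len(ids)
    D = np.zeros((n, n), dtype=int)
    for i in range(n):
        gi = partition.representative_genotype[ids[i]]
        for j in range(i + 1, n):
            gj = partition.representative_genotype[ids[j]]
            d = genotype_distance(gi, gj, skip_missing=skip_missing)
            D[i, j] = D[j, i] = d
    return D


def _agglomerate(
    n: int, D: np.ndarray, threshold: float, linkage: Linkage
) -> list[int]:
    """Cluster indices 0..n-1; returns a dense cluster label per index.

    Merge order: ascending inter-cluster distance, ties broken by the lowest
    member indices.  Merging continues while the best inter-cluster distance
    (max under farthest, min under nearest) is <= threshold.  Labels are
    dense and ordered by the smallest member index of each cluster.
    """
    clusters: list[list[int]] = [[i] for i in range(n)]
    M = D.astype(float).copy()
    np.fill_diagonal(M, np.inf)
    while len(clusters) > 1:
        k = len(clusters)
        iu = np.triu_indices(k, 1)
        dmin = float(M[iu].min())
        if dmin > threshold:
            break
        # clusters stay sorted by first member, so the lexicographically
        # smallest (a, b) among minimal pairs realizes the id tie-break
        hits = np.argwhere(np.triu(M == dmin, 1))
        a, b = (int(v) for v in hits[np.lexsort((hits[:, 1], hits[:, 0]))[0]])
        # Lance-Williams update (max = complete linkage, min = single)
        combine = np.maximum if linkage is Linkage.FARTHEST else np.minimum
        M[a, :] = combine(M[a, :], M[b, :])
        M[:, a] = M[a, :]
        M[a, a] = np.inf
        M = np.delete(np.delete(M, b, axis=0), b, axis=1)
        clusters[a] = sorted(clusters[a] + clusters[b])
        del clusters[b]
    labels = [0] * n
    for label, members in enumerate(clusters):
        for i in members:
            labels[i] = label
    return labels


def assign_mlls(
    partition: MLGPartition,
    distances: np.ndarray,
    threshold: float,
    linkage: Linkage | str = Linkage.FARTHEST,
) -> MLLPartition:
    """Merge MLGs whose inter-cluster distance is <= threshold into MLLs.

    Genet ids are dense ``1..G``, ordered by the first sample occurrence of
    each cluster's earliest MLG.  Threshold 0 keeps MLLs identical to MLGs.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    linkage = Linkage(linkage)
    ids = partition.mlg_ids
    labels = _agglomerate(len(ids), distances, threshold, linkage)
    genet_of_mlg = {ids[i]: labels[i] + 1 for i in range(len(ids))}
    return MLLPartition(genet_of_mlg, float(threshold), linkage)


def _cluster_count(D: np.ndarray, threshold: float, linkage: Linkage) -> int:
    return len(set(_agglomerate(D.shape[0], D, threshold, linkage)))


@dataclass
class ThresholdReport:
    """Diagnostics from :func:`predict_mll_threshold`."""

    candidates: list[float]
    retained: list[float]
    gaps: list[float]
    threshold: float


def predict_mll_threshold(
    distances: np.ndarray,
    clonal_fraction: float = 0.5,
    linkage: Linkage | str = Linkage.FARTHEST,
    full_report: bool = False,
) -> float | ThresholdReport:
    """Data-driven distance cutoff separating clone-mate from between-genet distances.

    Candidate cutoffs are the distinct distances at which the agglomerative
    MLL count changes while sweeping the threshold upward from 0.  The first
    ``ceil(clonal_fraction * n_candidates)`` candidates (the presumed
    clone-mate side of the distribution) are retained, and the threshold is
    the midpoint of the largest gap between consecutive retained candidates
    (ties resolved toward the lowest-distance gap).  Fewer than two retained
    candidates yield threshold 0 (no collapsing).
    """
    if not 0 < clonal_fraction <= 1:
        raise ValueError("clonal_fraction must be in (0, 1]")
    linkage = Linkage(linkage)
    n = distances.shape[0]
    if n < 2:
        report = ThresholdReport([], [], [], 0.0)
        return report if full_report else 0.0
    values = sorted(set(float(v) for v in distances[np.triu_indices(n, k=1)]))
    candidates: list[float] = []
    prev = n  # cluster count at threshold just below the smallest distance
    for v in values:
        count = _cluster_count(distances, v, linkage)
        if count != prev:
            candidates.append(v)
            prev = count
    n_keep = math.ceil(clonal_fraction * len(candidates))
    retained = candidates[:n_keep]
    if len(retained) < 2:
        report = ThresholdReport(candidates, retained, [], 0.0)
        return report if full_report else 0.0
    gaps = [retained[i + 1] - retained[i] for i in range(len(retained) - 1)]
    best = max(range(len(gaps)), key=lambda i: (gaps[i], -i))
    threshold = (retained[best] + retained[best + 1]) / 2.0
    report = ThresholdReport(candidates, retained, gaps, threshold)
    return report if full_report else threshold
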
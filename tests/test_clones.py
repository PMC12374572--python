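import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonalarch.clones import (
    Linkage,
    assign_mlls,
    accumulation_curve,
    collapse_mlgs,
    genotype_distance,
    locus_distance,
    pairwise_mlg_distances,
    pgen,
    plain_freqs,
    predict_mll_threshold,
    psex,
    round_robin_freqs,
    AlleleFreqTable,
    MLGPartition,
)
from clonalarch.io import LocusGenotype
from clonalarch.simulate import preset, simulate_quadrat

from conftest import make_sample_set


class TestCollapseMLGs:
    def test_identical_genotypes_one_mlg(self):
        ss = make_sample_set([[(100, 102)] * 11, [(100, 102)] * 11])
        assert collapse_mlgs(ss).n_mlgs == 1

    def test_one_allele_difference_two_mlgs(self):
        g = [(100, 102)] * 11
        g2 = [(100, 102)] * 10 + [(100, 104)]
        ss = make_sample_set([g, g2])
        assert collapse_mlgs(ss).n_mlgs == 2

    def test_ids_dense_by_first_occurrence(self):
        ss = make_sample_set([[(1, 2)], [(3, 4)], [(1, 2)], [(5, 6)]])
        part = collapse_mlgs(ss)
        assert [part.mlg_of_sample[f"S{i}"] for i in (1, 2, 3, 4)] == [1, 2, 1, 3]

    def test_empty_set_error(self):
        ss = make_sample_set([[(1, 2)]])
        ss.records = []
        with pytest.raises(ValueError):
            collapse_mlgs(ss)

    def test_partition_is_equivalence(self):
        rng = np.random.default_rng(7)
        rows = [[tuple(sorted(rng.integers(101, 105, 2).tolist()))
                 for _ in range(3)] for _ in range(30)]
        ss = make_sample_set(rows)
        part = collapse_mlgs(ss)
        for a, b in itertools.combinations(ss.records, 2):
            same_geno = a.genotype == b.genotype
            same_mlg = part.mlg_of_sample[a.sample_id] == part.mlg_of_sample[b.sample_id]
            assert same_geno == same_mlg

    @pytest.mark.parametrize("seed", range(5))
    def test_simulator_truth_no_noise(self, seed):
        ss, truth = simulate_quadrat(preset("young"), seed)
        part = collapse_mlgs(ss)
        assert part.n_mlgs == len(set(truth.true_genet_of_sample.values()))


class TestAccumulationCurve:
    def test_single_locus_single_point(self):
        ss = make_sample_set([[(1, 2)], [(3, 4)], [(1, 2)]])
        curve = accumulation_curve(ss)
        assert curve.subset_sizes == [1]
        assert curve.counts[1] == [2]
        assert curve.plateau_k == 1

    def test_plateau_when_one_locus_separates(self):
        # locus 1 alone separates all three samples; loci 2-3 identical
        ss = make_sample_set([
            [(1, 2), (9, 9), (5, 5)],
            [(3, 4), (9, 9), (5, 5)],
            [(5, 6), (9, 9), (5, 5)],
        ])
        curve = accumulation_curve(ss)
        assert curve.plateau_k == 1
        assert max(curve.counts[1]) == 3

    def test_max_count_nondecreasing_and_full_at_L(self):
        ss, _ = simulate_quadrat(preset("young"), 3)
        curve = accumulation_curve(ss, max_exhaustive=50, rng_seed=1)
        maxes = [max(curve.counts[k]) for k in curve.subset_sizes]
        assert all(a <= b for a, b in zip(maxes, maxes[1:]))
        assert curve.counts[curve.subset_sizes[-1]] == [curve.n_mlgs_full]

    def test_sampled_mode_deterministic(self):
        ss, _ = simulate_quadrat(preset("young"), 4)
        c1 = accumulation_curve(ss, max_exhaustive=10, rng_seed=9)
        c2 = accumulation_curve(ss, max_exhaustive=10, rng_seed=9)
        assert c1.counts == c2.counts
        assert "sampled" in c1.enumeration_mode.values()


class TestRoundRobinFreqs:
    def test_hand_enumeration(self, two_locus_trio):
        # locus-2-only MLGs: {A, C} -> representative A, {B} -> B;
        # locus-1 alleles over A, B: 100 x4
        table = round_robin_freqs(two_locus_trio)
        assert table.freqs["L01"] == {100: 1.0}

    def test_single_clone_frequencies(self):
        ss = make_sample_set([[(1, 2), (5, 5)]] * 4)
        table = round_robin_freqs(ss)
        assert table.freqs["L01"] == {1: 0.5, 2: 0.5}
        assert table.freqs["L02"] == {5: 1.0}

    def test_single_locus_falls_back_to_plain(self):
        ss = make_sample_set([[(1, 2)], [(1, 1)]])
        with pytest.warns(UserWarning, match="round-robin"):
            table = round_robin_freqs(ss)
        assert table.estimation_mode == "plain"
        assert table.freqs["L01"] == {1: 0.75, 2: 0.25}

    def test_agrees_with_plain_when_all_unique_at_projections(self):
        # brute force: random genotypes where every leave-one-out projection
        # is still unique per sample -> every MLG has one sample
        rng = np.random.default_rng(11)
        rows = []
        seen = set()
        while len(rows) < 12:
            row = tuple(
                tuple(sorted(rng.integers(1, 50, 2).tolist())) for _ in range(4)
            )
            if row not in seen:
                seen.add(row)
                rows.append([tuple(g) for g in row])
        ss = make_sample_set(rows)
        L = 4
        projections_unique = all(
            len({tuple(r.genotype[j] for j in range(L) if j != i)
                 for r in ss.records}) == len(ss.records)
            for i in range(L)
        )
        if projections_unique:
            rr = round_robin_freqs(ss)
            pl = plain_freqs(ss)
            for locus in rr.loci:
                assert rr.freqs[locus] == pytest.approx(pl.freqs[locus])


class TestPgen:
    def test_homozygote_freq_one(self):
        freqs = AlleleFreqTable(("L1",), {"L1": {100: 1.0}}, "plain")
        assert pgen((LocusGenotype(100, 100),), freqs) == pytest.approx(1.0)

    def test_two_locus_hand_product(self):
        freqs = AlleleFreqTable(
            ("L1", "L2"),
            {"L1": {1: 0.5, 2: 0.5}, "L2": {9: 0.2, 8: 0.8}},
            "plain",
        )
        geno = (LocusGenotype(1, 2), LocusGenotype(9, 9))
        assert pgen(geno, freqs) == pytest.approx(2 * 0.5 * 0.5 * 0.2 * 0.2)

    def test_missing_allele_is_error(self):
        freqs = AlleleFreqTable(("L1",), {"L1": {100: 1.0}}, "plain")
        with pytest.raises(KeyError):
            pgen((LocusGenotype(102, 102),), freqs)

    def test_log_space_matches_arbitrary_precision(self):
        from fractions import Fraction

        rng = np.random.default_rng(3)
        for _ in range(30):
            L = int(rng.integers(1, 12))
            loci = tuple(f"L{i}" for i in range(L))
            freqs = {}
            geno = []
            exact = Fraction(1)
            for locus in loci:
                w = rng.integers(1, 20, size=4)
                tot = int(w.sum())
                table = {a: int(w[k]) for k, a in enumerate((10, 12, 14, 16))}
                freqs[locus] = {a: c / tot for a, c in table.items()}
                a, b = sorted(rng.choice((10, 12, 14, 16), 2).tolist())
                geno.append(LocusGenotype(int(a), int(b)))
                exact *= Fraction(table[a], tot) * Fraction(table[b], tot)
                if a != b:
                    exact *= 2
            got = pgen(tuple(geno), AlleleFreqTable(loci, freqs, "plain"))
            assert got == pytest.approx(float(exact), rel=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_in_unit_interval_and_decreasing_in_loci(self, seed):
        ss, _ = simulate_quadrat(preset("young"), seed)
        freqs = plain_freqs(ss)
        for rec in ss.records[:20]:
            p = pgen(rec.genotype, freqs)
            assert 0 < p <= 1
        # log P_gen weakly decreases as loci are added
        rec = ss.records[0]
        prev = 1.0
        for k in range(1, ss.panel.n_loci + 1):
            sub_freqs = AlleleFreqTable(
                freqs.loci[:k], {l: freqs.freqs[l] for l in freqs.loci[:k]}, "plain"
            )
            p = pgen(rec.genotype[:k], sub_freqs)
            assert p <= prev + 1e-15
            prev = p


class TestPsex:
    def test_zero_pgen(self):
        assert psex(0.0, 1, 10) == 0.0
        assert psex(0.0, 3, 10) == 0.0

    def test_enumerate_four_outcomes(self):
        # N=2, n=1, p=0.5: P(X>=1) = 3/4
        assert psex(0.5, 1, 2) == pytest.approx(0.75)

    def test_closed_form_n1(self):
        for p in (0.01, 0.2, 0.7):
            for N in (1, 5, 50):
                assert psex(p, 1, N) == pytest.approx(1 - (1 - p) ** N, rel=1e-12)

    def test_monte_carlo_oracle(self):
        N, n, p = 100, 3, 0.01
        rng = np.random.default_rng(12345)
        draws = rng.binomial(N, p, size=10**6)
        est = float(np.mean(draws >= n))
        se = math.sqrt(est * (1 - est) / 10**6)
        assert abs(psex(p, n, N) - est) <= 3 * se

    def test_n_greater_than_N_error(self):
        with pytest.raises(ValueError):
            psex(0.5, 3, 2)

    def test_conditional_convention(self):
        assert psex(0.3, 1, 5, convention="conditional") == 1.0
        # conditional tail: P(Bin(N-1, p) >= n-1)
        from scipy.stats import binom
        assert psex(0.3, 2, 5, convention="conditional") == pytest.approx(
            float(binom.sf(0, 4, 0.3))
        )


class TestDistances:
    def test_identical_zero(self):
        a = LocusGenotype(100, 102)
        assert locus_distance(a, a) == 0

    def test_one_allele_difference(self):
        assert locus_distance(LocusGenotype(100, 102), LocusGenotype(100, 104)) == 1

    def test_optimal_pairing_shares_allele(self):
        assert locus_distance(LocusGenotype(100, 102), LocusGenotype(102, 104)) == 1

    def test_exhaustive_pairing_oracle(self):
        # minimum over both pairings of mismatch indicators
        rng = np.random.default_rng(5)
        for _ in range(200):
            a1, a2, b1, b2 = rng.integers(1, 5, 4).tolist()
            a = LocusGenotype(a1, a2)
            b = LocusGenotype(b1, b2)
            direct = min(
                int(a1 != b1) + int(a2 != b2),
                int(a1 != b2) + int(a2 != b1),
            )
            assert locus_distance(a, b) == direct

    def test_matrix_symmetric_zero_diagonal(self):
        ss, _ = simulate_quadrat(preset("young"), 1)
        part = collapse_mlgs(ss)
        D = pairwise_mlg_distances(ss, part)
        assert (D == D.T).all()
        assert (np.diag(D) == 0).all()


class TestThresholdPrediction:
    def _matrix_with_candidates(self):
        # chain 0-1-2 at distances 1,2 then cluster 3-4-5 far away; constructed
        # so the single-sweep candidates are {1, 2, 8, 9, 10}
        D = np.array([
            [0, 1, 3, 10, 10, 10],
            [1, 0, 2, 10, 10, 10],
            [3, 2, 0, 8, 10, 10],
            [10, 10, 10, 0, 9, 10],
            [10, 10, 10, 9, 0, 10],
            [10, 10, 10, 10, 10, 0],
        ])
        return D

    def test_hand_sweep_example(self):
        D = self._matrix_with_candidates()
        rep = predict_mll_threshold(D, 0.5, Linkage.NEAREST, full_report=True)
        assert rep.candidates == [1.0, 2.0, 8.0, 9.0, 10.0]
        assert rep.retained == [1.0, 2.0, 8.0]
        assert rep.threshold == 5.0

    def test_all_distances_equal_returns_zero(self):
        D = np.full((4, 4), 3.0)
        np.fill_diagonal(D, 0.0)
        assert predict_mll_threshold(D) == 0.0

    def test_fewer_than_two_mlgs(self):
        assert predict_mll_threshold(np.zeros((1, 1))) == 0.0

    def test_separated_clusters_threshold_in_gap(self):
        # four founder clusters of mutant MLGs: within-cluster distances
        # <= 2, between-cluster >= 8 -> threshold must fall in the gap
        blocks = [(0, 1), (2, 3), (4, 5), (6, 7)]
        within = {0: 1, 1: 1, 2: 2, 3: 2}
        D = np.zeros((8, 8))
        for bi, members in enumerate(blocks):
            i, j = members
            D[i, j] = D[j, i] = within[bi]
        for bi in range(4):
            for bj in range(bi + 1, 4):
                for i in blocks[bi]:
                    for j in blocks[bj]:
                        D[i, j] = D[j, i] = 8 + bi + bj
        thr = predict_mll_threshold(D)
        assert 2 < thr < 8


class TestAssignMLLs:
    def test_threshold_zero_identity(self):
        ss = make_sample_set([[(1, 2)], [(3, 4)], [(5, 6)]])
        part = collapse_mlgs(ss)
        D = pairwise_mlg_distances(ss, part)
        mll = assign_mlls(part, D, 0)
        assert mll.n_genets == part.n_mlgs
        assert mll.genet_of_mlg == {1: 1, 2: 2, 3: 3}

    def test_hand_agglomeration_both_linkages(self):
        part = MLGPartition({"a": 1, "b": 2, "c": 3}, {1: (), 2: (), 3: ()}, ())
        D = np.array([[0, 1, 5], [1, 0, 1], [5, 1, 0]])
        far = assign_mlls(part, D, 1, Linkage.FARTHEST)
        assert far.genet_of_mlg == {1: 1, 2: 1, 3: 2}
        near = assign_mlls(part, D, 1, Linkage.NEAREST)
        assert near.genet_of_mlg == {1: 1, 2: 1, 3: 1}

    def test_count_non_increasing_in_threshold(self):
        ss, _ = simulate_quadrat(preset("young"), 2)
        part = collapse_mlgs(ss)
        D = pairwise_mlg_distances(ss, part)
        counts = [assign_mlls(part, D, t).n_genets for t in range(0, 25, 3)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_nearest_merges_at_least_as_much_as_farthest(self):
        rng = np.random.default_rng(8)
        n = 12
        D = np.zeros((n, n), dtype=int)
        iu = np.triu_indices(n, 1)
        vals = rng.integers(1, 15, size=len(iu[0]))
        D[iu] = vals
        D = D + D.T
        part = MLGPartition({str(i): i + 1 for i in range(n)},
                            {i + 1: () for i in range(n)}, ())
        for t in (0, 2, 5, 9):
            near = assign_mlls(part, D, t, Linkage.NEAREST).n_genets
            far = assign_mlls(part, D, t, Linkage.FARTHEST).n_genets
            assert near <= far

    @pytest.mark.parametrize("seed", range(5))
    def test_simulator_recovery_below_founder_distance(self, seed):
        from clonalarch.clones import genotype_distance

        ss, truth = simulate_quadrat(preset("young"), seed)
        part = collapse_mlgs(ss)
        D = pairwise_mlg_distances(ss, part)
        min_founder = min(
            genotype_distance(a, b)
            for a, b in itertools.combinations(truth.founder_genotypes, 2)
        )
        for t in (0, 1, min_founder - 1):
            mll = assign_mlls(part, D, t)
            assert mll.n_genets == truth.n_founders
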
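"""Polarization, SFS construction, diversity statistics and FST."""

import numpy as np
import pytest

from selectscan.popgen import (MISSING, VariantTable, build_sfs, complete_sites,
                               harmonic_number, hudson_fst, pairwise_pi,
                               polarize_sites, sliding_windows, tajima_d,
                               watterson_theta)


def _table(ref, alt, genotypes, outgroups):
    n_sites = len(genotypes)
    return VariantTable(
        chrom=np.array(["chr1"] * n_sites, dtype=object),
        pos=np.arange(n_sites, dtype=np.int64) * 10,
        ref=np.array(ref), alt=np.array(alt),
        genotypes=np.array(genotypes, dtype=np.int8),
        outgroup_alleles=np.array(outgroups, dtype="<U1"),
        samples=["s1", "s2"], outgroup_names=["og1", "og2"])


class TestPolarize:
    @pytest.mark.parametrize("outgroups,expect_folded,expect_count", [
        (["A", "A"], False, 3),   # unanimous ancestral A -> derived = G copies
        (["A", "G"], True, 1),    # outgroup disagreement -> folded minor count
        (["C", "C"], True, 1),    # third allele, matches neither -> folded
        (["N", "N"], True, 1),    # no outgroup information -> folded
        (["G", "N"], False, 1),   # single informative outgroup: ancestral G
    ])
    def test_parsimony_rules(self, outgroups, expect_folded, expect_count):
        # focal alleles {A, G}, ref=A alt=G, genotypes carry 3 G copies of 4
        vt = _table(["A"], ["G"], [[2, 1]], [outgroups])
        pol = polarize_sites(vt)
        assert bool(pol.folded[0]) is expect_folded
        assert pol.derived_count[0] == expect_count

    def test_ancestral_equals_alt_counts_reference_allele_as_derived(self):
        vt = _table(["A"], ["G"], [[2, 1]], [["G", "G"]])
        pol = polarize_sites(vt)
        assert not pol.folded[0]
        assert pol.derived_count[0] == 1  # A copies = 4 - 3

    def test_missing_genotypes_reduce_n_called(self):
        vt = _table(["A"], ["G"], [[MISSING, 1]], [["A", "A"]])
        pol = polarize_sites(vt)
        assert pol.n_called[0] == 2


class TestSfs:
    def test_tally(self):
        from tests.conftest import make_polarized
        sites = make_polarized([0, 10, 20], [1, 1, 3], n_called=[6, 6, 6])
        sfs = build_sfs(sites, 6)
        assert list(sfs.counts) == [2, 0, 1, 0, 0]

    def test_fold_pairs_j_with_n_minus_j(self):
        from tests.conftest import make_sfs
        sfs = make_sfs([2, 0, 0, 0, 1], 6)
        folded = sfs.fold()
        assert list(folded.counts) == [3, 0, 0]

    def test_folding_idempotent_and_commutes_with_tally(self, rng):
        from tests.conftest import make_polarized
        counts = rng.integers(1, 10, size=200)
        sites = make_polarized(np.arange(200) * 5, counts,
                               n_called=np.full(200, 10))
        direct = build_sfs(sites, 10, folded=True)
        via_unfolded = build_sfs(sites, 10).fold()
        np.testing.assert_array_equal(direct.counts, via_unfolded.counts)
        np.testing.assert_array_equal(direct.fold().counts, direct.counts)

    def test_neutral_spectrum_matches_one_over_j(self):
        """Neutral simulation SFS fits P(j) ~ 1/j (chi2 GOF, fixed seed)."""
        from scipy.stats import chisquare

        from selectscan.simulate import SimParams, simulate_genotypes
        # n=10 haploid, ~1e5 segregating sites on one chromosome
        p = SimParams(rng_seed=11, n_individuals=5, n_chromosomes=1,
                      chrom_length_bp=1_000_000, theta_per_bp=0.0354,
                      sweep_specs=[], polarization_error=0.0,
                      outgroup_divergence=0.0)
        vt, truth = simulate_genotypes(p)
        assert vt.n_sites > 80_000
        obs = np.bincount(truth["derived_count"], minlength=10)[1:10]
        w = 1.0 / np.arange(1, 10)
        exp = w / w.sum() * obs.sum()
        assert chisquare(obs, exp).pvalue > 0.01

    def test_empty_input_raises(self):
        from tests.conftest import make_polarized
        with pytest.raises(ValueError):
            build_sfs(make_polarized([], []), 6)


class TestWatterson:
    @pytest.mark.parametrize("S,n,L,expected", [
        (5, 2, 1000, 0.005),        # a1 = 1 at n = 2
        (0, 10, 1000, 0.0),
    ])
    def test_examples(self, S, n, L, expected):
        assert watterson_theta(S, n, L) == pytest.approx(expected)

    def test_against_direct_formula(self):
        a1 = sum(1.0 / i for i in range(1, 10))
        assert watterson_theta(16, 10, 10_000) == pytest.approx(
            16 / (a1 * 10_000), rel=1e-12)

    def test_rejects_single_sequence(self):
        with pytest.raises(ValueError):
            watterson_theta(5, 1, 1000)


class TestTajimaD:
    def test_singleton_excess_is_negative(self):
        assert tajima_d(np.ones(20, dtype=int), 10) < 0

    def test_zero_when_pi_equals_watterson(self):
        # n=4: 8 singletons + 3 doubletons gives pi = S/a1 = 6 exactly
        counts = np.array([1] * 8 + [2] * 3)
        assert tajima_d(counts, 4) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_below_two_sites(self):
        assert np.isnan(tajima_d(np.array([1]), 10))

    def test_matches_bruteforce_from_published_constants(self, rng):
        """Random genotype windows vs an independent re-derivation: pi by
        explicit pairwise haplotype comparisons, D from the 1989 constants."""
        n = 10
        for _ in range(100):
            S = rng.integers(2, 25)
            hap = np.zeros((S, n), dtype=int)
            for s in range(S):
                j = rng.integers(1, n)
                hap[s, rng.choice(n, size=j, replace=False)] = 1
            counts = hap.sum(axis=1)
            # brute force pi: average pairwise differences
            diffs = sum(np.sum(hap[:, i] != hap[:, j])
                        for i in range(n) for j in range(i + 1, n))
            pi = diffs / (n * (n - 1) / 2)
            a1 = sum(1 / i for i in range(1, n))
            a2 = sum(1 / i**2 for i in range(1, n))
            b1 = (n + 1) / (3 * (n - 1))
            b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
            c1 = b1 - 1 / a1
            c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
            e1, e2 = c1 / a1, c2 / (a1**2 + a2)
            expected = (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
            assert tajima_d(counts, n) == pytest.approx(expected, abs=1e-12)
            assert pairwise_pi(counts, n) == pytest.approx(pi, abs=1e-12)


class TestSlidingWindows:
    def _uniform_table(self, rng, L=100_000, n_sites=400):
        pos = np.sort(rng.choice(L, size=n_sites, replace=False))
        gt = np.zeros((n_sites, 5), dtype=np.int8)
        for i in range(n_sites):
            gt[i, rng.choice(5, size=rng.integers(1, 5), replace=False)] = 1
        return VariantTable(
            chrom=np.array(["chr1"] * n_sites, dtype=object), pos=pos,
            ref=np.array(["A"] * n_sites), alt=np.array(["G"] * n_sites),
            genotypes=gt,
            outgroup_alleles=np.empty((n_sites, 0), dtype="<U1"),
            samples=list("abcde"), outgroup_names=[])

    def test_window_tiling_and_partial_flags(self, rng):
        vt = self._uniform_table(rng)
        stats = sliding_windows(vt, {"chr1": 100_000}, 50_000, 10_000)
        assert [w.start for w in stats] == list(range(0, 100_000, 10_000))
        assert [w.partial for w in stats] == [False] * 6 + [True] * 4
        assert stats[-1].surveyed_bp == 10_000

    def test_each_site_counted_in_every_overlapping_window(self, rng):
        vt = self._uniform_table(rng)
        stats = sliding_windows(vt, {"chr1": 100_000}, 50_000, 10_000)
        for w in stats:
            expected = int(np.sum((vt.pos >= w.start) & (vt.pos < w.end)))
            assert w.S == expected

    def test_windowed_theta_is_stable_under_uniform_density(self, rng):
        vt = self._uniform_table(rng, L=500_000, n_sites=4000)
        stats = sliding_windows(vt, {"chr1": 500_000}, 50_000, 10_000)
        full = [w.theta_w for w in stats if not w.partial]
        assert np.std(full) / np.mean(full) < 0.3

    def test_sweep_depression_localizes_minimum(self):
        """Windowed theta_W bottoms out near an implanted sweep center."""
        from selectscan.simulate import SimParams, SweepSpec, simulate_genotypes
        p = SimParams(rng_seed=7, n_chromosomes=1, chrom_length_bp=1_000_000,
                      sweep_specs=[SweepSpec("chr1", 500_000, 1e-4)])
        vt, _ = simulate_genotypes(p)
        stats = sliding_windows(vt, {"chr1": 1_000_000})
        full = [w for w in stats if not w.partial]
        best = min(full, key=lambda w: w.theta_w)
        assert abs(best.start + 25_000 - 500_000) <= 50_000

    def test_strong_sweep_depresses_windowed_theta(self):
        """A wide-footprint (small alpha) sweep removes >80% of windowed
        diversity over its center: few lineages escape anywhere nearby."""
        from selectscan.simulate import SimParams, SweepSpec, simulate_genotypes
        p = SimParams(rng_seed=7, n_chromosomes=1, chrom_length_bp=1_000_000,
                      sweep_specs=[SweepSpec("chr1", 500_000, 5e-7)])
        vt, _ = simulate_genotypes(p)
        stats = sliding_windows(vt, {"chr1": 1_000_000})
        full = [w for w in stats if not w.partial]
        chrom_mean = np.mean([w.theta_w for w in full])
        over_center = [w.theta_w for w in full if w.start <= 500_000 < w.end]
        assert min(over_center) < 0.2 * chrom_mean


class TestHudsonFst:
    def test_identical_frequencies_give_near_zero(self, rng):
        g = rng.integers(0, 3, size=(50, 20)).astype(np.int8)
        _, overall = hudson_fst(g, g.copy())
        assert overall == pytest.approx(0.0, abs=1e-9) or overall < 0.01

    def test_fixed_difference_is_one(self):
        a = np.full((1, 10), 2, dtype=np.int8)
        b = np.zeros((1, 10), dtype=np.int8)
        per_site, overall = hudson_fst(a, b)
        assert per_site[0] == pytest.approx(1.0)
        assert overall == pytest.approx(1.0)

    def test_ratio_of_sums_matches_per_site_bruteforce(self, rng):
        ga = rng.integers(0, 3, size=(200, 15)).astype(np.int8)
        gb = rng.integers(0, 3, size=(200, 12)).astype(np.int8)
        per_site, overall = hudson_fst(ga, gb)
        num = den = 0.0
        for s in range(200):
            n1, n2 = 30, 24
            p1, p2 = ga[s].sum() / n1, gb[s].sum() / n2
            if (p1 == 0 and p2 == 0) or (p1 == 1 and p2 == 1):
                continue
            N = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) \
                - p2 * (1 - p2) / (n2 - 1)
            D = p1 * (1 - p2) + p2 * (1 - p1)
            num += N
            den += D
            assert per_site[s] == pytest.approx(N / D, abs=1e-12)
        assert overall == pytest.approx(num / den, abs=1e-12)

    def test_population_label_swap_invariance(self, rng):
        ga = rng.integers(0, 3, size=(100, 10)).astype(np.int8)
        gb = rng.integers(0, 3, size=(100, 10)).astype(np.int8)
        _, f1 = hudson_fst(ga, gb)
        _, f2 = hudson_fst(gb, ga)
        assert f1 == pytest.approx(f2, abs=1e-12)


class TestEstimatorCalibration:
    def test_theta_estimators_unbiased_on_neutral_data(self):
        """theta_W and pi recover the generator's theta within 5%."""
        from selectscan.simulate import SimParams, simulate_genotypes
        p = SimParams(rng_seed=3, n_individuals=10, n_chromosomes=1,
                      chrom_length_bp=250_000, theta_per_bp=0.004,
                      sweep_specs=[])
        vt, _ = simulate_genotypes(p)
        n = 20
        S = vt.n_sites
        theta_w = watterson_theta(S, n, 250_000)
        counts = vt.genotypes.sum(axis=1)
        pi = pairwise_pi(np.minimum(counts, n - counts), n) / 250_000
        assert theta_w == pytest.approx(0.004, rel=0.05)
        assert pi == pytest.approx(0.004, rel=0.05)

    def test_neutral_tajima_d_near_zero(self):
        """Mean windowed D on neutral equilibrium data in [-0.2, 0.1]."""
        from selectscan.simulate import SimParams, simulate_genotypes
        p = SimParams(rng_seed=5, n_chromosomes=1, chrom_length_bp=600_000,
                      sweep_specs=[])
        vt, _ = simulate_genotypes(p)
        stats = sliding_windows(vt, {"chr1": 600_000})
        ds = [w.tajima_d for w in stats if not w.partial]
        assert len(ds) >= 50
        assert -0.2 < np.mean(ds) < 0.1
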
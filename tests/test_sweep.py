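"""Composite-likelihood sweep scan: likelihood oracle, grid scan,
thresholding, merging and gene association."""

import math

import numpy as np
import pandas as pd
import pytest

from selectscan.config import RunConfig
from selectscan.genome import GeneModel
from selectscan.sweep import (associate_genes, background_log_likelihood,
                              clr_at_point, merge_targets, scan_chromosome,
                              sweep_log_likelihood, threshold_targets)
from tests.conftest import make_polarized, make_sfs

# ---------------------------------------------------------------------------
# exhaustive-summation oracle for the sweep site likelihood
# ---------------------------------------------------------------------------


def oracle_site_distribution(d, alpha, phi, n):
    """P(count | polymorphic) by full enumeration over j', k and the escapee
    count, using math.comb only (independent of the scipy-based code path)."""
    p_e = 1.0 - math.exp(-alpha * max(d, 1.0))
    mass = [0.0] * (n + 1)
    for jp in range(1, n):
        w_j = phi[jp - 1]
        for k in range(n + 1):
            w_k = math.comb(n, k) * p_e**k * (1 - p_e)**(n - k)
            if k == n:
                mass[jp] += w_j * w_k
                continue
            for x in range(max(0, k - (n - jp)), min(jp, k) + 1):
                hg = (math.comb(jp, x) * math.comb(n - jp, k - x)
                      / math.comb(n, k))
                p_src = (jp - x) / (n - k)
                mass[x] += w_j * w_k * hg * (1 - p_src)
                mass[x + n - k] += w_j * w_k * hg * p_src
    interior = mass[1:n]
    total = sum(interior)
    return [m / total for m in interior]


def oracle_loglik(alpha, sites, phi, n):
    ll = 0.0
    for d, count, folded in sites:
        p = oracle_site_distribution(d, alpha, phi, n)
        if folded:
            m = count
            pr = p[m - 1] + (p[n - m - 1] if m != n - m else 0.0)
        else:
            pr = p[count - 1]
        ll += math.log(pr)
    return ll


TOY_SITES = [(100, 1, False), (500, 3, False), (1200, 2, True),
             (4000, 1, True), (9000, 2, False)]
TOY_PHI = [0.5, 0.3, 0.2]   # 3-class background, n = 4


class TestSweepLikelihood:
    @pytest.mark.parametrize("alpha", [1e-5, 1e-3, 1e-1])
    def test_toy_matches_exhaustive_summation(self, alpha):
        """5-site, n=4 toy: l1(alpha) equals full enumeration to 1e-10."""
        n = 4
        background = make_sfs(np.array(TOY_PHI) * 100, n)
        d = np.array([s[0] for s in TOY_SITES], dtype=float)
        counts = np.array([s[1] for s in TOY_SITES])
        folded = np.array([s[2] for s in TOY_SITES])
        got = sweep_log_likelihood(alpha, d, counts, folded, background,
                                   pseudocount=0.0)
        phi = list(np.array(TOY_PHI))
        expected = oracle_loglik(alpha, TOY_SITES, phi, n)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_large_alpha_boundary_recovers_background(self):
        """With every lineage escaping, the alternative equals phi_bg."""
        n = 4
        background = make_sfs(np.array(TOY_PHI) * 100, n)
        d = np.array([25_000.0])
        for count in (1, 2, 3):
            l1 = sweep_log_likelihood(1.0, d, np.array([count]),
                                      np.array([False]), background,
                                      pseudocount=0.0)
            l0 = background_log_likelihood(np.array([count]),
                                           np.array([False]), background,
                                           pseudocount=0.0)
            assert l1 == pytest.approx(l0, abs=1e-9)

    def test_null_window_gives_zero_clr(self):
        """A window whose empirical SFS equals the background exactly."""
        counts = np.array([1] * 6 + [2] * 3 + [3] * 2)
        sites = make_polarized(np.arange(counts.size) * 997, counts,
                               n_called=np.full(counts.size, 4))
        background = make_sfs([6, 3, 2], 4)
        clr, _ = clr_at_point(5_000, sites, background)
        assert clr <= 1e-6

    def test_translation_invariance(self):
        counts = np.array([1, 3, 2, 1, 2, 3, 1])
        pos = np.array([10, 400, 900, 1500, 2200, 3000, 4000])
        background = make_sfs([5, 3, 2], 4)
        base = clr_at_point(2000, make_polarized(pos, counts,
                                                 n_called=np.full(7, 4)),
                            background)
        for shift in (1_000, 123_456):
            moved = clr_at_point(2000 + shift,
                                 make_polarized(pos + shift, counts,
                                                n_called=np.full(7, 4)),
                                 background)
            assert moved[0] == pytest.approx(base[0], abs=1e-9)
            assert moved[1] == pytest.approx(base[1], rel=1e-6)

    def test_empty_radius_returns_none(self):
        sites = make_polarized([1_000_000], [2], n_called=[4])
        background = make_sfs([5, 3, 2], 4)
        assert clr_at_point(0, sites, background) is None


class TestScanChromosome:
    def test_one_target_per_grid_point(self, rng):
        pos = np.sort(rng.choice(10_000, size=200, replace=False))
        counts = rng.integers(1, 4, size=200)
        sites = make_polarized(pos, counts, n_called=np.full(200, 4))
        background = make_sfs([5, 3, 2], 4)
        targets = scan_chromosome(sites, background, chrom_length=10_000)
        assert len(targets) == 100
        assert list(targets["grid_pos"]) == list(range(0, 10_000, 100))
        assert (targets["clr"] >= 0).all()

    def test_site_order_invariance(self, rng):
        pos = np.sort(rng.choice(10_000, size=100, replace=False))
        counts = rng.integers(1, 4, size=100)
        sites = make_polarized(pos, counts, n_called=np.full(100, 4))
        background = make_sfs([5, 3, 2], 4)
        perm = rng.permutation(100)
        shuffled = make_polarized(pos[perm], counts[perm],
                                  n_called=np.full(100, 4))
        a = scan_chromosome(sites, background, chrom_length=10_000)
        b = scan_chromosome(shuffled, background, chrom_length=10_000)
        pd.testing.assert_frame_equal(a, b)

    def test_binned_scan_tracks_exact_point_likelihood(self, rng):
        """The lattice/binned fast path stays close to the golden-section
        exact path on the same data."""
        pos = np.sort(rng.choice(50_000, size=500, replace=False))
        counts = rng.integers(1, 6, size=500)
        sites = make_polarized(pos, counts, n_called=np.full(500, 6))
        background = make_sfs(np.bincount(counts, minlength=6)[1:6], 6)
        targets = scan_chromosome(sites, background, chrom_length=50_000)
        sample = targets.iloc[::50]
        for _, row in sample.iterrows():
            exact = clr_at_point(int(row["grid_pos"]), sites, background)
            assert row["clr"] == pytest.approx(exact[0], abs=0.6 + 0.1 * exact[0])


class TestThreshold:
    def test_exactly_top_k_with_distinct_scores(self, rng):
        df = pd.DataFrame({"chrom": "chr1",
                           "grid_pos": np.arange(1000) * 100,
                           "clr": rng.permutation(1000).astype(float),
                           "alpha_hat": 1e-4})
        sel = threshold_targets(df, 0.01)
        assert len(sel) == 10
        assert sel["clr"].min() >= 990

    def test_all_ties_retained(self):
        df = pd.DataFrame({"chrom": "chr1", "grid_pos": np.arange(50) * 100,
                           "clr": 7.0, "alpha_hat": 1e-4})
        assert len(threshold_targets(df, 0.01)) == 50

    def test_selected_fraction_on_large_mixed_scores(self, rng):
        # half zeros (floored CLRs), half positive, like a neutral scan
        clr = np.concatenate([np.zeros(50_000),
                              rng.exponential(1.0, size=50_000)])
        df = pd.DataFrame({"chrom": "chr1",
                           "grid_pos": np.arange(100_000) * 100,
                           "clr": clr, "alpha_hat": 1e-4})
        frac = len(threshold_targets(df, 0.01)) / 100_000
        assert 0.009 <= frac <= 0.012


class TestMergeAndAssociate:
    def test_adjacent_targets_merge_with_summed_score(self):
        df = pd.DataFrame({"chrom": "chr1", "grid_pos": [100, 200, 300],
                           "clr": [5.0, 6.0, 7.0], "alpha_hat": 1e-4})
        regions = merge_targets(df, 100)
        assert len(regions) == 1
        r = regions.iloc[0]
        assert (r["start"], r["end"]) == (100, 400)
        assert r["summed_clr"] == pytest.approx(18.0)
        assert r["n_targets"] == 3

    def test_gap_splits_regions(self):
        df = pd.DataFrame({"chrom": "chr1", "grid_pos": [100, 300],
                           "clr": [5.0, 6.0], "alpha_hat": 1e-4})
        regions = merge_targets(df, 100)
        assert len(regions) == 2
        assert list(regions["end"] - regions["start"]) == [100, 100]

    def test_empty_selection(self):
        assert len(merge_targets(pd.DataFrame(
            columns=["chrom", "grid_pos", "clr", "alpha_hat"]))) == 0

    def test_flanked_gene_association_example(self):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [13_000],
                                "end": [14_000], "summed_clr": [9.0],
                                "n_targets": [10]})
        genes = [GeneModel("g1", "chr1", 10_000, 12_000, "+")]
        table = associate_genes(regions, genes)
        assert list(table["gene_id"]) == ["g1"]
        assert table.iloc[0]["score"] == pytest.approx(9.0)

    def test_region_of_exactly_min_size_excluded(self):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [10_500],
                                "end": [10_800], "summed_clr": [9.0],
                                "n_targets": [3]})
        genes = [GeneModel("g1", "chr1", 10_000, 12_000, "+")]
        assert len(associate_genes(regions, genes)) == 0

    @staticmethod
    def _naive_merge(rows, grid, max_gap):
        rows = sorted(rows, key=lambda r: (r[0], r[1]))
        regions = []
        for chrom, pos, clr in rows:
            if regions and regions[-1][0] == chrom \
                    and pos - regions[-1][2] <= max_gap * grid:
                regions[-1][2] = pos
                regions[-1][3] += clr
                regions[-1][4] += 1
            else:
                regions.append([chrom, pos, pos, clr, 1])
        return [(c, s, e + grid, score, k) for c, s, e, score, k in regions]

    @staticmethod
    def _naive_associate(regions, genes, flank, min_region, top_fraction):
        scored = {}
        for gene in genes:
            best, hits = None, 0
            for chrom, s, e, score, _ in regions:
                if e - s <= min_region or chrom != gene.chrom:
                    continue
                if gene.start < e + flank and s - flank < gene.end:
                    hits += 1
                    best = score if best is None else max(best, score)
            if best is not None:
                scored[gene.gene_id] = (best, hits)
        k = max(1, math.ceil(top_fraction * len(genes)))
        ranked = sorted(scored.items(), key=lambda kv: -kv[1][0])
        selected = set()
        if ranked:
            if len(ranked) <= k:
                selected = {g for g, _ in ranked}
            else:
                cutoff = ranked[k - 1][1][0]
                selected = {g for g, (sc, _) in ranked if sc >= cutoff}
        return scored, selected

    def test_merge_and_associate_match_naive_oracle(self, rng):
        """1000 random target/gene configurations, exact agreement,
        including strict >300 bp and flank boundary cases."""
        cfg = RunConfig()
        for trial in range(1000):
            grid = 100
            n_t = rng.integers(1, 30)
            rows = set()
            while len(rows) < n_t:
                chrom = f"chr{rng.integers(1, 3)}"
                pos = int(rng.integers(0, 80)) * grid
                rows.add((chrom, pos))
            rows = [(c, p, float(rng.integers(1, 50))) for c, p in rows]
            df = pd.DataFrame(rows, columns=["chrom", "grid_pos", "clr"])
            df["alpha_hat"] = 1e-4
            regions = merge_targets(df, grid)
            naive = self._naive_merge(rows, grid, 1)
            got = sorted(map(tuple, regions[
                ["chrom", "start", "end", "summed_clr", "n_targets"]].values))
            assert got == sorted(naive)

            genes = [GeneModel(f"g{i}", f"chr{rng.integers(1, 3)}",
                               int(s), int(s) + int(rng.integers(100, 4000)),
                               "+")
                     for i, s in enumerate(rng.integers(0, 9000, size=5))]
            table = associate_genes(regions, genes, cfg)
            scored, selected = self._naive_associate(
                naive, genes, cfg.gene_flank_bp, cfg.min_region_bp,
                cfg.gene_top_fraction)
            assert set(table["gene_id"]) == set(scored)
            for _, row in table.iterrows():
                exp_score, exp_hits = scored[row["gene_id"]]
                assert row["score"] == pytest.approx(exp_score)
                assert row["n_regions"] == exp_hits
                assert bool(row["selected"]) == (row["gene_id"] in selected)
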
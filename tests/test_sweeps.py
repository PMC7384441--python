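"""Windowed diversity statistics and sweep calling."""

import numpy as np
import pandas as pd
import pytest

import sweepmap as sm
from sweepmap.io import GeneModel
from sweepmap.sweeps import _tajima_constants, _wc_components, tajima_d

from conftest import make_genotypes, random_genotypes


def wc_oracle(da, db):
    """Independent scalar transcription of the two-population variance
    components for one biallelic site of diploid genotypes."""
    stats = []
    for d in (da, db):
        d = d[~np.isnan(d)]
        n = d.size
        p = d.sum() / (2 * n)
        h = np.mean(d == 1)
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


def hamming_pi_oracle(dosage_block, length):
    """All-pairs mean pairwise difference per bp for complete haploid-coded
    (0/2) dosage data, counting each diploid as two identical sequences."""
    haps = []
    for row in dosage_block:
        h = (row / 2).astype(int)
        haps.append(h)
        haps.append(h.copy())
    haps = np.array(haps)
    n = haps.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += np.sum(haps[i] != haps[j])
    return total / (n * (n - 1) / 2) / length


class TestWindowPi:
    def test_monomorphic_window_zero(self):
        g = make_genotypes(np.zeros((6, 4)))
        stats = sm.window_stats(g, size=1000)
        assert stats.pi_A.iloc[0] == 0.0
        assert stats.pi_B.iloc[0] == 0.0

    def test_single_site_worked_example(self):
        # one SNP, 4 haploid-coded samples: alleles (0,0,1,1), p=0.5, n=8...
        # restrict to a 4-sample group: n=8 alleles counting diploids;
        # haploid-coded value: dosages (0,0,2,2) give p=0.5, n=8 alleles
        dose = np.array([[0.0], [0.0], [2.0], [2.0]])
        g = make_genotypes(dose, groups=["A"] * 4, pos=np.array([50]))
        stats = sm.window_stats(g, windows=pd.DataFrame({"chrom": [1], "start": [1], "end": [100]}))
        # (n/(n-1)) 2p(1-p) / L with n=8: (8/7)*0.5/100
        assert stats.pi_A.iloc[0] == pytest.approx((8 / 7) * 0.5 / 100)

    def test_window_split_additivity(self, rng):
        g = random_genotypes(rng, n=10, m=40)
        whole = pd.DataFrame({"chrom": [1], "start": [1], "end": [4000]})
        halves = pd.DataFrame({"chrom": [1, 1], "start": [1, 2001], "end": [2000, 4000]})
        s1 = sm.window_stats(g, windows=whole)
        s2 = sm.window_stats(g, windows=halves)
        total_whole = s1.pi_A.iloc[0] * 4000
        total_halves = (s2.pi_A * 2000).sum()
        assert total_whole == pytest.approx(total_halves, rel=1e-12)

    def test_matches_all_pairs_hamming_oracle(self, rng):
        """Window pi equals mean pairwise Hamming distance per bp on
        complete haploid-coded data (100 random instances)."""
        for _ in range(100):
            n, m = int(rng.integers(4, 10)), int(rng.integers(2, 12))
            dose = (rng.random((n, m)) < rng.uniform(0.2, 0.8)).astype(float) * 2
            length = int(rng.integers(m * 10, 5000))
            g = make_genotypes(dose, groups=["A"] * n,
                               pos=np.sort(rng.choice(np.arange(1, length), m, replace=False)))
            win = pd.DataFrame({"chrom": [1], "start": [1], "end": [length]})
            stats = sm.window_stats(g, windows=win)
            # diploid coding doubles each haplotype: (2n/(2n-1)) correction in
            # the estimator matches the all-pairs average over 2n sequences
            assert stats.pi_A.iloc[0] == pytest.approx(
                hamming_pi_oracle(dose, length), rel=1e-9
            )


class TestWindowFst:
    def test_identical_pools_near_zero(self, rng):
        # both groups drawn from one pool: Fst within sampling noise of the
        # permutation null
        dose = (rng.random((100, 500)) < 0.4).astype(float) * 2
        g = make_genotypes(dose, groups=["A"] * 50 + ["B"] * 50,
                           pos=np.arange(1, 501) * 10)
        stats = sm.window_stats(g, windows=pd.DataFrame({"chrom": [1], "start": [1], "end": [5010]}))
        assert abs(stats.fst.iloc[0]) < 0.02

    def test_fixed_differences_give_one(self):
        dose = np.vstack([np.zeros((5, 20)), np.full((5, 20), 2.0)])
        g = make_genotypes(dose, groups=["A"] * 5 + ["B"] * 5)
        stats = sm.window_stats(g, windows=pd.DataFrame({"chrom": [1], "start": [1], "end": [2100]}))
        assert stats.fst.iloc[0] == pytest.approx(1.0)

    def test_components_match_direct_transcription(self, rng):
        """Vectorized W&C components equal an independent per-site scalar
        transcription to 1e-12 (100 random sites, with hets and missing)."""
        for _ in range(100):
            na, nb = int(rng.integers(3, 15)), int(rng.integers(3, 15))
            da = rng.choice([0.0, 1.0, 2.0], size=na)
            db = rng.choice([0.0, 1.0, 2.0], size=nb)
            if np.all(da == da[0]) and np.all(db == db[0]) and da[0] == db[0]:
                da[0] = 2.0 - da[0]
            a, b, c = _wc_components(da[:, None], db[:, None])
            ao, bo, co = wc_oracle(da, db)
            assert a[0] == pytest.approx(ao, abs=1e-12)
            assert b[0] == pytest.approx(bo, abs=1e-12)
            assert c[0] == pytest.approx(co, abs=1e-12)

    def test_group_swap_invariance(self, rng):
        g = random_genotypes(rng, n=20, m=60)
        swapped = make_genotypes(
            g.dosage, groups=["B" if x == "A" else "A" for x in g.group], pos=g.pos
        )
        s1 = sm.window_stats(g, size=100_000)
        s2 = sm.window_stats(swapped, size=100_000)
        np.testing.assert_allclose(s1.fst, s2.fst, atol=1e-12)
        np.testing.assert_allclose(s1.pi_ratio, 1.0 / s2.pi_ratio, rtol=1e-9)


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        assert np.isnan(tajima_d(0.0, 0, 20))

    def test_zero_numerator_by_construction(self):
        n = 10
        k = _tajima_constants(n)
        s = 5
        assert tajima_d(s / k["a1"], s, n) == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_constants_derivation(self, rng):
        """D agrees with a second implementation that derives the Tajima
        normalization from scratch (random 20-sequence, 30-site windows)."""
        def oracle_d(pi_sum, s, n):
            a1 = sum(1.0 / i for i in range(1, n))
            a2 = sum(1.0 / i**2 for i in range(1, n))
            b1 = (n + 1) / (3 * (n - 1))
            b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
            c1 = b1 - 1 / a1
            c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
            e1 = c1 / a1
            e2 = c2 / (a1**2 + a2)
            return (pi_sum - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))

        for _ in range(100):
            n_seq = 20
            haps = (rng.random((n_seq, 30)) < rng.uniform(0.1, 0.9)).astype(int)
            p = haps.mean(axis=0)
            seg = (p > 0) & (p < 1)
            s = int(seg.sum())
            if s == 0:
                continue
            nn = float(n_seq)
            pi_sum = float(np.sum(nn / (nn - 1) * 2 * p[seg] * (1 - p[seg])))
            assert tajima_d(pi_sum, s, n_seq) == pytest.approx(
                oracle_d(pi_sum, s, n_seq), rel=1e-12
            )


class TestCallSweeps:
    @staticmethod
    def _stats_frame(pi_ratio, fst, n=10):
        k = len(pi_ratio)
        return pd.DataFrame(
            {"chrom": [1] * k, "start": np.arange(k) * 100_000 + 1,
             "end": (np.arange(k) + 1) * 100_000,
             "n_snps_A": [n] * k, "n_snps_B": [n] * k,
             "pi_A": [1e-4] * k, "pi_B": [1e-4] * k,
             "pi_ratio": pi_ratio, "fst": fst,
             "tajd_A": [0.0] * k, "tajd_B": [0.0] * k}
        )

    def test_single_extreme_window_called(self):
        ratio = [1.0] * 9 + [0.01]
        fst = [0.1] * 9 + [0.9]
        flagged, regions = sm.call_sweeps(self._stats_frame(ratio, fst), tail=0.10)
        assert flagged.swept_A.sum() == 1
        assert flagged.swept_B.sum() == 0
        assert len(regions) == 1
        assert regions.group.iloc[0] == "A"

    def test_identical_stats_yield_no_regions(self):
        flagged, regions = sm.call_sweeps(self._stats_frame([1.0] * 20, [0.2] * 20))
        assert flagged.swept_A.sum() == 0
        assert flagged.swept_B.sum() == 0
        assert regions.empty

    def test_flag_counts_bounded_by_tail(self, rng):
        ratio = rng.uniform(0.2, 5.0, size=200)
        fst = rng.uniform(0, 0.8, size=200)
        flagged, _ = sm.call_sweeps(self._stats_frame(ratio, fst), tail=0.10)
        # each rule intersects two 10% tails; ties can only add at threshold
        assert flagged.swept_A.sum() <= 0.10 * 200 + 1
        assert flagged.swept_B.sum() <= 0.10 * 200 + 1

    def test_adjacent_windows_merge_and_genes_attach(self):
        ratio = [0.01, 0.02] + [1.0] * 18
        fst = [0.9, 0.85] + [0.1] * 18
        genes = [GeneModel("gX", 1, 50_000, 120_000)]
        flagged, regions = sm.call_sweeps(self._stats_frame(ratio, fst), genes=genes)
        assert len(regions) == 1
        assert regions.n_windows.iloc[0] == 2
        assert regions.start.iloc[0] == 1 and regions.end.iloc[0] == 200_000
        assert regions.genes.iloc[0] == "gX"

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="eligible"):
            sm.call_sweeps(self._stats_frame([1.0] * 5, [0.1] * 5), tail=0.10)

    def test_low_snp_windows_leave_quantile_pool(self):
        frame = self._stats_frame([1.0] * 19 + [0.01], [0.1] * 19 + [0.9])
        frame.loc[19, "n_snps_A"] = 1  # unstable window: excluded
        flagged, _ = sm.call_sweeps(frame, tail=0.10)
        assert not flagged.swept_A.iloc[19]
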
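"""Kinship, P+K mixed-model scan, region building, haplotype grouping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import sweepmap as sm
from sweepmap.io import GeneModel

from conftest import make_genotypes, random_genotypes


def phen_frame(samples, values, trait="EL", env="E1"):
    return pd.DataFrame(
        {"sample_id": samples, "environment": env, "trait": trait,
         "replicate": 1, "value": values}
    )


class TestKinship:
    def test_duplicated_sample_rows_identical(self, rng):
        g = random_genotypes(rng, n=8, m=60)
        g.dosage[1] = g.dosage[0]
        k = sm.compute_kinship(g)
        np.testing.assert_allclose(k.iloc[0], k.iloc[1], atol=1e-12)
        off = k.iloc[0].drop(index=[g.samples[0], g.samples[1]])
        assert k.iloc[0, 1] > off.max()

    def test_symmetric_positive_trace(self, rng):
        g = random_genotypes(rng, n=10, m=80, missing=0.1)
        k = sm.compute_kinship(g).to_numpy()
        np.testing.assert_allclose(k, k.T, atol=1e-12)
        assert np.trace(k) > 0

    def test_mean_diagonal_near_one_unstructured(self, rng):
        # VanRaden scaling: average self-relatedness ~ 1 in an unstructured
        # population (HW-ish dosages)
        m = 2000
        p = rng.uniform(0.1, 0.9, size=m)
        dose = rng.binomial(2, p, size=(60, m)).astype(float)
        g = make_genotypes(dose, pos=np.arange(1, m + 1) * 10)
        k = sm.compute_kinship(g).to_numpy()
        assert np.mean(np.diag(k)) == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_only_rejected(self):
        g = make_genotypes(np.full((4, 5), 2.0))
        with pytest.raises(ValueError):
            sm.compute_kinship(g)


class TestMixedModelScan:
    def test_identity_kinship_equals_ols(self, rng):
        """With K = I and no PCs the scan reduces to per-SNP ordinary least
        squares (beta and p to 1e-8; >= 100 SNPs)."""
        g = random_genotypes(rng, n=40, m=120)
        y = pd.Series(rng.normal(size=40), index=g.samples)
        kin = pd.DataFrame(np.eye(40), index=g.samples, columns=g.samples)
        res = sm.mixed_model_scan(g, y, kin, n_pcs=0)
        assert len(res) >= 100
        checked = 0
        for rec in res.itertuples(index=False):
            j = int(np.flatnonzero((g.chrom == rec.chrom) & (g.pos == rec.pos))[0])
            x = g.dosage[:, j]
            slope, _i, _r, p, _se = sps.linregress(x, y.to_numpy())
            assert rec.beta == pytest.approx(slope, abs=1e-8)
            assert rec.p_value == pytest.approx(p, abs=1e-8)
            checked += 1
        assert checked == len(res)

    def test_p_values_invariant_to_affine_phenotype_rescaling(self, rng):
        g = random_genotypes(rng, n=30, m=50)
        y = pd.Series(rng.normal(size=30), index=g.samples)
        kin = sm.compute_kinship(g)
        p1 = sm.mixed_model_scan(g, y, kin, n_pcs=2)["p_value"]
        p2 = sm.mixed_model_scan(g, 3.5 * y + 11.0, kin, n_pcs=2)["p_value"]
        np.testing.assert_allclose(p1, p2, rtol=1e-6)

    def test_permuted_phenotype_loses_planted_signal(self, rng):
        from sweepmap.simulate import SimConfig

        cfg = SimConfig(n_a=30, n_b=60, census_factor=3, n_snps=600, n_chrom=6,
                        chrom_len=2_000_000, qtl=[(1, 1_000_000, 1.0, "EL")],
                        h2_target=0.6, seed=42)
        g = sm.simulate_populations(cfg)
        phen = sm.simulate_phenotypes(g, cfg)
        y = sm.entry_means(phen, "EL", "E1")
        kin = sm.compute_kinship(g)
        res = sm.mixed_model_scan(g, y, kin, n_pcs=3)
        qtl_p = float(res.loc[(res.chrom == 1) & (res.pos == 1_000_000), "p_value"].iloc[0])
        assert qtl_p <= 1e-3  # signal present before permutation
        lost = 0
        n_perm = 20
        for i in range(n_perm):
            perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            pres = sm.mixed_model_scan(g, perm, kin, n_pcs=3)
            pp = float(pres.loc[(pres.chrom == 1) & (pres.pos == 1_000_000), "p_value"].iloc[0])
            lost += pp > 1e-3
        assert lost >= 0.95 * n_perm

    def test_monomorphic_snps_absent(self, rng):
        g = random_genotypes(rng, n=20, m=30)
        g.dosage[:, 5] = 2.0
        y = pd.Series(rng.normal(size=20), index=g.samples)
        kin = pd.DataFrame(np.eye(20), index=g.samples, columns=g.samples)
        res = sm.mixed_model_scan(g, y, kin, n_pcs=0)
        assert f"1_{g.pos[5]}" not in set(res.snp_id)


class TestSignificantSnps:
    def test_boundary_inclusive_and_empty(self):
        res = pd.DataFrame({"snp_id": ["a", "b"], "p_value": [1e-3, 1.1e-3]})
        kept = sm.significant_snps(res, alpha=1e-3)
        assert list(kept.snp_id) == ["a"]
        assert sm.significant_snps(res.iloc[0:0], alpha=1e-3).empty

    def test_null_retention_matches_binomial_expectation(self, rng):
        # uniform p-values at alpha=1e-3: mean retained ~ n*alpha
        total = 0
        reps, n = 1000, 100
        for _ in range(reps):
            res = pd.DataFrame({"snp_id": np.arange(n).astype(str),
                                "p_value": rng.random(n)})
            total += len(sm.significant_snps(res, alpha=1e-3))
        mean = total / reps
        se = np.sqrt(n * 1e-3 * (1 - 1e-3) / reps)
        assert abs(mean - n * 1e-3) < 3 * se + 1e-6


class TestBuildRegions:
    def test_single_snp_flanks(self):
        snps = pd.DataFrame(
            {"snp_id": ["1_1000000"], "chrom": [1], "pos": [1_000_000],
             "trait": ["EL"], "environment": ["E1"], "p_value": [1e-4]}
        )
        out = sm.build_regions(snps, genes=[], flank=150_000)
        assert out.start.iloc[0] == 850_000
        assert out.end.iloc[0] == 1_150_000

    def test_clustered_snps_merge_to_one_region(self):
        snps = pd.DataFrame(
            {"snp_id": [f"1_{p}" for p in (1_000_000, 1_000_030, 1_000_060)],
             "chrom": [1] * 3, "pos": [1_000_000, 1_000_030, 1_000_060],
             "trait": ["EL"] * 3, "environment": ["E1"] * 3, "p_value": [1e-4] * 3}
        )
        out = sm.build_regions(snps, genes=[], flank=150_000)
        assert len(out) == 1
        assert out.start.iloc[0] == 850_000
        assert out.end.iloc[0] == 1_150_060

    def test_flank_floored_at_one(self):
        snps = pd.DataFrame(
            {"snp_id": ["1_1000"], "chrom": [1], "pos": [1000],
             "trait": ["EL"], "environment": ["E1"], "p_value": [1e-4]}
        )
        out = sm.build_regions(snps, genes=[], flank=150_000)
        assert out.start.iloc[0] == 1

    def test_gene_sharing_merges_disjoint_intervals(self):
        # intervals don't overlap but a gene spans the gap between them
        genes = [GeneModel("bridge", 1, 1_050_000, 1_450_000)]
        snps = pd.DataFrame(
            {"snp_id": ["1_1000000", "1_1500000"], "chrom": [1, 1],
             "pos": [1_000_000, 1_500_000], "trait": ["EL"] * 2,
             "environment": ["E1"] * 2, "p_value": [1e-4, 2e-4]}
        )
        out = sm.build_regions(snps, genes, flank=100_000)
        assert len(out) == 1
        assert out.genes.iloc[0] == "bridge"

    def test_matches_bruteforce_transitive_closure(self, rng):
        """Union-find merging equals all-pairs closure on random layouts."""
        for _ in range(25):
            n_snp = int(rng.integers(3, 12))
            pos = np.sort(rng.choice(np.arange(10_000, 3_000_000, 7), n_snp, replace=False))
            genes = [
                GeneModel(f"g{i}", 1, int(s), int(s + rng.integers(1000, 400_000)))
                for i, s in enumerate(rng.integers(1, 3_000_000, size=15))
            ]
            snps = pd.DataFrame(
                {"snp_id": [f"1_{p}" for p in pos], "chrom": 1, "pos": pos,
                 "trait": "EL", "environment": "E1", "p_value": 1e-4}
            )
            flank = 80_000
            out = sm.build_regions(snps, genes, flank=flank)

            # oracle: iterate pairwise merging until fixed point
            items = []
            for p in pos:
                s, e = max(1, p - flank), p + flank
                items.append([s, e, set(sm.genes_in_interval(genes, 1, s, e)), {f"1_{p}"}])
            changed = True
            while changed:
                changed = False
                for i in range(len(items)):
                    for j in range(i + 1, len(items)):
                        a, b = items[i], items[j]
                        if a[0] <= b[1] and b[0] <= a[1] or (a[2] & b[2]):
                            items[i] = [min(a[0], b[0]), max(a[1], b[1]), a[2] | b[2], a[3] | b[3]]
                            del items[j]
                            changed = True
                            break
                    if changed:
                        break
            expect = sorted((it[0], it[1], frozenset(it[3])) for it in items)
            got = sorted(
                (r.start, r.end, frozenset(r.member_snps.split(",")))
                for r in out.itertuples(index=False)
            )
            assert got == expect

    def test_output_regions_pairwise_non_mergeable(self, rng):
        pos = np.sort(rng.choice(np.arange(10_000, 2_000_000), 10, replace=False))
        snps = pd.DataFrame(
            {"snp_id": [f"1_{p}" for p in pos], "chrom": 1, "pos": pos,
             "trait": "EL", "environment": "E1", "p_value": 1e-4}
        )
        out = sm.build_regions(snps, genes=[], flank=120_000)
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                a, b = out.iloc[i], out.iloc[j]
                assert not (a.start <= b.end and b.start <= a.end)


class TestHaplotypeGroups:
    @staticmethod
    def _carrier_panel(n_b_hap1=91, n_b=95, n_a_hap2=10, n_a=26):
        """Panel shaped like the study's three co-localized SNPs: haplotype 1
        all-ref (GGG with G as ref), haplotype 2 all-alt."""
        n = n_a + n_b
        dose = np.zeros((n, 3))
        # group A first: n_a_hap2 of them carry the alt haplotype
        dose[:n_a_hap2, :] = 2.0
        # group B: the last (n_b - n_b_hap1) carry alt
        dose[n_a + n_b_hap1 :, :] = 2.0
        groups = ["A"] * n_a + ["B"] * n_b
        return make_genotypes(dose, groups=groups, ref=["G"] * 3, alt=["A"] * 3)

    def test_study_scale_percentages(self):
        g = self._carrier_panel()
        out = sm.haplotype_groups(g, [f"1_{p}" for p in g.pos])
        table = {(r.haplotype, r.group): (r.n, r.pct) for r in out.itertuples(index=False)}
        assert table[("GGG", "B")] == (91, 95.79)
        assert table[("AAA", "A")] == (10, 38.46)

    def test_all_homozygous_ref_single_haplotype(self):
        g = make_genotypes(np.zeros((6, 1)), ref=["T"], alt=["C"])
        out = sm.haplotype_groups(g, [f"1_{g.pos[0]}"])
        assert set(out.haplotype) == {"T"}
        assert out.pct.sum() == pytest.approx(200.0)  # 100% in each group

    def test_heterozygous_samples_excluded(self):
        dose = np.array([[0.0], [1.0], [2.0], [0.0]])
        g = make_genotypes(dose, groups=["A", "A", "B", "B"], ref=["G"], alt=["A"])
        out = sm.haplotype_groups(g, [f"1_{g.pos[0]}"])
        assert out.n.sum() == 3  # the het is gone

    def test_unknown_snp_named(self, rng):
        g = random_genotypes(rng, n=4, m=3)
        with pytest.raises(KeyError, match="1_999"):
            sm.haplotype_groups(g, ["1_999"])

    def test_trait_means_attached(self):
        g = self._carrier_panel(n_b_hap1=3, n_b=4, n_a_hap2=1, n_a=2)
        phen = phen_frame(g.samples, np.arange(len(g.samples), dtype=float))
        out = sm.haplotype_groups(g, [f"1_{p}" for p in g.pos], phen=phen, traits=["EL"])
        assert "mean_EL" in out.columns
        assert out["mean_EL"].notna().all()
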
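from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpforge import popgen as pg
from snpforge import synthetic_data as sd
from snpforge.matrix import NO_CALL

from .conftest import make_matrix
from .oracles import wc_f_multi, wc_f_single, wc_locus_components, wc_theta


def loci_to_matrix(loci):
    """Convert oracle-style nested genotype lists into a GenotypeMatrix."""
    pops = {}
    n_pops = len(loci[0])
    calls = {}
    sample = 0
    for ip in range(n_pops):
        for ii in range(len(loci[0][ip])):
            sid = f"s{sample}"
            calls[sid] = [locus[ip][ii] for locus in loci]
            pops[sid] = f"pop{ip}"
            sample += 1
    return make_matrix(calls, pops)


class TestAlleleFrequencies:
    def test_three_quarters(self):
        m = make_matrix({"a": [0], "b": [1]}, {"a": "p1", "b": "p1"})
        table = pg.allele_frequencies(m)
        assert table.loc[0, "p"] == pytest.approx(0.75)

    def test_all_nocall_missing(self):
        m = make_matrix({"a": [NO_CALL], "b": [NO_CALL]}, {"a": "p1", "b": "p1"})
        table = pg.allele_frequencies(m)
        assert np.isnan(table.loc[0, "p"])

    def test_monomorphic(self):
        m = make_matrix({"a": [0], "b": [0]}, {"a": "p1", "b": "p1"})
        assert pg.allele_frequencies(m).loc[0, "p"] == 1.0


class TestDiversity:
    def test_hwe_counts_f_near_zero(self):
        calls = {}
        i = 0
        for code, count in [(0, 25), (1, 50), (2, 25)]:
            for _ in range(count):
                calls[f"s{i}"] = [code]
                i += 1
        m = make_matrix(calls, {s: "p1" for s in calls})
        div = pg.diversity_summary(m, n_boot=50, seed=1)
        # exact-HWE counts: f is zero up to the finite-sample correction term
        assert div.per_population.loc["p1", "f"] == pytest.approx(0.0, abs=0.01)

    def test_complete_fixation(self):
        calls = {f"s{i}": [0] for i in range(50)}
        calls.update({f"t{i}": [2] for i in range(50)})
        m = make_matrix(calls, {s: "p1" for s in calls})
        div = pg.diversity_summary(m, n_boot=10, seed=1)
        assert div.per_population.loc["p1", "Ho"] == 0.0
        assert div.per_population.loc["p1", "f"] == pytest.approx(1.0)

    def test_four_genotype_example_matches_oracle(self):
        genotypes = [0, 1, 2, 1]  # AA, AB, BB, AB
        m = make_matrix({f"s{i}": [g] for i, g in enumerate(genotypes)},
                        {f"s{i}": "p1" for i in range(4)})
        div = pg.diversity_summary(m, n_boot=10, seed=0)
        row = div.per_population.loc["p1"]
        assert row["Ho"] == pytest.approx(0.5)
        assert row["He"] == pytest.approx((8 / 7) * 0.5)
        assert row["f"] == pytest.approx(wc_f_single([genotypes]), abs=1e-12)

    def test_single_individual_population_excluded(self):
        m = make_matrix({"a": [0], "b": [1], "c": [1]},
                        {"a": "lonely", "b": "p1", "c": "p1"})
        with pytest.warns(UserWarning):
            div = pg.diversity_summary(m, n_boot=10, seed=0)
        assert "lonely" not in div.per_population.index

    def test_regional_means_unweighted(self, hier_matrix):
        matrix, _ = hier_matrix
        div = pg.diversity_summary(matrix, n_boot=20, seed=3)
        for region, row in div.per_region.iterrows():
            pops = div.per_population[div.per_population["region"] == region]
            assert row["Ho"] == pytest.approx(pops["Ho"].mean())

    def test_bootstrap_ci_covers_point_estimate(self, hier_matrix):
        matrix, _ = hier_matrix
        div = pg.diversity_summary(matrix, n_boot=200, seed=4)
        pp = div.per_population
        assert ((pp["f_ci_low"] <= pp["f"]) & (pp["f"] <= pp["f_ci_high"])).all()


class TestWeirCockerhamOracle:
    def _random_instance(self, rng, n_pops, n_loci, max_n=20):
        sizes = [int(rng.integers(3, max_n)) for _ in range(n_pops)]
        loci = []
        for _ in range(n_loci):
            pops = []
            for n in sizes:
                p = rng.uniform(0.1, 0.9)
                g = rng.choice([0, 1, 2], size=n, p=[(1 - p) ** 2, 2 * p * (1 - p), p**2])
                pops.append(g.tolist())
            loci.append(pops)
        return loci

    @pytest.mark.parametrize("seed", range(5))
    def test_theta_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        loci = self._random_instance(rng, n_pops=int(rng.integers(2, 6)), n_loci=12)
        matrix = loci_to_matrix(loci)
        data = pg.AlleleData.from_matrix(matrix)
        assert pg.multilocus_theta(data) == pytest.approx(wc_theta(loci), abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_multi_pop_f_matches_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        loci = self._random_instance(rng, n_pops=3, n_loci=15)
        matrix = loci_to_matrix(loci)
        data = pg.AlleleData.from_matrix(matrix)
        assert pg.multilocus_f(data) == pytest.approx(wc_f_multi(loci), abs=1e-10)

    def test_single_locus_components_match(self):
        rng = np.random.default_rng(3)
        loci = self._random_instance(rng, n_pops=4, n_loci=1)
        a_o, b_o, c_o = wc_locus_components(loci[0])
        data = pg.AlleleData.from_matrix(loci_to_matrix(loci))
        a, b, c = pg._wc_abc(data, data.populations)
        # expansion sums both allele columns: exactly twice the one-allele values
        assert a.sum() == pytest.approx(2 * a_o, abs=1e-10)
        assert b.sum() == pytest.approx(2 * b_o, abs=1e-10)
        assert c.sum() == pytest.approx(2 * c_o, abs=1e-10)


class TestAmova:
    def test_panmictic_near_zero_with_nonsignificant_p(self):
        cfg = sd.PopulationSimConfig(
            n_regions=2, pops_per_region=[2, 2], n_per_pop=15, n_loci=150,
            theta_region=0.0, theta_pop=0.0, seed=13,
        )
        matrix, _ = sd.simulate_hierarchical_genotypes(cfg)
        res = pg.hierarchical_amova(matrix, n_perm=99, seed=1)
        assert abs(res.fst_t) < 0.03
        assert res.p_values["FstT"] > 0.05

    def test_fixed_regions_limit(self):
        calls = {}
        pops, regions = {}, {}
        i = 0
        for region, code in [("north", 0), ("south", 2)]:
            for pop in ("a", "b"):
                for _ in range(10):
                    sid = f"s{i}"
                    calls[sid] = [code] * 20
                    pops[sid] = f"{region}_{pop}"
                    regions[sid] = region
                    i += 1
        m = make_matrix(calls, pops, regions)
        res = pg.hierarchical_amova(m, n_perm=0)
        assert res.fst_r == pytest.approx(1.0, abs=1e-9)
        # no variation within or among pops inside a region: Vb = Vc = 0
        assert np.isnan(res.fst_pr) or abs(res.fst_pr) < 1e-9

    def test_structured_data_significant(self, hier_matrix):
        matrix, _ = hier_matrix
        res = pg.hierarchical_amova(matrix, n_perm=99, seed=2)
        assert res.p_values["FstT"] <= 0.05
        # with 5 pops in 2 regions few distinct region permutations exist,
        # so FstR significance is bounded away from zero
        assert res.p_values["FstR"] <= 0.5

    def test_fst_consistency_identity(self, hier_matrix):
        matrix, _ = hier_matrix
        res = pg.hierarchical_amova(matrix, n_perm=0)
        assert (1 - res.fst_r) * (1 - res.fst_pr) == pytest.approx(
            1 - res.fst_t, abs=1e-12
        )

    def test_percentages_sum_to_100(self, hier_matrix):
        matrix, _ = hier_matrix
        res = pg.hierarchical_amova(matrix, n_perm=0)
        if min(res.va, res.vb, res.vc) >= 0:
            total = res.pct_among_regions + res.pct_among_pops + res.pct_within
            assert total == pytest.approx(100.0)

    def test_requires_two_regions(self):
        m = make_matrix({"a": [0], "b": [1], "c": [2], "d": [1]},
                        {"a": "p1", "b": "p1", "c": "p2", "d": "p2"})
        with pytest.raises(ValueError):
            pg.hierarchical_amova(m)


class TestPairwiseFst:
    def test_identical_frequencies_near_zero(self):
        cfg = sd.PopulationSimConfig(
            n_regions=1, pops_per_region=[2], n_per_pop=40, n_loci=400,
            theta_region=0.0, theta_pop=0.0, seed=17,
        )
        matrix, _ = sd.simulate_hierarchical_genotypes(cfg)
        fst, _ = pg.pairwise_fst(matrix)
        assert abs(fst.iloc[0, 1]) < 0.02

    def test_fixed_pops_theta_one(self):
        calls = {f"a{i}": [0] * 10 for i in range(10)}
        calls.update({f"b{i}": [2] * 10 for i in range(10)})
        pops = {s: ("p1" if s.startswith("a") else "p2") for s in calls}
        m = make_matrix(calls, pops)
        fst, _ = pg.pairwise_fst(m)
        assert fst.loc["p1", "p2"] == pytest.approx(1.0)

    def test_balding_nichols_recovery(self):
        cfg = sd.PopulationSimConfig(
            n_regions=2, pops_per_region=[1, 1], n_per_pop=50, theta_region=0.1,
            theta_pop=0.0, n_loci=2000, seed=3,
        )
        matrix, _ = sd.simulate_hierarchical_genotypes(cfg)
        fst, _ = pg.pairwise_fst(matrix)
        assert fst.iloc[0, 1] == pytest.approx(0.1, abs=0.02)

    def test_permutation_pvalues(self):
        cfg = sd.PopulationSimConfig(
            n_regions=2, pops_per_region=[1, 1], n_per_pop=20, theta_region=0.2,
            theta_pop=0.0, n_loci=100, seed=4,
        )
        matrix, _ = sd.simulate_hierarchical_genotypes(cfg)
        fst, pvals = pg.pairwise_fst(matrix, n_perm=49, seed=5)
        assert pvals.iloc[0, 1] <= 0.05

    def test_theta_matches_oracle_pairwise(self):
        rng = np.random.default_rng(8)
        loci = []
        for _ in range(10):
            loci.append([
                rng.choice([0, 1, 2], size=12).tolist(),
                rng.choice([0, 1, 2], size=15).tolist(),
            ])
        matrix = loci_to_matrix(loci)
        fst, _ = pg.pairwise_fst(matrix)
        assert fst.iloc[0, 1] == pytest.approx(wc_theta(loci), abs=1e-10)


class TestDistancesAndPcoa:
    def test_identical_individuals_zero(self):
        m = make_matrix({"a": [0, 1, 2], "b": [0, 1, 2]}, {"a": "p", "b": "p"})
        d = pg.genetic_distance_matrix(m)
        assert d.loc["a", "b"] == 0.0

    def test_opposite_homozygotes_distance_four(self):
        m = make_matrix({"a": [0], "b": [2]}, {"a": "p", "b": "p"})
        assert pg.genetic_distance_matrix(m).loc["a", "b"] == pytest.approx(4.0)

    def test_codominant_scheme(self):
        # d2: AA-AB=1, AB-BB=1, AA-BB=4, AB-AB=0
        m = make_matrix({"a": [0, 1], "b": [1, 1]}, {"a": "p", "b": "p"})
        assert pg.genetic_distance_matrix(m).loc["a", "b"] == pytest.approx(0.5)

    def test_missing_locus_excluded_from_pair(self):
        m = make_matrix({"a": [0, NO_CALL], "b": [2, 2]}, {"a": "p", "b": "p"})
        assert pg.genetic_distance_matrix(m).loc["a", "b"] == pytest.approx(4.0)

    def test_equilateral_triangle_two_equal_axes(self):
        d2 = pd.DataFrame([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = pg.pcoa(d2)
        assert res.proportion_explained[0] == pytest.approx(0.5)
        assert res.proportion_explained[1] == pytest.approx(0.5)

    def test_collinear_points_single_axis(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        d2 = pd.DataFrame((x[:, None] - x[None, :]) ** 2)
        res = pg.pcoa(d2)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_distances_reconstructed(self):
        rng = np.random.default_rng(12)
        points = rng.normal(size=(6, 3))
        diff = points[:, None, :] - points[None, :, :]
        d2 = pd.DataFrame((diff**2).sum(-1))
        res = pg.pcoa(d2)
        coords = res.coordinates.to_numpy()
        rec = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        np.testing.assert_allclose(rec, d2.to_numpy(), atol=1e-8)

    def test_pcoa_agrees_with_skbio(self, hier_matrix):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        matrix, _ = hier_matrix
        d2 = pg.genetic_distance_matrix(matrix.subset_samples(matrix.calls.index[:30]))
        res = pg.pcoa(d2)
        from skbio import DistanceMatrix

        ref = skbio_ord.pcoa(DistanceMatrix(np.sqrt(d2.to_numpy())))
        np.testing.assert_allclose(
            res.proportion_explained[:3],
            ref.proportion_explained.iloc[:3],
            atol=1e-8,
        )


class TestResamplingSfsEvanno:
    def test_full_size_sets_equal_full_panel(self, hier_matrix):
        matrix, _ = hier_matrix
        data = pg.AlleleData.from_matrix(matrix)
        full = pg.hierarchical_amova(data, n_perm=0)
        res = pg.subset_resampling(data, set_size=data.n_loci, n_sets=3, seed=0)
        np.testing.assert_allclose(res["FstT"], full.fst_t, atol=1e-12)

    def test_same_seed_identical(self, hier_matrix):
        matrix, _ = hier_matrix
        a = pg.subset_resampling(matrix, set_size=50, n_sets=5, seed=7)
        b = pg.subset_resampling(matrix, set_size=50, n_sets=5, seed=7)
        assert a.equals(b)

    def test_set_size_too_large(self, hier_matrix):
        matrix, _ = hier_matrix
        with pytest.raises(ValueError):
            pg.subset_resampling(matrix, set_size=10_000)

    def test_sfs_rare_bin(self):
        maf = pd.Series([0.0, 0.004, 0.25])
        sfs = pg.site_frequency_spectrum(maf)
        assert sfs.loc[0, "count"] == 2
        assert sfs["count"].sum() == 3

    def test_sfs_counts_sum(self):
        rng = np.random.default_rng(5)
        maf = pd.Series(rng.uniform(0, 0.5, size=200))
        maf.iloc[:10] = np.nan
        sfs = pg.site_frequency_spectrum(maf)
        assert sfs["count"].sum() == 190

    def test_evanno_direct_formula(self):
        rows = []
        means = {1: -1000.0, 2: -800.0, 3: -790.0, 4: -788.0}
        d = np.sqrt(2)  # two runs at mu +/- sqrt(2) have sd exactly 2
        for k, mu in means.items():
            rows += [(k, 1, mu - d), (k, 2, mu + d)]
        table = pd.DataFrame(rows, columns=["K", "run", "log_likelihood"])
        ev = pg.evanno_delta_k(table)
        assert ev.loc[2, "delta_K"] == pytest.approx(95.0)
        assert np.isnan(ev.loc[1, "delta_K"])
        assert np.isnan(ev.loc[4, "delta_K"])

    def test_linear_means_zero_delta_k(self):
        rows = []
        for k in range(1, 6):
            mu = -1000 + 50 * k
            rows += [(k, 1, mu - 1.0), (k, 2, mu + 1.0)]
        ev = pg.evanno_delta_k(pd.DataFrame(rows, columns=["K", "run", "log_likelihood"]))
        assert ev["delta_K"].dropna().max() == pytest.approx(0.0, abs=1e-9)

    def test_zero_sd_excluded_with_warning(self):
        rows = []
        for k in range(1, 5):
            mu = {1: -900.0, 2: -700.0, 3: -690.0, 4: -685.0}[k]
            jitter = 0.0 if k == 2 else 1.0
            rows += [(k, 1, mu - jitter), (k, 2, mu + jitter)]
        table = pd.DataFrame(rows, columns=["K", "run", "log_likelihood"])
        with pytest.warns(UserWarning):
            ev = pg.evanno_delta_k(table)
        assert np.isnan(ev.loc[2, "delta_K"])

    def test_non_contiguous_k_rejected(self):
        rows = [(1, 1, -10.0), (1, 2, -11.0), (3, 1, -5.0), (3, 2, -6.0)]
        with pytest.raises(ValueError):
            pg.evanno_delta_k(pd.DataFrame(rows, columns=["K", "run", "log_likelihood"]))


class TestMicrosatelliteContrast:
    def test_multiallelic_loci_higher_he_lower_theta(self):
        """Hypervariable 10-allele loci: higher He, lower theta than SNPs."""
        rng = np.random.default_rng(99)
        theta = 0.25
        n_pops, n_per_pop, n_loci = 4, 20, 60
        pops = np.repeat([f"p{i}" for i in range(n_pops)], n_per_pop)
        regions = np.repeat(["r1", "r2"], 2 * n_per_pop)
        samples = pd.Index([f"s{i}" for i in range(n_pops * n_per_pop)])

        def simulate(n_alleles):
            pairs = np.zeros((n_pops * n_per_pop, n_loci, 2), dtype=int)
            for l in range(n_loci):
                base = rng.dirichlet(np.ones(n_alleles) * 5)
                for ip in range(n_pops):
                    scale = (1 - theta) / theta
                    freq = rng.dirichlet(base * scale)
                    draws = rng.choice(n_alleles, size=(n_per_pop, 2), p=freq)
                    pairs[ip * n_per_pop : (ip + 1) * n_per_pop, l] = draws
            return pg.AlleleData.from_allele_pairs(pairs, samples, pops, regions)

        micro = simulate(10)
        snp = simulate(2)
        div_micro = pg.diversity_summary(micro, n_boot=10, seed=1)
        div_snp = pg.diversity_summary(snp, n_boot=10, seed=1)
        assert div_micro.overall["He"] > div_snp.overall["He"]
        assert pg.multilocus_theta(micro) < pg.multilocus_theta(snp)
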
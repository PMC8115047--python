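"""Diversity, FST, rarefaction, Mantel and regional tests against oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from popcline import (
    DemographicScenario,
    GenotypeMatrix,
    PopulationMap,
    allelic_richness,
    chisq_pvalue,
    diversity,
    fst_matrix,
    mantel,
    mantel_ibd,
    pairwise_fst,
    regional_tests,
    simulate_snp_dataset,
    welch_t,
)


def _single_pop_geno(calls):
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    geno = GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        loci=pd.DataFrame({"id": [f"l{j}" for j in range(L)]}),
        calls=calls,
    )
    pm = PopulationMap(table=pd.DataFrame({
        "sample": geno.samples, "population": "P", "region": "R",
        "latitude": 55.0, "longitude": 13.0, "environment": 200.0}))
    return geno, pm


class TestDiversity:
    def test_monomorphic_population_zero_everything(self):
        geno, pm = _single_pop_geno(np.zeros((4, 3)))
        d = diversity(geno, pm)
        assert d.loc["P", ["pi", "he", "ho", "fis"]].tolist() == [0, 0, 0, 0]

    def test_unbiased_pi_two_chromosomes(self):
        # n=2 chromosomes, one of each allele: the correction forces pi = 1
        from popcline.sumstats import unbiased_pi_per_site

        assert unbiased_pi_per_site(1, 2) == pytest.approx(1.0)
        # and through the API: two diploids, opposite homozygotes (n=4)
        geno, pm = _single_pop_geno([[0], [2]])
        expect = unbiased_pi_per_site(2, 4)
        assert diversity(geno, pm).loc["P", "pi"] == pytest.approx(expect)

    def test_fis_near_zero_under_random_mating(self):
        sc = DemographicScenario(demes=["A"], ne={"A": 5000.0})
        fis = []
        for rep in range(20):
            geno, pm = simulate_snp_dataset(
                scenario=sc, n_loci=200, seed=400 + rep,
                n_populations_per_region=1, n_diploids_per_population=20)
            fis.append(diversity(geno, pm).loc[:, "fis"].iloc[0])
        assert abs(np.mean(fis)) < 0.02

    def test_invariant_to_sample_order_and_allele_flip(self, study_dataset):
        geno, pm = study_dataset
        geno_s = geno.subset_loci(np.arange(100))
        d0 = diversity(geno_s, pm)
        order = list(reversed(geno_s.samples))
        d1 = diversity(geno_s.subset_samples(order), pm)
        pd.testing.assert_frame_equal(d0, d1)
        flipped = geno_s.calls.copy()
        m = flipped >= 0
        flipped[m] = 2 - flipped[m]
        geno_f = GenotypeMatrix(samples=geno_s.samples, loci=geno_s.loci,
                                calls=flipped)
        d2 = diversity(geno_f, pm)
        pd.testing.assert_frame_equal(d0, d2)


class TestAllelicRichness:
    def test_monomorphic_locus_ar_one(self):
        geno, pm = _single_pop_geno(np.full((4, 2), 2))
        assert allelic_richness(geno, pm, g=4).loc["P"] == pytest.approx(1.0)

    def test_singleton_full_sample_ar_two(self):
        # allele counts (1, N-1) with g = N: every subsample is the full one
        geno, pm = _single_pop_geno([[1], [0], [0], [0]])
        assert allelic_richness(geno, pm, g=8).loc["P"] == pytest.approx(2.0)

    def test_matches_exhaustive_enumeration_n4(self):
        # N=4 genes with counts (2,2), g=2: enumerate all C(4,2) subsamples
        geno, pm = _single_pop_geno([[2], [0]])  # 2 diploids -> genes AABB
        genes = ["A", "A", "B", "B"]
        counts = [len(set(sub)) for sub in itertools.combinations(genes, 2)]
        expect = np.mean(counts)
        assert allelic_richness(geno, pm, g=2).loc["P"] == pytest.approx(expect)

    def test_monotone_in_g(self, study_dataset):
        geno, pm = study_dataset
        geno_s = geno.subset_loci(np.arange(150))
        prev = None
        for g in (2, 6, 12, 20):
            ar = allelic_richness(geno_s, pm, g=g)
            if prev is not None:
                assert (ar.values >= prev.values - 1e-12).all()
            prev = ar

    def test_error_names_population(self):
        geno, pm = _single_pop_geno([[1], [0]])
        with pytest.raises(ValueError, match="'P'"):
            allelic_richness(geno, pm, g=5)


class TestFst:
    def _two_pop(self, calls_a, calls_b):
        calls = np.vstack([calls_a, calls_b]).astype(np.int8)
        na = len(calls_a)
        geno = GenotypeMatrix(
            samples=[f"s{i}" for i in range(len(calls))],
            loci=pd.DataFrame({"id": [f"l{j}" for j in range(calls.shape[1])]}),
            calls=calls)
        pops = ["A"] * na + ["B"] * (len(calls) - na)
        pm = PopulationMap(table=pd.DataFrame({
            "sample": geno.samples, "population": pops, "region": pops,
            "latitude": [55.0 if p == "A" else 60.0 for p in pops],
            "longitude": 13.0, "environment": 200.0}))
        return geno, pm

    def test_null_identical_frequencies(self):
        sc = DemographicScenario(demes=["A"], ne={"A": 10_000.0})
        geno, pm = simulate_snp_dataset(
            scenario=sc, n_loci=1000, seed=77,
            n_populations_per_region=2, n_diploids_per_population=50)
        f = pairwise_fst(geno, pm, *pm.populations[:2])
        assert abs(f) < 0.01

    def test_fixed_differences_give_fst_one(self):
        geno, pm = self._two_pop(np.zeros((10, 20)), np.full((10, 20), 2))
        f = pairwise_fst(geno, pm, "A", "B")
        assert f >= 0.98

    def test_matrix_symmetric_zero_diagonal(self, study_dataset):
        geno, pm = study_dataset
        m = fst_matrix(geno.subset_loci(np.arange(120)), pm)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)
        assert m.values.max() < 1.0

    def test_no_shared_loci_raises(self):
        a = np.array([[0], [1]])
        b = np.array([[-1], [-1]])
        geno, pm = self._two_pop(a, b)
        with pytest.raises(ValueError, match="no shared"):
            pairwise_fst(geno, pm, "A", "B")


class TestMantel:
    def test_perfect_monotone_affine_relation(self):
        rng = np.random.default_rng(0)
        n = 6
        d = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        d[iu] = rng.uniform(1, 10, size=len(iu[0]))
        d += d.T
        y = 3.0 * d + 1.0
        np.fill_diagonal(y, 0)
        res = mantel(y, d, n_perm=719, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 720, abs=2e-3)

    def test_sampled_p_matches_exhaustive_enumeration_4pops(self):
        rng = np.random.default_rng(3)
        n = 4
        y = rng.uniform(size=(n, n));  y = (y + y.T) / 2; np.fill_diagonal(y, 0)
        x = rng.uniform(size=(n, n));  x = (x + x.T) / 2; np.fill_diagonal(x, 0)
        exact = mantel(y, x, exact=True)
        sampled = mantel(y, x, n_perm=20_000, seed=5)
        assert sampled.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_null_p_uniform_on_attainable_grid(self):
        """With genetics independent of distance the permutation p is
        uniform over its attainable grid (KS not rejected at 0.01)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(9)
        pvals = []
        n = 5
        for _ in range(200):
            y = rng.uniform(size=(n, n)); y = (y + y.T) / 2; np.fill_diagonal(y, 0)
            x = rng.uniform(size=(n, n)); x = (x + x.T) / 2; np.fill_diagonal(x, 0)
            pvals.append(mantel(y, x, n_perm=119, seed=int(rng.integers(2**31))).p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_ibd_on_clinal_data(self, study_dataset):
        geno, pm = study_dataset
        fst = fst_matrix(geno.subset_loci(np.arange(300)), pm)
        res = mantel_ibd(fst, pm, n_perm=999, seed=0)
        assert res.r > 0.5
        assert res.p_value < 0.05

    def test_fst_of_one_raises(self, tiny_popmap):
        f = pd.DataFrame(1.0, index=["P1", "P2"], columns=["P1", "P2"])
        np.fill_diagonal(f.values, 0)
        with pytest.raises(ValueError, match="undefined"):
            mantel_ibd(f, tiny_popmap, n_perm=9)


class TestRegionalAndChisq:
    def test_chisq_survival_function(self):
        assert chisq_pvalue(132, 121) == pytest.approx(0.2329, abs=5e-5)

    def test_welch_identical_groups(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0 and p == pytest.approx(1.0)

    def test_welch_df_equal_variance_equal_n(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=8)
        b = a + 1.0  # identical variances
        _, df, _ = welch_t(a, b)
        assert df == pytest.approx(2 * 8 - 2)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            welch_t([1.0, 1.0], [1.0, 1.0])

    def test_north_south_diversity_difference(self, study_dataset):
        geno, pm = study_dataset
        neutral = geno.subset_loci(~geno.loci["selected"].values)
        div = diversity(neutral, pm)
        res = regional_tests(div, pm, ["Skane", "Uppland"],
                             ["Vasterbotten", "Norrbotten"])
        # southern demes are larger in the generating model -> higher pi
        assert res.loc["pi", "mean_south"] > res.loc["pi", "mean_north"]
        assert res.loc["pi", "p_value"] < 0.05
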
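"""Selection scans: calibration, power, reductions and bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popcline import (
    GenotypeMatrix,
    LatentFactorRidgeScan,
    PCAOutlierScan,
    fdr,
    lfmm_ridge_scan,
    partition_outliers,
    pca,
    pcadapt_scan,
)


class TestPCA:
    def test_pc1_separates_diverged_demes(self, two_deme_spiked):
        from sklearn.metrics import silhouette_score

        geno, popmap = two_deme_spiked
        scores, _ = pca(geno, n_components=2)
        labels = [popmap.region_of_population()[popmap.population_of()[s]]
                  for s in geno.samples]
        assert silhouette_score(scores[:, :1], labels) > 0.8

    def test_duplicated_samples_get_identical_scores(self, two_deme_spiked):
        geno, _ = two_deme_spiked
        sub = geno.subset_loci(np.arange(300))
        doubled = GenotypeMatrix(
            samples=sub.samples + [f"{s}_dup" for s in sub.samples],
            loci=sub.loci, calls=np.vstack([sub.calls, sub.calls]))
        scores, _ = pca(doubled, n_components=3)
        n = sub.n_samples
        np.testing.assert_allclose(scores[:n], scores[n:], atol=1e-8)

    def test_explained_variances_sum_to_total(self, two_deme_spiked):
        from popcline.scan import _scaled_genotypes

        geno, _ = two_deme_spiked
        z, _ = _scaled_genotypes(geno)
        _, explained = pca(geno, n_components=5)
        zc = z - z.mean(axis=0)
        total = (zc**2).sum() / (geno.n_samples - 1)
        assert explained.sum() == pytest.approx(total, rel=1e-10)


class TestPcadaptScan:
    def test_null_type_one_error_calibrated(self, null_panmictic_dataset):
        geno, _ = null_panmictic_dataset
        res = pcadapt_scan(geno, k=1)
        pv = res.table["p_value"].dropna().values
        assert 0.03 <= (pv < 0.05).mean() <= 0.07

    def test_gif_near_one_on_null(self, null_panmictic_dataset):
        geno, _ = null_panmictic_dataset
        res = pcadapt_scan(geno, k=1)
        assert abs(res.gif - 1.0) < 0.1

    def test_power_and_fdr_on_spiked_clines(self, pcadapt_power):
        """>=80% of spiked clinal loci flagged at realised FDR <=10%,
        averaged over 10 replicate two-deme datasets."""
        power, fdr_real = pcadapt_power
        assert np.mean(power) >= 0.8
        assert np.mean(fdr_real) <= 0.10

    def test_locus_identical_to_pc_has_largest_distance(self, two_deme_spiked):
        geno, _ = two_deme_spiked
        sub = geno.subset_loci(np.arange(500))
        scores, _ = pca(sub, n_components=1)
        s = scores[:, 0]
        fake = np.clip(np.round(2 * (s - s.min()) / (s.max() - s.min())), 0, 2)
        calls = np.column_stack([sub.calls, fake.astype(np.int8)])
        loci = pd.concat([sub.loci, pd.DataFrame([{"id": "pc_clone"}])],
                         ignore_index=True)
        geno2 = GenotypeMatrix(samples=sub.samples, loci=loci, calls=calls)
        res = pcadapt_scan(geno2, k=1)
        t = res.table.set_index("locus")["stat"]
        assert t["pc_clone"] == t.max()

    def test_invariant_to_locus_order_and_allele_flip(self, two_deme_spiked):
        geno, _ = two_deme_spiked
        sub = geno.subset_loci(np.arange(400))
        res0 = pcadapt_scan(sub, k=1)
        perm = np.random.default_rng(0).permutation(400)
        res1 = pcadapt_scan(sub.subset_loci(perm), k=1)
        a = res0.table.set_index("locus").loc[:, "stat"]
        b = res1.table.set_index("locus").loc[a.index, "stat"]
        np.testing.assert_allclose(a.values, b.values, rtol=1e-6)
        # allele flip leaves D2 unchanged
        flipped = sub.calls.copy()
        m = flipped >= 0
        flipped[m] = 2 - flipped[m]
        res2 = pcadapt_scan(
            GenotypeMatrix(samples=sub.samples, loci=sub.loci, calls=flipped), k=1)
        np.testing.assert_allclose(res0.table["stat"].values,
                                   res2.table["stat"].values, rtol=1e-6)

    def test_k_bounds(self, tiny_geno):
        with pytest.raises(ValueError):
            PCAOutlierScan(n_components=0).fit(tiny_geno)
        with pytest.raises(ValueError):
            PCAOutlierScan(n_components=4).fit(tiny_geno)


class TestLfmmScan:
    def test_k0_reduces_to_simple_regression(self, two_deme_spiked):
        geno, popmap = two_deme_spiked
        sub = geno.subset_loci(np.arange(300))
        env = popmap.environment_per_sample(sub)
        scan = LatentFactorRidgeScan(n_factors=0, gif=False).fit(sub, env)
        # oracle: per-locus OLS z-statistic -> chi2_1 upper tail
        from popcline.scan import _scaled_genotypes

        y, keep = _scaled_genotypes(sub, 0.05)
        x = (env - env.mean()) / env.std()
        ps = []
        for j in range(y.shape[1]):
            res = stats.linregress(x, y[:, j])
            z = res.slope / res.stderr
            ps.append(stats.chi2.sf(z**2, 1))
        assert np.max(np.abs(scan.pvalues_ - np.array(ps))) < 1e-8

    def test_null_p_uniform_when_env_independent(self, null_panmictic_dataset):
        geno, popmap = null_panmictic_dataset
        rng = np.random.default_rng(5)
        env = rng.normal(size=geno.n_samples)
        scan = LatentFactorRidgeScan(n_factors=1).fit(geno, env)
        assert stats.kstest(scan.pvalues_, "uniform").pvalue > 0.01

    def test_power_and_fdr_on_spiked_env_loci(self, lfmm_power):
        power, fdr_real = lfmm_power
        assert np.mean(power) >= 0.8
        assert np.mean(fdr_real) <= 0.10

    def test_combined_union_fdr_bounded(self, two_deme_spiked):
        """Realised FDR of the two-scan union stays below 2*alpha."""
        geno, popmap = two_deme_spiked
        res_a = pcadapt_scan(geno, k=1)
        res_b = lfmm_ridge_scan(geno, popmap, k=1)
        part = partition_outliers(res_a.outlier_ids, res_b.outlier_ids,
                                  geno.locus_ids)
        sel_ids = set(geno.loci.loc[geno.loci["selected"], "id"])
        false = [x for x in part["union"] if x not in sel_ids]
        assert len(false) / max(part["n_union"], 1) <= 0.10

    def test_constant_env_raises(self, tiny_geno):
        with pytest.raises(ValueError, match="constant"):
            LatentFactorRidgeScan(n_factors=0).fit(tiny_geno, np.ones(4))


class TestFdr:
    def test_all_p_one_nothing_significant(self):
        q, sig = fdr(np.ones(10), alpha=0.05)
        assert not sig.any()

    def test_hand_enumerated_step_up(self):
        # m=5 p-values all equal alpha/m: every one passes BH (step-up at
        # rank m: p <= alpha*m/m); hand enumeration of the step-up rule
        alpha, m = 0.05, 5
        p = np.full(m, alpha / m)
        q, sig = fdr(p, alpha)
        assert sig.all()
        # distinct ladder: p_i = alpha*(i+1)/m * (1 + eps) fails except rank 1
        p2 = np.array([0.009, 0.05, 0.2, 0.5, 0.9])
        q2, sig2 = fdr(p2, alpha)
        # hand step-up: rank5 0.9>0.05; rank4 0.5>0.04; rank3 0.2>0.03;
        # rank2 0.05>0.02; rank1 0.009<=0.01 -> only the smallest survives
        assert sig2.tolist() == [True, False, False, False, False]

    def test_qvalues_dominate_pvalues(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q, _ = fdr(p)
        assert (q >= p - 1e-12).all()

    def test_empty_input(self):
        q, sig = fdr(np.array([]))
        assert q.size == 0 and sig.size == 0


class TestPartition:
    def test_study_bookkeeping(self):
        all_loci = [f"L{i}" for i in range(17_636)]
        a = set(all_loci[:472])
        b = set(all_loci[388:621])  # overlap of 84 with a
        part = partition_outliers(a, b, all_loci)
        assert part["n_overlap"] == 84
        assert part["n_union"] == 621
        assert part["n_neutral"] == 17_015

    def test_subset_and_empty_cases(self):
        alls = list("abcdef")
        assert partition_outliers({"a", "b"}, {"b"}, alls)["n_union"] == 2
        part = partition_outliers(set(), set(), alls)
        assert part["n_union"] == 0 and part["neutral"] == alls

    def test_stray_id_raises(self):
        with pytest.raises(ValueError, match="outside"):
            partition_outliers({"z"}, set(), ["a", "b"])
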
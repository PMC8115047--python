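"""Hierarchical AMOVA against a brute-force centroid oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from popcline import GenotypeMatrix, PopulationMap, amova, amova_permtest
from popcline.amova import _components, pairwise_sq_distances


def _toy(calls, pops, groups):
    calls = np.asarray(calls, dtype=np.int8)
    n = len(calls)
    geno = GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        loci=pd.DataFrame({"id": [f"l{j}" for j in range(calls.shape[1])]}),
        calls=calls)
    # one region per population keeps the mapping simple; ``groups`` aligns
    # with the unique populations in order of first appearance
    pm = PopulationMap(table=pd.DataFrame({
        "sample": geno.samples, "population": pops, "region": pops,
        "latitude": 55.0, "longitude": 13.0, "environment": 100.0}))
    lineages = dict(zip(list(dict.fromkeys(pops)), groups))
    return geno, pm, lineages


def _centroid_ss(x, pops, groups):
    """Independent SS decomposition from centroid deviations (no distance
    matrix): total, among groups, among pops within groups, within pops."""
    x = np.asarray(x, dtype=float)
    pops = np.asarray(pops)
    groups = np.asarray(groups)
    grand = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_wp = 0.0
    ss_ap = 0.0
    ss_ag = 0.0
    for g in np.unique(groups):
        xg = x[groups == g]
        ss_ag += len(xg) * ((xg.mean(axis=0) - grand) ** 2).sum()
        for p in np.unique(pops[groups == g]):
            xp = x[(groups == g) & (pops == p)]
            ss_wp += ((xp - xp.mean(axis=0)) ** 2).sum()
            ss_ap += len(xp) * ((xp.mean(axis=0) - xg.mean(axis=0)) ** 2).sum()
    return ss_total, ss_ag, ss_ap, ss_wp


class TestComponents:
    def test_identical_individuals_all_zero(self):
        geno, pm, lin = _toy(np.ones((8, 4)), ["P1"] * 2 + ["P2"] * 2 + ["P3"] * 2 + ["P4"] * 2,
                             ["g1", "g1", "g2", "g2"])
        res = amova(geno, pm, lin)
        assert np.allclose(res.table["SS"], 0)
        assert np.allclose(res.table["sigma2"], 0)

    def test_fixed_opposite_lineages_all_variance_among_lineages(self):
        calls = np.vstack([np.zeros((4, 6)), np.full((4, 6), 2)])
        geno, pm, lin = _toy(calls, ["P1", "P1", "P2", "P2", "P3", "P3", "P4", "P4"],
                             ["g1", "g1", "g2", "g2"])
        res = amova(geno, pm, lin)
        c = res.components
        assert c["within_populations"] == pytest.approx(0.0)
        assert c["among_populations"] == pytest.approx(0.0)
        assert c["among_lineages"] > 0
        assert res.phi["phi_CT"] == pytest.approx(1.0)

    def test_three_level_toy_matches_centroid_oracle(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(8, 4))
        pops = ["P1", "P1", "P2", "P2", "P3", "P3", "P4", "P4"]
        groups_of_pop = {"P1": "g1", "P2": "g1", "P3": "g2", "P4": "g2"}
        groups = [groups_of_pop[p] for p in pops]
        geno, pm, lin = _toy(calls, pops, ["g1", "g1", "g2", "g2"])
        res = amova(geno, pm, lin)
        ss_total, ss_ag, ss_ap, ss_wp = _centroid_ss(calls, pops, groups)
        assert res.table.loc["among_lineages", "SS"] == pytest.approx(ss_ag)
        assert res.table.loc["among_populations", "SS"] == pytest.approx(ss_ap)
        assert res.table.loc["within_populations", "SS"] == pytest.approx(ss_wp)
        assert res.meta["ss_total"] == pytest.approx(ss_total)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_random_toys_match_oracle_and_conserve_ss(self, seed):
        """On random <=12-individual three-level designs the distance-based
        SS partition equals the centroid decomposition and the expected-MS
        equations hold exactly."""
        rng = np.random.default_rng(seed)
        n_groups = 2
        pops_per_group = rng.integers(2, 4, size=n_groups)
        pops, groups = [], []
        pid = 0
        for g in range(n_groups):
            for _ in range(pops_per_group[g]):
                n_ind = rng.integers(2, 4)
                pops += [f"P{pid}"] * n_ind
                groups += [f"g{g}"] * n_ind
                pid += 1
        pops, groups = pops[:12], groups[:12]
        calls = rng.integers(0, 3, size=(len(pops), 5))
        pop_regions = list(dict.fromkeys(pops))
        geno, pm, _ = _toy(calls, pops, groups)
        lin = {p: g for p, g in zip(pops, groups)}
        res = amova(geno, pm, lin)
        ss_total, ss_ag, ss_ap, ss_wp = _centroid_ss(calls, pops, groups)
        np.testing.assert_allclose(
            res.table["SS"].values, [ss_ag, ss_ap, ss_wp], atol=1e-8)
        assert res.table["SS"].sum() == pytest.approx(ss_total, rel=1e-9, abs=1e-9)
        # components satisfy the expected-mean-square equations
        df = res.table["df"].values
        ms = res.table["MS"].values
        sig = res.table["sigma2"].values
        n = len(pops)
        n_p = pd.Series(pops).value_counts()
        n_g = pd.Series(groups).value_counts()
        g_of_p = {p: g for p, g in zip(pops, groups)}
        sum_np2_by_g = {g: sum(n_p[p] ** 2 for p in n_p.index if g_of_p[p] == g)
                        for g in n_g.index}
        n_prime = (n - sum(sum_np2_by_g[g] / n_g[g] for g in n_g.index)) / df[1]
        n_dprime = (sum(sum_np2_by_g[g] / n_g[g] for g in n_g.index)
                    - sum(n_p**2) / n) / df[0]
        n_tprime = (n - sum(n_g**2) / n) / df[0]
        assert ms[2] == pytest.approx(sig[2])
        assert ms[1] == pytest.approx(sig[2] + n_prime * sig[1])
        assert ms[0] == pytest.approx(sig[2] + n_dprime * sig[1] + n_tprime * sig[0])

    def test_degenerate_hierarchy_raises(self):
        geno, pm, lin = _toy(np.zeros((4, 3)), ["P1", "P1", "P2", "P2"],
                             ["g1", "g1"])
        with pytest.raises(ValueError, match="degenerate|lineage"):
            amova(geno, pm, lin)


class TestPermutation:
    def test_strong_structure_hits_p_floor(self, study_dataset):
        geno, pm = study_dataset
        sub = geno.subset_loci(np.arange(400))
        lin = {"Skane": "south", "Uppland": "south",
               "Vasterbotten": "north", "Norrbotten": "north"}
        res = amova_permtest(sub, pm, lin, n_perm=999, seed=0)
        assert res.table.loc["among_lineages", "p_value"] == pytest.approx(0.001)
        assert res.table.loc["within_populations", "p_value"] == pytest.approx(0.001)
        assert list(res.table["alternative"]) == ["greater", "greater", "less"]

    def test_null_p_approximately_uniform(self):
        """Random labels: lineage-level permutation p uniform over replicate
        datasets (KS at 0.01)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(120):
            calls = rng.integers(0, 3, size=(12, 30))
            pops = [f"P{i // 3}" for i in range(12)]
            groups = [g for g in ["g1", "g1", "g2", "g2"] for _ in range(3)]
            geno, pm, _ = _toy(calls, pops, groups)
            lin = {f"P{i}": g for i, g in enumerate(["g1", "g1", "g2", "g2"])}
            res = amova_permtest(geno, pm, lin, n_perm=99,
                                 seed=int(rng.integers(2**31)))
            pvals.append(res.table.loc["among_populations", "p_value"])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_same_seed_identical_p(self, study_dataset):
        geno, pm = study_dataset
        sub = geno.subset_loci(np.arange(100))
        lin = {"Skane": "south", "Uppland": "south",
               "Vasterbotten": "north", "Norrbotten": "north"}
        a = amova_permtest(sub, pm, lin, n_perm=99, seed=5)
        b = amova_permtest(sub, pm, lin, n_perm=99, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)
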
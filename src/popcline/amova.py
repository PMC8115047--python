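"""Hierarchical analysis of molecular variance (AMOVA) with permutation
significance.

Three-level hierarchy: individuals within populations, populations within
lineages (groups of regions, e.g. a northern and a southern recolonisation
lineage), lineages within the total.  Distances are squared Euclidean on
dosage vectors with pairwise-complete loci (scaled up to the full locus count
by ``L / L_shared``).  Sums of squares follow the classical distance
formulation; variance components come from the standard unbalanced-design
coefficient equations; Phi-statistics from the components.  Negative
components are reported as computed (a ``truncate`` switch zeroes them).

Permutation significance (randomisation test, default 999 permutations):

* within-population component — permute individuals among populations within
  their lineage; alternative "less";
* among-population component — permute individuals across populations;
  alternative "greater";
* among-lineage component — permute whole populations across lineages;
  alternative "greater".

p = (number of permuted statistics strictly more extreme + 1) / (n_perm + 1);
the +1 accounts for the observed labelling itself, so permutations that
merely re-create the observed partition (a tie, not a more extreme
arrangement) do not inflate p and fully separated data can reach the floor
1/(n_perm + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)


def pairwise_sq_distances(geno: GenotypeMatrix) -> np.ndarray:
    """Pairwise-complete squared Euclidean distances between individuals'
    dosage vectors, rescaled to the full locus count."""
    x = geno.dosage_float()
    called = np.isfinite(x)
    x0 = np.where(called, x, 0.0)
    c = called.astype(float)
    # sum over shared loci of (xi - xj)^2, expanded to avoid NxNxL memory
    sq = x0**2
    cross = x0 @ x0.T
    si = sq @ c.T        # sum_i xi^2 over loci called in both
    shared = c @ c.T
    d2 = si + si.T - 2.0 * cross
    L = geno.n_loci
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = d2 * (L / shared)
    if not np.all(shared[np.triu_indices_from(shared, k=1)] > 0):
        raise ValueError("individual pair with no shared called loci")
    np.fill_diagonal(d2, 0.0)
    return d2


@dataclass
class AmovaResult:
    """AMOVA table plus Phi statistics.

    ``table``: per stratum (among_lineages, among_populations,
    within_populations) the df, SS, MS, variance component ``sigma2``, and
    (after a permutation test) ``alternative``, ``perm_mean`` and
    ``p_value``.
    """

    table: pd.DataFrame
    phi: dict[str, float]
    n_perm: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def components(self) -> dict[str, float]:
        return dict(zip(self.table.index, self.table["sigma2"]))


def _ss_parts(d2: np.ndarray, pop_codes: np.ndarray, grp_codes: np.ndarray):
    """Sums of squares for the 3-level hierarchy from a squared-distance
    matrix: SS_total, SS among lineages, SS among pops within lineages,
    SS within pops."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)

    def within(codes):
        ss = 0.0
        for code in np.unique(codes):
            idx = np.flatnonzero(codes == code)
            ss += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
        return ss

    ss_wp = within(pop_codes)
    ss_wg = within(grp_codes)
    return ss_total, ss_total - ss_wg, ss_wg - ss_wp, ss_wp


def _components(d2, pop_codes, grp_codes):
    """(df, SS, MS, sigma2) per stratum via the unbalanced-design coefficient
    equations."""
    n = d2.shape[0]
    pops, pop_codes = np.unique(pop_codes, return_inverse=True)
    grps, grp_codes = np.unique(grp_codes, return_inverse=True)
    n_pops, n_grps = len(pops), len(grps)
    ss_total, ss_ag, ss_ap, ss_wp = _ss_parts(d2, pop_codes, grp_codes)
    df_ag, df_ap, df_wp = n_grps - 1, n_pops - n_grps, n - n_pops
    if min(df_ag, df_ap, df_wp) < 1:
        bad = {"among_lineages": df_ag, "among_populations": df_ap,
               "within_populations": df_wp}
        stratum = min(bad, key=bad.get)
        raise ValueError(f"degenerate hierarchy: no degrees of freedom for {stratum}")
    ms_ag, ms_ap, ms_wp = ss_ag / df_ag, ss_ap / df_ap, ss_wp / df_wp
    # sample-size coefficients
    n_p = np.bincount(pop_codes).astype(float)          # individuals per pop
    n_g = np.bincount(grp_codes).astype(float)          # individuals per group
    grp_of_pop = np.empty(n_pops, dtype=int)
    for p in range(n_pops):
        grp_of_pop[p] = grp_codes[np.flatnonzero(pop_codes == p)[0]]
    sum_np2_by_g = np.bincount(grp_of_pop, weights=n_p**2, minlength=n_grps)
    n_prime = (n - (sum_np2_by_g / n_g).sum()) / df_ap
    n_dprime = ((sum_np2_by_g / n_g).sum() - (n_p**2).sum() / n) / df_ag
    n_tprime = (n - (n_g**2).sum() / n) / df_ag
    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n_prime
    sigma_a = (ms_ag - sigma_c - n_dprime * sigma_b) / n_tprime
    return (
        np.array([df_ag, df_ap, df_wp], dtype=float),
        np.array([ss_ag, ss_ap, ss_wp]),
        np.array([ms_ag, ms_ap, ms_wp]),
        np.array([sigma_a, sigma_b, sigma_c]),
        ss_total,
    )


_STRATA = ["among_lineages", "among_populations", "within_populations"]


def _codes(geno: GenotypeMatrix, popmap: PopulationMap, lineages: dict[str, str]):
    pop_of = popmap.population_of()
    reg_of_pop = popmap.region_of_population()
    pop_codes = np.array([pop_of[s] for s in geno.samples])
    missing = {reg_of_pop[p] for p in np.unique(pop_codes)} - set(lineages)
    if missing:
        raise ValueError(f"regions without a lineage assignment: {sorted(missing)}")
    grp_codes = np.array([lineages[reg_of_pop[p]] for p in pop_codes])
    return pop_codes, grp_codes


def amova(geno: GenotypeMatrix, popmap: PopulationMap,
          lineages: dict[str, str], truncate: bool = False) -> AmovaResult:
    """Three-level AMOVA; ``lineages`` maps each region to a lineage label."""
    pop_codes, grp_codes = _codes(geno, popmap, lineages)
    d2 = pairwise_sq_distances(geno)
    df, ss, ms, sig, ss_total = _components(d2, pop_codes, grp_codes)
    if truncate:
        sig = np.maximum(sig, 0.0)
    table = pd.DataFrame(
        {"df": df.astype(int), "SS": ss, "MS": ms, "sigma2": sig}, index=_STRATA)
    a, b, c = sig
    tot = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        # NaN when there is no variance at all
        phi = {
            "phi_CT": a / tot,
            "phi_SC": b / (b + c),
            "phi_ST": (a + b) / tot,
        }
    return AmovaResult(table=table, phi=phi,
                       meta={"ss_total": ss_total, "n": d2.shape[0]})


def amova_permtest(geno: GenotypeMatrix, popmap: PopulationMap,
                   lineages: dict[str, str], n_perm: int = 999,
                   seed: int = 0) -> AmovaResult:
    """AMOVA with the three-scheme randomisation test (see module docstring)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pop_codes, grp_codes = _codes(geno, popmap, lineages)
    d2 = pairwise_sq_distances(geno)
    res = amova(geno, popmap, lineages)
    obs = res.table["sigma2"].values
    tol = 1e-9 * (1.0 + np.abs(obs))
    rng = np.random.default_rng(seed)
    n = len(pop_codes)
    hits = np.zeros(3)
    perm_sum = np.zeros(3)
    n_done = np.zeros(3)

    pops = np.unique(pop_codes)
    grp_of_pop = {p: grp_codes[np.flatnonzero(pop_codes == p)[0]] for p in pops}
    lineage_labels = np.array([grp_of_pop[p] for p in pops])
    can_perm_lineage = len(np.unique(lineage_labels)) > 1 and len(pops) > 2

    for _ in range(n_perm):
        # scheme 1: individuals among populations within lineages ("less")
        pc = pop_codes.copy()
        for g in np.unique(grp_codes):
            idx = np.flatnonzero(grp_codes == g)
            pc[idx] = pc[rng.permutation(idx)]
        sig = _components(d2, pc, grp_codes)[3]
        perm_sum[2] += sig[2]
        n_done[2] += 1
        if sig[2] < obs[2] - tol[2]:
            hits[2] += 1
        # scheme 2: individuals across all populations ("greater")
        perm = rng.permutation(n)
        sig = _components(d2, pop_codes[perm], grp_codes[perm])[3]
        # note: permuting (pop, lineage) jointly then testing the
        # among-population component against its null
        perm_sum[1] += sig[1]
        n_done[1] += 1
        if sig[1] > obs[1] + tol[1]:
            hits[1] += 1
        # scheme 3: whole populations across lineages ("greater")
        if can_perm_lineage:
            shuffled = dict(zip(pops, lineage_labels[rng.permutation(len(pops))]))
            gc = np.array([shuffled[p] for p in pop_codes])
            sig = _components(d2, pop_codes, gc)[3]
            perm_sum[0] += sig[0]
            n_done[0] += 1
            if sig[0] > obs[0] + tol[0]:
                hits[0] += 1
    p = np.full(3, np.nan)
    mean = np.full(3, np.nan)
    ok = n_done > 0
    p[ok] = (hits[ok] + 1) / (n_done[ok] + 1)
    mean[ok] = perm_sum[ok] / n_done[ok]
    if not can_perm_lineage:
        logger.warning("too few populations to permute across lineages; p = NA")
    res.table["alternative"] = ["greater", "greater", "less"]
    res.table["perm_mean"] = mean
    res.table["p_value"] = p
    res.n_perm = n_perm
    return res
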
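"""Synthetic study-design datasets.

Emulates the sampling design of a latitudinal ddRAD survey: 12 populations in
4 regions (3 populations per region, 10 diploids each) along a ~1400 km
south-to-north transect, genotyped at 10^3-10^4 unlinked biallelic SNPs.
Neutral loci are drawn from the structured coalescent of a demographic
scenario (regions are the coalescent demes; populations subdivide a region's
sample, consistent with the demographic models treating regions as panmictic).
A configurable minority of loci is "spiked" with a deterministic logistic
allele-frequency cline in the environmental covariate plus binomial sampling
noise, and flagged as ground-truth selected in the locus metadata.

The environmental covariate emulates growing-season length (days): a linear
function of latitude (about -8 days per degree northwards from ~200 days in
the south) plus weather-station-like noise.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import expit

from .coalescent import _strides, _tree_once
from .datamodel import GenotypeMatrix, PopulationMap
from .scenarios import REGIONS, DemographicScenario, MergeEvent, scenario_catalogue

logger = logging.getLogger(__name__)

#: Region reference latitudes (degrees N), south to north, ~1400 km apart end to end.
REGION_LATITUDES = {"Skane": 55.7, "Uppland": 59.9, "Vasterbotten": 64.0, "Norrbotten": 65.8}
REGION_LONGITUDES = {"Skane": 13.5, "Uppland": 17.6, "Vasterbotten": 19.6, "Norrbotten": 21.7}

#: Growing-season length model: days at 55.5 degrees N and decay per degree.
ENV_INTERCEPT = 200.0
ENV_SLOPE_PER_DEGREE = -8.0
ENV_NOISE_SD = 3.0


def default_scenario() -> DemographicScenario:
    """A plausible dual-route truth with central contact migration (the
    M4-style topology), used for bundled demo data.

    Sizes and times are calibrated to the differentiation scale of the
    emulated survey: larger southern demes (diploid N_e 15-20k) and smaller
    northern ones (4.5-5k) with route merges ~800-1200 generations ago and a
    common ancestor ~3000 generations (~9 kya at 3 years/generation) ago
    give a maximum pairwise F_ST around 0.15-0.19 and a clear south-to-north
    diversity decline.
    """
    cat = scenario_catalogue()
    params = dict(
        ne_skane=20_000.0, ne_uppland=15_000.0,
        ne_vasterbotten=5000.0, ne_norrbotten=4500.0,
        t1=800.0, dt2=400.0, dt3=1800.0, r1=1.0, r2=1.0, r3=0.5,
        m_uv=1e-3, m_vu=1e-3,
    )
    return cat["M4"].build(params)


def study_popmap(
    n_populations_per_region: int = 3,
    n_diploids_per_population: int = 10,
    regions: list[str] | None = None,
    seed: int = 0,
) -> PopulationMap:
    """Population map for the emulated design: populations on a latitudinal
    gradient within each region, environment decreasing with latitude."""
    regions = regions or list(REGIONS)
    rng = np.random.default_rng(seed)
    rows = []
    for r in regions:
        base_lat = REGION_LATITUDES.get(r, 55.0 + 3.0 * regions.index(r))
        base_lon = REGION_LONGITUDES.get(r, 14.0 + 2.0 * regions.index(r))
        for p in range(n_populations_per_region):
            lat = base_lat + (p - (n_populations_per_region - 1) / 2) * 0.4
            lon = base_lon + rng.normal(0, 0.2)
            env = (
                ENV_INTERCEPT
                + ENV_SLOPE_PER_DEGREE * (lat - 55.5)
                + rng.normal(0, ENV_NOISE_SD)
            )
            pop = f"{r}{p + 1}"
            for i in range(n_diploids_per_population):
                rows.append(
                    dict(sample=f"{pop}_{i + 1:02d}", population=pop, region=r,
                         latitude=round(lat, 4), longitude=round(lon, 4),
                         environment=round(env, 2))
                )
    return PopulationMap(table=pd.DataFrame(rows))


def _neutral_genotypes(scenario, region_diploids, n_loci, rng):
    """Dosage matrix (sum over 2*n diploids x n_loci) of coalescent loci with
    one mutation each, placed proportionally to branch length (always
    polymorphic in the total sample)."""
    n_per_deme = np.zeros(len(scenario.demes), dtype=np.int64)
    for d, nd in region_diploids.items():
        n_per_deme[scenario.demes.index(d)] = 2 * nd
    strides, _ = _strides(n_per_deme)
    sizes, mig, ev_t, ev_s, ev_d, ev_r = scenario.arrays()
    n_leaves = int(n_per_deme.sum())
    n_ind = n_leaves // 2
    out = np.zeros((n_ind, n_loci), dtype=np.int8)
    for j in range(n_loci):
        seed = int(rng.integers(0, 2**31 - 1))
        status, parent, ntime, br_cell, br_w, br_node, nb = _tree_once(
            seed, sizes, mig, ev_t, ev_s, ev_d, ev_r, n_per_deme, strides)
        if status != 0:
            raise ValueError("non-coalescing scenario")
        w = br_w[:nb]
        pick = rng.choice(nb, p=w / w.sum())
        node = br_node[pick]
        # leaves under the chosen node
        n_nodes = 2 * n_leaves - 1
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        for v in range(n_nodes - 1):
            children[parent[v]].append(v)
        stack = [int(node)]
        while stack:
            v = stack.pop()
            if v < n_leaves:
                out[v // 2, j] += 1
            else:
                stack.extend(children[v])
    return out


def simulate_snp_dataset(
    scenario: DemographicScenario | None = None,
    n_loci: int = 2000,
    seed: int = 0,
    spiked_fraction: float = 0.0,
    effect_size: float = 2.0,
    n_populations_per_region: int = 3,
    n_diploids_per_population: int = 10,
    popmap: PopulationMap | None = None,
) -> tuple[GenotypeMatrix, PopulationMap]:
    """Simulate a study-like SNP dataset.

    Parameters
    ----------
    scenario : DemographicScenario, optional
        Defaults to :func:`default_scenario` (dual routes with contact
        migration).  Regions of the population map must match scenario demes.
    n_loci : int
        Total loci; all polymorphic in the full sample by construction.
    spiked_fraction : float in [0, 1)
        Fraction of loci carrying an environment-associated logistic cline
        (flagged ``selected`` in locus metadata); the rest are neutral
        coalescent loci.
    effect_size : float
        Logit slope of the spiked cline per standard deviation of the
        population environment values.
    """
    if not 0 <= spiked_fraction < 1:
        raise ValueError("spiked_fraction must be in [0, 1)")
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    scenario = scenario or default_scenario()
    rng = np.random.default_rng(seed)
    if popmap is None:
        popmap = study_popmap(
            n_populations_per_region,
            n_diploids_per_population,
            regions=list(scenario.demes),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    ptab = popmap.population_table()
    reg_of_pop = popmap.region_of_population()
    pops = popmap.populations
    n_spiked = int(round(spiked_fraction * n_loci))
    if spiked_fraction > 0 and n_spiked == 0:
        logger.warning("spiked_fraction * n_loci < 1: no loci spiked")
    n_neutral = n_loci - n_spiked

    # diploids per region, populations concatenated in popmap order
    region_pops: dict[str, list[str]] = {}
    for p in pops:
        region_pops.setdefault(reg_of_pop[p], []).append(p)
    pop_sizes = popmap.table.groupby("population")["sample"].count()
    region_diploids = {r: int(sum(pop_sizes[p] for p in ps)) for r, ps in region_pops.items()}

    neutral = _neutral_genotypes(scenario, region_diploids, n_neutral, rng)

    # sample ordering: by region (scenario deme order), then population, then individual
    ordered_samples = []
    for r in scenario.demes:
        for p in region_pops.get(r, []):
            ordered_samples.extend(
                popmap.table.loc[popmap.table["population"] == p, "sample"]
            )
    n_ind = len(ordered_samples)

    # spiked loci: deterministic logistic cline in the environment + binomial noise
    env = ptab["environment"]
    z_env = (env - env.mean()) / env.std(ddof=0)
    spiked = np.zeros((n_ind, n_spiked), dtype=np.int8)
    sample_pop = [popmap.population_of()[s] for s in ordered_samples]
    for j in range(n_spiked):
        alpha = rng.normal(0.0, 0.75)
        p_pop = {p: expit(alpha + effect_size * z_env[p]) for p in pops}
        freqs = np.array([p_pop[p] for p in sample_pop])
        spiked[:, j] = rng.binomial(2, freqs).astype(np.int8)

    calls = np.concatenate([neutral, spiked], axis=1)
    selected = np.zeros(n_loci, dtype=bool)
    selected[n_neutral:] = True
    order = rng.permutation(n_loci)
    calls = calls[:, order]
    selected = selected[order]
    loci = pd.DataFrame(
        {
            "id": [f"L{j + 1:06d}" for j in range(n_loci)],
            "chrom": "1",
            "pos": np.arange(1, n_loci + 1) * 1000,
            "ref": "A",
            "alt": "T",
            "selected": selected,
        }
    )
    geno = GenotypeMatrix(samples=list(ordered_samples), loci=loci, calls=calls)
    return geno, popmap


def island_scenario(n_demes: int = 2, ne: float = 1000.0, scaled_mig: float = 1.0,
                    t_merge: float = 1e7) -> DemographicScenario:
    """Finite island model: ``n_demes`` demes of diploid size ``ne`` with
    symmetric migration at ``2*N*m = scaled_mig`` (an ancient merge far in
    the past makes the model proper)."""
    demes = [f"D{i + 1}" for i in range(n_demes)]
    m = scaled_mig / (2.0 * ne)
    mig = {(a, b): m for a in demes for b in demes if a != b}
    events = [MergeEvent(t_merge, d, demes[0]) for d in demes[1:]]
    return DemographicScenario(demes=demes, ne={d: ne for d in demes},
                               events=events, migration=mig)
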
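"""Shared fixtures: all data is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from popcline import (
    DemographicScenario,
    GenotypeMatrix,
    PopulationMap,
    island_scenario,
    simulate_snp_dataset,
)


@pytest.fixture(scope="session")
def tiny_geno() -> GenotypeMatrix:
    """4 samples x 5 loci with one missing call."""
    calls = np.array(
        [
            [0, 1, 2, 0, 1],
            [1, 1, 0, 0, 2],
            [2, 0, 0, 1, 1],
            [0, 2, 1, -1, 0],
        ],
        dtype=np.int8,
    )
    loci = pd.DataFrame(
        {
            "id": [f"snp{i}" for i in range(5)],
            "chrom": ["1", "1", "1", "2", "2"],
            "pos": [100, 200, 300, 50, 80],
            "ref": list("ACGTA"),
            "alt": list("GTACC"),
        }
    )
    return GenotypeMatrix(samples=["s1", "s2", "s3", "s4"], loci=loci, calls=calls)


@pytest.fixture(scope="session")
def tiny_popmap() -> PopulationMap:
    table = pd.DataFrame(
        {
            "sample": ["s1", "s2", "s3", "s4"],
            "population": ["P1", "P1", "P2", "P2"],
            "region": ["south", "south", "north", "north"],
            "latitude": [56.0, 56.0, 65.0, 65.0],
            "longitude": [13.0, 13.0, 21.0, 21.0],
            "environment": [200.0, 200.0, 120.0, 120.0],
        }
    )
    return PopulationMap(table=table)


@pytest.fixture(scope="session")
def panmictic_scenario() -> DemographicScenario:
    return DemographicScenario(demes=["A"], ne={"A": 5000.0})


@pytest.fixture(scope="session")
def study_dataset():
    """Study-design dataset: 12 populations x 10 diploids, 1200 loci, 5%
    spiked with a strong environmental cline."""
    return simulate_snp_dataset(n_loci=1200, seed=20260927, spiked_fraction=0.05,
                                effect_size=2.0)


@pytest.fixture(scope="session")
def two_deme_spiked():
    """Two-deme island dataset (moderate drift) with spiked clinal loci,
    used by the scan power checks."""
    sc = island_scenario(n_demes=2, ne=2000.0, scaled_mig=4.0)
    return simulate_snp_dataset(scenario=sc, n_loci=2000, seed=7, spiked_fraction=0.05,
                                effect_size=2.0, n_populations_per_region=3,
                                n_diploids_per_population=10)


def _scan_power(scan_fn, seed0):
    """Power and realised FDR of a scan over 10 replicate spiked two-deme
    datasets (5% spiked loci, effect size 2 logits per env SD)."""
    power, fdr_real = [], []
    sc = island_scenario(n_demes=2, ne=2000.0, scaled_mig=4.0)
    for rep in range(10):
        geno, popmap = simulate_snp_dataset(
            scenario=sc, n_loci=2000, seed=seed0 + rep, spiked_fraction=0.05,
            effect_size=2.0, n_populations_per_region=3,
            n_diploids_per_population=10)
        res = scan_fn(geno, popmap)
        sel = geno.loci["selected"].values
        flag = res.table["outlier"].values.astype(bool)
        power.append(flag[sel].mean())
        fdr_real.append((flag & ~sel).sum() / max(flag.sum(), 1))
    return np.array(power), np.array(fdr_real)


@pytest.fixture(scope="session")
def pcadapt_power():
    from popcline import pcadapt_scan

    return _scan_power(lambda g, pm: pcadapt_scan(g, k=1), seed0=6000)


@pytest.fixture(scope="session")
def lfmm_power():
    from popcline import lfmm_ridge_scan

    return _scan_power(lambda g, pm: lfmm_ridge_scan(g, pm, k=1), seed0=8000)


@pytest.fixture(scope="session")
def null_panmictic_dataset(panmictic_scenario):
    """Single panmictic deme at the study sample size (120 diploids), 5000
    loci: the null condition for scan calibration."""
    return simulate_snp_dataset(scenario=panmictic_scenario, n_loci=5000, seed=11,
                                n_populations_per_region=1,
                                n_diploids_per_population=120)
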
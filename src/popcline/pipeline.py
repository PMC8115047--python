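"""End-to-end orchestration: one config, all stages, a reproducible manifest.

Stage order mirrors the analysis design: selection scans run on the full SNP
set; the union of scan outliers is removed; every downstream stage (summary
statistics, isolation by distance, folded-mSFS demographic fitting, AMOVA,
admixture clustering) consumes the neutral set.  Every stage writes TSV
tables into the output directory and records its parameters, seeds and locus
bookkeeping in ``manifest.json``, which suffices to reproduce any stage in
isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .admixture import cross_validate, admixture_fit
from .amova import amova_permtest
from .datamodel import GenotypeMatrix, PopulationMap
from .demography import fit_scenario, model_select
from .scan import lfmm_ridge_scan, outlier_bed, partition_outliers, pcadapt_scan
from .scenarios import scenario_catalogue
from .sfs import build_folded_msfs
from .simulate import simulate_snp_dataset
from .sumstats import allelic_richness, diversity, fst_matrix, mantel_ibd, regional_tests

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated run configuration.

    Exactly one of ``vcf``+``popmap`` (input paths) or ``synthetic``
    (generator parameters) must be given; ``seed`` is mandatory.
    """

    outdir: str
    seed: int
    vcf: str | None = None
    popmap: str | None = None
    synthetic: dict | None = None
    stages: dict = field(default_factory=dict)
    scan: dict = field(default_factory=lambda: {"k": 4, "alpha": 0.05})
    ibd: dict = field(default_factory=lambda: {"permutations": 99_999})
    sfs: dict = field(default_factory=lambda: {
        "n_per_region": 7, "models": ["M2", "M4"], "n_sim": 10_000,
        "replicates": 2, "maxiter": 25})
    amova: dict = field(default_factory=lambda: {"permutations": 999})
    cluster: dict = field(default_factory=lambda: {
        "k_min": 1, "k_max": 6, "repeats": 5, "lambda_geo": 1.0})
    lineages: dict = field(default_factory=lambda: {
        "Skane": "south", "Uppland": "south",
        "Vasterbotten": "north", "Norrbotten": "north"})

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        has_input = self.vcf is not None or self.popmap is not None
        if has_input and self.synthetic is not None:
            raise ValueError("config must give either input paths or a synthetic block, not both")
        if not has_input and self.synthetic is None:
            raise ValueError("config needs input paths (vcf+popmap) or a synthetic block")
        if has_input and (self.vcf is None or self.popmap is None):
            raise ValueError("both vcf and popmap paths are required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))


def load_or_simulate(config: RunConfig) -> tuple[GenotypeMatrix, PopulationMap]:
    if config.synthetic is not None:
        syn = dict(config.synthetic)
        syn.setdefault("seed", config.seed)
        return simulate_snp_dataset(**syn)
    return pio.read_vcf(config.vcf), pio.read_popmap(config.popmap)


def run_all(config: RunConfig) -> dict:
    """Execute all enabled stages; returns the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    rng = np.random.default_rng(config.seed)

    def stage(name):
        t0 = time.time()
        logger.info("stage %s ...", name)
        return t0

    def done(name, t0, **info):
        manifest["stages"][name] = {"wall_s": round(time.time() - t0, 2), **info}

    t0 = stage("input")
    geno, popmap = load_or_simulate(config)
    pio.write_vcf(geno, out / "dataset.vcf")
    pio.write_popmap(popmap, out / "popmap.tsv")
    done("input", t0, n_samples=geno.n_samples, n_loci=geno.n_loci,
         synthetic=config.synthetic is not None)

    neutral_geno = geno
    if config.enabled("scan"):
        t0 = stage("scan")
        k = config.scan.get("k", 4)
        alpha = config.scan.get("alpha", 0.05)
        res_pca = pcadapt_scan(geno, k=k, alpha=alpha,
                               random_state=int(rng.integers(0, 2**31 - 1)))
        res_env = lfmm_ridge_scan(geno, popmap, k=k, alpha=alpha)
        pio.write_table(res_pca.table, out / "scan_pca.tsv", index=False)
        pio.write_table(res_env.table, out / "scan_env.tsv", index=False)
        if {"chrom", "pos"}.issubset(geno.loci.columns):
            bed = pd.concat([outlier_bed(res_pca, geno), outlier_bed(res_env, geno)])
            pio.write_table(bed, out / "outliers.bed.tsv", index=False)
        part = partition_outliers(res_pca.outlier_ids, res_env.outlier_ids,
                                  geno.locus_ids)
        neutral_geno = geno.subset_loci(np.array(part["neutral"]))
        done("scan", t0, k=k, alpha=alpha, gif_pca=res_pca.gif, gif_env=res_env.gif,
             n_pca=part["n_a"], n_env=part["n_b"], n_overlap=part["n_overlap"],
             n_union=part["n_union"], n_neutral=part["n_neutral"],
             outlier_union=part["union"])

    if config.enabled("sumstats"):
        t0 = stage("sumstats")
        div = diversity(neutral_geno, popmap)
        g_raref = 2 * min(
            popmap.table.groupby("population")["sample"].count().min(), 10)
        div[f"ar_g{g_raref}"] = allelic_richness(neutral_geno, popmap, g=g_raref)
        fst = fst_matrix(neutral_geno, popmap)
        pio.write_table(div, out / "diversity.tsv")
        pio.write_table(fst, out / "fst_matrix.tsv")
        regions = popmap.regions
        south, north = regions[: len(regions) // 2], regions[len(regions) // 2:]
        welch = regional_tests(div, popmap, south, north)
        pio.write_table(welch, out / "regional_tests.tsv")
        done("sumstats", t0, fst_max=float(np.nanmax(fst.values)))

        if config.enabled("ibd"):
            t0 = stage("ibd")
            n_perm = config.ibd.get("permutations", 99_999)
            mr = mantel_ibd(fst, popmap, n_perm=n_perm,
                            seed=int(rng.integers(0, 2**31 - 1)))
            (out / "ibd.json").write_text(json.dumps(
                {"r": mr.r, "p_value": mr.p_value, "n_perm": mr.n_perm}, indent=1))
            done("ibd", t0, r=mr.r, p_value=mr.p_value, n_perm=mr.n_perm)

    if config.enabled("sfs"):
        t0 = stage("sfs")
        cfgs = config.sfs
        npr = cfgs.get("n_per_region", 7)
        obs = build_folded_msfs(neutral_geno, popmap, n_per_region=npr)
        cat = scenario_catalogue()
        sample_config = {r: npr for r in obs.regions}
        fits = []
        for name in cfgs.get("models", ["M2", "M4"]):
            fits.append(fit_scenario(
                obs, cat[name], sample_config, n_sim=cfgs.get("n_sim", 10_000),
                n_replicates=cfgs.get("replicates", 2),
                maxiter=cfgs.get("maxiter", 25),
                seed=int(rng.integers(0, 2**31 - 1))))
        table = model_select(fits)
        pio.write_table(table, out / "model_selection.tsv")
        done("sfs", t0, n_per_region=npr, S=obs.total,
             best_model=str(table["AIC"].idxmin()),
             aic={n: float(v) for n, v in table["AIC"].items()})

    if config.enabled("amova"):
        t0 = stage("amova")
        n_perm = config.amova.get("permutations", 999)
        res = amova_permtest(neutral_geno, popmap, config.lineages,
                             n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1)))
        pio.write_table(res.table, out / "amova.tsv")
        done("amova", t0, n_perm=n_perm,
             p_values={s: (None if np.isnan(p) else float(p))
                       for s, p in res.table["p_value"].items()})

    if config.enabled("cluster"):
        t0 = stage("cluster")
        cf = config.cluster
        ks = range(cf.get("k_min", 1), cf.get("k_max", 6) + 1)
        cv = cross_validate(neutral_geno, popmap, k_values=ks,
                            lambda_geo=cf.get("lambda_geo", 1.0),
                            n_init=cf.get("repeats", 5),
                            seed=int(rng.integers(0, 2**31 - 1)))
        pio.write_table(cv.scores.rename("cv_rmse").to_frame(), out / "cluster_cv.tsv")
        est = admixture_fit(neutral_geno, popmap, k=cv.best_k,
                            lambda_geo=cf.get("lambda_geo", 1.0),
                            seed=int(rng.integers(0, 2**31 - 1)),
                            n_init=cf.get("repeats", 5))
        qdf = pd.DataFrame(est.Q_, index=neutral_geno.samples,
                           columns=[f"Q{i + 1}" for i in range(est.Q_.shape[1])])
        pio.write_table(qdf, out / "admixture_Q.tsv")
        done("cluster", t0, best_k=cv.best_k,
             cv_scores={int(k): float(v) for k, v in cv.scores.items()})

    manifest["outputs"] = sorted(p.name for p in out.iterdir() if p.is_file())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
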
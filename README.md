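# popcline

Population-genomic inference of postglacial recolonisation along latitudinal
gradients, built for reduced-representation (RAD-style) SNP surveys of the
kind used to ask how a species re-entered Scandinavia after the Last Glacial
Maximum: from one direction, or from two directions meeting at a contact
zone?

The package provides, as a library, an sklearn-style estimator collection and
a command-line pipeline:

* **Synthetic data / coalescent simulation** — an exact structured
  coalescent over multiple demes with merge events, resizes and migration.
  It generates study-like genotype datasets (12 populations in 4 regions x
  10 diploids, unlinked biallelic SNPs, an environmental gradient, an
  optional minority of loci with environment-associated allele-frequency
  clines) and Monte-Carlo expected folded multidimensional site-frequency
  spectra (mSFS).
* **Selection scans** — `PCAOutlierScan` (per-locus z-scores on K principal
  components, robust Mahalanobis distance D², genomic-inflation calibration,
  χ²_K p-values, Benjamini–Hochberg FDR) and `LatentFactorRidgeScan`
  (gene–environment association with K latent factors and a ridge penalty).
  The union of both outlier sets is removed to form the neutral SNP panel.
* **Summary statistics** — unbiased per-site π, H_e/H_o, F_is, rarefied
  allelic richness, multilocus Weir–Cockerham F_ST, and isolation by
  distance via a Mantel test of F_ST/(1−F_ST) against ln(great-circle km).
* **Demographic model selection** — six colonisation scenarios (M1/M2:
  single route from north/south; M3–M6: dual routes, with or without
  contact-zone migration) fitted to the observed folded mSFS by
  simulation-based composite likelihood, ranked by AIC = 2k − 2 ln CL and
  Akaike weights.
* **Structure inference** — three-level AMOVA (individuals / populations /
  lineages) with a 999-permutation randomisation test, and geographically
  penalised least-squares admixture (`AdmixtureLS`) with masked-entry
  cross-validation over K.

## Worked example

```python
import numpy as np
from popcline import (simulate_snp_dataset, pcadapt_scan, lfmm_ridge_scan,
                      partition_outliers, fst_matrix, mantel_ibd)

geno, popmap = simulate_snp_dataset(n_loci=2000, seed=42,
                                    spiked_fraction=0.05, effect_size=2.0)
a = pcadapt_scan(geno, k=4)
b = lfmm_ridge_scan(geno, popmap, k=4)
part = partition_outliers(a.outlier_ids, b.outlier_ids, geno.locus_ids)
print(part["n_a"], part["n_b"], part["n_overlap"], part["n_union"])
neutral = geno.subset_loci(np.array(part["neutral"]))
fst = fst_matrix(neutral, popmap)
res = mantel_ibd(fst, popmap, n_perm=9999, seed=1)
print(f"max FST = {np.nanmax(fst.values):.3f}, Mantel r = {res.r:.3f}, p = {res.p_value:.4f}")
```

prints (seed 42):

```
75 72 68 79
max FST = 0.227, Mantel r = 0.706, p = 0.0002
```

75 loci are flagged by the PCA scan and 72 by the gene–environment scan, 68
by both, so 79 loci (a subset of the 100 truly spiked ones plus a handful of
false positives) are removed before the neutral-panel analyses.
Differentiation tops out near 0.23 between the southernmost and northernmost
populations and genetic distance increases with geographic distance
(isolation by distance, p near the permutation floor).

The same stages are available as subcommands of one executable
(`popcline simulate | scan-pca | scan-env | scan-combine | sumstats | ibd |
sfs-build | sfs-fit | sfs-select | amova | cluster | run-all`); `run-all`
executes everything from one YAML config and writes a `manifest.json` that
records every seed, parameter and locus-bookkeeping decision.

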
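# Methods

This note documents the models, estimators and numerical choices behind
`popcline`, and what the synthetic-data tests do and do not establish.

## Coalescent engine

The simulator implements the exact single-locus structured coalescent.
Backward in time, each open deme `d` with `k_d` lineages and diploid size
`N_d` contributes a coalescence rate `k_d (k_d - 1) / (4 N_d)` per
generation; lineages additionally migrate between demes at the
per-generation probabilities of the scenario's migration matrix.  Waiting
times are exponential; merge events are applied at their exact times (the
source deme's lineages move to the destination, the source closes, and the
destination size is multiplied by its resize factor).  A configuration that
cannot fully coalesce (isolated demes with no remaining events) is an error.

Because every locus is a single unlinked SNP, no recombination machinery is
needed: the exact coalescent and the sequentially-Markovian approximations
used by large-scale SFS simulators coincide per locus.  Mutations follow the
infinite-sites model with exactly one segregating site retained per locus,
placed on the genealogy proportionally to branch length; any such placement
is polymorphic in the total sample, so conditioning on polymorphism is
automatic.  The engine records, for every non-root lineage, its per-deme
descendant-leaf counts (fixed at the lineage's birth, unchanged by
migration), so a single pass accumulates both branch-length-weighted
expected SFS contributions and per-locus sampled mutation cells.  The hot
loop is numba-compiled; a seed reproduces bit-identical output.

Cross-checks: mean TMRCA for a pair (`2N`), expected total tree length
(`4N * H_{n-1}`), the neutral folded SFS shape
`(1/i + 1/(2n-i)) / (1 + delta_{i,n})`, island-model F_ST, and agreement
with `msprime` on a two-deme split model.

## Scenario catalogue

Six templates describe the recolonisation of a four-region south-to-north
transect (Skane, Uppland, Vasterbotten, Norrbotten).  M1 and M2 are serial
single-route topologies entering from the north and the south respectively;
M3–M6 derive two routes from one ancestral population and differ in whether
Uppland attaches to the southern (M3/M4) or northern (M5/M6) route; M4 and
M6 add secondary-contact migration between the two central regions (Uppland
and Vasterbotten), active from the present until the first route-internal
merge.  Free parameters: four contemporary diploid sizes (uniform priors,
default 500–50,000), three divergence times parameterised as T1 plus
positive increments so T1 <= T2 <= T3 (uniform, default 50–5,000
generations), three resize factors applied to the receiving deme at each
merge (log-uniform, 0.01–100), and for M4/M6 two directed contact migration
rates (log-uniform, 1e-5–1e-2 per generation).  This gives k = 10 or k = 12
free parameters with complex (derived) parameters counted once.  Generation
time is 3 years and the per-site mutation rate 7.7e-10 (an anuran estimate);
neither enters the conditioned-SFS likelihood, but both are carried for
interpretation of fitted times.  Prior bounds are part of the configuration:
they are not printed in the source study, so the defaults above are
documented package choices.

## Folded mSFS and composite likelihood

The joint spectrum over R regions is a tensor indexed by per-region derived
counts.  Observed spectra are built by projecting each locus's per-region
derived count from the called chromosomes down to a fixed `2n` via the
hypergeometric expectation (fractional contributions), then folding by the
global minor allele; cells invisible to polymorphism (global count 0 or
maximal) are masked, and at the half-fold boundary the canonical cell is the
one with the smaller flat index.  Downsampling deliberately moves rare-site
mass into masked monomorphic cells, mirroring the practice of projecting
down to reduce missing-data artefacts.

The composite log-likelihood is `sum_i m_i ln p_i` over unmasked cells with
observed count `m_i > 0`; expected proportions below `1/(10 n_sim)` are
floored there to avoid `-inf` from finite simulation.  The saturated
likelihood `sum_i m_i ln(m_i / S)` bounds it above (Gibbs).  Fitting maps
parameters to the prior unit cube (linear or log-linear per prior) and runs
Nelder–Mead from prior draws, with every evaluation of one replicate reusing
one simulation seed (common random numbers) so the optimiser sees a
deterministic surface; independent replicates (default 3) restart from fresh
draws and seeds and the best is kept.  Model selection uses
`AIC = 2k - 2 ln CL` on the natural-log scale — the published model table's
arithmetic is consistent with exactly this convention, which fixes the
likelihood scale — and Akaike weights computed in log space.

Identifiability note: for a constant-size single deme the conditioned folded
SFS is scale-free, so N_e alone is not identifiable.  The N_e-recovery test
therefore uses a single deme with an ancestral resize at a fixed absolute
time, which breaks the scale invariance; recovery is then within a few
percent at S = 50,000.

## Selection scans

Genotypes are centred and scaled by `sqrt(2 p (1-p))` with per-locus mean
imputation of missing calls.  Loci with minor-allele frequency below 0.05
are excluded from scans (with 0.5/(2n) as a hard floor): coalescent data are
dominated by rare variants whose discrete scaled genotypes make the z-score
cloud heavy-tailed, and at the method's standard 0.05 filter the null
type-I error calibrates (empirically ~0.06 at 120 samples and 5,000 loci).

PCA scan: each locus is regressed on the leading K principal-component
scores; the K-vector of z-scores is summarised by a Mahalanobis distance
using a minimum-covariance-determinant location/scatter (breakdown ~50%,
deterministic given `random_state`); the genomic inflation factor
`lambda = median(D^2)/median(chi^2_K)` rescales distances before chi^2_K
upper-tail p-values.  Gene–environment scan: `Y = X B' + U V' + E` with a
ridge penalty; latent factors U come from the SVD of Y projected off the
shrunken fixed effect, and per-locus z-scores from the OLS of each locus on
(X, U); `K = 0` reduces exactly to simple regression (normal-scale
p-values).  Genomic-inflation calibration is applied in both scans for
symmetry and is switchable.  Benjamini–Hochberg q-values flag outliers at
FDR 0.05 ("q-value below 0.05" is read as FDR control); the union of both
scans' outliers is removed and all downstream stages consume the neutral
panel.

## Summary statistics

Per-site diversity uses the unbiased estimator `2 p (1-p) n/(n-1)` over
called chromosomes; H_e carries the same correction so pi and H_e coincide
per site, and a locus contributes to a population where at least two
individuals are called.  F_is = 1 − H_o/H_e from multilocus means with 0/0
defined as 0.  Pairwise F_ST is Weir–Cockerham (1984) with ratio-of-sums
multilocus combination; negative estimates are reported as computed.  The
island-model oracle used in tests is the between-deme-pair form
`1/(1 + 4Nm d/(d-1))`, which is the quantity the estimator targets (the
classical `1/(1 + 4Nm (d/(d-1))^2)` refers to total-population pairs).
Rarefied allelic richness is the exact expectation
`sum_a [1 − C(N−N_a, g)/C(N, g)]`, computed in log-gamma space.  Geographic
distances are haversine on a spherical Earth (R = 6371 km); isolation by
distance is a one-sided (greater) Mantel test of `F_ST/(1−F_ST)` against
ln km with simultaneous row/column permutation and the add-one p convention
(default 99,999 permutations; an exact enumeration mode exists for small
matrices).

## AMOVA

Three-level hierarchy on squared Euclidean distances between dosage vectors
(pairwise-complete loci, rescaled to the full locus count); variance
components via the standard unbalanced-design coefficient equations;
Phi-statistics from components; negative components reported as computed
(a `truncate` switch exists).  The randomisation test (default 999
permutations) uses three schemes — individuals among populations within
lineages (alternative "less" for the within component), individuals across
all populations ("greater" for the among-population component), and whole
populations across lineages ("greater" for the among-lineage component).
Permuted statistics are counted when strictly more extreme than the
observed one; the +1 of the add-one convention stands for the observed
labelling itself, so relabelings that merely re-create the observed
partition do not inflate p and fully separated data attain the floor
`1/(n_perm+1)`.  Whether the lineage stratum should shuffle populations or
individuals is a genuinely open design point; population-level shuffling is
the default and the schemes are documented here so the alternative is a
small change.

## Admixture clustering

`X ~ Q G` on dosages/2, Q rows on the probability simplex, G in [0, 1],
plus a geographic penalty `lambda_geo tr(Q' L Q)` with L the graph Laplacian
of `W_ij = exp(-d_ij / sigma)` over sample coordinates, `sigma` the median
nonzero inter-population distance, and L normalised to unit mean degree so
`lambda_geo` weights the penalty relative to the per-sample reconstruction
error (default 1.0, a gentle smoothing).  Alternating projected least
squares: the G update is a clipped normal-equation solve, the Q update an
exact Sylvester solve followed by row-wise simplex projection; multi-start
(default 50 restarts) keeps the best objective.  K = 1 has the closed form
Q = 1, G = column means.  Cross-validation hides a fraction of entries
(default 10%), re-imputes them EM-style over a few fit rounds, and scores
the RMSE of the reconstructed dosages on the hidden entries; the suggested
K is the smallest K >= 2 whose improvement over K−1 falls below 25% of the
K=1→2 improvement.  Tests compare clusterings up to label permutation.

## Synthetic study design

The generator emulates the survey layout: 4 regions spanning ~10 degrees of
latitude (~1400 km), 3 populations per region, 10 diploids each.
Growing-season length is modelled as `200 − 8 (lat − 55.5)` days with
weather-noise SD 3 days — a linear stand-in for observed station data.
Neutral loci come from the coalescent with regions as demes (populations
subdivide a region's sample, consistent with the demographic models treating
regions as panmictic — so the generator produces no within-region
substructure).  Spiked loci follow a deterministic logistic cline,
`p = expit(alpha + beta z_env)` with per-locus `alpha ~ N(0, 0.75)` and
effect size `beta` in logits per SD of the population environment (default
2.0, the documented threshold at which both scans reach >=80% power at
realised FDR <=10% in the two-deme test condition), plus binomial sampling
noise.  The default demographic truth is the dual-route-with-contact
topology calibrated to the survey's printed differentiation scale (maximum
pairwise F_ST ~0.15–0.2, clear south-to-north diversity decline).

What passing tests show — and do not.  The synthetic data are unlinked,
cleanly biallelic, missing-data-free by default, and carry environmental
effects that are exactly logistic in a single covariate.  Real
reduced-representation data add linkage within tags, genotyping error and
allele dropout, missingness correlated with coverage, and selection regimes
far from single-locus logistic clines; power and calibration results here
bound the idealised regime only.

## Problem sizes

Defaults in tests and the acceptance script are desk-scale, chosen as the
package's own study conditions: 1,200–5,000 SNPs, 120 diploids, 10,000
coalescent simulations per likelihood evaluation, 2–3 optimiser restarts
with <=25 Nelder–Mead iterations, 999 AMOVA and 9,999 Mantel permutations.
The topology-recovery check fits the generating dual-route model and the
single-route rival to 10 replicate 5,000-SNP spectra at 4 regions x 7
diploids and requires the generating topology to win by AIC in at least 8.
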
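"""Diversity and differentiation statistics, and isolation by distance.

Estimators
----------
* per-site nucleotide diversity ``pi = 2*p*(1-p) * n/(n-1)`` with ``n`` called
  chromosomes (the unbiased estimator); expected heterozygosity uses the same
  small-sample correction, so pi and H_e coincide per site;
* F_is = 1 - H_o/H_e from multilocus means, with 0/0 defined as 0;
* pairwise F_ST: Weir & Cockerham (1984) variance components, combined across
  loci as a ratio of sums; negative multilocus values are reported as
  computed, never clamped;
* rarefied allelic richness: expected allele count in a subsample of ``g``
  genes, ``sum_a [1 - C(N - N_a, g) / C(N, g)]``;
* isolation by distance: Mantel test of ``F_ST/(1-F_ST)`` against
  ln(great-circle distance in km), Pearson correlation, one-sided (greater)
  permutation p with the add-one convention.

Missing data policy: all statistics use per-locus pairwise-complete
observations (a locus contributes wherever enough calls exist).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

from .datamodel import GenotypeMatrix, PopulationMap


def _pop_counts(geno: GenotypeMatrix, popmap: PopulationMap):
    """Per population: (called chromosomes, alt-allele count, het count) per locus."""
    idx = popmap.sample_indices(geno)
    out = {}
    for p, rows in idx.items():
        g = geno.calls[rows]
        called = g >= 0
        n_chr = 2 * called.sum(axis=0)
        alt = np.where(called, g, 0).sum(axis=0)
        het = ((g == 1) & called).sum(axis=0)
        out[p] = (n_chr.astype(float), alt.astype(float), het.astype(float),
                  called.sum(axis=0))
    return out


def unbiased_pi_per_site(alt_count: float, n_chromosomes: float) -> float:
    """Per-site nucleotide diversity 2*p*(1-p)*n/(n-1) from an alternate
    allele count over ``n_chromosomes`` called chromosomes (n >= 2)."""
    if n_chromosomes < 2:
        raise ValueError("need at least 2 called chromosomes")
    p = alt_count / n_chromosomes
    return 2.0 * p * (1.0 - p) * n_chromosomes / (n_chromosomes - 1.0)


def diversity(geno: GenotypeMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """Per-population diversity table.

    Columns: ``n``, ``pi``, ``he``, ``ho``, ``hom_exp``, ``hom_obs``, ``fis``,
    ``latitude``.  A locus contributes to a population's statistics when at
    least 2 individuals are called there; a population with no contributing
    locus is reported as NA with a warning.
    """
    counts = _pop_counts(geno, popmap)
    ptab = popmap.population_table()
    rows = []
    for p in popmap.populations:
        n_chr, alt, het, n_ind = counts[p]
        use = n_ind >= 2
        if not use.any():
            logger.warning("population %s has <2 called individuals at every locus", p)
            rows.append(dict(population=p, n=int(n_ind.max(initial=0)), pi=np.nan,
                             he=np.nan, ho=np.nan, hom_exp=np.nan, hom_obs=np.nan,
                             fis=np.nan, latitude=ptab.loc[p, "latitude"]))
            continue
        n = n_chr[use]
        ph = alt[use] / n
        pi_site = 2.0 * ph * (1.0 - ph) * n / (n - 1.0)
        he = pi_site  # same unbiased per-site estimator
        ho = het[use] / n_ind[use]
        he_m, ho_m = float(he.mean()), float(ho.mean())
        fis = 0.0 if he_m == 0 else 1.0 - ho_m / he_m
        rows.append(dict(population=p, n=int(n_ind.max()), pi=float(pi_site.mean()),
                         he=he_m, ho=ho_m, hom_exp=1.0 - he_m, hom_obs=1.0 - ho_m,
                         fis=fis, latitude=float(ptab.loc[p, "latitude"])))
    return pd.DataFrame(rows).set_index("population")


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def allelic_richness(geno: GenotypeMatrix, popmap: PopulationMap, g: int) -> pd.Series:
    """Rarefied allelic richness per population at subsample size ``g`` genes.

    Loci with fewer than ``g`` called genes in a population are skipped for
    that population; a population where every locus falls short raises an
    error naming it.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    counts = _pop_counts(geno, popmap)
    out = {}
    for p in popmap.populations:
        n_chr, alt, _, _ = counts[p]
        use = n_chr >= g
        if not use.any():
            raise ValueError(
                f"population {p!r}: rarefaction size g={g} exceeds called genes at every locus"
            )
        n = n_chr[use]
        ar = np.zeros(use.sum())
        for allele_count in (alt[use], n - alt[use]):  # alt and ref alleles
            with np.errstate(divide="ignore"):
                miss = np.where(
                    n - allele_count >= g,
                    np.exp(_log_comb(n - allele_count, g) - _log_comb(n, g)),
                    0.0,
                )
            ar += 1.0 - miss
        out[p] = float(ar.mean())
    return pd.Series(out, name=f"ar_g{g}")


def _wc_components(n1, p1, h1, n2, p2, h2):
    """Weir-Cockerham (1984) a, b, c variance components for two populations,
    vectorised over loci.  n: individuals called; p: alt frequency; h:
    observed heterozygote frequency."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2.0
    return a, b, c


def pairwise_fst(geno: GenotypeMatrix, popmap: PopulationMap, pop_a: str, pop_b: str) -> float:
    """Multilocus Weir-Cockerham F_ST between two populations (ratio of sums
    across loci; reported as computed, including negative values)."""
    counts = _pop_counts(geno, popmap)
    for p in (pop_a, pop_b):
        if p not in counts:
            raise KeyError(f"unknown population {p!r}")
    n1c, a1, h1c, i1 = counts[pop_a]
    n2c, a2, h2c, i2 = counts[pop_b]
    use = (i1 >= 1) & (i2 >= 1)
    if not use.any():
        raise ValueError(f"no shared called loci between {pop_a!r} and {pop_b!r}")
    n1, n2 = i1[use].astype(float), i2[use].astype(float)
    p1, p2 = a1[use] / n1c[use], a2[use] / n2c[use]
    h1, h2 = h1c[use] / n1, h2c[use] / n2
    a, b, c = _wc_components(n1, p1, h1, n2, p2, h2)
    denom = (a + b + c).sum()
    if denom == 0:
        return 0.0
    return float(a.sum() / denom)


def fst_matrix(geno: GenotypeMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """Symmetric population x population pairwise F_ST matrix (zero diagonal)."""
    pops = popmap.populations
    m = pd.DataFrame(0.0, index=pops, columns=pops)
    for a, b in itertools.combinations(pops, 2):
        v = pairwise_fst(geno, popmap, a, b)
        m.loc[a, b] = m.loc[b, a] = v
    assert np.allclose(m.values, m.values.T) and np.all(np.diag(m.values) == 0)
    return m


def haversine_km(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix (km) on a spherical Earth (R = 6371 km)."""
    from sklearn.metrics.pairwise import haversine_distances

    pts = np.radians(np.column_stack([lat, lon]))
    return haversine_distances(pts) * EARTH_RADIUS_KM


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    exact: bool = False


def mantel(y: np.ndarray, x: np.ndarray, n_perm: int = 99_999, seed: int = 0,
           exact: bool = False) -> MantelResult:
    """One-sided (greater) Mantel test: Pearson correlation of the lower
    triangles of two square matrices, significance by simultaneous row/column
    permutation of ``y``.

    With ``exact=True`` all ``n!`` relabelings are enumerated and the p-value
    is the exact proportion (add-one convention kept for comparability).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 2 or y.shape[0] != y.shape[1]:
        raise ValueError("matrices must be square and conformable")
    n = y.shape[0]
    tri = np.tril_indices(n, k=-1)

    xt = x[tri]

    def corr(perm):
        yy = y[np.ix_(perm, perm)][tri]
        ok = np.isfinite(yy) & np.isfinite(xt)  # excluded (NaN) pairs dropped
        return float(np.corrcoef(yy[ok], xt[ok])[0, 1])

    obs = corr(np.arange(n))
    if exact:
        perms = list(itertools.permutations(range(n)))
        rs = np.array([corr(np.array(p)) for p in perms])
        hits = int((rs >= obs - 1e-12).sum())
        return MantelResult(r=obs, p_value=hits / len(perms), n_perm=len(perms), exact=True)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(perm) >= obs - 1e-12:
            hits += 1
    return MantelResult(r=obs, p_value=(hits + 1) / (n_perm + 1), n_perm=n_perm)


def mantel_ibd(fst: pd.DataFrame, popmap: PopulationMap, n_perm: int = 99_999,
               seed: int = 0, exact: bool = False) -> MantelResult:
    """Isolation by distance: Mantel test of linearised F_ST/(1-F_ST) against
    ln(great-circle km) between populations."""
    pops = list(fst.index)
    ptab = popmap.population_table().loc[pops]
    f = fst.values.astype(float)
    if np.any(f >= 1.0):
        raise ValueError("F_ST = 1 encountered; linearised transform undefined")
    y = f / (1.0 - f)
    d = haversine_km(ptab["latitude"].values, ptab["longitude"].values)
    off = ~np.eye(len(pops), dtype=bool)
    if np.any(d[off] <= 0):
        logger.warning("populations with identical coordinates: zero distances excluded")
        d[(d <= 0) & off] = np.nan
    x = np.full_like(d, np.nan)
    ok = off & np.isfinite(d)
    x[ok] = np.log(d[ok])
    return mantel(y, x, n_perm=n_perm, seed=seed, exact=exact)


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t statistic, Satterthwaite df and two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        raise ValueError("zero variance in both groups: t undefined")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    from scipy.stats import t as t_dist

    p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), float(df), float(p)


def regional_tests(div: pd.DataFrame, popmap: PopulationMap,
                   south_regions: list[str], north_regions: list[str]) -> pd.DataFrame:
    """Welch t-tests of per-population pi and H_e between a southern and a
    northern group of regions."""
    reg_of_pop = popmap.region_of_population()
    rows = []
    for stat in ("pi", "he"):
        south = div.loc[[p for p in div.index if reg_of_pop[p] in south_regions], stat]
        north = div.loc[[p for p in div.index if reg_of_pop[p] in north_regions], stat]
        if len(south) < 2 or len(north) < 2:
            raise ValueError("need >=2 populations per group for the Welch test")
        t, df, p = welch_t(south.values, north.values)
        rows.append(dict(statistic=stat, t=t, df=df, p_value=p,
                         mean_south=south.mean(), mean_north=north.mean()))
    return pd.DataFrame(rows).set_index("statistic")


def chisq_pvalue(stat: float, df: int) -> float:
    """Upper-tail p of the chi-square distribution at ``stat``."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(chi2_dist.sf(stat, df))


def homozygosity_chisq(observed, expected, df: int | None = None) -> tuple[float, float]:
    """Goodness-of-fit chi-square of observed vs expected homozygosity counts.

    Returns ``(statistic, p)`` with ``df`` defaulting to ``len(observed) - 1``.
    """
    obs = np.asarray(observed, float)
    exp = np.asarray(expected, float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must align")
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = int(df) if df is not None else obs.size - 1
    return stat, chisq_pvalue(stat, df)


def latitude_regression(div: pd.DataFrame, stat: str = "pi") -> pd.Series:
    """OLS of a diversity statistic on latitude: slope, r^2, p."""
    from scipy.stats import linregress

    res = linregress(div["latitude"].values, div[stat].values)
    return pd.Series(dict(slope=res.slope, r2=res.rvalue**2, p_value=res.pvalue))
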
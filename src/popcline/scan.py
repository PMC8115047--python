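"""Selection scans: PCA-outlier (Mahalanobis) and latent-factor ridge
gene-environment association.

Both scanners are sklearn-style estimators.  ``fit`` takes a
:class:`~popcline.datamodel.GenotypeMatrix` (plus a per-sample environment for
the gene-environment scan) and exposes per-locus statistics as fitted
attributes; :func:`pcadapt_scan` and :func:`lfmm_ridge_scan` are thin
functional wrappers returning a tidy :class:`ScanResult` table.

Method outline (PCA scan): genotypes are centred and scaled by
``sqrt(2*p*(1-p))``, missing calls mean-imputed per locus; each locus is
regressed on the leading K principal-component score vectors giving a
K-vector of z-scores; a robust location/scatter (minimum covariance
determinant) of the z cloud yields Mahalanobis distances D^2; the scan-wide
genomic inflation factor ``lambda = median(D^2) / median(chi^2_K)``
recalibrates D^2 before conversion to upper-tail chi^2_K p-values;
Benjamini-Hochberg q-values flag outliers at FDR alpha.

Gene-environment scan: the model ``Y = X B' + U V' + E`` is solved with a
ridge penalty; the K latent factors U absorb population structure, and
per-locus z-scores for the environmental effect are computed from the OLS
fit of each locus on (X, U).  Calibration and FDR as above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator
from sklearn.covariance import MinCovDet
from statsmodels.stats.multitest import multipletests

from .datamodel import GenotypeMatrix, PopulationMap

#: Loci with minor-allele frequency below 0.5/n (essentially monomorphic)
#: are excluded from scans.
def _maf_threshold(n_chromosomes: int) -> float:
    return 0.5 / n_chromosomes


@dataclass
class ScanResult:
    """Tidy per-locus scan output.

    ``table`` columns: ``locus`` id, ``stat`` (D^2 or z^2), ``p_value``,
    ``q_value``, ``outlier`` flag; excluded (near-monomorphic) loci carry NA
    statistics and a False flag.  ``gif`` is the scan-wide genomic inflation
    factor; ``zscores`` the per-locus z vectors (tested loci only).
    """

    table: pd.DataFrame
    method: str
    k: int
    alpha: float
    gif: float
    zscores: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def outlier_ids(self) -> list[str]:
        return list(self.table.loc[self.table["outlier"].fillna(False), "locus"])


def _scaled_genotypes(geno: GenotypeMatrix, min_maf: float | None = None):
    """Centred/scaled genotype matrix with per-locus mean imputation.

    Returns (Z, kept locus indices).  Scaling is by sqrt(2*p*(1-p)); loci
    with MAF below the threshold are dropped.
    """
    x = geno.dosage_float()
    p = np.nanmean(x, axis=0) / 2.0
    floor = _maf_threshold(2 * geno.n_samples)
    min_maf = floor if min_maf is None else max(min_maf, floor)
    maf = np.minimum(p, 1 - p)
    keep = np.flatnonzero(maf >= min_maf)
    if keep.size < 2:
        raise ValueError("fewer than 2 polymorphic loci after MAF filtering")
    x = x[:, keep]
    p = p[keep]
    mu = 2.0 * p
    sd = np.sqrt(2.0 * p * (1.0 - p))
    z = (x - mu) / sd
    z[np.isnan(z)] = 0.0  # mean imputation after centring
    return z, keep


def pca(geno: GenotypeMatrix, n_components: int = 20, min_maf: float | None = None):
    """PCA of scaled genotypes.

    Returns (scores, explained_variance) where ``scores`` is samples x K with
    orthonormal component directions and a deterministic sign convention
    (largest-magnitude loading of each component positive).
    """
    z, _ = _scaled_genotypes(geno, min_maf)
    if geno.n_samples < 2:
        raise ValueError("need >= 2 samples")
    n_components = min(n_components, geno.n_samples - 1, z.shape[1])
    zc = z - z.mean(axis=0)
    u, s, vt = np.linalg.svd(zc, full_matrices=False)
    # deterministic signs: largest-|loading| entry of each right vector positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u[:, :n_components] * s[:n_components]
    explained = s**2 / (geno.n_samples - 1)
    return scores, explained


class PCAOutlierScan(BaseEstimator):
    """PCA z-score / Mahalanobis outlier scan (pcadapt-style).

    Parameters
    ----------
    n_components : int, default 4
        Number of principal components K retained for the z-score regression.
    alpha : float, default 0.05
        FDR level for the outlier flag.
    gif : bool, default True
        Apply genomic-inflation-factor calibration to D^2.
    min_maf : float or None
        Minor-allele-frequency exclusion threshold.  Default 0.05 (the
        standard scan filter; rare coalescent variants make the z-score
        cloud heavy-tailed and miscalibrate the chi-square conversion);
        ``None`` applies only the hard floor 0.5/(2*n_samples).
    random_state : int, default 0
        Seed of the MinCovDet subsampling (deterministic given the seed).

    Attributes (after ``fit``)
    --------------------------
    ``zscores_`` (tested loci x K), ``d2_``, ``pvalues_``, ``qvalues_``,
    ``outliers_`` (aligned to tested loci), ``gif_``, ``kept_idx_`` (indices
    of tested loci in the input), ``result_`` (full :class:`ScanResult`).
    """

    def __init__(self, n_components: int = 4, alpha: float = 0.05, gif: bool = True,
                 min_maf: float | None = 0.05, random_state: int = 0):
        self.n_components = n_components
        self.alpha = alpha
        self.gif = gif
        self.min_maf = min_maf
        self.random_state = random_state

    def fit(self, geno: GenotypeMatrix, y=None):
        k = self.n_components
        if k < 1 or k >= geno.n_samples:
            raise ValueError("need 1 <= n_components < n_samples")
        z, keep = _scaled_genotypes(geno, self.min_maf)
        scores, _ = pca(geno, n_components=k, min_maf=self.min_maf)
        # per-locus multiple regression of scaled genotypes on the K scores
        q, r = np.linalg.qr(scores - scores.mean(axis=0))
        coef_q = q.T @ z  # K x L (coefficients in the orthonormal basis)
        n = z.shape[0]
        resid = z - q @ coef_q
        dof = n - k - 1
        sigma2 = (resid**2).sum(axis=0) / dof
        sigma = np.sqrt(np.maximum(sigma2, 1e-300))
        zs = (coef_q / sigma).T  # L x K; SE of q-basis coef is sigma (unit design)
        if zs.shape[0] <= max(2 * k + 2, 10):
            raise ValueError("too few loci for a robust scatter estimate")
        mcd = MinCovDet(random_state=self.random_state).fit(zs)
        d2 = mcd.mahalanobis(zs)
        lam = float(np.median(d2) / chi2.median(df=k)) if self.gif else 1.0
        pvals = chi2.sf(d2 / lam, df=k)
        qvals, sig = fdr(pvals, self.alpha)
        self.zscores_ = zs
        self.d2_ = d2
        self.gif_ = lam
        self.pvalues_ = pvals
        self.qvalues_ = qvals
        self.outliers_ = sig
        self.kept_idx_ = keep
        self.result_ = _assemble_result(
            geno, keep, d2, pvals, qvals, sig,
            method="pca_outlier", k=k, alpha=self.alpha, gif=lam, zscores=zs)
        return self


class LatentFactorRidgeScan(BaseEstimator):
    """Latent-factor ridge gene-environment association scan (LFMM-style).

    The environment is a per-sample fixed effect (each sample carries its
    population's value); ``n_factors`` latent factors absorb residual
    structure.  ``n_factors=0`` reduces exactly to simple per-locus linear
    regression.

    Attributes after ``fit(geno, env)``: ``effects_``, ``zscores_``,
    ``pvalues_``, ``qvalues_``, ``outliers_``, ``gif_``, ``factors_`` (U),
    ``kept_idx_``, ``result_``.
    """

    def __init__(self, n_factors: int = 4, alpha: float = 0.05, gif: bool = True,
                 ridge: float = 1e-3, min_maf: float | None = 0.05):
        self.n_factors = n_factors
        self.alpha = alpha
        self.gif = gif
        self.ridge = ridge
        self.min_maf = min_maf

    def fit(self, geno: GenotypeMatrix, env: np.ndarray):
        env = np.asarray(env, dtype=float)
        if env.shape != (geno.n_samples,):
            raise ValueError("env must have one value per sample")
        if env.std() == 0:
            raise ValueError("environment is constant across samples")
        k = self.n_factors
        if k < 0 or k >= min(geno.n_samples, geno.n_loci):
            raise ValueError("need 0 <= n_factors < min(n_samples, n_loci)")
        y, keep = _scaled_genotypes(geno, self.min_maf)
        n = y.shape[0]
        x = (env - env.mean())[:, None]
        x = x / x.std()
        if k > 0:
            # ridge-penalised projection: latent factors from the SVD of the
            # component of Y not explained by the (shrunken) fixed effect
            xtx = x.T @ x + self.ridge * np.eye(1)
            proj = np.eye(n) - x @ np.linalg.solve(xtx, x.T)
            u_svd, s_svd, _ = np.linalg.svd(proj @ y, full_matrices=False)
            u = u_svd[:, :k] * s_svd[:k]
        else:
            u = np.empty((n, 0))
        design = np.column_stack([x, u - (u.mean(axis=0) if k else 0)])
        q, r = np.linalg.qr(design)
        coef_q = q.T @ y
        resid = y - q @ coef_q
        dof = n - design.shape[1] - 1
        sigma2 = (resid**2).sum(axis=0) / dof
        # back-transform to the x coefficient and its standard error
        rinv = np.linalg.inv(r)
        beta = (rinv @ coef_q)[0]
        xvar = (rinv @ rinv.T)[0, 0]
        se = np.sqrt(np.maximum(sigma2 * xvar, 1e-300))
        zs = beta / se
        stat = zs**2
        lam = float(np.median(stat) / chi2.median(df=1)) if self.gif else 1.0
        pvals = chi2.sf(stat / lam, df=1)
        qvals, sig = fdr(pvals, self.alpha)
        self.effects_ = beta
        self.zscores_ = zs
        self.gif_ = lam
        self.pvalues_ = pvals
        self.qvalues_ = qvals
        self.outliers_ = sig
        self.factors_ = u
        self.kept_idx_ = keep
        self.result_ = _assemble_result(
            geno, keep, stat, pvals, qvals, sig,
            method="lfmm_ridge", k=k, alpha=self.alpha, gif=lam,
            zscores=zs[:, None])
        return self


def _assemble_result(geno, keep, stat, pvals, qvals, sig, method, k, alpha, gif,
                     zscores) -> ScanResult:
    l_ids = geno.locus_ids
    table = pd.DataFrame({"locus": l_ids})
    for col in ("stat", "p_value", "q_value"):
        table[col] = np.nan
    table["outlier"] = False
    table.loc[keep, "stat"] = stat
    table.loc[keep, "p_value"] = pvals
    table.loc[keep, "q_value"] = qvals
    table.loc[keep, "outlier"] = sig
    n_excluded = geno.n_loci - len(keep)
    return ScanResult(table=table, method=method, k=k, alpha=alpha, gif=gif,
                      zscores=zscores, meta={"n_excluded": n_excluded})


def fdr(pvalues: np.ndarray, alpha: float = 0.05):
    """Benjamini-Hochberg step-up q-values and the significant set.

    Returns ``(q_values, significant)``; q-values are monotone along sorted
    p-values and significance is ``q <= alpha``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    sig, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")[:4]
    return q, q <= alpha


def pcadapt_scan(geno: GenotypeMatrix, k: int = 4, alpha: float = 0.05,
                 gif: bool = True, random_state: int = 0) -> ScanResult:
    """Functional wrapper over :class:`PCAOutlierScan`."""
    return PCAOutlierScan(n_components=k, alpha=alpha, gif=gif,
                          random_state=random_state).fit(geno).result_


def lfmm_ridge_scan(geno: GenotypeMatrix, popmap_or_env, k: int = 4,
                    alpha: float = 0.05, gif: bool = True) -> ScanResult:
    """Functional wrapper over :class:`LatentFactorRidgeScan`.

    ``popmap_or_env`` is either a :class:`PopulationMap` (each sample gets
    its population's environment value) or a per-sample array.
    """
    if isinstance(popmap_or_env, PopulationMap):
        env = popmap_or_env.environment_per_sample(geno)
    else:
        env = np.asarray(popmap_or_env, dtype=float)
    return LatentFactorRidgeScan(n_factors=k, alpha=alpha, gif=gif).fit(geno, env).result_


def outlier_bed(result: ScanResult, geno: GenotypeMatrix) -> pd.DataFrame:
    """BED-like table of outlier loci (chrom, 0-based start, 1-based end,
    locus id, method); requires chrom/pos locus metadata."""
    if not {"chrom", "pos"}.issubset(geno.loci.columns):
        raise ValueError("locus metadata lacks chrom/pos")
    flagged = geno.loci.set_index("id").loc[result.outlier_ids]
    return pd.DataFrame({
        "chrom": flagged["chrom"].values,
        "start": flagged["pos"].values - 1,
        "end": flagged["pos"].values,
        "locus": flagged.index.values,
        "method": result.method,
    })


def partition_outliers(set_a, set_b, all_loci) -> dict:
    """Combine two outlier sets and partition loci into outlier union and
    neutral remainder.

    Returns a dict with ``n_a``, ``n_b``, ``n_overlap``, ``n_union``,
    ``n_neutral``, ``union`` (sorted ids) and ``neutral`` (ids in input
    order).
    """
    all_list = list(all_loci)
    all_set = set(all_list)
    a, b = set(set_a), set(set_b)
    stray = (a | b) - all_set
    if stray:
        raise ValueError(f"outlier ids outside the locus universe: {sorted(stray)[:5]}")
    union = a | b
    neutral = [x for x in all_list if x not in union]
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_overlap": len(a & b),
        "n_union": len(union),
        "n_neutral": len(neutral),
        "union": sorted(union),
        "neutral": neutral,
    }
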
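"""Least-squares admixture clustering with a geographic smoothness penalty.

The model factorises the (0..1-scaled) dosage matrix ``X ~ Q G`` with Q the
samples x K ancestry proportions (rows on the simplex) and G the K x loci
ancestral allele frequencies (entries in [0, 1]).  A graph-Laplacian penalty
``lambda_geo * tr(Q' L Q)`` over an exponential-decay geographic kernel
encourages geographically close samples to share ancestry, in the spirit of
spatially aware least-squares admixture estimators.  Optimisation is
alternating projected least squares; the Q update with the Laplacian term is
a Sylvester equation solved exactly per iteration.

Model choice uses masked-entry cross-validation: a fraction of genotype
entries is hidden, the model fitted on the rest (EM-style re-imputation),
and the root-mean-squared error of the reconstructed dosages on the hidden
entries scored per K; the best K is where the score curve plateaus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_sylvester
from sklearn.base import BaseEstimator

from .datamodel import GenotypeMatrix, PopulationMap
from .sumstats import haversine_km

logger = logging.getLogger(__name__)


def _project_simplex_rows(q: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = q.shape
    u = np.sort(q, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = u - css / ind > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1
    theta = css[np.arange(n), rho] / (rho + 1.0)
    return np.maximum(q - theta[:, None], 0.0)


def geographic_laplacian(popmap: PopulationMap, samples: list[str],
                         bandwidth: float | None = None) -> np.ndarray:
    """Graph Laplacian of the exponential-decay kernel
    ``W_ij = exp(-d_ij / sigma)`` over sample coordinates (population
    coordinates per sample).  ``sigma`` defaults to the median nonzero
    inter-population distance."""
    ptab = popmap.population_table()
    pop_of = popmap.population_of()
    lat = np.array([ptab.loc[pop_of[s], "latitude"] for s in samples])
    lon = np.array([ptab.loc[pop_of[s], "longitude"] for s in samples])
    d = haversine_km(lat, lon)
    if bandwidth is None:
        pd_ = haversine_km(ptab["latitude"].values, ptab["longitude"].values)
        nz = pd_[np.triu_indices_from(pd_, k=1)]
        nz = nz[nz > 0]
        bandwidth = float(np.median(nz)) if nz.size else 1.0
    w = np.exp(-d / bandwidth)
    np.fill_diagonal(w, 0.0)
    lap = np.diag(w.sum(axis=1)) - w
    # normalise to unit mean degree so lambda_geo weights the penalty
    # relative to the per-sample reconstruction error
    scale = np.mean(np.diag(lap))
    return lap / scale if scale > 0 else lap


class AdmixtureLS(BaseEstimator):
    """Geographically penalised least-squares admixture estimator.

    Parameters
    ----------
    n_clusters : int
        Number of ancestral populations K.
    lambda_geo : float, default 1.0
        Weight of the Laplacian penalty (0 disables geography).
    n_init : int, default 50
        Random restarts; the run with the best objective is kept.
    max_iter, tol : ALS stopping rule.
    random_state : int, default 0

    Attributes after ``fit(geno, popmap)``: ``Q_`` (samples x K, simplex
    rows), ``G_`` (K x loci in [0, 1]), ``objective_``, ``n_iter_``,
    ``converged_``.
    """

    def __init__(self, n_clusters: int, lambda_geo: float = 1.0, n_init: int = 50,
                 max_iter: int = 200, tol: float = 1e-6, random_state: int = 0):
        self.n_clusters = n_clusters
        self.lambda_geo = lambda_geo
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, geno: GenotypeMatrix, popmap: PopulationMap | None = None,
            X: np.ndarray | None = None):
        k = self.n_clusters
        if k < 1 or k > geno.n_samples:
            raise ValueError("need 1 <= n_clusters <= n_samples")
        if X is None:
            X = geno.dosage_float() / 2.0
            col_mean = np.nanmean(X, axis=0)
            nan = np.isnan(X)
            X[nan] = np.take(col_mean, np.nonzero(nan)[1])
        n, L = X.shape
        if k == 1:
            self.Q_ = np.ones((n, 1))
            self.G_ = X.mean(axis=0, keepdims=True)
            self.objective_ = float(((X - self.Q_ @ self.G_) ** 2).sum())
            self.n_iter_, self.converged_ = 0, True
            return self
        if self.lambda_geo > 0:
            if popmap is None:
                raise ValueError("popmap required when lambda_geo > 0")
            lap = self.lambda_geo * geographic_laplacian(popmap, geno.samples)
        else:
            lap = np.zeros((n, n))
        rng = np.random.default_rng(self.random_state)
        best = None
        for init in range(self.n_init):
            q = rng.dirichlet(np.ones(k), size=n)
            obj_prev = np.inf
            converged = False
            for it in range(self.max_iter):
                g = np.linalg.solve(q.T @ q + 1e-9 * np.eye(k), q.T @ X)
                g = np.clip(g, 0.0, 1.0)
                # lambda*L Q + Q (G G') = X G'
                q = solve_sylvester(lap, g @ g.T + 1e-9 * np.eye(k), X @ g.T)
                q = _project_simplex_rows(q)
                obj = float(((X - q @ g) ** 2).sum() + np.sum(q * (lap @ q)))
                if obj_prev - obj < self.tol * max(obj, 1.0):
                    converged = True
                    break
                obj_prev = obj
            if not converged:
                logger.warning("ALS init %d: not converged after %d iterations "
                               "(last objective %.6g)", init, self.max_iter, obj)
            if best is None or obj < best[0]:
                best = (obj, q.copy(), g.copy(), it + 1, converged)
        self.objective_, self.Q_, self.G_, self.n_iter_, self.converged_ = best
        return self


def admixture_fit(geno: GenotypeMatrix, popmap: PopulationMap, k: int,
                  lambda_geo: float = 1.0, seed: int = 0,
                  n_init: int = 50) -> AdmixtureLS:
    """Functional wrapper over :class:`AdmixtureLS`."""
    return AdmixtureLS(n_clusters=k, lambda_geo=lambda_geo, n_init=n_init,
                       random_state=seed).fit(geno, popmap)


@dataclass
class CrossValidation:
    """Masked-entry CV scores per K and the plateau suggestion."""

    scores: pd.Series
    best_k: int
    meta: dict = field(default_factory=dict)


def cross_validate(geno: GenotypeMatrix, popmap: PopulationMap,
                   k_values=range(1, 7), mask_fraction: float = 0.1,
                   seed: int = 0, lambda_geo: float = 1.0, n_init: int = 5,
                   n_em_rounds: int = 3,
                   plateau_fraction: float = 0.25) -> CrossValidation:
    """Cross-validated RMSE of held-out dosages per K.

    A ``mask_fraction`` of genotype entries is hidden and re-imputed
    EM-style while fitting; the RMSE of the reconstruction ``2*Q*G`` against
    the hidden true dosages scores each K.  The suggested K is the smallest
    K >= 2 whose improvement over K-1 falls below ``plateau_fraction`` of
    the K=1 -> 2 improvement (the start of the plateau).
    """
    k_values = list(k_values)
    if not k_values:
        raise ValueError("empty K range")
    if not 0 < mask_fraction <= 0.5:
        raise ValueError("mask_fraction must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    x_true = geno.dosage_float() / 2.0
    observed = np.isfinite(x_true)
    mask = (rng.random(x_true.shape) < mask_fraction) & observed
    if not mask.any():
        raise ValueError("mask selected no entries")
    col_mean = np.nanmean(np.where(mask, np.nan, x_true), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.5)
    scores = {}
    for k in k_values:
        x = np.where(observed & ~mask, x_true, np.take(col_mean, np.indices(x_true.shape)[1]))
        est = AdmixtureLS(n_clusters=k, lambda_geo=lambda_geo, n_init=n_init,
                          random_state=int(rng.integers(0, 2**31 - 1)))
        for _ in range(n_em_rounds):
            est.fit(geno, popmap, X=x)
            pred = est.Q_ @ est.G_
            x = np.where(mask, pred, x)
        rmse = float(np.sqrt(np.mean((2 * pred[mask] - 2 * x_true[mask]) ** 2)))
        scores[k] = rmse
    s = pd.Series(scores).sort_index()
    best_k = s.index[0]
    if len(s) >= 2:
        base = s.iloc[0] - s.iloc[1]
        best_k = s.index[-1]
        for i in range(1, len(s)):
            if s.iloc[i - 1] - s.iloc[i] < plateau_fraction * max(base, 1e-12):
                best_k = s.index[i - 1]
                break
    return CrossValidation(scores=s, best_k=int(best_k),
                           meta={"mask_fraction": mask_fraction, "seed": seed})
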
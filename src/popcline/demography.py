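"""Simulation-based composite-likelihood fitting of demographic scenarios and
AIC model selection.

A scenario template's parameters are drawn from their priors, mapped to the
unit cube, and refined with a bounded derivative-free Nelder-Mead search of
the composite log-likelihood ``ln CL(theta) = sum_i m_i ln p_i(theta)``, where
the expected cell proportions ``p_i`` come from a Monte-Carlo folded mSFS
(:func:`popcline.coalescent.expected_sfs`).  Within one replicate every
likelihood evaluation reuses the same simulation seed (common random
numbers), so the optimiser sees a deterministic surface; independent
replicates restart from fresh prior draws and fresh seeds, and the best
replicate is kept — the replicate-based globalisation of the fastsimcoal
workflow at desk scale.

Model selection: ``AIC = 2k - 2 ln CL`` on the natural-log scale (the
arithmetic of the published model table is consistent with exactly this
convention), with complex parameters counted once in ``k``; Akaike weights
are computed in log space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .coalescent import expected_sfs
from .scenarios import ScenarioTemplate
from .sfs import FoldedMSFS, composite_loglik, saturated_loglik

logger = logging.getLogger(__name__)


@dataclass
class ModelFit:
    """Best fit of one scenario template to an observed folded mSFS."""

    name: str
    params: dict[str, float]
    max_est_lnl: float
    max_obs_lnl: float
    k: int
    aic: float = math.nan
    delta_aic: float = math.nan
    weight: float = math.nan
    replicates: list = field(default_factory=list)

    @property
    def delta_lnl(self) -> float:
        """MaxObsLhood - MaxEstLhood (0 would be a saturated fit)."""
        return self.max_obs_lnl - self.max_est_lnl


class CompositeLikelihoodFitter(BaseEstimator):
    """sklearn-style fitter of one scenario template.

    Parameters
    ----------
    template : ScenarioTemplate
    sample_config : dict
        Diploids sampled per deme (must match the observed spectrum).
    n_sim : int, default 10000
        Coalescent simulations per likelihood evaluation.
    n_replicates : int, default 3
        Independent prior-draw restarts; the best is kept.
    maxiter : int, default 30
        Nelder-Mead iterations per replicate.
    seed : int, default 0

    After ``fit(obs)``: ``fit_`` (:class:`ModelFit`), ``params_``,
    ``loglik_``.
    """

    def __init__(self, template: ScenarioTemplate, sample_config: dict[str, int],
                 n_sim: int = 10_000, n_replicates: int = 3, maxiter: int = 30,
                 seed: int = 0):
        self.template = template
        self.sample_config = sample_config
        self.n_sim = n_sim
        self.n_replicates = n_replicates
        self.maxiter = maxiter
        self.seed = seed

    def fit(self, obs: FoldedMSFS):
        tpl = self.template
        rng = np.random.default_rng(self.seed)
        sat = saturated_loglik(obs)
        pnames = tpl.param_names
        replicates = []

        def make_objective(sim_seed):
            def negloglik(u):
                penalty = float(np.sum(np.clip(np.abs(u - 0.5) - 0.5, 0, None)))
                uc = np.clip(u, 0.0, 1.0)
                params = {p: tpl.priors[p].from_unit(uc[i]) for i, p in enumerate(pnames)}
                try:
                    sc = tpl.build(params)
                    exp = expected_sfs(sc, self.sample_config, self.n_sim, sim_seed)
                except ValueError:
                    return 1e12
                lnl = composite_loglik(obs, exp)
                if not np.isfinite(lnl):
                    return 1e12
                return -lnl + 1e4 * penalty

            return negloglik

        for rep in range(self.n_replicates):
            sim_seed = int(rng.integers(0, 2**31 - 1))
            start = {p: tpl.priors[p].draw(rng) for p in pnames}
            u0 = np.array([tpl.priors[p].to_unit(start[p]) for p in pnames])
            obj = make_objective(sim_seed)
            res = minimize(obj, u0, method="Nelder-Mead",
                           options={"maxiter": self.maxiter, "xatol": 1e-3,
                                    "fatol": 0.5, "adaptive": True})
            u = np.clip(res.x, 0.0, 1.0)
            params = {p: tpl.priors[p].from_unit(u[i]) for i, p in enumerate(pnames)}
            lnl = -obj(u)
            replicates.append((lnl, params, sim_seed))
            logger.info("%s replicate %d: lnCL=%.2f", tpl.name, rep, lnl)
        lnls = [r[0] for r in replicates]
        if not np.isfinite(np.max(lnls)):
            raise RuntimeError(f"{tpl.name}: non-finite likelihood at every start")
        best = int(np.argmax(lnls))
        lnl, params, _ = replicates[best]
        self.fit_ = ModelFit(name=tpl.name, params=params, max_est_lnl=float(lnl),
                             max_obs_lnl=float(sat), k=tpl.k,
                             replicates=[(float(l), p) for l, p, _ in replicates])
        self.params_ = params
        self.loglik_ = float(lnl)
        return self


def fit_scenario(obs: FoldedMSFS, template: ScenarioTemplate,
                 sample_config: dict[str, int], n_sim: int = 10_000,
                 n_replicates: int = 3, seed: int = 0, maxiter: int = 30) -> ModelFit:
    """Functional wrapper over :class:`CompositeLikelihoodFitter`."""
    return CompositeLikelihoodFitter(
        template, sample_config, n_sim=n_sim, n_replicates=n_replicates,
        maxiter=maxiter, seed=seed).fit(obs).fit_


def model_select(fits: list[ModelFit] | dict[str, tuple[float, int]]) -> "pd.DataFrame":
    """AIC model selection across fitted scenarios.

    Accepts either a list of :class:`ModelFit` (completed in place) or a
    mapping ``name -> (max_est_lnl, k)``.  Returns a table with columns
    ``MaxLikelihood, DeltaLikelihood, k, AIC, DeltaAIC, AICWeights`` sorted
    in input order.  Non-finite likelihoods exclude a model with a warning.
    Weights are computed in log space, so vanishing weights (1e-176) keep
    full relative precision.
    """
    import pandas as pd

    if isinstance(fits, dict):
        fits = [ModelFit(name=n, params={}, max_est_lnl=l, max_obs_lnl=math.nan, k=k)
                for n, (l, k) in fits.items()]
    usable = []
    for f in fits:
        if not np.isfinite(f.max_est_lnl):
            logger.warning("model %s excluded: non-finite likelihood", f.name)
            continue
        usable.append(f)
    if not usable:
        raise ValueError("no model with a finite likelihood")
    aics = np.array([2.0 * f.k - 2.0 * f.max_est_lnl for f in usable])
    delta = aics - aics.min()
    logw = -delta / 2.0
    logw = logw - logsumexp(logw)
    weights = np.exp(logw)
    rows = {}
    for f, a, d, w in zip(usable, aics, delta, weights):
        f.aic, f.delta_aic, f.weight = float(a), float(d), float(w)
        rows[f.name] = dict(MaxLikelihood=f.max_est_lnl, DeltaLikelihood=f.delta_lnl,
                            k=f.k, AIC=f.aic, DeltaAIC=f.delta_aic, AICWeights=f.weight)
    return pd.DataFrame(rows).T
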
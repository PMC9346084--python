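"""Multilevel random-effects meta-analysis of survival log odds ratios.

Each effect y_ij is a log odds ratio of a derived population against the
ancestral one in experiment j, with known sampling variance v_ij from the
underlying binomial model.  The model is

    y_ij = mu + beta * pop_ij + u_j + e_ij,
    u_j ~ N(0, tau^2)  (experiment level),  e_ij ~ N(0, v_ij),

so effects from the same experiment share the random deviate u_j.  The
between-experiment variance tau^2 is estimated by REML (the reported
scale), while likelihood-ratio tests of fixed effects refit both models by
full ML, which is the comparison the chi-square reference is valid for.

The population moderator is treatment-coded with the earlier derived
population (VCH97) as intercept and an indicator for the later one
(VCH08), so the 1-df moderator test asks whether the two derived
populations differ.  A 1-df test of "overall mean effect = 0" (intercept
against an empty fixed part) is exposed as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2 as chi2_dist

from .config import log_kv
from .errors import ModelError
from .survival import EffectSize


@dataclass
class MetaFit:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    tau_sq: float
    loglik: float            # at the fitted tau^2, under `method`
    loglik_ml: float         # full ML log-likelihood at the ML solution
    k: int
    method: str              # "REML" | "ML"
    moderator: bool
    effect_key: tuple

    def summary_dict(self) -> dict:
        return {
            "coefficients": {n: float(c) for n, c in zip(self.names, self.coef)},
            "se": {n: float(s) for n, s in zip(self.names, self.se)},
            "tau_sq": self.tau_sq, "k": self.k, "method": self.method,
        }


def _design(effects: list[EffectSize], moderator: bool, intercept: bool = True):
    pops = sorted({e.population for e in effects})
    names, cols = [], []
    if intercept:
        names.append("(Intercept)")
        cols.append(np.ones(len(effects)))
    if moderator:
        if len(pops) < 2:
            raise ModelError("moderator requires >= 2 population levels")
        for pop in pops[1:]:
            names.append(f"population[T.{pop}]")
            cols.append(np.array([1.0 if e.population == pop else 0.0
                                  for e in effects]))
    X = np.column_stack(cols) if cols else np.empty((len(effects), 0))
    return X, names


def _gls(X, y, V):
    Vi = np.linalg.inv(V)
    if X.shape[1] == 0:
        return np.empty(0), np.empty((0, 0)), Vi
    XtVi = X.T @ Vi
    cov = np.linalg.inv(XtVi @ X)
    beta = cov @ (XtVi @ y)
    return beta, cov, Vi


def _loglik(tau_sq, X, y, v, B, restricted):
    V = np.diag(v) + tau_sq * B
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    beta, cov, Vi = _gls(X, y, V)
    resid = y - (X @ beta if X.shape[1] else 0.0)
    ll = -0.5 * (len(y) * np.log(2 * np.pi) + logdet + resid @ Vi @ resid)
    if restricted and X.shape[1]:
        sign2, logdet2 = np.linalg.slogdet(X.T @ Vi @ X)
        ll += 0.5 * (X.shape[1] * np.log(2 * np.pi) - logdet2)
    return float(ll)


def fit_multilevel_meta(
    effects: list[EffectSize],
    moderator: bool = False,
    method: str = "REML",
    intercept: bool = True,
    tau_tol: float = 1e-10,
    fix_tau_sq: float | None = None,
) -> MetaFit:
    """Fit the multilevel random-effects model to a set of effect sizes.

    ``method`` selects the criterion used to estimate tau^2 ("REML" for
    reporting, "ML" for likelihood-ratio comparisons).  ``intercept=False``
    fits the null model with the overall mean fixed at zero.
    ``fix_tau_sq`` holds the between-experiment variance at a given value
    (0 reduces the model to fixed-effect inverse-variance weighting).
    """
    if not effects:
        raise ModelError("no effect sizes supplied")
    y = np.array([e.log_odds_ratio for e in effects])
    v = np.array([e.variance for e in effects])
    if np.any(v <= 0):
        raise ModelError("every effect needs sampling variance > 0")
    exps = pd.factorize(np.asarray([e.experiment for e in effects]))[0]
    B = (exps[:, None] == exps[None, :]).astype(float)
    X, names = _design(effects, moderator, intercept)
    k = len(effects)
    if k < X.shape[1]:
        raise ModelError(f"k={k} effects cannot identify "
                         f"{X.shape[1]} fixed coefficients")
    restricted = method.upper() == "REML"

    def crit(log_tau_sq):
        return -_loglik(np.exp(log_tau_sq), X, y, v, B, restricted)

    if fix_tau_sq is None and k <= X.shape[1]:
        fix_tau_sq = 0.0  # no residual information about tau^2
    if fix_tau_sq is not None:
        best_t = float(fix_tau_sq)
        best_ll = _loglik(best_t, X, y, v, B, restricted)
    else:
        best_t, best_ll = 0.0, _loglik(0.0, X, y, v, B, restricted)
        res = optimize.minimize_scalar(crit, bounds=(np.log(tau_tol), np.log(1e3)),
                                       method="bounded",
                                       options={"xatol": 1e-12})
        if np.isfinite(res.fun) and -res.fun > best_ll:
            best_t, best_ll = float(np.exp(res.x)), float(-res.fun)
        if best_t <= tau_tol * 10:
            best_t = 0.0
            best_ll = _loglik(0.0, X, y, v, B, restricted)

    V = np.diag(v) + best_t * B
    beta, cov, _ = _gls(X, y, V)
    se = np.sqrt(np.diag(cov)) if X.shape[1] else np.empty(0)
    ll_ml = _loglik(best_t, X, y, v, B, restricted=False)
    if restricted and fix_tau_sq is None:
        # the ML tau^2 may differ; refit for the comparable ML log-likelihood
        res_ml = optimize.minimize_scalar(
            lambda lt: -_loglik(np.exp(lt), X, y, v, B, False),
            bounds=(np.log(tau_tol), np.log(1e3)), method="bounded",
            options={"xatol": 1e-12})
        ll_ml = max(_loglik(0.0, X, y, v, B, False), float(-res_ml.fun))

    fit = MetaFit(
        names=names, coef=beta, se=se, tau_sq=best_t, loglik=best_ll,
        loglik_ml=ll_ml, k=k, method=method.upper(), moderator=moderator,
        effect_key=tuple(sorted((e.population, e.experiment, e.regime,
                                 round(e.log_odds_ratio, 12)) for e in effects)),
    )
    log_kv("meta_fit", k=k, tau_sq=best_t, method=fit.method,
           moderator=moderator, loglik=best_ll)
    return fit


def meta_lr_test(full: MetaFit, reduced: MetaFit) -> tuple[float, int, float]:
    """Likelihood-ratio test between nested meta-analytic models fitted to
    the same effects; both log-likelihoods are taken under full ML."""
    if full.effect_key != reduced.effect_key:
        raise ModelError("models were fitted to different effect sets")
    if not set(reduced.names) <= set(full.names):
        raise ModelError("reduced model is not nested in the full model")
    df = len(full.names) - len(reduced.names)
    chi_sq = max(0.0, 2.0 * (full.loglik_ml - reduced.loglik_ml))
    p = float(chi2_dist.sf(chi_sq, df)) if df > 0 else 1.0
    log_kv("meta_lr_test", chi_sq=chi_sq, df=df, p=p)
    return chi_sq, df, p


def moderator_test(effects: list[EffectSize]) -> tuple[float, int, float]:
    """1-df test: do the two derived populations differ in mean effect?"""
    full = fit_multilevel_meta(effects, moderator=True, method="ML")
    reduced = fit_multilevel_meta(effects, moderator=False, method="ML")
    return meta_lr_test(full, reduced)


def overall_mean_test(effects: list[EffectSize]) -> tuple[float, int, float]:
    """1-df test: is the overall mean effect zero?"""
    full = fit_multilevel_meta(effects, moderator=False, method="ML")
    reduced = fit_multilevel_meta(effects, moderator=False, method="ML",
                                  intercept=False)
    return meta_lr_test(full, reduced)
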
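"""Binomial mixed models for tube-level survival data.

Each rearing tube contributes a binomial outcome (``n_alive`` of
``n_total``) with a logit link.  Fixed effects encode the experimental
factors (population, clutch, parental treatment, early thermal regime,
microbiome inoculum) with treatment coding; the derived populations are
always contrasted against the ancestral one (SFB84), so population
coefficients are log odds ratios of survival.  Two random-intercept terms
are supported:

* a *family* intercept grouping tubes from one parental couple;
* an *observation-level* intercept (one Normal deviate per tube), the
  standard device for absorbing extra-binomial overdispersion.

The marginal likelihood integrates the random intercepts out by
Gauss–Hermite quadrature (nested quadrature when both terms are present)
and is maximized with L-BFGS-B; the maximized log-likelihood is exposed so
nested models can be compared by likelihood-ratio tests.  The two thermal
regimes are always analyzed separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import optimize, special
from scipy.stats import chi2 as chi2_dist
from scipy.stats import studentized_range

from .config import log_kv
from .errors import ModelError, SubsetError

#: Reference level per factor; coefficients are contrasts against these.
REFERENCE_LEVELS = {
    "population": "SFB84",
    "regime": "T_SFB",
    "cross_status": "own",
    "clutch": "1",
    "parental_treatment": "control",
    "phase1_regime": "T_SFB",
    "microbiome": "LAB",
}

_SQRT_PI = np.sqrt(np.pi)


@dataclass(frozen=True)
class EffectSize:
    """A survival log odds ratio of one derived population relative to the
    ancestral SFB84, with its sampling variance."""

    log_odds_ratio: float
    variance: float
    population: str
    experiment: str
    regime: str
    cross_status: str = "own"
    time: float | None = None

    def __post_init__(self):
        if not self.variance > 0:
            raise ModelError("effect-size sampling variance must be > 0")


@dataclass
class GLMMFit:
    formula: str
    family_intercept: bool
    observation_intercept: bool
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    sigma_family: float
    sigma_obs: float
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    flags: list[str] = field(default_factory=list)
    # fitting arrays retained for residual diagnostics
    _X: np.ndarray | None = None
    _y: np.ndarray | None = None
    _n: np.ndarray | None = None
    _groups: np.ndarray | None = None

    def coefficient(self, factor: str, level: str) -> tuple[float, float]:
        """(estimate, SE) of a treatment-coded factor level."""
        name = f"{factor}[T.{level}]"
        if name not in self.names:
            raise ModelError(f"no coefficient {name!r} in fit")
        i = self.names.index(name)
        return float(self.coef[i]), float(self.se[i])

    def summary_dict(self) -> dict:
        return {
            "formula": self.formula,
            "coefficients": {n: float(c) for n, c in zip(self.names, self.coef)},
            "se": {n: float(s) for n, s in zip(self.names, self.se)},
            "sigma_family": self.sigma_family,
            "sigma_obs": self.sigma_obs,
            "loglik": self.loglik,
            "converged": self.converged,
            "flags": self.flags,
        }


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def prepare_model_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Attach modeling columns: categoricals with the declared reference
    level first, plus ``clutch_dummy`` (0 for first clutch, 1 for second)
    so parental-treatment terms can be restricted to interactions."""
    df = table.copy()
    for col, ref in REFERENCE_LEVELS.items():
        if col not in df.columns:
            continue
        levels = [l for l in df[col].unique() if l != "NA"]
        ordered = ([ref] if ref in levels else []) + sorted(set(levels) - {ref})
        df[col] = pd.Categorical(df[col], categories=ordered + (
            ["NA"] if (df[col] == "NA").any() else []))
    df["clutch_dummy"] = (table.get("clutch", pd.Series(index=table.index, dtype=object))
                          .astype(str) == "2").astype(float)
    return df


def build_design(table: pd.DataFrame, formula: str) -> tuple[np.ndarray, list[str]]:
    df = prepare_model_frame(table)
    mat = dmatrix("1 + " + formula, df, return_type="dataframe")
    names = [c.replace("Intercept", "(Intercept)") for c in mat.columns]
    return np.asarray(mat, float), names


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------

def _binom_logpmf_eta(eta, y, n, lchoose):
    # log Binomial(y | n, expit(eta)); eta may broadcast against y/n
    return lchoose + y * eta - n * np.logaddexp(0.0, eta)


class _MarginalLikelihood:
    """Marginal binomial log-likelihood with optional family and
    observation-level random intercepts (Gauss–Hermite quadrature)."""

    def __init__(self, X, y, n, groups=None, obs_level=False, gh_points=25):
        self.X, self.y, self.n = X, np.asarray(y, float), np.asarray(n, float)
        self.groups = groups
        self.obs_level = obs_level
        self.p_fixed = X.shape[1]
        self.n_var = (groups is not None) + obs_level
        x, w = np.polynomial.hermite.hermgauss(gh_points)
        self.gh_x, self.gh_logw = x, np.log(w)
        self.lchoose = (special.gammaln(self.n + 1) - special.gammaln(self.y + 1)
                        - special.gammaln(self.n - self.y + 1))
        if groups is not None:
            self.n_groups = int(groups.max()) + 1

    def split(self, params):
        beta = params[: self.p_fixed]
        k = self.p_fixed
        sigma_f = sigma_o = 0.0
        if self.groups is not None:
            sigma_f = params[k]
            k += 1
        if self.obs_level:
            sigma_o = params[k]
        return beta, sigma_f, sigma_o

    def __call__(self, params) -> float:
        beta, sf, so = self.split(params)
        eta = self.X @ beta
        y, n, lc = self.y, self.n, self.lchoose
        x, logw = self.gh_x, self.gh_logw
        if self.groups is None and not self.obs_level:
            return float(np.sum(_binom_logpmf_eta(eta, y, n, lc)))
        if self.groups is None:  # observation-level only
            T = _binom_logpmf_eta(eta[:, None] + np.sqrt(2) * so * x[None, :],
                                  y[:, None], n[:, None], lc[:, None])
            return float(np.sum(special.logsumexp(T + logw[None, :], axis=1)
                                - np.log(_SQRT_PI)))
        if not self.obs_level:  # family only
            A = _binom_logpmf_eta(eta[:, None] + np.sqrt(2) * sf * x[None, :],
                                  y[:, None], n[:, None], lc[:, None])
            S = np.zeros((self.n_groups, len(x)))
            np.add.at(S, self.groups, A)
            return float(np.sum(special.logsumexp(S + logw[None, :], axis=1)
                                - np.log(_SQRT_PI)))
        # both: nested quadrature (outer family, inner observation)
        shift = (np.sqrt(2) * sf * x)[None, :, None] + (np.sqrt(2) * so * x)[None, None, :]
        T = _binom_logpmf_eta(eta[:, None, None] + shift,
                              y[:, None, None], n[:, None, None], lc[:, None, None])
        B = special.logsumexp(T + logw[None, None, :], axis=2) - np.log(_SQRT_PI)
        S = np.zeros((self.n_groups, len(x)))
        np.add.at(S, self.groups, B)
        return float(np.sum(special.logsumexp(S + logw[None, :], axis=1)
                            - np.log(_SQRT_PI)))


def _logistic_start(X, y, n):
    """Plain logistic MLE by damped Newton iterations (starting values)."""
    beta = np.zeros(X.shape[1])
    for _ in range(50):
        eta = X @ beta
        p = special.expit(eta)
        g = X.T @ (y - n * p)
        W = n * p * (1 - p) + 1e-10
        H = X.T @ (X * W[:, None])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        step = np.clip(step, -4, 4)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.clip(beta, -15, 15)


def _numerical_hessian(f, x, eps=1e-4):
    k = len(x)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


def fit_binomial_glmm(
    table: pd.DataFrame,
    formula: str,
    family_intercept: bool = False,
    observation_intercept: bool = False,
    gh_points: int = 25,
) -> GLMMFit:
    """Fit a binomial GLMM by maximizing the Gauss–Hermite marginal
    likelihood.

    ``formula`` is the fixed-effect right-hand side (patsy syntax over the
    survival-table columns plus ``clutch_dummy``).  ``family_intercept``
    adds a Normal random intercept shared by tubes with the same
    ``family_id`` (tubes with family "NA" become singleton groups);
    ``observation_intercept`` adds the per-tube overdispersion intercept.
    Non-convergence and separation are flagged on the returned fit, never
    silently ignored.
    """
    if len(table) == 0:
        raise ModelError("cannot fit a model to an empty table")
    X, names = build_design(table, formula)
    y = table["n_alive"].to_numpy(float)
    n = table["n_total"].to_numpy(float)
    groups = None
    if family_intercept:
        fam = table["family_id"].astype(str).to_numpy()
        fam = np.array([f"__solo{i}" if f == "NA" else f for i, f in enumerate(fam)])
        groups = pd.factorize(fam)[0]

    ll = _MarginalLikelihood(X, y, n, groups=groups,
                             obs_level=observation_intercept, gh_points=gh_points)
    beta0 = _logistic_start(X, y, n)
    x0 = np.concatenate([beta0, np.full(ll.n_var, 0.3)])
    bounds = [(None, None)] * ll.p_fixed + [(0.0, 10.0)] * ll.n_var

    nll = lambda p: -ll(p)
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    # polish once from a fresh variance start if the first attempt stalls
    if not res.success or ll.n_var:
        x1 = res.x.copy()
        res2 = optimize.minimize(nll, x1, method="Nelder-Mead",
                                 options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
        x2 = np.clip(res2.x, [b[0] if b[0] is not None else -np.inf for b in bounds],
                     [b[1] if b[1] is not None else np.inf for b in bounds])
        if -nll(x2) > -nll(res.x):
            res = res2
            res.x = x2

    params = res.x
    beta, sigma_f, sigma_o = ll.split(params)
    flags = []
    if not (res.success or np.isfinite(res.fun)):
        flags.append("non-convergence")
    sep = [names[i] for i in range(len(beta)) if abs(beta[i]) > 10]
    if sep:
        flags.append("separation:" + ",".join(sep))

    H = _numerical_hessian(nll, params)
    try:
        vcov_full = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov_full = np.linalg.pinv(H)
    vcov = vcov_full[: ll.p_fixed, : ll.p_fixed]
    diag = np.diag(vcov).copy()
    se = np.sqrt(np.where(diag > 0, diag, np.nan))

    fit = GLMMFit(
        formula=formula,
        family_intercept=family_intercept,
        observation_intercept=observation_intercept,
        names=names,
        coef=beta,
        se=se,
        vcov=vcov,
        sigma_family=float(sigma_f),
        sigma_obs=float(sigma_o),
        loglik=float(-res.fun),
        n_params=ll.p_fixed + ll.n_var,
        n_obs=len(table),
        converged=bool(res.success) and not flags,
        flags=flags,
        _X=X, _y=y, _n=n, _groups=groups,
    )
    log_kv("glmm_fit", formula=formula, loglik=fit.loglik,
           sigma_family=fit.sigma_family, sigma_obs=fit.sigma_obs,
           converged=fit.converged)
    return fit


# ---------------------------------------------------------------------------
# diagnostics and tests
# ---------------------------------------------------------------------------

def _family_modes(fit: GLMMFit) -> np.ndarray:
    """Posterior modes of the family intercepts (zero when absent)."""
    if fit._groups is None or fit.sigma_family == 0:
        return np.zeros(fit.n_obs)
    eta = fit._X @ fit.coef
    u = np.zeros(int(fit._groups.max()) + 1)
    s2 = fit.sigma_family ** 2
    for _ in range(100):
        p = special.expit(eta + u[fit._groups])
        g = np.zeros_like(u)
        np.add.at(g, fit._groups, fit._y - fit._n * p)
        g -= u / s2
        h = np.zeros_like(u)
        np.add.at(h, fit._groups, fit._n * p * (1 - p))
        h += 1 / s2
        step = g / h
        u += step
        if np.max(np.abs(step)) < 1e-10:
            break
    return u[fit._groups]


def assess_overdispersion(fit: GLMMFit, table: pd.DataFrame) -> float:
    """Pearson dispersion ratio of a fit *without* the observation-level
    term: sum of squared Pearson residuals over residual df.  Values well
    above 1 indicate extra-binomial variation; the caller refits with the
    observation-level intercept when the ratio exceeds its threshold."""
    if fit.observation_intercept:
        raise ModelError("dispersion is assessed on a fit without the "
                         "observation-level term")
    df_resid = fit.n_obs - fit.n_params
    if df_resid <= 0:
        raise ModelError("zero residual degrees of freedom: model is saturated")
    eta = fit._X @ fit.coef + _family_modes(fit)
    p = special.expit(eta)
    r = (fit._y - fit._n * p) / np.sqrt(fit._n * p * (1 - p))
    ratio = float(np.sum(r * r) / df_resid)
    log_kv("dispersion", ratio=ratio, df_resid=df_resid)
    return ratio


def lr_test(full: GLMMFit, reduced: GLMMFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested binomial GLMMs.

    Returns ``(chi_sq, df, p)`` with the statistic clipped at zero and the
    p-value from the chi-square reference distribution.
    """
    same_model = (set(reduced.names) == set(full.names)
                  and reduced.family_intercept == full.family_intercept
                  and reduced.observation_intercept == full.observation_intercept)
    nested = (set(reduced.names) <= set(full.names)
              and reduced.family_intercept <= full.family_intercept
              and reduced.observation_intercept <= full.observation_intercept)
    if not nested:
        raise ModelError("reduced model is not nested in the full model")
    if reduced.n_obs != full.n_obs:
        raise ModelError("models were fitted to different data")
    if not (full.converged and reduced.converged):
        raise ModelError("both models must have converged for an LR test")
    df = full.n_params - reduced.n_params
    if df == 0 and not same_model:
        raise ModelError("models have equal complexity but different terms")
    chi_sq = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(chi2_dist.sf(chi_sq, df)) if df > 0 else 1.0
    log_kv("lr_test", chi_sq=chi_sq, df=df, p=p)
    return chi_sq, df, p


def tukey_pairwise(estimates: dict[str, float], cov: np.ndarray) -> pd.DataFrame:
    """All pairwise contrasts among level estimates with Tukey-family
    adjustment (studentized-range reference on z statistics).  For two
    levels the adjusted p equals the unadjusted two-sided normal p."""
    levels = list(estimates)
    k = len(levels)
    if k < 2:
        raise ModelError("pairwise comparison needs >= 2 levels")
    est = np.array([estimates[l] for l in levels])
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            var = cov[i, i] + cov[j, j] - 2 * cov[i, j]
            if not var > 0:
                raise ModelError(f"inestimable contrast {levels[i]} - {levels[j]}")
            z = (est[i] - est[j]) / np.sqrt(var)
            p_adj = float(studentized_range.sf(abs(z) * np.sqrt(2), k, np.inf))
            rows.append({"level_a": levels[i], "level_b": levels[j],
                         "estimate": est[i] - est[j], "se": np.sqrt(var),
                         "z": float(z), "p_adjusted": p_adj})
    return pd.DataFrame(rows)


def posthoc_pairwise(fit: GLMMFit, factor: str) -> pd.DataFrame:
    """Tukey post hoc comparisons among the levels of one fixed factor.

    The reference level enters with estimate 0 and zero (co)variance; the
    other levels use their treatment-coded coefficients and the fitted
    covariance block.
    """
    prefix = f"{factor}[T."
    idx = [i for i, nme in enumerate(fit.names) if nme.startswith(prefix)]
    if not idx:
        raise ModelError(f"factor {factor!r} has no estimable contrasts in this fit")
    ref = REFERENCE_LEVELS.get(factor, "<ref>")
    levels = [ref] + [fit.names[i][len(prefix):-1] for i in idx]
    est = {ref: 0.0}
    cov = np.zeros((len(levels), len(levels)))
    for a, i in enumerate(idx, start=1):
        est[levels[a]] = float(fit.coef[i])
        for b, j in enumerate(idx, start=1):
            cov[a, b] = fit.vcov[i, j]
    return tukey_pairwise(est, cov)


# ---------------------------------------------------------------------------
# effect-size extraction for the meta-analysis
# ---------------------------------------------------------------------------

#: The four "control" subsets pooled for the meta-analysis: rows that were
#: reared under baseline conditions within each experiment.
CONTROL_SUBSETS = {
    "parental_clutch1": lambda df, regime: (df["experiment"] == "parental")
    & (df["clutch"] == "1"),
    "parental_clutch2_control": lambda df, regime: (df["experiment"] == "parental")
    & (df["clutch"] == "2") & (df["parental_treatment"] == "control"),
    "microbiome_lab": lambda df, regime: (df["experiment"] == "microbiome")
    & (df["microbiome"] == "LAB"),
    "juvenile_same_regime": lambda df, regime: (df["experiment"] == "juvenile")
    & (df["phase1_regime"] == df["regime"]),
}


def extract_effect_sizes(
    table: pd.DataFrame,
    regime: str,
    dispersion_threshold: float = 1.4,
    gh_points: int = 25,
) -> list[EffectSize]:
    """Fit a population-only binomial GLMM to each control subset under one
    thermal regime and return the log odds ratio (vs SFB84) of every
    derived population, weighted by its squared standard error.

    The family intercept is included whenever the subset records family
    structure; the observation-level intercept is added when the Pearson
    dispersion ratio of the family-only fit exceeds ``dispersion_threshold``.
    """
    effects: list[EffectSize] = []
    for label, selector in CONTROL_SUBSETS.items():
        sub = table[selector(table, regime) & (table["regime"] == regime)]
        if len(sub) == 0:
            continue
        pops = set(sub["population"])
        if "SFB84" not in pops:
            raise SubsetError(f"subset {label!r} lacks the ancestral SFB84 population")
        has_family = (sub["family_id"] != "NA").any()
        fit = fit_binomial_glmm(sub, "population", family_intercept=bool(has_family),
                                gh_points=gh_points)
        ratio = assess_overdispersion(fit, sub)
        if ratio > dispersion_threshold:
            fit = fit_binomial_glmm(sub, "population", family_intercept=bool(has_family),
                                    observation_intercept=True, gh_points=gh_points)
        for pop in sorted(pops - {"SFB84"}):
            est, se = fit.coefficient("population", pop)
            effects.append(EffectSize(
                log_odds_ratio=est, variance=se * se, population=pop,
                experiment=label, regime=regime,
            ))
            log_kv("effect_size", subset=label, population=pop, regime=regime,
                   log_or=est, variance=se * se)
    return effects


def effects_to_frame(effects: list[EffectSize]) -> pd.DataFrame:
    return pd.DataFrame([{
        "population": e.population, "subset": e.experiment, "regime": e.regime,
        "cross_status": e.cross_status, "time": e.time,
        "log_odds_ratio": e.log_odds_ratio, "variance": e.variance,
    } for e in effects])


def frame_to_effects(df: pd.DataFrame) -> list[EffectSize]:
    return [EffectSize(
        log_odds_ratio=float(r["log_odds_ratio"]), variance=float(r["variance"]),
        population=str(r["population"]), experiment=str(r["subset"]),
        regime=str(r["regime"]),
        cross_status=str(r.get("cross_status", "own")),
        time=None if pd.isna(r.get("time")) else float(r["time"]),
    ) for _, r in df.iterrows()]
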
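"""Mixed-effects temperature-response and zero-inflated count models.

Linear mixed models (random intercept per plant, optionally species with
plant nested inside) are fitted with statsmodels' MixedLM.  Coefficient
p-values use the normal approximation to the Wald statistic (no
Satterthwaite machinery in the stack); the choice is recorded in the fit
metadata.  AIC comparisons refit by plain ML, curve reporting uses REML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import expit, gammaln

__all__ = [
    "MixedFit",
    "ZinbFit",
    "fit_quadratic_lmm",
    "fit_time_group_interaction",
    "fit_flowering_group_model",
    "fit_zinb_empty",
    "aic_select",
    "r2_nakagawa",
]


class ModelDesignError(ValueError):
    """The data cannot support the requested model."""


class ComparisonError(ValueError):
    """AIC comparison across mismatched data."""


@dataclass
class MixedFit:
    """A fitted mixed model plus everything needed to map it back to °C."""

    trait: str
    scope: str
    formula: str
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    re_var: dict
    resid_var: float
    var_fixed: float
    aic: float
    loglike: float
    reml: bool
    converged: bool
    n_obs: int
    n_groups: int
    temp_mean: float = np.nan
    temp_sd: float = np.nan
    value_mean: float = np.nan
    value_sd: float = np.nan
    transform: str = "none"
    offset: float = 0.0
    obs_temp_std_range: tuple = (np.nan, np.nan)
    obs_value_std_range: tuple = (np.nan, np.nan)
    df_method: str = "normal"
    notes: list = field(default_factory=list)

    @property
    def r2m(self) -> float:
        return r2_nakagawa(self)[0]

    @property
    def r2c(self) -> float:
        return r2_nakagawa(self)[1]


def _attach_meta(fit: MixedFit, meta: dict | None, frame: pd.DataFrame) -> MixedFit:
    if meta:
        fit.temp_mean = meta.get("temp_mean", np.nan)
        fit.temp_sd = meta.get("temp_sd", np.nan)
        fit.value_mean = meta.get("value_mean", np.nan)
        fit.value_sd = meta.get("value_sd", np.nan)
        fit.transform = meta.get("transform", "none")
        fit.offset = meta.get("offset", 0.0)
    if "temp_std" in frame:
        fit.obs_temp_std_range = (
            float(frame["temp_std"].min()), float(frame["temp_std"].max())
        )
    fit.obs_value_std_range = (
        float(frame["value_std"].min()), float(frame["value_std"].max())
    )
    return fit


def _perfect_fit(y: np.ndarray, X: pd.DataFrame) -> pd.Series | None:
    """Exact OLS solution when the data lie on the fixed-effect surface.

    With zero residual the profiled mixed-model likelihood is degenerate, so
    return the (exact) OLS coefficients instead of letting the optimizer
    wander.
    """
    beta, ssr, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
    resid = y - X.to_numpy() @ beta
    if np.max(np.abs(resid)) < 1e-10 * max(1.0, np.max(np.abs(y))):
        return pd.Series(beta, index=X.columns)
    return None


def _fit_md(md, reml: bool):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = md.fit(reml=reml)
            if res.converged:
                return res
        except np.linalg.LinAlgError:
            res = None
        retry = md.fit(reml=reml, method="powell", maxiter=2000)
        return retry if res is None or retry.converged else res


def _mixedlm(y, X: pd.DataFrame, groups, reml: bool):
    return _fit_md(sm.MixedLM(y, X, groups=groups), reml)


def _mixedlm_nested(df: pd.DataFrame, rhs_cols: list[str], reml: bool):
    """Random intercepts for species and plant-within-species via vc_formula."""
    formula = "value_std ~ " + " + ".join(rhs_cols)
    md = sm.MixedLM.from_formula(
        formula,
        data=df,
        groups="species",
        re_formula="1",
        vc_formula={"plant": "0 + C(plant_id)"},
    )
    return _fit_md(md, reml)


def _fit_to_mixedfit(
    res, trait, scope, formula, X, reml, n_groups, re_names=("plant",)
) -> MixedFit:
    fe = res.fe_params
    k_fe = len(fe)
    bse = res.bse[: k_fe]
    z = fe / bse
    p = 2 * stats.norm.sf(np.abs(z))
    re_var = {}
    if res.k_re > 0:
        re_var[re_names[0]] = float(np.asarray(res.cov_re)[0, 0])
    if getattr(res, "vcomp", None) is not None and len(res.vcomp):
        for name, v in zip(res.model.exog_vc.names, res.vcomp):
            re_var[name] = float(v)
    pred_fixed = X.to_numpy() @ fe.to_numpy()
    var_fixed = float(np.var(pred_fixed, ddof=1))
    k_par = k_fe + res.k_re + len(getattr(res, "vcomp", [])) + 1
    aic = float(2 * k_par - 2 * res.llf)
    return MixedFit(
        trait=trait,
        scope=scope,
        formula=formula,
        params=fe.copy(),
        bse=pd.Series(np.asarray(bse), index=fe.index),
        zvalues=pd.Series(np.asarray(z), index=fe.index),
        pvalues=pd.Series(p, index=fe.index),
        re_var=re_var,
        resid_var=float(res.scale),
        var_fixed=var_fixed,
        aic=aic,
        loglike=float(res.llf),
        reml=reml,
        converged=bool(res.converged),
        n_obs=int(res.nobs),
        n_groups=int(n_groups),
    )


def fit_quadratic_lmm(
    frame: pd.DataFrame,
    meta: dict | None = None,
    trait: str = "",
    scope: str = "per-species",
    reml: bool = True,
) -> MixedFit:
    """value ~ 1 + T + T^2 with a random intercept per plant.

    ``frame`` must carry standardized ``value_std`` and ``temp_std`` columns
    plus ``plant_id`` (as produced by ``preprocess.build_trait_frame``).
    """
    if frame["plant_id"].nunique() < 2:
        raise ModelDesignError("need >= 2 plants for a plant random intercept")
    if frame["temp_std"].nunique() < 3:
        raise ModelDesignError("need >= 3 temperature levels for a quadratic")
    trait = trait or (meta or {}).get("trait", "")
    y = frame["value_std"].to_numpy(dtype=float)
    X = pd.DataFrame(
        {
            "Intercept": np.ones(len(frame)),
            "temp": frame["temp_std"].to_numpy(dtype=float),
            "temp2": frame["temp_std"].to_numpy(dtype=float) ** 2,
        }
    )
    formula = "value ~ temp + temp2 + (1 | plant)"

    exact = _perfect_fit(y, X)
    if exact is not None:
        zeros = pd.Series(0.0, index=X.columns)
        fit = MixedFit(
            trait=trait, scope=scope, formula=formula, params=exact,
            bse=zeros, zvalues=zeros, pvalues=zeros.replace(0.0, np.nan),
            re_var={"plant": 0.0}, resid_var=0.0,
            var_fixed=float(np.var(X.to_numpy() @ exact.to_numpy(), ddof=1)),
            aic=-np.inf, loglike=np.inf, reml=reml, converged=True,
            n_obs=len(frame), n_groups=frame["plant_id"].nunique(),
        )
        fit.notes.append("perfect fit: exact interpolation, no stochastic variation")
        return _attach_meta(fit, meta, frame)

    res = _mixedlm(y, X, frame["plant_id"].to_numpy(), reml)
    fit = _fit_to_mixedfit(
        res, trait, scope, formula, X, reml, frame["plant_id"].nunique()
    )
    if not fit.converged:
        fit.notes.append("optimizer did not report convergence")
    return _attach_meta(fit, meta, frame)


_PRETTY = {
    "time_c": "time",
    "time_c2": "time2",
    "grp": "group",
    "time_grp": "time:group",
    "time2_grp": "time2:group",
    "temp_c": "temp",
    "temp_c2": "temp2",
    "temp_grp": "temp:group",
    "temp2_grp": "temp2:group",
}


def _rename(series: pd.Series) -> pd.Series:
    return series.rename(index=lambda c: _PRETTY.get(c, c))


def _fit_grouped(frame, cols: dict, formula, trait, scope, combined, reml):
    df = frame[["plant_id", "species", "value_std"]].copy()
    for name, values in cols.items():
        df[name] = values
    rhs = list(cols)
    if combined:
        if frame["species"].nunique() < 2:
            raise ModelDesignError("combined model needs >= 2 species")
        res = _mixedlm_nested(df, rhs, reml)
        X = df[rhs].copy()
        X.insert(0, "Intercept", 1.0)
        X = X.reindex(columns=res.fe_params.index)
        fit = _fit_to_mixedfit(
            res, trait, scope, formula + " + (1 | species/plant)", X, reml,
            frame["species"].nunique(), re_names=("species",),
        )
    else:
        X = pd.DataFrame({"Intercept": np.ones(len(df)), **{c: df[c].to_numpy() for c in rhs}})
        res = _mixedlm(df["value_std"].to_numpy(dtype=float), X,
                       frame["plant_id"].to_numpy(), reml)
        fit = _fit_to_mixedfit(
            res, trait, scope, formula + " + (1 | plant)", X, reml,
            frame["plant_id"].nunique(),
        )
    for attr in ("params", "bse", "zvalues", "pvalues"):
        setattr(fit, attr, _rename(getattr(fit, attr)))
    if not fit.converged:
        fit.notes.append("optimizer did not report convergence")
    return fit


def fit_time_group_interaction(
    frame: pd.DataFrame,
    meta: dict | None = None,
    trait: str = "",
    combined: bool = False,
    reml: bool = True,
) -> MixedFit:
    """Control-group validation: value ~ time*group + time^2*group.

    ``group`` is coded control = 0, experimental = 1.  The time x group
    interaction terms isolate the manipulated-temperature effect from the
    shared drift through the flowering period.  Per-species fits use a plant
    random intercept; the combined fit nests plant within species.
    """
    groups_present = set(frame["group"].unique())
    if groups_present != {"experimental", "control"}:
        raise ModelDesignError(
            f"need both experimental and control records, have {sorted(groups_present)}"
        )
    trait = trait or (meta or {}).get("trait", "")
    t = frame["time_std"].to_numpy(dtype=float)
    g = (frame["group"].to_numpy() == "experimental").astype(float)
    cols = {
        "time_c": t, "time_c2": t**2, "grp": g,
        "time_grp": t * g, "time2_grp": t**2 * g,
    }
    fit = _fit_grouped(
        frame, cols, "value ~ time*group + time2*group", trait,
        (meta or {}).get("scope", "pooled" if combined else "per-species"),
        combined, reml,
    )
    return _attach_meta(fit, meta, frame)


def fit_flowering_group_model(
    frame: pd.DataFrame,
    meta: dict | None = None,
    trait: str = "",
    quadratic: bool = True,
    reml: bool = True,
) -> MixedFit:
    """Early/late flowering contrast: value ~ T*group (+ T^2*group).

    ``frame`` needs a ``flowering_group`` column ('early'/'late'); plant is
    nested within species.  Set ``quadratic=False`` to drop the squared
    terms (used when AIC prefers the linear trend, e.g. for concentration).
    """
    groups_present = set(frame["flowering_group"].unique())
    if not groups_present.issuperset({"early", "late"}):
        raise ModelDesignError("need both early and late flowering groups")
    for g in ("early", "late"):
        if frame.loc[frame["flowering_group"] == g, "species"].nunique() < 2:
            warnings.warn(f"flowering group {g!r} has < 2 species", stacklevel=2)
    trait = trait or (meta or {}).get("trait", "")
    x = frame["temp_std"].to_numpy(dtype=float)
    g = (frame["flowering_group"].to_numpy() == "late").astype(float)
    if quadratic:
        cols = {
            "temp_c": x, "temp_c2": x**2, "grp": g,
            "temp_grp": x * g, "temp2_grp": x**2 * g,
        }
    else:
        cols = {"temp_c": x, "grp": g, "temp_grp": x * g}
    fit = _fit_grouped(
        frame, cols,
        "value ~ temp*flowering_group" + (" + temp2*flowering_group" if quadratic else ""),
        trait, (meta or {}).get("scope", "pooled"), combined=True, reml=reml,
    )
    return _attach_meta(fit, meta, frame)


def r2_nakagawa(fit: MixedFit) -> tuple[float, float]:
    """Marginal and conditional R² from the fit's variance decomposition.

    R²m = var(fixed) / (var(fixed) + Σ random + residual);
    R²c adds the random-intercept variances to the numerator.
    """
    if not fit.converged:
        raise ValueError("cannot compute R² for a non-converged fit")
    vr = sum(fit.re_var.values())
    total = fit.var_fixed + vr + fit.resid_var
    if total <= 0:
        return (np.nan, np.nan)
    return fit.var_fixed / total, (fit.var_fixed + vr) / total


def aic_select(frame: pd.DataFrame, meta: dict | None = None, trait: str = "") -> dict:
    """Compare linear vs quadratic temperature trends by ML AIC.

    Both models share the plant random-intercept structure and are refitted
    by maximum likelihood (REML AICs are not comparable across fixed
    effects).  Returns the winning label, ΔAIC and both fits.
    """
    trait = trait or (meta or {}).get("trait", "")
    y = frame["value_std"].to_numpy(dtype=float)
    x = frame["temp_std"].to_numpy(dtype=float)
    X_lin = pd.DataFrame({"Intercept": np.ones(len(frame)), "temp": x})
    X_quad = X_lin.assign(temp2=x**2)
    fits = {}
    for label, X in (("linear", X_lin), ("quadratic", X_quad)):
        res = _mixedlm(y, X, frame["plant_id"].to_numpy(), reml=False)
        fits[label] = _fit_to_mixedfit(
            res, trait, "per-species", f"value ~ {label} temp trend", X, False,
            frame["plant_id"].nunique(),
        )
    delta = fits["linear"].aic - fits["quadratic"].aic
    chosen = "quadratic" if delta > 0 else "linear"
    return {
        "chosen": chosen,
        "delta_aic": abs(delta),
        "aic": {k: f.aic for k, f in fits.items()},
        "fits": fits,
    }


# ---------------------------------------------------------------------------
# zero-inflated negative binomial for empty-flower counts

@dataclass
class ZinbFit:
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    zi_prob: float
    dispersion_alpha: float
    loglike: float
    converged: bool
    saturated: bool = False
    random_intercept_sd: float | None = None
    notes: list = field(default_factory=list)


def _zinb_loglike_obs(y, mu, alpha, pi):
    """Pointwise ZINB log-likelihood (NB2: var = mu + alpha mu^2).

    Stable in the Poisson limit alpha -> 0: all logs take arguments bounded
    away from 0 and 1.
    """
    size = 1.0 / max(alpha, 1e-12)
    log_p = np.log(size) - np.log(size + mu)     # log P(success)
    log_q = np.log(mu) - np.log(size + mu)       # log(1 - P)
    nb_logpmf = (
        gammaln(y + size) - gammaln(size) - gammaln(y + 1)
        + size * log_p + y * log_q
    )
    log_nb_zero = size * log_p
    ll = np.where(
        y == 0,
        np.log(pi + (1 - pi) * np.exp(np.maximum(log_nb_zero, -700))),
        np.log1p(-pi) + nb_logpmf,
    )
    return ll


def fit_zinb_empty(
    frame: pd.DataFrame,
    count_col: str = "n_empty",
    random_intercept: bool | None = None,
    meta: dict | None = None,
) -> ZinbFit:
    """Zero-inflated NB fit of empty-flower counts on temperature.

    The count mean is log-linear in ``temp_std`` and ``temp_std**2``; the
    zero-inflation probability is a single intercept-only parameter.  An
    optional plant random intercept (Gauss-Hermite marginalization) defaults
    to off for fewer than 10 plants, where the approximation is unstable.
    """
    y = frame[count_col].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ModelDesignError("counts must be non-negative integers")
    x = frame["temp_std"].to_numpy(dtype=float)
    names = ["Intercept", "temp", "temp2"]
    if np.all(y == 0):
        nanp = pd.Series(np.nan, index=names)
        return ZinbFit(
            params=nanp, bse=nanp, zvalues=nanp, pvalues=nanp,
            zi_prob=1.0, dispersion_alpha=np.nan, loglike=0.0,
            converged=True, saturated=True,
            notes=["all counts zero: zero-inflation saturated"],
        )
    n_plants = frame["plant_id"].nunique() if "plant_id" in frame else 0
    if random_intercept is None:
        random_intercept = False
    if random_intercept and n_plants < 10:
        random_intercept = False

    X = np.column_stack([np.ones_like(x), x, x**2])
    if random_intercept:
        return _fit_zinb_gh(y, X, frame["plant_id"].to_numpy(), names)
    return _fit_zinb_ml(y, X, names)


# dispersion parameterized as log(alpha); alpha -> 0 (Poisson limit) is the
# lower box bound, reached by underdispersed bounded counts
_LOG_ALPHA_BOUNDS = (-12.0, 5.0)


def _fit_zinb_ml(y: np.ndarray, X: np.ndarray, names) -> ZinbFit:
    """Direct ML fit of the intercept-only-inflation ZINB."""

    def negll(theta):
        gamma_infl = theta[0]
        beta = theta[1:-1]
        alpha = np.exp(theta[-1])
        with np.errstate(all="ignore"):
            mu = np.exp(np.clip(X @ beta, -30, 30))
            ll = _zinb_loglike_obs(y, mu, alpha, expit(gamma_infl))
        return -np.sum(ll)

    zero_frac = float(np.mean(y == 0))
    b0 = np.log(max(y[y > 0].mean(), 0.1)) if np.any(y > 0) else -2.0
    from scipy.special import logit as _logit

    starts = [
        np.array([_logit(max(min(zero_frac / 2, 0.9), 0.02)), b0, 0.0, 0.0, -1.0]),
        np.array([-2.0, b0, 0.0, 0.0, 0.0]),
        np.array([0.0, 0.0, 0.0, 0.0, -2.0]),
    ]
    bounds = [(-15, 15)] + [(-30, 30)] * (X.shape[1]) + [_LOG_ALPHA_BOUNDS]
    best = None
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        for s in starts:
            res = optimize.minimize(negll, s, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
    theta = best.x
    notes = []
    at_bound = theta[-1] <= _LOG_ALPHA_BOUNDS[0] + 1e-6
    if at_bound:
        notes.append("dispersion at Poisson limit (underdispersed counts)")

    # observed-information SEs; drop the dispersion row when it is pinned
    free = slice(0, len(theta) - 1) if at_bound else slice(0, len(theta))
    se = np.full(len(theta), np.nan)
    try:
        if at_bound:
            fixed = theta[-1]

            def nll_sub(t):
                return negll(np.concatenate([t, [fixed]]))

            hess = _numeric_hessian(nll_sub, theta[:-1])
        else:
            hess = _numeric_hessian(negll, theta)
        cov = np.linalg.inv(hess)
        se[free] = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        notes.append("observed information singular; SEs unavailable")

    beta = pd.Series(theta[1:-1], index=names)
    bse = pd.Series(se[1:-1], index=names)
    z = beta / bse
    return ZinbFit(
        params=beta,
        bse=bse,
        zvalues=z,
        pvalues=pd.Series(2 * stats.norm.sf(np.abs(z)), index=names),
        zi_prob=float(expit(theta[0])),
        dispersion_alpha=float(np.exp(theta[-1])),
        loglike=float(-best.fun),
        converged=bool(best.success),
        random_intercept_sd=None,
        notes=notes,
    )


def _fit_zinb_gh(y, X, plant_ids, names, n_nodes: int = 21) -> ZinbFit:
    """ZINB with a plant random intercept via Gauss-Hermite quadrature."""
    # probabilists' Hermite: weights integrate against exp(-x^2/2), so
    # E[f(b)] with b ~ N(0, sd^2) is sum w_k f(sd * node_k) / sqrt(2 pi)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    w_norm = weights / np.sqrt(2 * np.pi)
    plants = pd.unique(plant_ids)
    masks = [plant_ids == p for p in plants]

    def negll(theta):
        gamma_infl, b0, b1, b2, log_alpha, log_sd = theta
        pi = expit(np.clip(gamma_infl, -30, 30))
        alpha = np.exp(np.clip(log_alpha, -12.0, 5.0))
        sd = np.exp(np.clip(log_sd, -8.0, 3.0))
        eta = np.clip(X @ np.array([b0, b1, b2]), -30, 30)
        total = 0.0
        with np.errstate(all="ignore"):
            for m in masks:
                # loglik per GH node
                lls = np.empty(len(nodes))
                for k, b in enumerate(sd * nodes):
                    mu = np.exp(eta[m] + b)
                    lls[k] = np.sum(_zinb_loglike_obs(y[m], mu, alpha, pi))
                mx = lls.max()
                total += mx + np.log(np.sum(w_norm * np.exp(lls - mx)))
        return -total if np.isfinite(total) else 1e12

    # NB dispersion and the plant intercept variance compete for the same
    # overdispersion; multi-start to dodge the sd -> 0 local optimum
    b0 = np.log(max(y.mean(), 0.1))
    starts = [
        np.array([-2.0, b0, 0.0, 0.0, -5.0, np.log(0.5)]),
        np.array([-2.0, b0, 0.0, 0.0, 0.0, np.log(0.3)]),
        np.array([0.0, b0, 0.0, 0.0, -2.0, np.log(0.1)]),
    ]
    res = None
    for s in starts:
        cand = optimize.minimize(
            negll, s, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8},
        )
        if res is None or cand.fun < res.fun:
            res = cand
    theta = res.x
    # numerical Hessian for SEs
    try:
        hess = _numeric_hessian(negll, theta)
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_all = np.full(len(theta), np.nan)
    beta = pd.Series(theta[1:4], index=names)
    bse = pd.Series(se_all[1:4], index=names)
    z = beta / bse
    return ZinbFit(
        params=beta, bse=bse, zvalues=z,
        pvalues=pd.Series(2 * stats.norm.sf(np.abs(z)), index=names),
        zi_prob=float(expit(np.clip(theta[0], -30, 30))),
        dispersion_alpha=float(np.exp(np.clip(theta[4], -12.0, 5.0))),
        loglike=float(-res.fun),
        converged=bool(res.success),
        random_intercept_sd=float(np.exp(np.clip(theta[5], -8.0, 3.0))),
        notes=["plant random intercept via Gauss-Hermite quadrature"],
    )


def _numeric_hessian(f, x, h: float = 1e-4):
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H
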
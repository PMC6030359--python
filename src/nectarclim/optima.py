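"""Temperature optima and the 5%-band optimal temperature range.

A fitted quadratic ``y = b0 + b1 x + b2 x**2`` (x = standardized 24-h mean
temperature) has its vertex at ``x* = -b1 / (2 b2)``.  The optimal range is
the interval over which the curve stays within ``delta`` of the vertex
value, where ``delta`` is 5% of the observed trait-value range on the model
(transformed, standardized) scale; in closed form ``x* ± sqrt(delta/|b2|)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import MixedFit

CONCAVE = "unimodal_concave"
CONVEX = "unimodal_convex"
LINEAR_UP = "linear_increasing"
LINEAR_DOWN = "linear_decreasing"
FLAT = "flat"

SHAPE_SYMBOLS = {
    CONCAVE: "∩",   # ∩
    CONVEX: "∪",    # ∪
    LINEAR_UP: "/",
    LINEAR_DOWN: "\\",
    FLAT: "-",
}

BETA_TOL = 1e-12


class NoOptimumError(ValueError):
    """The fitted shape has no interior optimum."""


class NoRangeError(ValueError):
    """The fitted shape does not admit a 5%-band interval."""


def significance_band(p: float) -> str:
    """Annotation bands: *** < 0.001 < ** < 0.01 < * < 0.05 < . < 0.1 < ns."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return "ns"


@dataclass
class OptimalRange:
    trait: str
    species: str
    t_opt: float
    t_lo: float
    t_hi: float
    delta: float
    shape: str
    quadratic_p: float
    annotation: str
    extrapolated: bool
    truncated: bool = False


def _coef(fit: MixedFit, name: str) -> float:
    return float(fit.params.get(name, 0.0))


def classify_shape(fit: MixedFit, alpha: float = 0.05, tol: float = BETA_TOL):
    """Shape from coefficient point estimates; significance is annotation only."""
    if not fit.converged:
        raise ValueError("cannot classify a non-converged fit")
    b1, b2 = _coef(fit, "temp"), _coef(fit, "temp2")
    p2 = float(fit.pvalues.get("temp2", np.nan))
    p1 = float(fit.pvalues.get("temp", np.nan))
    if abs(b2) > tol:
        shape = CONCAVE if b2 < 0 else CONVEX
        return shape, significance_band(p2)
    if abs(b1) > tol:
        return (LINEAR_UP if b1 > 0 else LINEAR_DOWN), significance_band(p1)
    return FLAT, ""


def destandardize_temperature(x, mean: float, sd: float):
    """Inverse of temperature standardization: mean + sd * x."""
    if not sd > 0:
        raise ValueError(f"temperature SD must be > 0, got {sd}")
    return mean + sd * np.asarray(x, dtype=float) if np.ndim(x) else mean + sd * float(x)


def optimum_temperature(fit: MixedFit, tol: float = BETA_TOL) -> tuple[float, bool]:
    """Vertex of the fitted quadratic in °C plus an extrapolation flag.

    The flag is set when the vertex lies outside the observed standardized
    temperature range (the fitted curve peaks beyond the tested schedule).
    """
    b1, b2 = _coef(fit, "temp"), _coef(fit, "temp2")
    if abs(b2) <= tol:
        raise NoOptimumError("quadratic coefficient is zero: no vertex")
    x_star = -b1 / (2.0 * b2)
    lo, hi = fit.obs_temp_std_range
    extrapolated = bool(x_star < lo or x_star > hi)
    return float(destandardize_temperature(x_star, fit.temp_mean, fit.temp_sd)), extrapolated


def optimal_range(
    fit: MixedFit,
    observed_min: float | None = None,
    observed_max: float | None = None,
    band_fraction: float = 0.05,
    truncate: bool = False,
    alpha: float = 0.05,
    species: str = "",
) -> OptimalRange:
    """5%-band temperature interval around the fitted optimum.

    ``observed_min``/``observed_max`` bound the measured trait values on the
    model scale (defaults: the range stored in the fit).  For a convex fit
    the band sits above the minimum (same formula on the negated curve).
    Linear and flat shapes raise :class:`NoRangeError`.  With
    ``truncate=True`` the interval is clipped to the tested temperature
    range; the default reports the analytic interval.
    """
    shape, annotation = classify_shape(fit, alpha=alpha)
    if shape not in (CONCAVE, CONVEX):
        raise NoRangeError(f"no optimal range for shape {shape!r}")
    if observed_min is None or observed_max is None:
        observed_min, observed_max = fit.obs_value_std_range
    if not observed_max > observed_min:
        raise ValueError("observed trait range must have positive width")
    delta = band_fraction * (observed_max - observed_min)

    b1, b2 = _coef(fit, "temp"), _coef(fit, "temp2")
    x_star = -b1 / (2.0 * b2)
    half_width = np.sqrt(delta / abs(b2))
    x_lo, x_hi = x_star - half_width, x_star + half_width
    lo_obs, hi_obs = fit.obs_temp_std_range
    truncated = False
    if truncate:
        new_lo, new_hi = max(x_lo, lo_obs), min(x_hi, hi_obs)
        truncated = (new_lo, new_hi) != (x_lo, x_hi)
        x_lo, x_hi = new_lo, new_hi
    t_opt, extrapolated = optimum_temperature(fit)
    return OptimalRange(
        trait=fit.trait,
        species=species,
        t_opt=t_opt,
        t_lo=float(destandardize_temperature(x_lo, fit.temp_mean, fit.temp_sd)),
        t_hi=float(destandardize_temperature(x_hi, fit.temp_mean, fit.temp_sd)),
        delta=float(delta),
        shape=shape,
        quadratic_p=float(fit.pvalues.get("temp2", np.nan)),
        annotation=annotation,
        extrapolated=extrapolated,
        truncated=truncated,
    )


def format_range(opt: OptimalRange, decimals: int = 1) -> str:
    """Render as 'T_opt (T_lo-T_hi)' in °C, e.g. '15.7 (11.1-20.3)'."""
    f = f"{{:.{decimals}f}}"
    return (
        f"{f.format(opt.t_opt)} ({f.format(opt.t_lo)}–{f.format(opt.t_hi)})"
    )
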
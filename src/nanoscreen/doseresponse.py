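"""Hill-equation IC50 estimation from concentration–viability data.

The four-parameter logistic (Hill) model

    V(c) = bottom + (top - bottom) / (1 + (c / IC50)^h)

describes viability falling from ``top`` (no drug) to ``bottom`` (saturating
drug) with half-maximal inhibition at c = IC50 and steepness h.  Because
viability is control-normalised, top and bottom default to 100 and 0 and are
fixed; they can be freed.  The fit runs in log10(IC50) space for
conditioning, by nonlinear least squares; the IC50 standard error comes from
the parameter covariance at the optimum (delta method back to the µM scale)
or, optionally, from a seeded bootstrap over replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

__all__ = ["DoseResponseData", "HillFit", "HillFitError", "hill_model", "fit_ic50"]


class HillFitError(RuntimeError):
    """Degenerate or impossible dose–response fit."""


@dataclass(frozen=True)
class DoseResponseData:
    """Concentration (µM) / viability (%) pairs; replicates share a concentration."""

    concentrations_uM: np.ndarray
    viability_pct: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_uM, dtype=float)
        v = np.asarray(self.viability_pct, dtype=float)
        object.__setattr__(self, "concentrations_uM", c)
        object.__setattr__(self, "viability_pct", v)
        if c.ndim != 1 or v.ndim != 1 or c.size != v.size:
            raise ValueError("concentrations and viabilities must match in length")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("viabilities must be finite and non-negative")
        if np.unique(c).size < 4:
            raise ValueError("need >= 4 distinct concentrations for a stable fit")


def hill_model(
    concentration_uM,
    ic50_uM: float,
    hill_coefficient: float,
    top_pct: float = 100.0,
    bottom_pct: float = 0.0,
):
    """Predicted viability % under the Hill model (vectorised over concentration)."""
    if ic50_uM <= 0 or hill_coefficient <= 0:
        raise ValueError("ic50 and hill coefficient must be positive")
    c = np.asarray(concentration_uM, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (c / ic50_uM) ** hill_coefficient, 0.0)
    out = bottom_pct + (top_pct - bottom_pct) / (1.0 + ratio)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters with uncertainty and goodness of fit."""

    ic50_uM: float
    hill_coefficient: float
    top_pct: float
    bottom_pct: float
    ic50_se: float
    r_squared: float
    converged: bool
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "ic50_uM": self.ic50_uM,
            "hill_coefficient": self.hill_coefficient,
            "top_pct": self.top_pct,
            "bottom_pct": self.bottom_pct,
            "ic50_se": self.ic50_se,
            "r_squared": self.r_squared,
            "converged": self.converged,
            "message": self.message,
        }


def _model_logspace(c, log10_ic50, h, top, bottom):
    return bottom + (top - bottom) / (1.0 + (c / 10.0**log10_ic50) ** h)


def fit_ic50(
    data: DoseResponseData,
    fix_top: Optional[float] = 100.0,
    fix_bottom: Optional[float] = 0.0,
    se_method: str = "covariance",
    n_bootstrap: int = 1000,
    seed: Optional[int] = None,
) -> HillFit:
    """Least-squares Hill fit; returns IC50 (µM) with SE, slope and r².

    Initialisation: IC50 at the geometric mean of the tested concentrations,
    hill coefficient 1.  ``fix_top``/``fix_bottom`` pin the asymptotes
    (``None`` frees them).  ``se_method`` is ``"covariance"`` (delta method on
    the covariance of log10 IC50) or ``"bootstrap"`` (seeded resampling of
    replicates within each concentration).

    A monotonically increasing dose–viability relationship cannot be
    described by an inhibitory Hill curve; such fits come back with
    ``converged=False`` and an explanatory message.
    """
    c = data.concentrations_uM
    v = data.viability_pct
    if np.all(v == v[0]):
        raise HillFitError("all viabilities equal: dose-response fit is degenerate")

    p0 = [float(np.mean(np.log10(c))), 1.0]
    lo = [-9.0, 1e-3]
    hi = [9.0, 50.0]
    if fix_top is None:
        p0.append(float(np.max(v)))
        lo.append(-np.inf)
        hi.append(np.inf)
    if fix_bottom is None:
        p0.append(float(np.min(v)))
        lo.append(-np.inf)
        hi.append(np.inf)

    def model(cc, *params):
        log_ic50, h = params[0], params[1]
        idx = 2
        top = fix_top
        if top is None:
            top = params[idx]
            idx += 1
        bottom = fix_bottom if fix_bottom is not None else params[idx]
        return _model_logspace(cc, log_ic50, h, top, bottom)

    message = ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                model, c, v, p0=p0, bounds=(lo, hi), maxfev=20000
            )
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError as exc:
        popt, pcov = np.array(p0), np.full((len(p0), len(p0)), np.nan)
        converged = False
        message = f"optimizer failed: {exc}"

    log_ic50, h = float(popt[0]), float(popt[1])
    ic50 = 10.0**log_ic50
    idx = 2
    top = fix_top
    if top is None:
        top = float(popt[idx])
        idx += 1
    bottom = fix_bottom if fix_bottom is not None else float(popt[idx])

    pred = model(c, *popt)
    ss_res = float(np.sum((v - pred) ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    # non-informative fits: slope collapsed to a bound or IC50 far outside
    # the tested range (e.g. viability increasing with dose)
    if converged:
        rho = stats.spearmanr(c, v).statistic
        if h <= 2e-3 or h >= hi[1] - 1e-6:
            converged = False
            message = "hill coefficient hit a bound: non-informative fit"
        elif not (c.min() / 100.0 <= ic50 <= c.max() * 100.0):
            converged = False
            message = "IC50 far outside the tested concentration range"
        elif rho is not None and rho > 0.5:
            converged = False
            message = "viability increases with dose: inhibitory model misfit"

    if se_method == "bootstrap":
        ic50_se = _bootstrap_se(
            data, fix_top, fix_bottom, n_bootstrap, seed
        )
    else:
        var_log = pcov[0, 0] if np.all(np.isfinite(pcov)) else np.nan
        ic50_se = (
            float(math.log(10.0) * ic50 * math.sqrt(var_log))
            if np.isfinite(var_log)
            else float("nan")
        )

    return HillFit(
        ic50_uM=ic50,
        hill_coefficient=h,
        top_pct=float(top),
        bottom_pct=float(bottom),
        ic50_se=ic50_se,
        r_squared=r2,
        converged=converged,
        message=message,
    )


def _bootstrap_se(
    data: DoseResponseData,
    fix_top: Optional[float],
    fix_bottom: Optional[float],
    n_bootstrap: int,
    seed: Optional[int],
) -> float:
    """SE of IC50 by resampling replicates within each concentration."""
    rng = np.random.default_rng(seed)
    c = data.concentrations_uM
    v = data.viability_pct
    levels = np.unique(c)
    estimates = []
    for _ in range(n_bootstrap):
        vb = np.empty_like(v)
        for lev in levels:
            mask = c == lev
            vals = v[mask]
            vb[mask] = rng.choice(vals, size=vals.size, replace=True)
        try:
            fit = fit_ic50(
                DoseResponseData(c, vb),
                fix_top=fix_top,
                fix_bottom=fix_bottom,
                se_method="covariance",
            )
        except HillFitError:
            continue
        if np.isfinite(fit.ic50_uM):
            estimates.append(fit.ic50_uM)
    if len(estimates) < 2:
        return float("nan")
    return float(np.std(estimates, ddof=1))
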
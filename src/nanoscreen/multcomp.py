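"""Many-to-one (Dunnett) and all-pairs (Tukey HSD) adjusted p-values.

Dunnett's statistics T_j = (mean_j - mean_0) / (s_p * sqrt(1/n_j + 1/n_0))
share the control mean and the pooled error estimate, so under the null they
follow a multivariate t distribution with the one-factor correlation
structure rho_ij = lambda_i * lambda_j, lambda_j = sqrt(n_j / (n_j + n_0))
(rho = 1/2 for balanced designs).  The two-sided adjusted p-value of
comparison i is

    p_i = 1 - P(max_j |T_j| <= |t_i|),

and the maximum probability factorises over a shared standard-normal Z and
the pooled scale S = sqrt(chi2_df / df):

    P(q) = E_{S,Z} prod_j [ Phi((qS - l_j Z)/c_j) - Phi((-qS - l_j Z)/c_j) ],

with c_j = sqrt(1 - l_j^2).  The expectation is evaluated by deterministic
Gauss–Hermite (Z) x Gauss–Legendre (S) quadrature, accurate to ~1e-12; for a
single contrast it reduces to the ordinary two-sided pooled t-test p-value.

Tukey HSD uses the studentized-range distribution with the Tukey–Kramer
standard error for (possibly) unbalanced pairs.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = ["dunnett_max_abs_prob", "dunnett_pvalues", "tukey_pvalues"]


def dunnett_max_abs_prob(
    q: float,
    lam: Sequence[float],
    df: float,
    n_hermite: int = 64,
    n_scale: int = 96,
) -> float:
    """P(max_j |T_j| <= q) for the factor-correlated multivariate t."""
    if q <= 0:
        return 0.0
    lam = np.asarray(lam, dtype=float)
    c = np.sqrt(1.0 - lam**2)
    # scale nodes: Gauss-Legendre over the effective support of S
    lo = np.sqrt(stats.chi2.ppf(1e-13, df) / df)
    hi = np.sqrt(stats.chi2.ppf(1.0 - 1e-13, df) / df)
    xs, ws = np.polynomial.legendre.leggauss(n_scale)
    s = 0.5 * (hi - lo) * (xs + 1.0) + lo
    ws = 0.5 * (hi - lo) * ws
    log_fs = (
        np.log(2.0)
        + 0.5 * df * np.log(df / 2.0)
        - gammaln(df / 2.0)
        + (df - 1.0) * np.log(s)
        - df * s**2 / 2.0
    )
    fs = np.exp(log_fs)
    xh, wh = np.polynomial.hermite.hermgauss(n_hermite)
    z = np.sqrt(2.0) * xh
    wz = wh / np.sqrt(np.pi)

    S = s[:, None, None]
    Z = z[None, :, None]
    F = stats.norm.cdf((q * S - lam * Z) / c) - stats.norm.cdf((-q * S - lam * Z) / c)
    P = np.prod(F, axis=2)
    return float(np.clip((ws * fs) @ (P @ wz), 0.0, 1.0))


def dunnett_pvalues(
    t_values: Sequence[float],
    n_treat: Sequence[int],
    n_control: int,
    df: float,
) -> np.ndarray:
    """Two-sided Dunnett-adjusted p-values for treatment-vs-control t statistics."""
    t_values = np.asarray(t_values, dtype=float)
    n_treat = np.asarray(n_treat, dtype=float)
    lam = np.sqrt(n_treat / (n_treat + float(n_control)))
    return np.array(
        [1.0 - dunnett_max_abs_prob(abs(t), lam, df) for t in t_values]
    )


def tukey_pvalues(
    t_values: Sequence[float], n_groups: int, df: float
) -> np.ndarray:
    """Studentized-range adjusted p-values from pairwise t statistics.

    The pairwise statistic q = sqrt(2)*|t| is referred to the studentized
    range with ``n_groups`` means; for two groups this collapses to the
    two-sided t-test p-value.
    """
    t_values = np.asarray(t_values, dtype=float)
    q = np.sqrt(2.0) * np.abs(t_values)
    return stats.studentized_range.sf(q, n_groups, df)
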
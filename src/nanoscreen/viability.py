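"""Viability normalisation and the gated cytotoxicity statistics pipeline.

The workflow mirrors how XTT plate data are analysed for nanoparticle
cytotoxicity: absorbances are normalised to percent viability against an
untreated control, distributional assumptions are checked per group
(Shapiro–Wilk) and across groups (Levene), a one-way fixed-effects ANOVA with
partial eta squared quantifies the concentration effect, Dunnett compares
every treatment with the control while Tukey HSD compares all pairs, a
Kruskal–Wallis test re-validates the omnibus result whenever any group fails
normality, and Hedges' g (with the small-sample correction
J = 1 - 3/(4N - 9)) reports standardised effect sizes.

The ANOVA is always run; Kruskal–Wallis is run *in addition*, not instead,
when normality fails — the pipeline validates rather than switches tests.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from nanoscreen.multcomp import dunnett_pvalues, tukey_pvalues

__all__ = [
    "ViabilityGroup",
    "ViabilityPlate",
    "AssumptionReport",
    "OmnibusReport",
    "PosthocReport",
    "EffectSizeReport",
    "ViabilityReport",
    "PlateError",
    "normalize_viability",
    "replicate_summary",
    "assumption_checks",
    "omnibus_tests",
    "posthoc_tests",
    "effect_sizes",
    "hedges_g",
    "kruskal_exact",
    "run_viability_pipeline",
    "read_plate_csv",
]


class PlateError(ValueError):
    """Invalid plate structure."""


@dataclass(frozen=True)
class ViabilityGroup:
    """One labelled concentration group of replicate viability percentages."""

    label: str
    concentration_uM: Optional[float]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise PlateError(f"group {self.label!r} needs >= 2 replicates")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise PlateError(f"group {self.label!r} has negative or non-finite values")
        if self.concentration_uM is not None and self.concentration_uM < 0:
            raise PlateError("concentration must be non-negative")


@dataclass(frozen=True)
class ViabilityPlate:
    """Ordered concentration groups plus the designated control label."""

    groups: Tuple[ViabilityGroup, ...]
    control_label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        labels = [g.label for g in self.groups]
        if labels.count(self.control_label) != 1:
            raise PlateError(
                f"exactly one group must carry the control label {self.control_label!r}"
            )
        if len(set(labels)) != len(labels):
            raise PlateError("group labels must be unique")

    @property
    def control(self) -> ViabilityGroup:
        return next(g for g in self.groups if g.label == self.control_label)

    @property
    def treatments(self) -> Tuple[ViabilityGroup, ...]:
        return tuple(g for g in self.groups if g.label != self.control_label)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": g.label,
                "concentration_uM": g.concentration_uM,
                "replicate": i + 1,
                "viability_pct": v,
            }
            for g in self.groups
            for i, v in enumerate(g.values)
        ]
        return pd.DataFrame(rows)


def read_plate_csv(path, control_label: str) -> ViabilityPlate:
    """Read a long-format plate CSV.

    Expects columns ``group`` and either ``viability_pct`` or ``absorbance``
    (plus optional ``concentration_uM``).  Absorbance input is normalised to
    percent viability against the control group mean.
    """
    df = pd.read_csv(path)
    if "group" not in df.columns:
        raise PlateError("plate CSV needs a 'group' column")
    value_col = "viability_pct" if "viability_pct" in df.columns else "absorbance"
    if value_col not in df.columns:
        raise PlateError("plate CSV needs 'viability_pct' or 'absorbance'")
    groups = []
    for label, sub in df.groupby("group", sort=False):
        conc = None
        if "concentration_uM" in sub.columns:
            c = sub["concentration_uM"].iloc[0]
            conc = None if pd.isna(c) else float(c)
        groups.append(ViabilityGroup(str(label), conc, sub[value_col].to_numpy(float)))
    plate = ViabilityPlate(tuple(groups), control_label)
    if value_col == "absorbance":
        plate = normalize_viability(plate, control_label)
    return plate


def normalize_viability(
    absorbance_plate: ViabilityPlate,
    control_label: Optional[str] = None,
    blank: float = 0.0,
) -> ViabilityPlate:
    """Convert absorbances to percent viability against the control mean.

    viability% = 100 * (A - blank) / (mean(A_control) - blank); the control
    group mean is exactly 100 after normalisation.  Blank subtraction is off
    by default.
    """
    control_label = control_label or absorbance_plate.control_label
    ctrl = next(
        (g for g in absorbance_plate.groups if g.label == control_label), None
    )
    if ctrl is None:
        raise PlateError(f"control label {control_label!r} not found")
    denom = float(np.mean(ctrl.values)) - blank
    if denom <= 0:
        raise PlateError("control mean absorbance (after blank) must be positive")
    groups = tuple(
        ViabilityGroup(
            g.label, g.concentration_uM, 100.0 * (g.values - blank) / denom
        )
        for g in absorbance_plate.groups
    )
    return ViabilityPlate(groups, control_label)


def replicate_summary(
    values: Sequence[float], decimals: int = 1
) -> Tuple[float, float]:
    """Mean and sample standard deviation (n-1), rounded to ``decimals``.

    The convention used for replicate measurement tables such as triplicate
    zeta potentials.  A single value yields sd = 0 with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("replicate_summary needs at least one value")
    if v.size == 1:
        warnings.warn("single replicate: standard deviation reported as 0")
        return round(float(v[0]), decimals), 0.0
    return (
        round(float(np.mean(v)), decimals),
        round(float(np.std(v, ddof=1)), decimals),
    )


@dataclass(frozen=True)
class AssumptionReport:
    """Per-group Shapiro–Wilk and across-group Levene results."""

    shapiro: pd.DataFrame  # columns: group, W, p, normal, note
    levene_W: float
    levene_p: float
    alpha: float
    all_normal: bool
    homoscedastic: bool


def assumption_checks(plate: ViabilityPlate, alpha: float = 0.05) -> AssumptionReport:
    """Shapiro–Wilk normality per group and classic (mean-centred) Levene test.

    A constant group has no defined W statistic; it is flagged non-normal
    with an explanatory note rather than raising.
    """
    rows = []
    for g in plate.groups:
        if np.unique(g.values).size < 3:
            rows.append(
                {
                    "group": g.label,
                    "W": np.nan,
                    "p": np.nan,
                    "normal": False,
                    "note": "normality undefined: fewer than 3 distinct values",
                }
            )
            continue
        W, p = stats.shapiro(g.values)
        rows.append(
            {"group": g.label, "W": float(W), "p": float(p), "normal": p > alpha, "note": ""}
        )
    shapiro_df = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lev_W, lev_p = stats.levene(*[g.values for g in plate.groups], center="mean")
    if not np.isfinite(lev_W):
        # every group has zero spread: no evidence of heteroscedasticity
        lev_W, lev_p = 0.0, 1.0
    return AssumptionReport(
        shapiro=shapiro_df,
        levene_W=float(lev_W),
        levene_p=float(lev_p),
        alpha=alpha,
        all_normal=bool(shapiro_df["normal"].all()),
        homoscedastic=bool(lev_p > alpha),
    )


@dataclass(frozen=True)
class OmnibusReport:
    """One-way ANOVA with partial eta squared, plus Kruskal–Wallis."""

    F: float
    df_between: int
    df_within: int
    p_anova: float
    partial_eta_sq: float
    H: float
    p_kw: float
    kw_run: bool = False


def _anova_sums(groups: Sequence[np.ndarray]) -> Tuple[float, float, int, int]:
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    dfb = len(groups) - 1
    dfw = allv.size - len(groups)
    return ssb, ssw, dfb, dfw


def omnibus_tests(plate: ViabilityPlate, kw_run: bool = False) -> OmnibusReport:
    """One-way fixed-effects ANOVA, partial eta squared and Kruskal–Wallis H.

    partial eta² = SS_between / (SS_between + SS_within), which for the
    one-way layout equals SS_between / SS_total.  With zero within-group
    variance and unequal means, F is reported as +inf with a warning.
    """
    groups = [g.values for g in plate.groups]
    if len(groups) < 2:
        raise PlateError("omnibus tests need at least 2 groups")
    ssb, ssw, dfb, dfw = _anova_sums(groups)
    sst = ssb + ssw
    eta = ssb / sst if sst > 0 else 0.0
    if ssw == 0.0:
        if ssb > 0.0:
            warnings.warn("zero within-group variance with unequal means: F = +inf")
            F, p = math.inf, 0.0
        else:
            F, p = 0.0, 1.0
    else:
        F = (ssb / dfb) / (ssw / dfw)
        p = float(stats.f.sf(F, dfb, dfw))
    H, p_kw = stats.kruskal(*groups)
    return OmnibusReport(
        F=float(F),
        df_between=dfb,
        df_within=dfw,
        p_anova=p,
        partial_eta_sq=float(eta),
        H=float(H),
        p_kw=float(p_kw),
        kw_run=kw_run,
    )


def _kw_statistic(groups: Sequence[np.ndarray]) -> float:
    """Kruskal–Wallis H with tie correction (matches the standard definition)."""
    allv = np.concatenate(groups)
    n = allv.size
    ranks = stats.rankdata(allv)
    offset = 0
    h = 0.0
    for g in groups:
        r = ranks[offset : offset + g.size]
        h += r.sum() ** 2 / g.size
        offset += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(allv, return_counts=True)
    tie = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    if tie == 0.0:
        return 0.0
    return h / tie


def kruskal_exact(
    groups: Sequence[Sequence[float]], max_layouts: int = 500_000
) -> Tuple[float, float]:
    """Kruskal–Wallis H with an exact permutation p-value.

    Enumerates every distinct assignment of the pooled observations into
    groups of the observed sizes and reports the fraction whose H statistic
    is at least the observed one (ties in the data are handled by midranks
    throughout, so tied layouts are counted identically).  Intended for small
    samples; raises if the layout count exceeds ``max_layouts``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)
    n = pooled.size
    total = math.factorial(n)
    for s in sizes:
        total //= math.factorial(s)
    if total > max_layouts:
        raise ValueError(f"{total} layouts exceed max_layouts={max_layouts}")

    h_obs = _kw_statistic(groups)
    ranks = stats.rankdata(pooled)

    count = 0
    n_total = 0
    indices = list(range(n))

    def assignments(remaining: List[int], sizes_left: List[int]):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = [i for i in remaining if i not in combo]
            for tail in assignments(rest, sizes_left[1:]):
                yield [list(combo)] + tail

    for layout in assignments(indices, sizes):
        perm_groups = [ranks[idx] for idx in layout]
        n_tot = n
        h = 0.0
        for r in perm_groups:
            h += r.sum() ** 2 / r.size
        h = 12.0 / (n_tot * (n_tot + 1)) * h - 3.0 * (n_tot + 1)
        _, counts = np.unique(pooled, return_counts=True)
        tie = 1.0 - float(np.sum(counts**3 - counts)) / (n_tot**3 - n_tot)
        h = 0.0 if tie == 0.0 else h / tie
        n_total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return h_obs, count / n_total


@dataclass(frozen=True)
class PosthocReport:
    """Dunnett many-to-one and Tukey HSD all-pairs tables."""

    dunnett: pd.DataFrame  # group, mean_diff, t, p_unadjusted, p_adjusted
    tukey: pd.DataFrame  # group_1, group_2, mean_diff, t, p_unadjusted, p_adjusted


def _pooled_error(groups: Sequence[np.ndarray]) -> Tuple[float, int]:
    dfw = sum(g.size for g in groups) - len(groups)
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    return ssw / dfw, dfw


def posthoc_tests(
    plate: ViabilityPlate, control_label: Optional[str] = None
) -> PosthocReport:
    """Dunnett (vs control) and Tukey HSD (all pairs) with adjusted p-values.

    Both procedures share the ANOVA pooled error variance.  Dunnett p-values
    come from the multivariate-t maximum via deterministic quadrature
    (:mod:`nanoscreen.multcomp`); with a single treatment group this reduces
    exactly to the pooled two-sample t-test.  Tukey p-values come from the
    studentized-range distribution with the Tukey–Kramer standard error.
    """
    control_label = control_label or plate.control_label
    if not any(g.label == control_label for g in plate.groups):
        raise PlateError(f"control label {control_label!r} not found")
    ctrl = next(g for g in plate.groups if g.label == control_label)
    treats = [g for g in plate.groups if g.label != control_label]
    if not treats:
        raise PlateError("posthoc tests need at least one treatment group")
    all_groups = [g.values for g in plate.groups]
    ms_error, dfw = _pooled_error(all_groups)
    if ms_error <= 0:
        raise PlateError("zero pooled error variance: post-hoc tests undefined")

    # Dunnett: every treatment vs control
    t_vals, diffs = [], []
    for g in treats:
        se = math.sqrt(ms_error * (1.0 / g.values.size + 1.0 / ctrl.values.size))
        diff = float(g.values.mean() - ctrl.values.mean())
        diffs.append(diff)
        t_vals.append(diff / se)
    p_adj = dunnett_pvalues(
        t_vals, [g.values.size for g in treats], ctrl.values.size, dfw
    )
    p_raw = 2.0 * stats.t.sf(np.abs(t_vals), dfw)
    dunnett_df = pd.DataFrame(
        {
            "group": [g.label for g in treats],
            "mean_diff": diffs,
            "t": t_vals,
            "p_unadjusted": p_raw,
            "p_adjusted": np.maximum(p_adj, p_raw),
        }
    )

    # Tukey HSD over all pairs (Tukey-Kramer for unbalanced)
    k = len(plate.groups)
    rows = []
    for g1, g2 in itertools.combinations(plate.groups, 2):
        se = math.sqrt(ms_error * (1.0 / g1.values.size + 1.0 / g2.values.size))
        diff = float(g1.values.mean() - g2.values.mean())
        t = diff / se
        rows.append((g1.label, g2.label, diff, t))
    t_pair = np.array([r[3] for r in rows])
    p_adj_t = tukey_pvalues(t_pair, k, dfw)
    p_raw_t = 2.0 * stats.t.sf(np.abs(t_pair), dfw)
    tukey_df = pd.DataFrame(
        {
            "group_1": [r[0] for r in rows],
            "group_2": [r[1] for r in rows],
            "mean_diff": [r[2] for r in rows],
            "t": t_pair,
            "p_unadjusted": p_raw_t,
            "p_adjusted": np.maximum(p_adj_t, p_raw_t),
        }
    )
    return PosthocReport(dunnett=dunnett_df, tukey=tukey_df)


def hedges_g(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Hedges' g and its correction factor J for two samples.

    g = J * (mean_x - mean_y) / s_pooled with the df-weighted pooled standard
    deviation and J = 1 - 3/(4N - 9), N the combined sample size.  Zero
    pooled variance makes g undefined (returned as nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need >= 2 values")
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    N = nx + ny
    J = 1.0 - 3.0 / (4.0 * N - 9.0)
    if sp2 == 0.0:
        if x.mean() == y.mean():
            return 0.0, J
        return math.nan, J
    return float(J * (x.mean() - y.mean()) / math.sqrt(sp2)), J


@dataclass(frozen=True)
class EffectSizeReport:
    """Hedges' g for each treatment-vs-control comparison."""

    comparisons: pd.DataFrame  # group_1, group_2, hedges_g, correction_J, defined


def effect_sizes(
    plate: ViabilityPlate,
    control_label: Optional[str] = None,
    all_pairs: bool = False,
) -> EffectSizeReport:
    """Standardised effect sizes (Hedges' g) vs control, optionally all pairs."""
    control_label = control_label or plate.control_label
    ctrl = next(
        (g for g in plate.groups if g.label == control_label), None
    )
    if ctrl is None:
        raise PlateError(f"control label {control_label!r} not found")
    if all_pairs:
        pairs = list(itertools.combinations(plate.groups, 2))
    else:
        pairs = [(g, ctrl) for g in plate.groups if g.label != control_label]
    rows = []
    for g1, g2 in pairs:
        g, J = hedges_g(g1.values, g2.values)
        rows.append(
            {
                "group_1": g1.label,
                "group_2": g2.label,
                "hedges_g": g,
                "correction_J": J,
                "defined": not math.isnan(g),
            }
        )
    return EffectSizeReport(comparisons=pd.DataFrame(rows))


@dataclass(frozen=True)
class ViabilityReport:
    """Composite report from the full gated pipeline."""

    assumptions: AssumptionReport
    omnibus: OmnibusReport
    posthoc: PosthocReport
    effects: EffectSizeReport

    def to_dict(self) -> dict:
        return {
            "assumptions": {
                "shapiro": self.assumptions.shapiro.to_dict(orient="records"),
                "levene_W": self.assumptions.levene_W,
                "levene_p": self.assumptions.levene_p,
                "alpha": self.assumptions.alpha,
                "all_normal": self.assumptions.all_normal,
                "homoscedastic": self.assumptions.homoscedastic,
            },
            "omnibus": {
                "F": self.omnibus.F,
                "df_between": self.omnibus.df_between,
                "df_within": self.omnibus.df_within,
                "p_anova": self.omnibus.p_anova,
                "partial_eta_sq": self.omnibus.partial_eta_sq,
                "H": self.omnibus.H,
                "p_kw": self.omnibus.p_kw,
                "kw_run": self.omnibus.kw_run,
            },
            "dunnett": self.posthoc.dunnett.to_dict(orient="records"),
            "tukey": self.posthoc.tukey.to_dict(orient="records"),
            "hedges_g": self.effects.comparisons.to_dict(orient="records"),
        }


def run_viability_pipeline(
    plate: ViabilityPlate, alpha: float = 0.05
) -> ViabilityReport:
    """Run the full gated pipeline on one plate.

    Order: assumption checks, then the omnibus ANOVA (always) with
    Kruskal–Wallis flagged as a validating test whenever any group fails
    normality, then Dunnett/Tukey post hocs, then Hedges' g effect sizes.
    Errors from any stage propagate with the stage named.
    """
    stage = "assumption_checks"
    try:
        assumptions = assumption_checks(plate, alpha=alpha)
        stage = "omnibus_tests"
        omnibus = omnibus_tests(plate, kw_run=not assumptions.all_normal)
        stage = "posthoc_tests"
        posthoc = posthoc_tests(plate)
        stage = "effect_sizes"
        effects = effect_sizes(plate)
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
    return ViabilityReport(
        assumptions=assumptions, omnibus=omnibus, posthoc=posthoc, effects=effects
    )
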
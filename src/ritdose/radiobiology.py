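"""Clonogenic survival, DNA-damage dose response, and group comparisons.

Survival is modelled as a single-hit exponential, SF = exp(−a·D), with the
radiosensitivity coefficient a (Gy⁻¹) fitted by least squares on the SF
scale. γ-H2AX integrated density vs nucleus dose is fitted by ordinary
linear regression. Group comparisons use the unpaired two-tailed Student's
t-test (pooled variance) for two groups and one-way ANOVA for more.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


@dataclass
class ClonogenicCondition:
    """Colony counts for one exposure condition of a clonogenic assay."""

    label: str
    cells_seeded: int
    colonies: list[int]
    activity_mbq: float | None = None
    dose_gy: float | None = None

    def __post_init__(self) -> None:
        if self.cells_seeded <= 0:
            raise ValueError("cells_seeded must be positive")
        for c in self.colonies:
            if c < 0 or c != int(c):
                raise ValueError("colony counts must be non-negative integers")
            if c > self.cells_seeded:
                raise ValueError("colonies cannot exceed cells seeded")


def plating_efficiency(condition: ClonogenicCondition) -> float:
    """Mean colonies formed per cell seeded."""
    return float(np.mean(condition.colonies)) / condition.cells_seeded


def surviving_fraction(treated: ClonogenicCondition,
                       control: ClonogenicCondition) -> float:
    """PE(treated) / PE(control); control with zero PE is rejected."""
    pe_c = plating_efficiency(control)
    if pe_c == 0:
        raise ValueError("control plating efficiency is zero")
    sf = plating_efficiency(treated) / pe_c
    if sf > 1:
        warnings.warn(f"surviving fraction {sf:.3f} > 1 (noise); not clipped",
                      stacklevel=2)
    return sf


@dataclass
class SurvivalFit:
    """Fitted single-hit survival model SF = exp(−a·D)."""

    a: float                      # Gy⁻¹
    a_se: float                   # nan for a saturated single-point fit
    n_points: int
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))


def fit_survival(doses_gy, sf) -> SurvivalFit:
    """Least-squares fit of SF = exp(−a·D) on the SF scale, a ≥ 0.

    A single dosed point inverts in closed form (a = −ln SF / D, no SE).
    """
    d = np.asarray(doses_gy, float)
    s = np.asarray(sf, float)
    if d.size == 0 or np.all(d == 0):
        raise ValueError("need at least one point with dose > 0")
    if np.any(s <= 0) or np.any(s > 1 + 1e-9):
        raise ValueError("surviving fractions must be in (0, 1]")
    dosed = d > 0
    if np.count_nonzero(dosed) == 1 and d.size == 1:
        a = -math.log(s[dosed][0]) / d[dosed][0]
        return SurvivalFit(max(a, 0.0), math.nan, 1)
    a0 = max(-np.polyfit(d, np.log(s), 1)[0], 1e-6)
    popt, pcov = optimize.curve_fit(lambda x, a: np.exp(-a * x), d, s,
                                    p0=[a0], bounds=(0, np.inf))
    a = float(popt[0])
    resid = s - np.exp(-a * d)
    a_se = float(np.sqrt(pcov[0, 0])) if d.size > 1 else math.nan
    return SurvivalFit(a, a_se, int(d.size), resid)


def fit_survival_from_counts(treated: list[ClonogenicCondition],
                             control: ClonogenicCondition) -> SurvivalFit:
    """Fit SF = exp(−a·D) from colony counts with a counting-error SE.

    The coefficient is the same unweighted least-squares estimate as
    :func:`fit_survival`; its standard error propagates the Poisson
    counting variance of the colony totals, including the covariance all
    SF points share through the common control denominator. Conditions
    with zero colonies (no information on the SF scale) are dropped with
    a warning.
    """
    c_tot = int(np.sum(control.colonies))
    if c_tot == 0:
        raise ValueError("control has zero colonies")
    pe_c = plating_efficiency(control)
    doses, sfs, t_tots = [], [], []
    for cond in treated:
        if cond.dose_gy is None or cond.dose_gy <= 0:
            continue
        t_tot = int(np.sum(cond.colonies))
        if t_tot == 0:
            warnings.warn(f"{cond.label}: zero colonies; point dropped",
                          stacklevel=2)
            continue
        doses.append(cond.dose_gy)
        sfs.append(min(plating_efficiency(cond) / pe_c, 1.0))
        t_tots.append(t_tot)
    if not doses:
        raise ValueError("no dosed conditions with surviving colonies")
    d = np.asarray(doses, float)
    s = np.asarray(sfs, float)
    t_tots = np.asarray(t_tots, float)
    base = fit_survival(d, s)
    a = base.a
    # delta-method variance of the unweighted LS estimator:
    # da/dSF_i = g_i / Σ g², with g_i = D_i·exp(−a·D_i);
    # Cov(SF_i,SF_j) = SF_i·SF_j·(δ_ij/T_i + 1/C) for Poisson totals T, C
    g = d * np.exp(-a * d)
    cov = np.outer(s, s) / c_tot + np.diag(s ** 2 / t_tots)
    denom = float(np.sum(g ** 2))
    a_se = math.sqrt(float(g @ cov @ g)) / denom if denom > 0 else math.nan
    return SurvivalFit(a, a_se, int(d.size), base.residuals)


def fit_survival_loglinear(doses_gy, sf) -> SurvivalFit:
    """Alternative fit on the log-SF scale (slope of −ln SF vs D)."""
    d = np.asarray(doses_gy, float)
    s = np.asarray(sf, float)
    if np.any(s <= 0):
        raise ValueError("surviving fractions must be positive")
    res = stats.linregress(d, -np.log(s))
    return SurvivalFit(float(res.slope), float(res.stderr), int(d.size))


@dataclass
class DSBMeasurement:
    """γ-H2AX integrated focal density per nucleus area at one dose."""

    label: str
    dose_gy: float
    integrated_density: float
    n_nuclei: int | None = None

    def __post_init__(self) -> None:
        if self.integrated_density < 0:
            raise ValueError("integrated density must be non-negative")


def fit_dsb_linear(measurements: list[DSBMeasurement]) -> dict[str, float]:
    """OLS of integrated γ-H2AX density on nucleus dose (Gy).

    Returns slope (density per Gy), its standard error, and the intercept.
    """
    d = np.array([m.dose_gy for m in measurements], float)
    y = np.array([m.integrated_density for m in measurements], float)
    if np.unique(d).size < 2:
        raise ValueError("need at least 2 distinct doses for regression")
    res = stats.linregress(d, y)
    return {"slope": float(res.slope), "slope_se": float(res.stderr),
            "intercept": float(res.intercept),
            "r_squared": float(res.rvalue) ** 2}


def compare_groups(*samples, equal_var: bool = True,
                   alpha: float = 0.05) -> dict[str, float | bool | str]:
    """Two groups: unpaired two-tailed t-test; more: one-way ANOVA.

    ``equal_var=True`` gives the classical pooled-variance Student test;
    set False for the Welch variant.
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(s, float) for s in samples]
    for arr in arrays:
        if arr.size < 2:
            raise ValueError("each group needs at least 2 observations")
    if len(arrays) == 2:
        t, p = stats.ttest_ind(*arrays, equal_var=equal_var)
        out = {"test": "t", "statistic": float(t), "p": float(p)}
    else:
        f, p = stats.f_oneway(*arrays)
        out = {"test": "anova", "statistic": float(f), "p": float(p)}
    out["significant"] = bool(out["p"] < alpha)
    return out
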
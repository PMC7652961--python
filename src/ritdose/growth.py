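"""Tumour volume, growth/body-weight indices, and doubling-time fitting.

Caliper volume: V = length × width² × 0.5 (mm³), with width the smaller
dimension. The tumour growth index TGI(t) = V(t)/V(0) is fitted to an
exponential growth model TGI = c·exp(k·t) by least squares on log TGI;
the tumour doubling time is TDT = ln 2 / k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .radioactivity import LN2
from .radiobiology import compare_groups


def tumour_volume(length_mm: float, width_mm: float) -> float:
    """V = L × W² × 0.5 after canonicalizing width as the smaller dimension."""
    if length_mm < 0 or width_mm < 0:
        raise ValueError("caliper dimensions must be non-negative")
    if width_mm > length_mm:
        length_mm, width_mm = width_mm, length_mm
    return length_mm * width_mm ** 2 * 0.5


@dataclass
class TumourMeasurement:
    day: float
    length_mm: float
    width_mm: float

    def __post_init__(self) -> None:
        if self.width_mm > self.length_mm:  # canonicalize
            self.length_mm, self.width_mm = self.width_mm, self.length_mm

    @property
    def volume_mm3(self) -> float:
        return tumour_volume(self.length_mm, self.width_mm)


@dataclass
class GrowthCurve:
    """One animal's caliper measurements and body weights over the study."""

    animal_id: str
    group: str
    measurements: list[TumourMeasurement]
    body_weights: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        days = [m.day for m in self.measurements]
        if any(b > a for a, b in zip(days[1:], days)):
            raise ValueError("measurement days must be non-decreasing")
        if not days or days[0] != 0:
            raise ValueError("a day-0 baseline measurement is required")

    @property
    def days(self) -> np.ndarray:
        return np.array([m.day for m in self.measurements], float)

    @property
    def volumes_mm3(self) -> np.ndarray:
        return np.array([m.volume_mm3 for m in self.measurements], float)


def growth_index(curve: GrowthCurve) -> tuple[np.ndarray, np.ndarray]:
    """TGI(day) = V(day)/V(day 0); TGI(0) = 1 by construction."""
    vols = curve.volumes_mm3
    if vols[0] <= 0:
        raise ValueError("baseline tumour volume must be positive")
    return curve.days, vols / vols[0]


def body_weight_index(curve: GrowthCurve) -> tuple[np.ndarray, np.ndarray]:
    """BWI(day) = weight(day)/weight(day 0)."""
    if not curve.body_weights:
        raise ValueError("no body weights recorded")
    days = np.array([d for d, _ in curve.body_weights], float)
    w = np.array([g for _, g in curve.body_weights], float)
    if w[0] <= 0:
        raise ValueError("baseline body weight must be positive")
    return days, w / w[0]


@dataclass
class GrowthFit:
    """Exponential growth fit TGI = c·exp(k·t)."""

    k_per_day: float
    tdt_days: float        # ln2/k; nan (flagged) when k <= 0
    intercept: float       # fitted c
    r_squared: float
    n_points: int

    @property
    def growing(self) -> bool:
        return self.k_per_day > 0


def fit_growth(days, tgi, pin_intercept: bool = False) -> GrowthFit:
    """Log-linear least-squares fit of the TGI curve.

    With ``pin_intercept`` the model is forced through TGI(0)=1
    (regression of log TGI on t without intercept).
    """
    t = np.asarray(days, float)
    y = np.asarray(tgi, float)
    if t.size < 3:
        raise ValueError("need at least 3 points to fit growth")
    if np.any(y <= 0):
        raise ValueError("TGI values must be positive")
    ly = np.log(y)
    if pin_intercept:
        k = float(np.sum(t * ly) / np.sum(t * t))
        c = 1.0
    else:
        k, lc = np.polyfit(t, ly, 1)
        k, c = float(k), float(np.exp(lc))
    pred = np.log(c) + k * t
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    tdt = LN2 / k if k > 0 else math.nan
    return GrowthFit(k, tdt, c, r2, int(t.size))


def group_mean_tgi(curves: list[GrowthCurve]) -> tuple[np.ndarray, np.ndarray]:
    """Mean TGI over animals at each common observation day."""
    series = [growth_index(c) for c in curves]
    common = sorted(set.intersection(*(set(d.tolist()) for d, _ in series)))
    if not common:
        raise ValueError("no common observation days across animals")
    days = np.array(common, float)
    mat = np.array([[tgi[np.nonzero(d == day)[0][0]] for day in days]
                    for d, tgi in series])
    return days, mat.mean(axis=0)


def fit_group_growth(curves: list[GrowthCurve],
                     per_animal: bool = False) -> GrowthFit | list[GrowthFit]:
    """Fit the group-mean TGI curve (default) or each animal separately."""
    if per_animal:
        return [fit_growth(*growth_index(c)) for c in curves]
    return fit_growth(*group_mean_tgi(curves))


def group_summary(groups: dict[str, list[GrowthCurve]], day: float,
                  min_alive: int = 3) -> dict:
    """Mean ± SD TGI per group at (nearest day to) ``day``, with comparisons.

    Groups with fewer than ``min_alive`` animals still measured at that day
    are excluded (with a warning recorded in the output). Two or more
    retained groups are compared (t-test / ANOVA) and pairwise fold
    differences of the means reported.
    """
    import warnings as _warnings

    per_group: dict[str, np.ndarray] = {}
    excluded = []
    for name, curves in groups.items():
        vals = []
        for c in curves:
            d, tgi = growth_index(c)
            if d[-1] >= day or np.isclose(d[-1], day):
                vals.append(tgi[int(np.argmin(np.abs(d - day)))])
        if len(vals) < min_alive:
            excluded.append(name)
            _warnings.warn(f"group {name!r} has < {min_alive} animals at "
                           f"day {day}; excluded", stacklevel=2)
        else:
            per_group[name] = np.array(vals)

    out: dict = {"day": day, "excluded": excluded, "groups": {
        name: {"mean": float(v.mean()), "sd": float(v.std(ddof=1)),
               "n": int(v.size)} for name, v in per_group.items()}}
    names = list(per_group)
    if len(names) >= 2:
        out["comparison"] = compare_groups(*per_group.values())
        out["fold_differences"] = {
            f"{a}/{b}": float(per_group[a].mean() / per_group[b].mean())
            for i, a in enumerate(names) for b in names[i + 1:]}
    return out
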
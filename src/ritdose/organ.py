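"""Small-animal organ and tumour dosimetry from biodistribution time courses.

Time-integrated activity (TIA) rules for a serial-sacrifice design sampled
from 24 to 168 h post-injection:

* normal organ uptake phase, 0–24 h: triangle rule
  Ã₀₋₂₄ = ½ × 24 h × 3600 s/h × A(24 h);
* normal organ elimination phase, 24 h–∞: mono-exponential fit of A(t)
  (log-linear least squares), Ã₂₄₋∞ = A₂₄(fit)/k;
* tumour, 0–168 h: trapezoidal AUC with A(0) = 0, plus a decay-only tail
  Ã₁₆₈₋∞ = A(168 h)/λ (no further biological elimination assumed).

Organ doses follow the MIRD schema D(T) = Σ_S Ã_S × S(T←S) with a mouse
phantom S-factor matrix; the tumour dose uses a unit-density sphere model
table (dose per unit TIA vs sphere mass, interpolated log-log).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .radioactivity import Radionuclide, S_PER_HOUR

UPTAKE_END_H = 24.0
LAST_SAMPLE_H = 168.0


@dataclass
class OrganSeries:
    """Group-mean activity vs time for one organ (serial sacrifice)."""

    times_h: np.ndarray
    mean_bq: np.ndarray
    sd_bq: np.ndarray | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.mean_bq = np.asarray(self.mean_bq, dtype=float)
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.mean_bq < 0):
            raise ValueError("activities must be non-negative")
        if self.sd_bq is not None:
            self.sd_bq = np.asarray(self.sd_bq, dtype=float)

    def at(self, t_h: float) -> float:
        idx = np.nonzero(np.isclose(self.times_h, t_h))[0]
        if idx.size == 0:
            raise ValueError(f"no sample at {t_h} h")
        return float(self.mean_bq[idx[0]])


@dataclass
class BiodistributionStudy:
    """Per-organ activity time courses after a single injection."""

    nuclide: Radionuclide
    injected_mbq: float
    organs: dict[str, OrganSeries]
    tumour: OrganSeries | None = None
    tumour_mass_g: float | None = None
    n_cycles: int = 1

    def __post_init__(self) -> None:
        if self.injected_mbq <= 0:
            raise ValueError("injected activity must be positive")
        for name, series in self.organs.items():
            if series.times_h.size < 2:
                raise ValueError(f"organ {name!r} needs >= 2 time points")


@dataclass(frozen=True)
class OrganSFactorMatrix:
    """Mouse-phantom S factors, Gy/(Bq·s), target rows × source columns."""

    table: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if (self.table.values < 0).any():
            raise ValueError("S factors must be non-negative")

    def lookup(self, target: str, source: str) -> float:
        try:
            return float(self.table.loc[target, source])
        except KeyError:
            missing = source if source not in self.table.columns else target
            raise KeyError(f"organ {missing!r} not in S-factor matrix") from None

    @property
    def targets(self) -> list[str]:
        return list(self.table.index)

    @property
    def sources(self) -> list[str]:
        return list(self.table.columns)


@dataclass(frozen=True)
class SphereSTable:
    """Unit-density sphere dose per unit TIA (Gy/(Bq·s)) vs sphere mass (g)."""

    mass_g: np.ndarray
    s_gy_per_bq_s: np.ndarray
    nuclide: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "mass_g", np.asarray(self.mass_g, float))
        object.__setattr__(self, "s_gy_per_bq_s",
                           np.asarray(self.s_gy_per_bq_s, float))
        if np.any(np.diff(self.mass_g) <= 0):
            raise ValueError("sphere masses must be strictly increasing")
        if np.any(np.diff(self.s_gy_per_bq_s) >= 0):
            raise ValueError("dose per TIA must decrease with sphere mass")

    def s_at(self, mass_g: float) -> float:
        """Log-log interpolated S for a mass inside the table range."""
        if not (self.mass_g[0] <= mass_g <= self.mass_g[-1]):
            raise ValueError(
                f"mass {mass_g} g outside table range "
                f"[{self.mass_g[0]}, {self.mass_g[-1]}] g")
        return float(np.exp(np.interp(np.log(mass_g), np.log(self.mass_g),
                                      np.log(self.s_gy_per_bq_s))))


def organ_uptake_tia(activity_at_24h_bq: float) -> float:
    """Triangle-rule uptake TIA: ½ × 24 h × 3600 s/h × A(24 h), Bq·s."""
    if activity_at_24h_bq < 0:
        raise ValueError("activity must be non-negative")
    return 0.5 * UPTAKE_END_H * S_PER_HOUR * activity_at_24h_bq


@dataclass
class EliminationFit:
    k_per_s: float
    a24_bq: float
    tia_bq_s: float
    r_squared: float


def organ_elimination_tia(times_h: np.ndarray, activity_bq: np.ndarray,
                          fallback_nuclide: Radionuclide | None = None,
                          ) -> EliminationFit:
    """Mono-exponential elimination tail from 24 h.

    Fits ``A(t) = A₂₄ · exp(−k·(t − 24 h))`` by ordinary least squares on
    log A vs time (seconds); Ã₂₄₋∞ = A₂₄/k. A non-positive fitted k (a
    series that does not fall) is an error unless ``fallback_nuclide`` is
    given, in which case the physical decay constant is used as k.
    """
    t = np.asarray(times_h, float)
    a = np.asarray(activity_bq, float)
    if t.size < 2:
        raise ValueError("need at least 2 time points for elimination fit")
    if np.any(a <= 0):
        raise ValueError("activities must be positive for log-linear fitting")
    ts = (t - UPTAKE_END_H) * S_PER_HOUR
    slope, intercept = np.polyfit(ts, np.log(a), 1)
    k = -slope
    if k <= 0:
        if fallback_nuclide is None:
            raise ValueError(
                "fitted elimination rate is non-positive (series not "
                "falling); supply fallback_nuclide to use a decay-only tail")
        k = fallback_nuclide.decay_constant
        intercept = float(np.mean(np.log(a) + k * ts))
    a24 = float(np.exp(intercept))
    log_a = np.log(a)
    ss_res = float(np.sum((log_a - (intercept - k * ts)) ** 2))
    ss_tot = float(np.sum((log_a - log_a.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return EliminationFit(k, a24, a24 / k, r2)


def tumour_tia(times_h: np.ndarray, activity_bq: np.ndarray,
               nuclide: Radionuclide) -> dict[str, float]:
    """Tumour TIA: trapezoid over 0–168 h (A(0)=0) plus decay-only tail.

    Returns ``{"tia_0_168", "tia_168_inf", "tia_total"}`` in Bq·s.
    """
    t = np.asarray(times_h, float)
    a = np.asarray(activity_bq, float)
    if not np.isclose(t[-1], LAST_SAMPLE_H):
        raise ValueError("tumour series must end at 168 h post-injection")
    if t[0] > 0:
        t = np.concatenate(([0.0], t))
        a = np.concatenate(([0.0], a))
    auc = float(np.trapezoid(a, t * S_PER_HOUR))
    tail = float(a[-1] / nuclide.decay_constant)
    return {"tia_0_168": auc, "tia_168_inf": tail, "tia_total": auc + tail}


@dataclass
class OrganDoseReport:
    """TIA components and absorbed doses per organ for one study."""

    tia: pd.DataFrame          # index organ, columns uptake/elimination/total (Bq·s)
    dose_gy: pd.Series         # index target organ (incl. whole body if present)
    dose_rel_sd: pd.Series | None = None
    tumour_tia: dict[str, float] | None = None
    tumour_dose_gy: float | None = None
    n_cycles: int = 1
    elimination_fits: dict[str, EliminationFit] = field(default_factory=dict)


def organ_tia_table(study: BiodistributionStudy,
                    fallback_to_decay: bool = False) -> pd.DataFrame:
    """Uptake + elimination TIA components for every normal organ."""
    rows = {}
    fits = {}
    fb = study.nuclide if fallback_to_decay else None
    for organ, series in study.organs.items():
        uptake = organ_uptake_tia(series.at(UPTAKE_END_H))
        fit = organ_elimination_tia(series.times_h, series.mean_bq, fb)
        fits[organ] = fit
        rows[organ] = {"uptake": uptake, "elimination": fit.tia_bq_s,
                       "total": uptake + fit.tia_bq_s}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.attrs["elimination_fits"] = fits
    return table


def organ_doses(study: BiodistributionStudy, sfactors: OrganSFactorMatrix,
                sphere: SphereSTable | None = None,
                fallback_to_decay: bool = False) -> OrganDoseReport:
    """Absorbed dose per target organ: D(T) = n_cycles · Σ_S Ã_S × S(T←S).

    Source organs absent from the S-factor matrix raise; the tumour is
    handled separately through the sphere model when ``sphere`` and the
    study's tumour mass are available.
    """
    tia = organ_tia_table(study, fallback_to_decay)
    for organ in tia.index:
        if organ not in sfactors.sources:
            raise KeyError(f"organ {organ!r} not in S-factor matrix")
    doses = {}
    for target in sfactors.targets:
        doses[target] = study.n_cycles * sum(
            tia.loc[src, "total"] * sfactors.lookup(target, src)
            for src in tia.index)
    dose = pd.Series(doses)

    rel_sd = _propagate_rel_sd(study)

    t_tia = t_dose = None
    if study.tumour is not None:
        t_tia = tumour_tia(study.tumour.times_h, study.tumour.mean_bq,
                           study.nuclide)
        if sphere is not None and study.tumour_mass_g is not None:
            t_dose = study.n_cycles * tumour_sphere_dose(
                t_tia["tia_total"], study.tumour_mass_g, sphere)
    return OrganDoseReport(tia, dose, rel_sd, t_tia, t_dose,
                           study.n_cycles,
                           tia.attrs.get("elimination_fits", {}))


def _propagate_rel_sd(study: BiodistributionStudy) -> pd.Series | None:
    """Relative dose uncertainty per organ: per-time relative SDs of the
    group means combined in quadrature and averaged (reported only)."""
    out = {}
    for organ, series in study.organs.items():
        if series.sd_bq is None:
            return None
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(series.mean_bq > 0,
                           series.sd_bq / series.mean_bq, 0.0)
        out[organ] = float(np.sqrt(np.sum(rel ** 2)) / rel.size)
    return pd.Series(out)


def tumour_sphere_dose(tia_bq_s: float, tumour_mass_g: float,
                       sphere: SphereSTable) -> float:
    """Sphere-model tumour dose: Ã × S(mass), S interpolated log-log."""
    if tia_bq_s < 0:
        raise ValueError("TIA must be non-negative")
    return tia_bq_s * sphere.s_at(tumour_mass_g)
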
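"""Cellular (subcellular-compartment) dosimetry.

Computes time-integrated activities (TIA, Ã, Bq·s) in the cell-surface
(CS, a.k.a. cell membrane CM), cytoplasm (Cy), nucleus (N) and culture
medium source compartments from a fractionation time course, then the
absorbed dose in the nucleus via the MIRD schema

    D(N) = Σ_S Ã_S × S(N ← S)

where S(N←S) is the cellular S-value (Gy per Bq·s) for the source
compartment S under the monolayer geometry of the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .radioactivity import Radionuclide, S_PER_HOUR

#: canonical cell-associated source compartments, in report order
CELL_COMPARTMENTS = ("CS", "Cy", "N")
MEDIUM = "medium"
_ALIASES = {"CM": "CS", "cs": "CS", "cm": "CS", "cy": "Cy", "n": "N",
            "Medium": "medium", "MEDIUM": "medium"}


def canonical_compartment(label: str) -> str:
    label = label.strip()
    label = _ALIASES.get(label, label)
    if label not in CELL_COMPARTMENTS and label != MEDIUM:
        raise ValueError(f"unknown source compartment {label!r}")
    return label


@dataclass
class SubcellularTimeCourse:
    """Activity per subcellular compartment vs incubation time.

    ``times_h`` are the measurement times (strictly increasing); activity
    arrays are Bq per compartment at those times, for the whole well.
    A(0) = 0 is implied for cell compartments (no activity before the
    conjugate is added) and A(0) = added_activity for the medium.
    """

    times_h: np.ndarray
    activity: dict[str, np.ndarray]  # compartment -> Bq series
    added_activity_bq: float
    medium_bq: np.ndarray | None = None
    concentration_nmol_per_l: float | None = None
    condition: str = "specific"
    nuclide: str | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        self.activity = {canonical_compartment(k): np.asarray(v, dtype=float)
                         for k, v in self.activity.items()}
        for comp, series in self.activity.items():
            if series.shape != self.times_h.shape:
                raise ValueError(f"{comp} series length mismatch")
            if np.any(series < 0):
                raise ValueError(f"negative activity in {comp}")
        if self.medium_bq is not None:
            self.medium_bq = np.asarray(self.medium_bq, dtype=float)
        bound = self.cell_bound_bq()
        if np.any(bound > self.added_activity_bq * (1 + 1e-9)):
            raise ValueError("cell-bound activity exceeds added activity")

    def cell_bound_bq(self) -> np.ndarray:
        """Total cell-associated activity (CS+Cy+N) at each time."""
        return sum(self.activity[c] for c in self.activity)

    def medium_series(self) -> np.ndarray:
        """Medium activity; mass balance (added − bound) if not measured."""
        if self.medium_bq is not None:
            return self.medium_bq
        return self.added_activity_bq - self.cell_bound_bq()


@dataclass(frozen=True)
class CellSValueTable:
    """Cellular S-values S(N←source), Gy/(Bq·s), per radionuclide.

    Keys of ``s`` are (nuclide name, source compartment). Geometry metadata
    (cell/nucleus radii, monolayer flag) is informational.
    """

    s: dict[tuple[str, str], float]
    cell_radius_um: float | None = None
    nucleus_radius_um: float | None = None
    monolayer: bool = True

    def __post_init__(self) -> None:
        for (nuc, src), val in self.s.items():
            if val < 0:
                raise ValueError(f"negative S-value for {nuc}/{src}")

    def lookup(self, nuclide: str, source: str) -> float:
        source = canonical_compartment(source)
        try:
            return self.s[(nuclide, source)]
        except KeyError:
            raise KeyError(
                f"no S-value for nuclide {nuclide!r}, source {source!r}"
            ) from None

    def sources(self, nuclide: str) -> list[str]:
        return [src for (nuc, src) in self.s if nuc == nuclide]


@dataclass
class CompartmentTIA:
    """Time-integrated activity Ã (Bq·s) per source compartment."""

    tia_bq_s: dict[str, float]
    window_h: tuple[float, float] = (0.0, 16.0)

    def __post_init__(self) -> None:
        self.tia_bq_s = {canonical_compartment(k): float(v)
                         for k, v in self.tia_bq_s.items()}
        for comp, v in self.tia_bq_s.items():
            if v < 0:
                raise ValueError(f"negative TIA for {comp}")

    @property
    def cell_total_bq_s(self) -> float:
        """Total cell-associated Ã (CS+Cy+N), Bq·s."""
        return sum(v for k, v in self.tia_bq_s.items() if k != MEDIUM)


@dataclass
class NucleusDoseReport:
    """Absorbed dose in the nucleus, broken down by source compartment."""

    dose_gy: dict[str, float]
    nuclide: str = ""
    tia: CompartmentTIA | None = None

    @property
    def total_cell_dose_gy(self) -> float:
        return sum(v for k, v in self.dose_gy.items() if k != MEDIUM)

    @property
    def total_dose_gy(self) -> float:
        return sum(self.dose_gy.values())

    @property
    def fractions(self) -> dict[str, float]:
        total = self.total_dose_gy
        if total <= 0:
            raise ValueError("total dose is zero; fractions undefined")
        return {k: v / total for k, v in self.dose_gy.items()}


def time_integrated_activity(course: SubcellularTimeCourse,
                             window_h: tuple[float, float] = (0.0, 16.0),
                             decay_in_integral: "Radionuclide | None" = None,
                             ) -> CompartmentTIA:
    """Trapezoidal Ã over ``window_h`` for every compartment and the medium.

    A(0)=0 is prepended to cell-compartment series (A(0)=added for the
    medium); the piecewise-linear interpolant is integrated over the window.
    The window must lie inside the sampled range — no extrapolation.

    By default measured activities are taken as the physical activities
    present at each time, so no decay factor is applied. If the series are
    instead decay-corrected counts, pass ``decay_in_integral`` to multiply
    the integrand by exp(−λt) (evaluated on a 1 s grid).
    """
    t0, t1 = window_h
    if t0 < 0 or t1 <= t0:
        raise ValueError("window must satisfy 0 <= start < end")
    if t1 > course.times_h[-1]:
        raise ValueError(
            f"window end {t1} h beyond last sample {course.times_h[-1]} h")

    def integrate(times_h: np.ndarray, series: np.ndarray, a0: float) -> float:
        if times_h[0] > 0:
            times_h = np.concatenate(([0.0], times_h))
            series = np.concatenate(([a0], series))
        if decay_in_integral is not None:
            grid = np.arange(t0 * S_PER_HOUR, t1 * S_PER_HOUR + 0.5, 1.0)
            vals = np.interp(grid / S_PER_HOUR, times_h, series) \
                * np.exp(-decay_in_integral.decay_constant * grid)
            return float(np.trapezoid(vals, grid))
        # resample exactly at the window edges, then trapezoid in seconds
        grid = np.unique(np.concatenate((times_h, [t0, t1])))
        grid = grid[(grid >= t0) & (grid <= t1)]
        vals = np.interp(grid, times_h, series)
        return float(np.trapezoid(vals, grid * S_PER_HOUR))

    tia = {comp: integrate(course.times_h, series, 0.0)
           for comp, series in course.activity.items()}
    tia[MEDIUM] = integrate(course.times_h, course.medium_series(),
                            course.added_activity_bq)
    return CompartmentTIA(tia, (t0, t1))


def nucleus_dose(tia: CompartmentTIA, s_table: CellSValueTable,
                 nuclide: Radionuclide | str) -> NucleusDoseReport:
    """MIRD sum D(N) = Σ Ã_S × S(N←S) over the compartments present."""
    name = nuclide if isinstance(nuclide, str) else nuclide.name
    doses = {src: a * s_table.lookup(name, src)
             for src, a in tia.tia_bq_s.items()}
    return NucleusDoseReport(doses, nuclide=name, tia=tia)


def major_contributor(report: NucleusDoseReport,
                      decimals: int = 2) -> tuple[list[str], int]:
    """Dominant cell-associated source compartment(s) and percent of total.

    Sources whose doses round to the same value as the maximum at report
    precision (``decimals``) are reported jointly — a tie at the precision
    the doses are quoted at is a tie.
    """
    if report.total_dose_gy <= 0:
        raise ValueError("total dose is zero")
    cell = {k: v for k, v in report.dose_gy.items() if k != MEDIUM}
    top = max(cell.values())
    joint = [k for k in CELL_COMPARTMENTS if k in cell
             and round(cell[k], decimals) == round(top, decimals)]
    percent = round(100.0 * top / report.total_dose_gy)
    return joint, int(percent)


def cell_bound_fraction(report: NucleusDoseReport) -> float:
    """Fraction of nucleus dose from cell-associated sources (1 − medium share)."""
    total = report.total_dose_gy
    if total <= 0:
        raise ValueError("total dose is zero")
    return (total - report.dose_gy.get(MEDIUM, 0.0)) / total


def scale_dose_to_activity(report: NucleusDoseReport, ref_mbq: float,
                           target_mbq: float) -> NucleusDoseReport:
    """Linearly rescale a dose report from a reference to a target activity.

    Valid when the exposures differ only in molar activity (same molar
    concentration), so every Ã — hence every dose — scales with activity.
    """
    if ref_mbq <= 0:
        raise ValueError("reference activity must be positive")
    if target_mbq < 0:
        raise ValueError("target activity must be non-negative")
    f = target_mbq / ref_mbq
    return NucleusDoseReport({k: v * f for k, v in report.dose_gy.items()},
                             nuclide=report.nuclide, tia=report.tia)


def percent_cell_bound(course: SubcellularTimeCourse) -> np.ndarray:
    """Percent of added activity that is cell-associated at each time."""
    if course.added_activity_bq <= 0:
        raise ValueError("added activity must be positive")
    return 100.0 * course.cell_bound_bq() / course.added_activity_bq
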
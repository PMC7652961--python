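"""Seeded generators for every input the pipeline consumes.

Each generator is a deterministic function of (seed, parameters) and emits
data with the statistical structure the corresponding analysis stage
assumes:

* subcellular uptake — saturating cell binding split into fixed
  compartment fractions, lognormal multiplicative noise;
* biodistribution — organ activity peaking at 24 h then clearing
  mono-exponentially, on top of physical decay; group means over n mice;
* clonogenic assays — Poisson colony counts under SF = exp(−a·D);
* tumour growth — exponential volume growth with lognormal caliper noise,
  caliper pairs back-solved at a fixed length/width aspect ratio;
* γ-H2AX densitometry — linear dose response with Gaussian noise.

Default parameter values mirror the experimental design the package
models: 2×10⁵ cells exposed to 1.2 MBq for 16 h sampled at 1/4/8/24 h,
biodistribution at 24–168 h with n = 5 mice per time, ~700 cells seeded
per clonogenic well, and caliper measurements every 2–3 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cellular import SubcellularTimeCourse
from .growth import GrowthCurve, TumourMeasurement
from .organ import BiodistributionStudy, OrganSeries
from .radioactivity import Radionuclide, S_PER_HOUR, get_nuclide
from .radiobiology import ClonogenicCondition, DSBMeasurement

#: compartment split of cell-bound activity (CS, Cy, N): membrane-dominated,
#: matching the observed subcellular distribution of the Lu-177 conjugate
DEFAULT_COMPARTMENT_FRACTIONS = (0.846, 0.093, 0.061)

#: nucleus doses (Gy) delivered by 0.3/0.6/1.2 MBq of the Lu-177 conjugate
#: under linear dose–activity scaling from the 16 h dosimetry
DEFAULT_CLONO_DOSES = (1.17, 2.34, 4.68)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1 + cv ** 2))
    return rng.lognormal(-sigma ** 2 / 2, sigma, size)


def gen_subcellular(seed: int,
                    uptake_plateau_fraction: float = 0.05,
                    uptake_rate_per_h: float = 0.3,
                    compartment_fractions=DEFAULT_COMPARTMENT_FRACTIONS,
                    added_bq: float = 1.2e6,
                    concentration_nmol_per_l: float = 2.5,
                    times_h=(1.0, 4.0, 8.0, 24.0),
                    noise_cv: float = 0.0,
                    condition: str = "specific") -> SubcellularTimeCourse:
    """Saturating cellular uptake split into CS/Cy/N compartments.

    Cell-bound activity follows A(t) = plateau·(1−exp(−rate·t))·added and
    is divided among the compartments in fixed proportions.
    """
    fr = np.asarray(compartment_fractions, float)
    if not np.isclose(fr.sum(), 1.0):
        raise ValueError("compartment fractions must sum to 1")
    rng = np.random.default_rng(seed)
    t = np.asarray(times_h, float)
    bound = uptake_plateau_fraction * (1 - np.exp(-uptake_rate_per_h * t)) \
        * added_bq
    activity = {}
    for comp, f in zip(("CS", "Cy", "N"), fr):
        activity[comp] = bound * f * _lognormal_factor(rng, noise_cv, t.size)
    medium = added_bq - sum(activity.values())
    return SubcellularTimeCourse(t, activity, added_bq, medium,
                                 concentration_nmol_per_l, condition)


DEFAULT_ORGAN_KINETICS = {  # organ: (peak fraction of injected, biological k s⁻¹)
    "heart": (0.03, 2.5e-6),
    "lungs": (0.04, 2.5e-6),
    "liver": (0.15, 1.5e-6),
    "spleen": (0.08, 1.5e-6),
    "pancreas": (0.02, 2.0e-6),
    "stomach": (0.02, 3.0e-6),
    "intestine": (0.05, 3.0e-6),
    "kidneys": (0.10, 2.0e-6),
}


def gen_biodistribution(seed: int,
                        nuclide: Radionuclide | str = "Lu-177",
                        injected_mbq: float = 6.0,
                        organ_params: dict | None = None,
                        tumour_params: tuple[float, float] = (0.08, 5.0e-7),
                        tumour_mass_g: float = 0.3,
                        times_h=(24.0, 72.0, 120.0, 168.0),
                        n_per_time: int = 5,
                        noise_cv: float = 0.0,
                        n_cycles: int = 1) -> BiodistributionStudy:
    """Bi-phasic organ kinetics: peak at 24 h, then biological clearance on
    top of physical decay. Reported activities are group means over
    ``n_per_time`` simulated mice."""
    if isinstance(nuclide, str):
        nuclide = get_nuclide(nuclide)
    rng = np.random.default_rng(seed)
    t = np.asarray(times_h, float)
    id_bq = injected_mbq * 1e6
    lam = nuclide.decay_constant

    def series(peak_fraction: float, k_bio: float) -> OrganSeries:
        mean = id_bq * peak_fraction * np.exp(-(k_bio) * (t - 24.0) * S_PER_HOUR) \
            * np.exp(-lam * t * S_PER_HOUR)
        draws = mean * _lognormal_factor(rng, noise_cv, (n_per_time, t.size))
        return OrganSeries(t, draws.mean(axis=0), draws.std(axis=0, ddof=1),
                           n_per_time)

    params = organ_params or DEFAULT_ORGAN_KINETICS
    organs = {name: series(pf, kb) for name, (pf, kb) in params.items()}
    tumour = series(*tumour_params)
    return BiodistributionStudy(nuclide, injected_mbq, organs, tumour,
                                tumour_mass_g, n_cycles)


def gen_clonogenic(seed: int,
                   true_a_per_gy: float = 0.56,
                   doses_gy=DEFAULT_CLONO_DOSES,
                   cells_seeded: int = 700,
                   control_pe: float = 0.20,
                   wells: int = 3,
                   label: str = "RIC") -> list[ClonogenicCondition]:
    """Poisson colony counts under the exponential survival model.

    Returns a control (dose 0) plus one condition per dose; colonies per
    well ~ Poisson(cells × PE₀ × exp(−a·D)).
    """
    rng = np.random.default_rng(seed)
    out = []
    for dose in (0.0, *doses_gy):
        mean = cells_seeded * control_pe * np.exp(-true_a_per_gy * dose)
        counts = rng.poisson(mean, wells).tolist()
        name = "control" if dose == 0 else f"{label}@{dose:g}Gy"
        out.append(ClonogenicCondition(name, cells_seeded, counts,
                                       dose_gy=dose))
    return out


def gen_dsb(seed: int,
            slope_per_gy: float = 0.46,
            intercept: float = 0.5,
            doses_gy=DEFAULT_CLONO_DOSES,
            n_per_dose: int = 12,
            noise_sd: float = 0.2,
            label: str = "RIC") -> list[DSBMeasurement]:
    """Linear γ-H2AX dose response with additive Gaussian noise."""
    rng = np.random.default_rng(seed)
    out = []
    for dose in (0.0, *doses_gy):
        dens = intercept + slope_per_gy * dose \
            + rng.normal(0, noise_sd, n_per_dose)
        for v in np.clip(dens, 0, None):
            out.append(DSBMeasurement(label, dose, float(v)))
    return out


def gen_tumour_growth(seed: int,
                      n_animals: int = 10,
                      tdt_days: float = 51.8,
                      baseline_mm3: float = 200.0,
                      obs_every_days: float = 3.0,
                      horizon_days: float = 42.0,
                      noise_cv: float = 0.10,
                      aspect_ratio: float = 1.25,
                      body_weight_g: float = 25.0,
                      group: str = "treated") -> list[GrowthCurve]:
    """Exponential tumour growth with multiplicative caliper noise.

    V(t) = V₀·2^(t/TDT)·ε, ε lognormal with the given CV. The caliper pair
    is back-solved at a fixed length = aspect_ratio × width so that
    V = L·W²/2 reproduces the noisy volume exactly.
    """
    if tdt_days <= 0:
        raise ValueError("doubling time must be positive")
    rng = np.random.default_rng(seed)
    days = np.arange(0.0, horizon_days + 1e-9, obs_every_days)
    curves = []
    for i in range(n_animals):
        v = baseline_mm3 * 2.0 ** (days / tdt_days) \
            * _lognormal_factor(rng, noise_cv, days.size)
        width = (2.0 * v / aspect_ratio) ** (1.0 / 3.0)
        length = aspect_ratio * width
        weights = body_weight_g * _lognormal_factor(rng, noise_cv / 5, days.size)
        curves.append(GrowthCurve(
            f"{group}-{i + 1}", group,
            [TumourMeasurement(d, l, w) for d, l, w in zip(days, length, width)],
            list(zip(days.tolist(), weights.tolist()))))
    return curves
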
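"""Umbrella analysis: wire the stages into the two end-to-end workflows.

In vitro: subcellular time course (or tabulated Ã) → nucleus dose →
survival / DNA-damage dose response. In vivo: biodistribution → organ and
tumour doses; caliper measurements → growth indices → doubling times.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from . import io as rio
from .cellular import (cell_bound_fraction, major_contributor, nucleus_dose,
                       time_integrated_activity)
from .growth import fit_group_growth, growth_index
from .organ import organ_doses
from .radiobiology import (fit_dsb_linear, fit_survival_from_counts,
                           fit_survival_loglinear, plating_efficiency,
                           surviving_fraction)


def _config_hash(config: rio.AnalysisConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def celldose_report(tia_by_conjugate, s_table,
                    config: rio.AnalysisConfig | None = None) -> dict:
    """Nucleus dose per conjugate from per-compartment Ã and S-values."""
    config = config or rio.AnalysisConfig()
    nd = config.output_decimals
    out = {}
    for conj, (nuclide, tia) in tia_by_conjugate.items():
        report = nucleus_dose(tia, s_table, nuclide)
        labels, pct = major_contributor(report, nd)
        out[conj] = {
            "nuclide": nuclide,
            "tia_bq_s": dict(tia.tia_bq_s),
            "cell_total_tia_bq_s": tia.cell_total_bq_s,
            "dose_gy": dict(report.dose_gy),
            "total_cell_dose_gy": report.total_cell_dose_gy,
            "total_dose_gy": report.total_dose_gy,
            "major_contributor": {"sources": labels, "percent": pct},
            "cell_bound_fraction": cell_bound_fraction(report),
        }
    return out


def survival_report(conditions, config: rio.AnalysisConfig | None = None,
                    control_label: str = "control") -> dict:
    """PE/SF per condition and the exponential survival fit over dosed points."""
    config = config or rio.AnalysisConfig()
    control = next((c for c in conditions if c.label == control_label), None)
    if control is None:
        raise ValueError(f"no condition labelled {control_label!r}")
    rows = {}
    for cond in conditions:
        rows[cond.label] = {"pe": plating_efficiency(cond),
                            "sf": surviving_fraction(cond, control),
                            "dose_gy": cond.dose_gy}
    if config.survival_fit_scale == "log":
        pts = [(c.dose_gy, rows[c.label]["sf"]) for c in conditions
               if c.dose_gy and c.dose_gy > 0 and rows[c.label]["sf"] > 0]
        fit = fit_survival_loglinear(*zip(*pts))
    else:
        fit = fit_survival_from_counts(
            [c for c in conditions if c is not control], control)
    return {"conditions": rows,
            "fit": {"a_per_gy": fit.a, "a_se": fit.a_se,
                    "n_points": fit.n_points}}


def growth_report(groups, config: rio.AnalysisConfig | None = None) -> dict:
    """Group-level doubling times from mean TGI curves."""
    config = config or rio.AnalysisConfig()
    out = {}
    for name, curves in groups.items():
        fit = fit_group_growth(curves)
        out[name] = {"n_animals": len(curves), "k_per_day": fit.k_per_day,
                     "tdt_days": fit.tdt_days, "r_squared": fit.r_squared}
    return out


def run_pipeline(inputs: dict[str, str | Path],
                 config: rio.AnalysisConfig | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Run every stage for which an input table was supplied.

    ``inputs`` maps stage names to CSV paths: ``cell_tia`` (+ optional
    ``cell_svalues``), ``subcellular``, ``biodistribution`` (+ optional
    ``sfactors``, ``sphere``), ``clonogenic``, ``dsb``, ``growth``.
    Unrecognized keys raise. Returns the structured report; with
    ``outdir`` it is also written as JSON.
    """
    config = config or rio.AnalysisConfig()
    known = {"cell_tia", "cell_svalues", "subcellular", "biodistribution",
             "sfactors", "sphere", "clonogenic", "dsb", "growth"}
    unknown = set(inputs) - known
    if unknown:
        raise ValueError(f"unknown input keys: {sorted(unknown)}")
    report: dict = {"package_version": __version__,
                    "config": asdict(config),
                    "config_hash": _config_hash(config),
                    "stages": {}}
    if not inputs:
        import warnings
        warnings.warn("no inputs supplied; nothing to do", stacklevel=2)

    s_table = rio.read_cell_svalues(inputs.get("cell_svalues"))

    if "cell_tia" in inputs or "subcellular" in inputs:
        tia_by_conj = {}
        if "cell_tia" in inputs:
            tia_by_conj.update(rio.read_cell_tia(inputs["cell_tia"]))
        if "subcellular" in inputs:
            course = rio.read_subcellular(inputs["subcellular"])
            nuclide_name = course.nuclide or "Lu-177"
            decay_nuc = None
            if config.decay_correct_cell_integral:
                from .radioactivity import get_nuclide
                decay_nuc = get_nuclide(nuclide_name,
                                        config.published_rounded_lambda)
            tia = time_integrated_activity(course, config.cell_window_h,
                                           decay_nuc)
            tia_by_conj["measured"] = (nuclide_name, tia)
        report["stages"]["celldose"] = celldose_report(tia_by_conj, s_table,
                                                       config)

    if "biodistribution" in inputs:
        study = rio.read_biodistribution(inputs["biodistribution"])
        sfac = rio.read_sfactor_matrix(inputs.get("sfactors"))
        sphere = rio.read_sphere_table(inputs.get("sphere"),
                                       study.nuclide.name)
        od = organ_doses(study, sfac, sphere)
        report["stages"]["organdose"] = {
            "nuclide": study.nuclide.name,
            "n_cycles": study.n_cycles,
            "tia_bq_s": {o: dict(r) for o, r in
                         od.tia.to_dict(orient="index").items()},
            "dose_gy": od.dose_gy.to_dict(),
            "tumour_tia_bq_s": od.tumour_tia,
            "tumour_dose_gy": od.tumour_dose_gy,
        }

    if "clonogenic" in inputs:
        conditions = rio.read_clonogenic(inputs["clonogenic"])
        report["stages"]["survival"] = survival_report(conditions, config)

    if "dsb" in inputs:
        measurements = rio.read_dsb(inputs["dsb"])
        report["stages"]["dsb"] = fit_dsb_linear(measurements)

    if "growth" in inputs:
        groups = rio.read_growth(inputs["growth"])
        report["stages"]["growth"] = growth_report(groups, config)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, default=_json_default))
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
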
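"""CSV readers/writers for every table schema, plus analysis configuration.

All tables are plain CSV with an optional header block of ``# key: value``
lines before the column header. Parsing is locale-independent (decimal
point). Packaged reference fixtures (cellular S-values and worked-example
TIAs; synthetic mouse S-factor matrix and sphere table) load through the
same readers.
"""

from __future__ import annotations

import io as _io
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cellular import CellSValueTable, CompartmentTIA, SubcellularTimeCourse
from .growth import GrowthCurve, TumourMeasurement
from .organ import (BiodistributionStudy, OrganSeries, OrganSFactorMatrix,
                    SphereSTable)
from .radioactivity import get_nuclide
from .radiobiology import ClonogenicCondition, DSBMeasurement


class SchemaError(ValueError):
    """A table did not match its expected schema."""


def _read_with_header(path) -> tuple[dict[str, str], pd.DataFrame]:
    text = Path(path).read_text()
    header: dict[str, str] = {}
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            header[key.strip()] = val.strip()
    try:
        df = pd.read_csv(_io.StringIO(text), comment="#")
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.empty and df.columns.size == 0:
        raise SchemaError(f"{path}: empty table")
    return header, df


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; "
                          f"found {list(df.columns)}")


def _numeric(df: pd.DataFrame, columns: list[str], path) -> None:
    for col in columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise SchemaError(f"{path}: non-numeric value in column "
                              f"{col!r}, row {row}")
        df[col] = vals


def _header_comment(meta: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def _write(path, meta: dict, df: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(meta))
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------- cellular

def read_cell_svalues(path=None) -> CellSValueTable:
    """Cellular S-value table; default is the packaged monolayer fixture."""
    if path is None:
        path = resources.files("ritdose.data") / "cell_svalues_panc1.csv"
    header, df = _read_with_header(path)
    _require(df, ["nuclide", "source", "target", "s_gy_per_bq_s"], path)
    _numeric(df, ["s_gy_per_bq_s"], path)
    s = {(r.nuclide, r.source): float(r.s_gy_per_bq_s)
         for r in df.itertuples()}
    return CellSValueTable(
        s,
        cell_radius_um=float(header["cell_radius_um"])
        if "cell_radius_um" in header else None,
        nucleus_radius_um=float(header["nucleus_radius_um"])
        if "nucleus_radius_um" in header else None,
        monolayer=header.get("monolayer", "true").lower() == "true")


def read_cell_tia(path=None) -> dict[str, tuple[str, CompartmentTIA]]:
    """Worked-example TIAs: conjugate → (nuclide, per-compartment Ã)."""
    if path is None:
        path = resources.files("ritdose.data") / "cell_tia_panc1.csv"
    _, df = _read_with_header(path)
    _require(df, ["conjugate", "nuclide", "source", "tia_bq_s"], path)
    _numeric(df, ["tia_bq_s"], path)
    out = {}
    for (conj, nuc), grp in df.groupby(["conjugate", "nuclide"]):
        out[conj] = (nuc, CompartmentTIA(
            dict(zip(grp["source"], grp["tia_bq_s"]))))
    return out


def read_subcellular(path) -> SubcellularTimeCourse:
    header, df = _read_with_header(path)
    _require(df, ["time_h", "compartment", "activity_bq"], path)
    _numeric(df, ["time_h", "activity_bq"], path)
    if "added_mbq" not in header:
        raise SchemaError(f"{path}: header must declare added_mbq")
    added_bq = float(header["added_mbq"]) * 1e6
    piv = df.pivot_table(index="time_h", columns="compartment",
                         values="activity_bq")
    times = piv.index.to_numpy(float)
    medium = piv.pop("medium").to_numpy(float) if "medium" in piv else None
    return SubcellularTimeCourse(
        times, {c: piv[c].to_numpy(float) for c in piv.columns},
        added_bq, medium,
        float(header["concentration_nm"]) if "concentration_nm" in header
        else None,
        header.get("condition", "specific"),
        header.get("nuclide"))


def write_subcellular(course: SubcellularTimeCourse, path) -> None:
    rows = []
    series = dict(course.activity)
    series["medium"] = course.medium_series()
    for comp, vals in series.items():
        for t, a in zip(course.times_h, vals):
            rows.append({"time_h": t, "compartment": comp, "activity_bq": a})
    meta = {"schema": "subcellular v1",
            "added_mbq": course.added_activity_bq / 1e6,
            "condition": course.condition}
    if course.concentration_nmol_per_l is not None:
        meta["concentration_nm"] = course.concentration_nmol_per_l
    if course.nuclide is not None:
        meta["nuclide"] = course.nuclide
    _write(path, meta, pd.DataFrame(rows))


# ------------------------------------------------------------------- organ

def read_biodistribution(path) -> BiodistributionStudy:
    header, df = _read_with_header(path)
    _require(df, ["organ", "time_h"], path)
    if "mean_activity_bq" in df.columns:
        _numeric(df, ["time_h", "mean_activity_bq"], path)
    elif "percent_id" in df.columns:
        _numeric(df, ["time_h", "percent_id"], path)
        df["mean_activity_bq"] = (df["percent_id"] / 100.0
                                  * float(header["injected_mbq"]) * 1e6)
    else:
        raise SchemaError(f"{path}: need mean_activity_bq or percent_id")
    nuclide = get_nuclide(header["nuclide"])
    organs, tumour = {}, None
    for organ, grp in df.groupby("organ"):
        grp = grp.sort_values("time_h")
        series = OrganSeries(
            grp["time_h"].to_numpy(float),
            grp["mean_activity_bq"].to_numpy(float),
            grp["sd"].to_numpy(float) if "sd" in grp else None,
            int(grp["n"].iloc[0]) if "n" in grp else None)
        if str(organ).lower() == "tumour":
            tumour = series
        else:
            organs[str(organ)] = series
    return BiodistributionStudy(
        nuclide, float(header["injected_mbq"]), organs, tumour,
        float(header["tumour_mass_g"]) if "tumour_mass_g" in header else None,
        int(header.get("n_cycles", 1)))


def write_biodistribution(study: BiodistributionStudy, path) -> None:
    rows = []
    items = list(study.organs.items())
    if study.tumour is not None:
        items.append(("tumour", study.tumour))
    for organ, s in items:
        for i, t in enumerate(s.times_h):
            rows.append({"organ": organ, "time_h": t,
                         "mean_activity_bq": s.mean_bq[i],
                         "sd": s.sd_bq[i] if s.sd_bq is not None else "",
                         "n": s.n if s.n is not None else ""})
    meta = {"schema": "biodistribution v1", "nuclide": study.nuclide.name,
            "injected_mbq": study.injected_mbq, "n_cycles": study.n_cycles}
    if study.tumour_mass_g is not None:
        meta["tumour_mass_g"] = study.tumour_mass_g
    _write(path, meta, pd.DataFrame(rows))


def read_sfactor_matrix(path=None) -> OrganSFactorMatrix:
    """Organ S-factor matrix; default is the packaged synthetic phantom."""
    if path is None:
        path = resources.files("ritdose.data") / "mouse_sfactors_synthetic.csv"
    header, df = _read_with_header(path)
    _require(df, ["target", "source", "s_gy_per_bq_s"], path)
    _numeric(df, ["s_gy_per_bq_s"], path)
    table = df.pivot_table(index="target", columns="source",
                           values="s_gy_per_bq_s")
    if table.isna().any().any():
        raise SchemaError(f"{path}: S-factor matrix has missing entries")
    return OrganSFactorMatrix(table, header.get("provenance", str(path)))


def read_sphere_table(path=None, nuclide: str = "Lu-177") -> SphereSTable:
    """Sphere dose-per-TIA table for one nuclide; default fixture is synthetic."""
    if path is None:
        path = resources.files("ritdose.data") / "sphere_svalues_synthetic.csv"
    _, df = _read_with_header(path)
    _require(df, ["nuclide", "mass_g", "s_gy_per_bq_s"], path)
    _numeric(df, ["mass_g", "s_gy_per_bq_s"], path)
    sub = df[df["nuclide"] == nuclide].sort_values("mass_g")
    if sub.empty:
        raise SchemaError(f"{path}: no sphere rows for nuclide {nuclide!r}")
    return SphereSTable(sub["mass_g"].to_numpy(float),
                        sub["s_gy_per_bq_s"].to_numpy(float), nuclide)


# ------------------------------------------------------------ radiobiology

def read_clonogenic(path) -> list[ClonogenicCondition]:
    """One row per well: condition, cells_seeded, colonies[, dose_gy, ...]."""
    _, df = _read_with_header(path)
    _require(df, ["condition", "cells_seeded", "colonies"], path)
    _numeric(df, ["cells_seeded", "colonies"], path)
    out = []
    for cond, grp in df.groupby("condition", sort=False):
        out.append(ClonogenicCondition(
            str(cond), int(grp["cells_seeded"].iloc[0]),
            [int(c) for c in grp["colonies"]],
            activity_mbq=float(grp["activity_mbq"].iloc[0])
            if "activity_mbq" in grp else None,
            dose_gy=float(grp["dose_gy"].iloc[0])
            if "dose_gy" in grp else None))
    return out


def write_clonogenic(conditions: list[ClonogenicCondition], path) -> None:
    rows = [{"condition": c.label, "activity_mbq": c.activity_mbq,
             "dose_gy": c.dose_gy, "cells_seeded": c.cells_seeded,
             "colonies": col}
            for c in conditions for col in c.colonies]
    _write(path, {"schema": "clonogenic v1"}, pd.DataFrame(rows))


def read_dsb(path) -> list[DSBMeasurement]:
    _, df = _read_with_header(path)
    _require(df, ["condition", "dose_gy", "integrated_density"], path)
    _numeric(df, ["dose_gy", "integrated_density"], path)
    return [DSBMeasurement(str(r.condition), float(r.dose_gy),
                           float(r.integrated_density))
            for r in df.itertuples()]


def write_dsb(measurements: list[DSBMeasurement], path) -> None:
    rows = [{"condition": m.label, "dose_gy": m.dose_gy,
             "integrated_density": m.integrated_density}
            for m in measurements]
    _write(path, {"schema": "dsb v1"}, pd.DataFrame(rows))


# ------------------------------------------------------------------ growth

def read_growth(path) -> dict[str, list[GrowthCurve]]:
    """Growth CSV → curves grouped by treatment group."""
    _, df = _read_with_header(path)
    _require(df, ["animal_id", "group", "day", "length_mm", "width_mm"], path)
    _numeric(df, ["day", "length_mm", "width_mm"], path)
    groups: dict[str, list[GrowthCurve]] = {}
    for (group, animal), grp in df.groupby(["group", "animal_id"],
                                           sort=False):
        grp = grp.sort_values("day")
        weights = (list(zip(grp["day"], grp["body_weight_g"]))
                   if "body_weight_g" in grp else [])
        curve = GrowthCurve(str(animal), str(group), [
            TumourMeasurement(float(r.day), float(r.length_mm),
                              float(r.width_mm)) for r in grp.itertuples()],
            weights)
        groups.setdefault(str(group), []).append(curve)
    return groups


def write_growth(groups: dict[str, list[GrowthCurve]], path) -> None:
    rows = []
    for curves in groups.values():
        for c in curves:
            weights = dict(c.body_weights)
            for m in c.measurements:
                rows.append({"animal_id": c.animal_id, "group": c.group,
                             "day": m.day, "length_mm": m.length_mm,
                             "width_mm": m.width_mm,
                             "body_weight_g": weights.get(m.day, "")})
    _write(path, {"schema": "growth v1"}, pd.DataFrame(rows))


# ------------------------------------------------------------------ config

@dataclass
class AnalysisConfig:
    """Pipeline options; round-trips unchanged through YAML."""

    published_rounded_lambda: bool = False
    antibody_molar_mass: float = 1.45e5
    cell_window_h: tuple[float, float] = (0.0, 16.0)
    decay_correct_cell_integral: bool = False
    survival_fit_scale: str = "sf"      # "sf" | "log"
    welch_t: bool = False
    pin_growth_intercept: bool = False
    n_cycles: int = 1
    output_decimals: int = 2

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["cell_window_h"] = list(data["cell_window_h"])
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "cell_window_h" in data:
            data["cell_window_h"] = tuple(data["cell_window_h"])
        return cls(**data)
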
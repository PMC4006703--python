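"""Loading of packaged fixtures and user configuration files.

All numeric model constants — grid bounds, molecular volumes, the
surface-ratio table, nascent compositions, calibration anchors and the
reference parameter set — live in versioned, unit-annotated TSV/YAML
files so that none of them is hard-coded in the model core and every one
can be overridden from user-supplied files.  The packaged fixtures are
synthetic stand-ins (see the file headers) calibrated against the
published structural constraints.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .composition import GridSpec, LipoType, SurfaceRatioTable, build_grid
from .fplc import CalibrationFit, FractionBoundaries, fit_calibration, fraction_boundaries
from .kinetics import Model, NascentHDLType, Parameter, ParameterSet

__all__ = [
    "data_path",
    "load_surface_table",
    "load_model_config",
    "default_model",
    "default_calibration",
    "default_boundaries",
    "load_parameters",
    "save_parameters",
    "default_parameters",
    "default_estimation_options",
]


def data_path(name: str) -> Path:
    """Path of a packaged data fixture."""
    return Path(resources.files("lipogrid.data") / name)


def load_surface_table(path: str | Path | None = None) -> SurfaceRatioTable:
    path = data_path("surface_ratios_synthetic.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    return SurfaceRatioTable(
        core_radius=df["core_radius_nm"].to_numpy(),
        fc_ratio=df["fc_per_core"].to_numpy(),
        pl_ratio=df["pl_per_core"].to_numpy(),
    )


def load_model_config(path: str | Path | None = None) -> dict:
    path = data_path("model_synthetic.yaml") if path is None else Path(path)
    with open(path) as fh:
        return yaml.safe_load(fh)


def _grid_from_config(cfg: dict, geometry: dict, lipo_type: LipoType) -> GridSpec:
    return GridSpec(
        lipo_type=lipo_type,
        i_max=int(cfg["i_max"]),
        j_max=int(cfg["j_max"]),
        tg_min=float(cfg["tg_min"]),
        tg_max=float(cfg["tg_max"]),
        ce_min=float(cfg["ce_min"]),
        ce_max=float(cfg["ce_max"]),
        surface_thickness=float(geometry["surface_thickness_nm"]),
        v_tg=float(geometry["v_tg_nm3"]),
        v_ce=float(geometry["v_ce_nm3"]),
    )


def default_model(config_path=None, surface_path=None) -> Model:
    """Model container built from the packaged (or given) config files."""
    cfg = load_model_config(config_path)
    table = load_surface_table(surface_path)
    geometry = cfg["geometry"]
    hdl_grid = _grid_from_config(cfg["grids"]["hdl"], geometry, LipoType.HDL)
    vldl_grid = _grid_from_config(cfg["grids"]["vldl"], geometry, LipoType.VLDL)
    nascent = cfg["nascent"]
    types = tuple(
        NascentHDLType(target_tc=float(t["target_tc"]), sigma_log=float(t["sigma_log"]))
        for t in nascent["hdl_types"]
    )
    refs = cfg["reference_sizes"]
    return Model(
        hdl=build_grid(hdl_grid, table),
        vldl=build_grid(vldl_grid, table),
        surface_table=table,
        nascent_hdl_types=types,
        vldl_nascent_tg_ce_ratio=float(nascent["vldl_tg_ce_ratio"]),
        vldl_nascent_cv=float(nascent["vldl_cv"]),
        e3_tg_ce_ratio=float(nascent["e3_tg_ce_ratio"]),
        d_ref_hdl=float(refs["d_ref_hdl_nm"]),
        d_ref_vldl=float(refs["d_ref_vldl_nm"]),
    )


def default_calibration(config_path=None) -> CalibrationFit:
    """Calibration fitted to the packaged class-median anchors."""
    cfg = load_model_config(config_path)
    anchors = cfg["calibration_anchors"]
    return fit_calibration(anchors["fractions"], anchors["diameters_nm"])


def default_boundaries(config_path=None) -> FractionBoundaries:
    cfg = load_model_config(config_path)
    calib = default_calibration(config_path)
    fr = cfg["fractions"]
    return fraction_boundaries(calib, (int(fr["first"]), int(fr["last"])))


def load_parameters(path: str | Path | None = None) -> ParameterSet:
    path = data_path("params_wildtype_synthetic.yaml") if path is None else Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    params = [
        Parameter(
            name=e["name"],
            value=float(e["value"]),
            transform=e["transform"],
            bounds=(float(e["bounds"][0]), float(e["bounds"][1])),
            role=e.get("role", ""),
            fixed=bool(e.get("fixed", False)),
            note=e.get("note", ""),
        )
        for e in doc["parameters"]
    ]
    return ParameterSet(params, extension=doc.get("extension"))


def save_parameters(pset: ParameterSet, path: str | Path) -> None:
    doc = {
        "extension": pset.extension,
        "parameters": [
            {
                "name": p.name,
                "value": float(p.value),
                "transform": p.transform,
                "bounds": [float(p.bounds[0]), float(p.bounds[1])],
                "role": p.role,
                "fixed": bool(p.fixed),
                "note": p.note,
            }
            for p in pset
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_parameters(path=None) -> ParameterSet:
    return load_parameters(path)


def default_estimation_options(config_path=None) -> dict:
    cfg = load_model_config(config_path)
    est = cfg["estimation"]
    return {
        "weight_floor": float(est["weight_floor_nmol"]),
        "weight_cv": float(est["weight_cv"]),
        "lambda_steady_state": float(est["lambda_steady_state"]),
        "lambda_boundary": float(est["lambda_boundary"]),
    }


def default_measured_vldl_tg_production(config_path=None) -> float:
    cfg = load_model_config(config_path)
    return float(cfg["study_conditions"]["measured_vldl_tg_production_nmol_h"])
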
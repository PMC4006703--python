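"""In silico interventions: knockouts, LXR production adaptation, model
extensions and the Triton lipolysis-block experiment.

Knockouts are emulated by scaling the parameter(s) of the affected
process over a published factor range (a sweep, since the residual
activity of a deleted protein is uncertain):

* SR-B1 (HDL selective uptake receptor): scale ``hdl_sel_rate`` to
  0.1–5 % of wild type.
* PLTP (surface-remnant transfer to HDL): scale ``hdl_chol_rate`` to
  30–50 % of wild type.
* LDLr (Apo B/E receptor): scale both VLDL whole-particle uptake
  parameters to 40–92.5 % of wild type.

The LXR-agonist adaptation keeps the nascent VLDL particle secretion
rate and CE content at untreated values and multiplies the nascent TG
content by the measured relative increase in VLDL-TG production; the
nascent diameter then follows from the composition and stops being a
free parameter (16 -> 15 free).

Extensions E1–E3 are alternative mechanisms for the enlarged HDL seen
under LXR activation: extra TC accumulation into large particles (E1),
extra catabolism of large particles through Apo E-binding receptors
(mirroring the VLDL surface-area uptake law; E2), or direct input of
large CE-rich particles (E3).  Each nests the base model: with its added
rate at zero the extended right-hand side is identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .composition import NMOL_PER_MOLECULE, diameter_of_core
from .kinetics import (
    MOLECULES_PER_NMOL,
    CoupledSteadyState,
    Model,
    Parameter,
    ParameterSet,
    build_system,
    couple_submodels,
    nascent_vldl_moments,
    vldl_production_field,
    vldl_rate_fields,
    hdl_rate_fields,
    hdl_production_field,
)

__all__ = [
    "ScenarioSpec",
    "KNOCKOUT_SCENARIOS",
    "apply_knockout",
    "sweep_summary",
    "lxr_production_adaptation",
    "EXTENSION_PARAMETERS",
    "extend_model",
    "simulate_triton",
    "TritonResult",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """A named parameter-scaling scenario with a sweep of factors."""

    name: str
    scalings: dict[str, tuple[float, float]]  # param -> (low, high) factor
    n_points: int = 5

    def __post_init__(self) -> None:
        for pname, (lo, hi) in self.scalings.items():
            if lo <= 0 or hi <= 0 or hi < lo:
                raise ValueError(f"{self.name}: invalid factor range for {pname!r}")

    def factors(self) -> np.ndarray:
        ranges = list(self.scalings.values())
        lo, hi = ranges[0]
        if self.n_points == 1:
            return np.array([lo])
        # All parameters of one scenario share the sweep grid (relative
        # position within their own range).
        return np.linspace(0.0, 1.0, self.n_points)


#: The published knockout emulations.
KNOCKOUT_SCENARIOS = {
    "SR-B1": ScenarioSpec("SR-B1", {"hdl_sel_rate": (0.001, 0.05)}),
    "PLTP": ScenarioSpec("PLTP", {"hdl_chol_rate": (0.30, 0.50)}),
    "LDLr": ScenarioSpec(
        "LDLr",
        {"vldl_upt_const": (0.40, 0.925), "vldl_upt_surf_rate": (0.40, 0.925)},
    ),
}


def apply_knockout(base_params: ParameterSet, scenario: ScenarioSpec) -> list[ParameterSet]:
    """One parameter set per sweep point; only listed parameters change."""
    out = []
    for t in scenario.factors():
        factors = {
            name: lo + t * (hi - lo) for name, (lo, hi) in scenario.scalings.items()
        }
        out.append(base_params.scaled(factors))
    return out


def sweep_summary(
    model: Model,
    base_params: ParameterSet,
    scenario: ScenarioSpec,
    measured_vldl_tg_rate: float,
):
    """Plasma TC/TG (total and per sub-model, nmol) along a knockout sweep.

    Returns a list of dicts, one per sweep point, each including the
    relative change versus the wild-type steady state.
    """
    def totals(coupled: CoupledSteadyState):
        res = {}
        for name, state, comp in (
            ("hdl", coupled.hdl_state, model.hdl),
            ("vldl", coupled.vldl_state, model.vldl),
        ):
            res[f"{name}_tc"] = float((state * comp.n_tc).sum()) * NMOL_PER_MOLECULE
            res[f"{name}_tg"] = float((state * comp.n_tg).sum()) * NMOL_PER_MOLECULE
        res["plasma_tc"] = res["hdl_tc"] + res["vldl_tc"]
        res["plasma_tg"] = res["hdl_tg"] + res["vldl_tg"]
        return res

    base = totals(couple_submodels(model, base_params, measured_vldl_tg_rate))
    rows = []
    for t, pset in zip(scenario.factors(), apply_knockout(base_params, scenario)):
        tot = totals(couple_submodels(model, pset, measured_vldl_tg_rate))
        row = {"sweep_position": float(t), **tot}
        for key in ("plasma_tc", "plasma_tg", "hdl_tc", "hdl_tg"):
            row[f"{key}_rel_change"] = tot[key] / base[key] - 1.0
        rows.append(row)
    return rows


def lxr_production_adaptation(
    model: Model,
    base_params: ParameterSet,
    relative_tg_increase: float,
    measured_vldl_tg_rate: float,
) -> tuple[Model, ParameterSet]:
    """Fix VLDL production to the LXR-adapted nascent composition.

    The untreated nascent VLDL particle secretion rate and CE content are
    retained; the TG content is multiplied by the relative increase in
    VLDL-TG production.  The nascent diameter follows from the scaled
    composition, so it leaves the free parameter set (16 -> 15).

    Returns the adapted model (carrying the production override) and the
    reduced parameter set.
    """
    if relative_tg_increase <= 0:
        raise ValueError("relative TG increase must be positive")
    d0 = base_params["vldl_nascent_diameter"]
    mean_tg, mean_ce = nascent_vldl_moments(model, d0)
    base_prod = vldl_production_field(model, d0, measured_vldl_tg_rate)
    particle_rate = float(base_prod.sum())
    new_tg = mean_tg * relative_tg_increase
    grid = model.vldl.grid
    if not (grid.tg_min <= new_tg <= grid.tg_max):
        raise ValueError("scaled nascent TG content falls outside the grid")
    from dataclasses import replace as dc_replace

    adapted_model = dc_replace(
        model, vldl_production_override=(new_tg, mean_ce, particle_rate)
    )
    adapted_params = base_params.with_fixed(["vldl_nascent_diameter"])
    return adapted_model, adapted_params


def lxr_nascent_diameter(model: Model, base_params: ParameterSet, relative_tg_increase: float) -> float:
    """Diameter implied by the LXR-scaled nascent composition (nm)."""
    mean_tg, mean_ce = nascent_vldl_moments(model, base_params["vldl_nascent_diameter"])
    grid = model.vldl.grid
    return float(
        diameter_of_core(mean_tg * relative_tg_increase, mean_ce, grid)
    )


#: Added parameters per extension (values are nesting-neutral defaults:
#: the added rate is 0, so the extended model equals the base model).
EXTENSION_PARAMETERS = {
    "E1": [
        Parameter("ext_chol_rate", 0.0, "linear", (-1e-12, 1.0), "E1 extra TC accumulation rate"),
        Parameter("ext_chol_d50", 12.0, "linear", (8.0, 25.0), "E1 size threshold (nm)"),
    ],
    "E2": [
        Parameter("ext_upt_rate", 0.0, "linear", (-1e-12, 10.0), "E2 extra catabolism ceiling (1/h)"),
        Parameter("ext_upt_d50", 14.0, "linear", (8.0, 25.0), "E2 half-maximal diameter (nm)"),
        Parameter("ext_upt_hill", 4.0, "linear", (1.0, 8.0), "E2 saturation steepness"),
    ],
    "E3": [
        Parameter("ext_prod_rate", 0.0, "linear", (-1e-12, 1e16), "E3 large-HDL input (particles/h)"),
        Parameter("ext_prod_diameter", 18.0, "linear", (12.0, 24.0), "E3 nascent diameter (nm)"),
        Parameter("ext_prod_cv", 0.1, "linear", (0.02, 0.5), "E3 nascent content CV"),
    ],
}


def extend_model(base_params: ParameterSet, extension: str, values=None) -> ParameterSet:
    """Parameter set of an extended model variant (E1, E2 or E3).

    The extensions are alternatives and are applied one at a time.  With
    the added rate parameter at zero the extended kinetics are identical
    to the base model's.
    """
    if base_params.extension is not None:
        raise ValueError(
            f"parameters already carry extension {base_params.extension!r}; "
            "extensions are tested separately, not combined"
        )
    try:
        added = EXTENSION_PARAMETERS[extension]
    except KeyError:
        raise ValueError(f"unknown extension {extension!r}; one of E1, E2, E3")
    pset = base_params.with_parameters(added, extension=extension)
    if values:
        pset = pset.with_values(values)
    return pset


@dataclass(frozen=True)
class TritonResult:
    """Outcome of the in silico lipolysis-block (Triton) experiment."""

    times: np.ndarray            # h
    plasma_tg: np.ndarray        # nmol, VLDL + HDL
    tg_rise: float               # nmol over the horizon
    production_estimate: float   # nmol TG/h, rise / horizon
    true_production: float       # nmol TG/h input into VLDL


def simulate_triton(
    model: Model,
    params: ParameterSet,
    measured_vldl_tg_rate: float,
    horizon_hours: float = 4.0,
    n_times: int = 41,
) -> TritonResult:
    """VLDL-TG production estimated from plasma TG accumulation with
    peripheral lipolysis turned off.

    Starting from the wild-type coupled steady state, all lipolysis
    fluxes are zeroed and the system is integrated over the horizon; the
    plasma TG rise divided by the horizon is the Triton-style production
    estimate.  Whole-particle uptake remains active, so the estimate is a
    lower bound on the true production.
    """
    coupled = couple_submodels(model, params, measured_vldl_tg_rate)
    # lip_rate is log-transformed (strictly positive); zero the fluxes by
    # zeroing the assembled rate fields instead of the parameters.
    v_rates = vldl_rate_fields(model, params)
    v_rates["lip_universal"] = np.zeros_like(v_rates["lip_universal"])
    v_rates["lip_vldl"] = np.zeros_like(v_rates["lip_vldl"])
    h_rates = hdl_rate_fields(model, params, coupled.pl_release)
    h_rates["lip"] = np.zeros_like(h_rates["lip"])

    times = np.linspace(0.0, horizon_hours, n_times)
    tg_totals = np.zeros_like(times)
    for (rates, prod, state0, comp) in (
        (v_rates, coupled.vldl_production, coupled.vldl_state, model.vldl),
        (h_rates, coupled.hdl_production, coupled.hdl_state, model.hdl),
    ):
        m, p = build_system(rates, prod)
        sol = solve_ivp(
            lambda t, y: m @ y + p,
            (0.0, horizon_hours),
            state0.ravel(),
            method="BDF",
            jac=m,
            t_eval=times,
            rtol=1e-8,
            atol=1e-6 * max(p.max(), 1.0),
        )
        if not sol.success:
            raise RuntimeError(f"Triton time integration failed: {sol.message}")
        tg_totals += (sol.y.T @ comp.n_tg.ravel()) * NMOL_PER_MOLECULE

    rise = float(tg_totals[-1] - tg_totals[0])
    true_prod = float((coupled.vldl_production * model.vldl.n_tg).sum()) * NMOL_PER_MOLECULE
    return TritonResult(
        times=times,
        plasma_tg=tg_totals,
        tg_rise=rise,
        production_estimate=rise / horizon_hours,
        true_production=true_prod,
    )
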
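"""Kinetic sub-models of HDL and VLDL/LDL metabolism on the composition grid.

Each sub-model is a population balance over its 320 grid states: particles
enter by production, move between neighbouring states by remodelling
(lipolysis, selective uptake, lipid accumulation), and leave by whole-
particle catabolism.  All grid boundaries are closed (fluxes over them are
zero); the only exits are the catabolic terms.

Rate laws (the phenomenological contracts; see docs/methods.md for the
full reference):

* Lipolysis removes TG at a rate proportional to the particle's absolute
  TG content, modulated by a power of the *relative* TG content
  (``lip_rate * relTG**lip_exp * n_tg`` molecules/h per particle).  The
  same two parameters act on both HDL and VLDL (lipoprotein lipase does
  not distinguish the carrier); VLDL additionally has a specific lipolysis
  term that grows with a power of particle size.
* Selective uptake removes CE in proportion to absolute CE content,
  relative CE content and particle size (one rate parameter per type).
* HDL TC and TG accumulation are driven by the rate of surface-remnant
  (phospholipid) entry from VLDL remodelling and scale with particle
  surface area (one parameter each).
* HDL catabolism is inversely proportional to particle diameter; VLDL
  catabolism is a constant first-order term plus a saturating
  surface-area-dependent term (Apo E-mediated uptake of large particles).

Because every rate is linear in the state, each sub-model's steady state
is the solution of a sparse linear system; the system matrix is a proper
transition-rate matrix minus positive uptake rates (an M-matrix), so the
steady state is unique and non-negative whenever catabolism is active
everywhere.  A stiff time-integration fallback covers degenerate
parameter draws during optimization.

Remodelling moves a particle one index step, but an index step removes or
adds a composition-dependent number of molecules.  The per-state
correction factor (lipid rate divided by the lipid content change of the
step) converts molecular rates into index-step particle fluxes, keeping
the molecular ledger exact on the non-uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .composition import (
    NMOL_PER_MOLECULE,
    CompositionField,
    GridSpec,
    surface_counts,
)

__all__ = [
    "Parameter",
    "ParameterSet",
    "Model",
    "SteadyStateDiagnostics",
    "CoupledSteadyState",
    "hdl_production_field",
    "vldl_production_field",
    "hdl_rate_fields",
    "vldl_rate_fields",
    "hdl_remodelling_fluxes",
    "vldl_remodelling_and_uptake_fluxes",
    "build_system",
    "rhs",
    "steady_state",
    "vldl_surface_release",
    "couple_submodels",
    "hdl_joint_rescaling",
]

MOLECULES_PER_NMOL = 1.0 / NMOL_PER_MOLECULE

#: The six HDL rate parameters whose joint scaling leaves the HDL steady
#: state exactly invariant (production + the five kinetic rates).  With the
#: shared lipolysis rate pinned by the VLDL sub-model, the remaining five
#: are only identifiable as ratios.
HDL_SCALING_GROUP = (
    "hdl_prod_rate",
    "lip_rate",
    "hdl_sel_rate",
    "hdl_chol_rate",
    "hdl_trig_rate",
    "hdl_upt_rate",
)


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class Parameter:
    """One named model parameter with optimizer metadata."""

    name: str
    value: float
    transform: str  # 'log' or 'linear'
    bounds: tuple[float, float]
    role: str
    fixed: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.transform not in ("log", "linear"):
            raise ValueError(f"unknown transform {self.transform!r}")
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError(f"{self.name}: empty bounds {self.bounds}")
        if self.transform == "log" and lo <= 0:
            raise ValueError(f"{self.name}: log-transformed bounds must be positive")


class ParameterSet:
    """Ordered collection of named parameters.

    ``pset['name']`` returns the value; the :class:`Parameter` records are
    reachable through ``pset.spec('name')``.  ``extension`` marks a set
    belonging to an extended model variant (E1/E2/E3).
    """

    def __init__(self, parameters, extension: str | None = None):
        self._params: dict[str, Parameter] = {}
        for p in parameters:
            if p.name in self._params:
                raise ValueError(f"duplicate parameter {p.name!r}")
            self._params[p.name] = p
        self.extension = extension
        frac = self._params.get("hdl_prod_small_frac")
        if frac is not None and not (0.0 <= frac.value <= 1.0):
            raise ValueError("hdl_prod_small_frac must lie in [0, 1]")

    def __getitem__(self, name: str) -> float:
        return self._params[name].value

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __iter__(self):
        return iter(self._params.values())

    def __len__(self) -> int:
        return len(self._params)

    def spec(self, name: str) -> Parameter:
        return self._params[name]

    @property
    def names(self) -> list[str]:
        return list(self._params)

    @property
    def free_names(self) -> list[str]:
        return [p.name for p in self._params.values() if not p.fixed]

    def values(self) -> dict[str, float]:
        return {p.name: p.value for p in self._params.values()}

    def with_values(self, updates: Mapping[str, float]) -> "ParameterSet":
        """New set with the given values replaced (bounds not enforced)."""
        unknown = set(updates) - set(self._params)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        return ParameterSet(
            [
                replace(p, value=float(updates.get(p.name, p.value)))
                for p in self._params.values()
            ],
            extension=self.extension,
        )

    def scaled(self, factors: Mapping[str, float]) -> "ParameterSet":
        """New set with named values multiplied by positive factors."""
        for name, f in factors.items():
            if f <= 0:
                raise ValueError(f"scaling factor for {name!r} must be > 0")
            if name not in self._params:
                raise KeyError(f"unknown parameter {name!r}")
        return self.with_values(
            {n: self._params[n].value * f for n, f in factors.items()}
        )

    def with_parameters(self, new: list[Parameter], extension=None) -> "ParameterSet":
        return ParameterSet(list(self._params.values()) + list(new), extension=extension)

    def with_fixed(self, names, fixed=True) -> "ParameterSet":
        names = set(names)
        return ParameterSet(
            [replace(p, fixed=fixed) if p.name in names else p for p in self._params.values()],
            extension=self.extension,
        )

    def drop(self, names) -> "ParameterSet":
        names = set(names)
        return ParameterSet(
            [p for p in self._params.values() if p.name not in names],
            extension=self.extension,
        )


# ---------------------------------------------------------------------------
# model container


@dataclass(frozen=True)
class NascentHDLType:
    """One nascent HDL species: minimal TG, log-normal CE with a target TC."""

    target_tc: float
    sigma_log: float = 0.12


@dataclass(frozen=True)
class Model:
    """Composition geometry plus the fixed physiological constants.

    The kinetic parameters live in a :class:`ParameterSet`; everything
    here is structural (grids, surface ratios, nascent compositions and
    reference sizes) and is shared by all parameter sets.
    """

    hdl: CompositionField
    vldl: CompositionField
    surface_table: object
    nascent_hdl_types: tuple[NascentHDLType, ...] = (
        NascentHDLType(target_tc=55.0),  # type 1: the larger species
        NascentHDLType(target_tc=24.0),  # type 2: the smaller species
    )
    vldl_nascent_tg_ce_ratio: float = 10.0
    vldl_nascent_cv: float = 0.2
    e3_tg_ce_ratio: float = 0.05
    d_ref_hdl: float = 10.0
    d_ref_vldl: float = 40.0
    #: production override: (mean_tg, mean_ce, particles_per_h) replaces the
    #: diameter-parameterized VLDL production (used by the LXR adaptation).
    vldl_production_override: tuple[float, float, float] | None = None

    def hdl_nascent_distribution(self, ntype: NascentHDLType) -> np.ndarray:
        """Discrete distribution of one nascent HDL type over the grid.

        Nascent HDL carries the minimal TG content (the exponential TG
        ladder excludes TG-free particles), so the distribution lives on
        the first TG row; CE is spread log-normally around the content at
        which total cholesterol (CE + FC) matches the type's target.
        """
        grid = self.hdl.grid

        def tc_of_ce(ce):
            fc, _ = surface_counts(grid.tg_min, ce, self.surface_table, grid)
            return float(ce + fc) - ntype.target_tc

        lo, hi = grid.ce_min, grid.ce_max
        if tc_of_ce(lo) > 0 or tc_of_ce(hi) < 0:
            raise ValueError(
                f"nascent HDL target TC {ntype.target_tc} not representable on grid"
            )
        ce_star = brentq(tc_of_ce, lo, hi, xtol=1e-10)
        ce = self.hdl.n_ce[0, :]
        dce = _dce_dj(np.arange(1, grid.j_max + 1, dtype=float), grid)
        sigma = ntype.sigma_log
        mu = np.log(ce_star)
        dens = np.exp(-((np.log(ce) - mu) ** 2) / (2 * sigma**2)) / ce
        weights = dens * dce
        dist = np.zeros((grid.i_max, grid.j_max))
        dist[0, :] = weights / weights.sum()
        return dist


# ---------------------------------------------------------------------------
# index-step geometry


def _step_sizes(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(down, up) lipid content change per index step along a ladder.

    ``down[k] = values[k] - values[k-1]`` (NaN at the first level, where
    the boundary is closed) and ``up[k] = values[k+1] - values[k]`` (NaN at
    the last level).
    """
    down = np.empty_like(values)
    up = np.empty_like(values)
    down[1:] = np.diff(values)
    down[0] = np.nan
    up[:-1] = np.diff(values)
    up[-1] = np.nan
    return down, up


def _dce_dj(j, grid: GridSpec):
    """Analytic d(CE)/dj of the CE ladder at real-valued j."""
    t = (np.asarray(j, dtype=float) - 1.0) / (grid.j_max - 1.0)
    d = grid.d_min * (grid.d_max / grid.d_min) ** t
    dd_dj = d * np.log(grid.d_max / grid.d_min) / (grid.j_max - 1.0)
    dv_dd = 2.0 * np.pi * (d / 2.0 - grid.surface_thickness) ** 2
    return dv_dd * dd_dj / grid.v_ce


def _dtg_di(i, grid: GridSpec):
    """Analytic d(TG)/di of the TG ladder at real-valued i."""
    i = np.asarray(i, dtype=float)
    tg = grid.tg_min * grid.growth_factor_g ** (i - 1.0)
    return tg * np.log(grid.growth_factor_g)


# ---------------------------------------------------------------------------
# production inputs


def hdl_production_field(model: Model, params: ParameterSet) -> np.ndarray:
    """Per-state HDL particle input (particles/h), summing to the
    production rate parameter.

    The small-type fraction parameter weights the smaller nascent species;
    the weights of all species sum to one, preserving the production rate
    parameter as the total particle input.
    """
    k_prod = params["hdl_prod_rate"]
    k2 = params["hdl_prod_small_frac"]
    if not 0.0 <= k2 <= 1.0:
        raise ValueError("nascent-type weights must sum to 1 with weights in [0,1]")
    w = (1.0 - k2, k2)  # (larger type, smaller type)
    out = np.zeros_like(model.hdl.n_tg)
    for weight, ntype in zip(w, model.nascent_hdl_types):
        if weight > 0:
            out += weight * model.hdl_nascent_distribution(ntype)
    field_ = k_prod * out
    if params.extension == "E3":
        field_ = field_ + e3_production_field(model, params)
    return field_


def discretized_lognormal_input(
    comp: CompositionField, mean_tg: float, mean_ce: float, cv: float
) -> np.ndarray:
    """Independent 2-D log-normal over (TG, CE), integrated per grid cell.

    Cell integrals use 2-point Gauss quadrature per index dimension with
    the ladder Jacobians; the result is renormalized to sum to one over
    the grid support.
    """
    grid = comp.grid
    sigma2 = np.log(1.0 + cv**2)
    sigma = np.sqrt(sigma2)
    mu_tg = np.log(mean_tg) - sigma2 / 2.0
    mu_ce = np.log(mean_ce) - sigma2 / 2.0

    def logn(x, mu):
        return np.exp(-((np.log(x) - mu) ** 2) / (2 * sigma2)) / (
            x * sigma * np.sqrt(2 * np.pi)
        )

    gx, gw = np.polynomial.legendre.leggauss(2)
    gx = gx / 2.0
    gw = gw / 2.0
    i = np.arange(1, grid.i_max + 1, dtype=float)
    j = np.arange(1, grid.j_max + 1, dtype=float)
    w_i = np.zeros(grid.i_max)
    w_j = np.zeros(grid.j_max)
    for q in range(2):
        iq = np.clip(i + gx[q], 1.0, grid.i_max)
        jq = np.clip(j + gx[q], 1.0, grid.j_max)
        tg = grid.tg_min * grid.growth_factor_g ** (iq - 1.0)
        from .composition import ce_of_index

        ce = ce_of_index(jq, grid)
        w_i += gw[q] * logn(tg, mu_tg) * _dtg_di(iq, grid)
        w_j += gw[q] * logn(ce, mu_ce) * _dce_dj(jq, grid)
    dist = np.outer(w_i, w_j)
    total = dist.sum()
    if total <= 0:
        raise ValueError("log-normal production density vanishes on the grid")
    return dist / total


def nascent_vldl_moments(model: Model, diameter: float) -> tuple[float, float]:
    """Mean (TG, CE) content of nascent VLDL of the given diameter.

    The core volume implied by the diameter is split between TG and CE at
    the fixed nascent molar ratio.
    """
    grid = model.vldl.grid
    r_core = diameter / 2.0 - grid.surface_thickness
    if r_core <= 0:
        raise ValueError(f"nascent diameter {diameter} nm leaves no core volume")
    volume = (4.0 / 3.0) * np.pi * r_core**3
    rho = model.vldl_nascent_tg_ce_ratio
    mean_ce = volume / (rho * grid.v_tg + grid.v_ce)
    return rho * mean_ce, mean_ce


def vldl_production_field(
    model: Model,
    diameter: float,
    measured_vldl_tg_rate: float,
    cv: float | None = None,
    override: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Per-state VLDL particle input (particles/h).

    A discretized 2-D log-normal over (TG, CE) whose means follow from the
    nascent-diameter parameter and the fixed nascent TG:CE ratio, globally
    rescaled so that the simulated VLDL-TG production equals the measured
    rate (``measured_vldl_tg_rate`` in nmol TG/h).

    When ``override`` is given (the LXR production adaptation) it supplies
    ``(mean_tg, mean_ce, particles_per_h)`` directly and the measured rate
    is ignored.
    """
    grid = model.vldl.grid
    cv = model.vldl_nascent_cv if cv is None else cv
    if override is not None:
        mean_tg, mean_ce, rate = override
        if not (grid.tg_min <= mean_tg <= grid.tg_max) or not (
            grid.ce_min <= mean_ce <= grid.ce_max
        ):
            raise ValueError("nascent VLDL content outside the representable grid")
        dist = discretized_lognormal_input(model.vldl, mean_tg, mean_ce, cv)
        return rate * dist
    mean_tg, mean_ce = nascent_vldl_moments(model, diameter)
    if not (grid.tg_min <= mean_tg <= grid.tg_max) or not (
        grid.ce_min <= mean_ce <= grid.ce_max
    ):
        raise ValueError(
            f"nascent diameter {diameter} nm implies contents outside the grid"
        )
    if measured_vldl_tg_rate <= 0:
        raise ValueError("measured VLDL-TG production must be positive")
    dist = discretized_lognormal_input(model.vldl, mean_tg, mean_ce, cv)
    tg_per_dist = float((dist * model.vldl.n_tg).sum())
    if tg_per_dist <= 0:
        raise ValueError("VLDL production distribution carries no TG")
    rate = measured_vldl_tg_rate * MOLECULES_PER_NMOL / tg_per_dist
    return rate * dist


def e3_production_field(model: Model, params: ParameterSet) -> np.ndarray:
    """E3 extension: input of very large, TG-poor, CE-rich HDL particles."""
    grid = model.hdl.grid
    d = params["ext_prod_diameter"]
    r_core = d / 2.0 - grid.surface_thickness
    if r_core <= 0:
        raise ValueError("E3 nascent diameter leaves no core volume")
    volume = (4.0 / 3.0) * np.pi * r_core**3
    rho = model.e3_tg_ce_ratio  # TG:CE molar ratio, << 1
    mean_ce = volume / (rho * grid.v_tg + grid.v_ce)
    mean_tg = max(rho * mean_ce, grid.tg_min)
    dist = discretized_lognormal_input(model.hdl, mean_tg, mean_ce, params["ext_prod_cv"])
    return params["ext_prod_rate"] * dist


# ---------------------------------------------------------------------------
# rate fields (per-state first-order coefficients, 1/h)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def hdl_rate_fields(model: Model, params: ParameterSet, vldl_pl_release: float):
    """Per-state first-order rate coefficients of the HDL processes.

    Returns a dict of arrays (1/h): ``lip`` (i -> i-1), ``sel``
    (j -> j-1), ``chol`` (j -> j+1), ``trig`` (i -> i+1) and ``upt``
    (removal).  Boundary entries are exactly zero (closed grid).
    ``vldl_pl_release`` is the surface-remnant PL influx in nmol/h.
    """
    if vldl_pl_release < 0:
        raise ValueError("surface-remnant PL release must be >= 0")
    comp = model.hdl
    core = comp.n_tg + comp.n_ce
    rel_tg = comp.n_tg / core
    rel_ce = comp.n_ce / core
    area = comp.surface_area
    d = comp.diameter

    tg_down, tg_up = _step_sizes(comp.n_tg[:, 0])
    ce_down, ce_up = _step_sizes(comp.n_ce[0, :])

    v_lip = params["lip_rate"] * rel_tg ** params["lip_exp"] * comp.n_tg
    r_lip = np.zeros_like(v_lip)
    r_lip[1:, :] = v_lip[1:, :] / tg_down[1:, None]

    v_sel = params["hdl_sel_rate"] * rel_ce * (d / model.d_ref_hdl) * comp.n_ce
    r_sel = np.zeros_like(v_sel)
    r_sel[:, 1:] = v_sel[:, 1:] / ce_down[None, 1:]

    v_chol = params["hdl_chol_rate"] * vldl_pl_release * area
    if params.extension == "E1":
        v_chol = v_chol + (
            params["ext_chol_rate"]
            * vldl_pl_release
            * area
            * _logistic(d - params["ext_chol_d50"])
        )
    r_chol = np.zeros_like(v_chol)
    r_chol[:, :-1] = v_chol[:, :-1] / ce_up[None, :-1]

    v_trig = params["hdl_trig_rate"] * vldl_pl_release * area
    r_trig = np.zeros_like(v_trig)
    r_trig[:-1, :] = v_trig[:-1, :] / tg_up[:-1, None]

    r_upt = params["hdl_upt_rate"] * (model.d_ref_hdl / d)
    if params.extension == "E2":
        a50 = np.pi * params["ext_upt_d50"] ** 2
        h = params["ext_upt_hill"]
        r_upt = r_upt + params["ext_upt_rate"] * area**h / (a50**h + area**h)

    return {"lip": r_lip, "sel": r_sel, "chol": r_chol, "trig": r_trig, "upt": r_upt}


def vldl_rate_fields(model: Model, params: ParameterSet):
    """Per-state rate coefficients of the VLDL processes.

    ``lip_universal`` and ``lip_vldl`` both move i -> i-1, ``sel`` moves
    j -> j-1, ``upt_const`` and ``upt_surface`` remove particles.  Core
    content never increases (no gain processes).
    """
    comp = model.vldl
    core = comp.n_tg + comp.n_ce
    rel_tg = comp.n_tg / core
    rel_ce = comp.n_ce / core
    area = comp.surface_area
    d = comp.diameter

    tg_down, _ = _step_sizes(comp.n_tg[:, 0])
    ce_down, _ = _step_sizes(comp.n_ce[0, :])

    v_lip_u = params["lip_rate"] * rel_tg ** params["lip_exp"] * comp.n_tg
    v_lip_v = (
        params["vldl_lip_rate"]
        * (d / model.d_ref_vldl) ** params["vldl_lip_exp"]
        * comp.n_tg
    )
    r_lip_u = np.zeros_like(v_lip_u)
    r_lip_v = np.zeros_like(v_lip_v)
    r_lip_u[1:, :] = v_lip_u[1:, :] / tg_down[1:, None]
    r_lip_v[1:, :] = v_lip_v[1:, :] / tg_down[1:, None]

    v_sel = params["vldl_sel_rate"] * rel_ce * (d / model.d_ref_vldl) * comp.n_ce
    r_sel = np.zeros_like(v_sel)
    r_sel[:, 1:] = v_sel[:, 1:] / ce_down[None, 1:]

    r_upt_const = np.full_like(d, params["vldl_upt_const"])
    a50 = np.pi * params["vldl_upt_surf_d50"] ** 2
    h = params["vldl_upt_surf_hill"]
    r_upt_surf = params["vldl_upt_surf_rate"] * area**h / (a50**h + area**h)

    return {
        "lip_universal": r_lip_u,
        "lip_vldl": r_lip_v,
        "sel": r_sel,
        "upt_const": r_upt_const,
        "upt_surface": r_upt_surf,
    }


# ---------------------------------------------------------------------------
# system assembly and steady state


def _shift_matrix(rate: np.ndarray, axis: int, direction: int, shape) -> np.ndarray:
    """Dense transition matrix moving particles one step along an axis."""
    n = shape[0] * shape[1]
    m = np.zeros((n, n))
    r = rate.ravel()
    idx = np.arange(n).reshape(shape)
    if axis == 0:
        src = idx[1:, :] if direction < 0 else idx[:-1, :]
        dst = idx[:-1, :] if direction < 0 else idx[1:, :]
    else:
        src = idx[:, 1:] if direction < 0 else idx[:, :-1]
        dst = idx[:, :-1] if direction < 0 else idx[:, 1:]
    src = src.ravel()
    dst = dst.ravel()
    m[dst, src] += r[src]
    m[src, src] -= r[src]
    return m


def build_system(rates: dict, production: np.ndarray):
    """(M, p) of the affine ODE dx/dt = M x + p from rate fields."""
    shape = production.shape
    n = production.size
    m = np.zeros((n, n))
    moves = {
        "lip": (0, -1),
        "lip_universal": (0, -1),
        "lip_vldl": (0, -1),
        "sel": (1, -1),
        "chol": (1, +1),
        "trig": (0, +1),
    }
    for name, rate in rates.items():
        if name in moves:
            axis, direction = moves[name]
            m += _shift_matrix(rate, axis, direction, shape)
        else:  # uptake: pure removal
            m[np.arange(n), np.arange(n)] -= rate.ravel()
    return m, production.ravel()


def rhs(state: np.ndarray, rates: dict, production: np.ndarray) -> np.ndarray:
    """Time derivative of the state field (particles/h per state)."""
    x = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(x)):
        bad = np.argwhere(~np.isfinite(x))
        raise FloatingPointError(f"non-finite state at grid indices {bad[:3] + 1}")
    out = production.copy()
    for name, rate in rates.items():
        flux = rate * x
        if not np.all(np.isfinite(flux)):
            bad = np.argwhere(~np.isfinite(flux))
            raise FloatingPointError(
                f"non-finite {name} flux at grid indices {bad[:3] + 1}"
            )
        out -= flux
        if name in ("lip", "lip_universal", "lip_vldl"):
            out[:-1, :] += flux[1:, :]
        elif name == "sel":
            out[:, :-1] += flux[:, 1:]
        elif name == "chol":
            out[:, 1:] += flux[:, :-1]
        elif name == "trig":
            out[1:, :] += flux[:-1, :]
        # uptake terms only remove
    return out


@dataclass(frozen=True)
class SteadyStateDiagnostics:
    converged: bool
    residual_norm: float
    rel_residual: float
    boundary_mass_fraction: float
    method: str


def _boundary_mass_fraction(state: np.ndarray) -> float:
    total = state.sum()
    if total <= 0:
        return 0.0
    top = state[-2:, :].sum() + state[:, -2:].sum() - state[-2:, -2:].sum()
    return float(top / total)


def steady_state(
    rates: dict,
    production: np.ndarray,
    rel_tol: float = 1e-8,
    t_max: float = 2e4,
) -> tuple[np.ndarray, SteadyStateDiagnostics]:
    """Solve the sub-model steady state.

    The affine system is solved directly; if the direct solve fails or
    returns a physically invalid state, stiff time integration from the
    empty state is used instead.  Non-convergence is reported through the
    diagnostics (never raised) so that cost functions can penalize it.
    """
    m, p = build_system(rates, production)
    shape = production.shape
    state = None
    method = "linear_solve"
    try:
        x = np.linalg.solve(m, -p)
        if np.all(np.isfinite(x)) and x.min() > -1e-9 * max(x.max(), 1.0):
            state = np.maximum(x, 0.0).reshape(shape)
    except np.linalg.LinAlgError:
        state = None
    if state is None:
        method = "time_integration"
        sol = solve_ivp(
            lambda t, y: m @ y + p,
            (0.0, t_max),
            np.zeros(p.size),
            method="BDF",
            jac=m,
            rtol=1e-8,
            atol=1e-6 * max(p.max(), 1.0),
        )
        state = np.maximum(sol.y[:, -1], 0.0).reshape(shape)
    res = rhs(state, rates, production)
    res_norm = float(np.linalg.norm(res.ravel(), np.inf))
    scale = float(max(np.abs(state).max(), production.sum(), 1.0))
    rel = res_norm / scale
    diag = SteadyStateDiagnostics(
        converged=bool(rel < rel_tol),
        residual_norm=res_norm,
        rel_residual=rel,
        boundary_mass_fraction=_boundary_mass_fraction(state),
        method=method,
    )
    return state, diag


# ---------------------------------------------------------------------------
# flux decompositions


def _lipid_fluxes_for_process(comp: CompositionField, name: str, particle_flux):
    """Molecular fluxes (molecules/h per state) carried by one process."""
    grid_tg = comp.n_tg
    grid_ce = comp.n_ce
    out = {}
    if name in ("lip", "lip_universal", "lip_vldl"):
        dtg = np.zeros_like(grid_tg)
        dtg[1:, :] = grid_tg[1:, :] - grid_tg[:-1, :]
        out["TG"] = particle_flux * dtg
    elif name == "sel":
        dce = np.zeros_like(grid_ce)
        dce[:, 1:] = grid_ce[:, 1:] - grid_ce[:, :-1]
        out["CE"] = particle_flux * dce
    elif name == "chol":
        dce = np.zeros_like(grid_ce)
        dce[:, :-1] = grid_ce[:, 1:] - grid_ce[:, :-1]
        out["CE"] = particle_flux * dce
    elif name == "trig":
        dtg = np.zeros_like(grid_tg)
        dtg[:-1, :] = grid_tg[1:, :] - grid_tg[:-1, :]
        out["TG"] = particle_flux * dtg
    elif name.startswith("upt") or name == "prod":
        for lipid, content in (
            ("TG", comp.n_tg),
            ("CE", comp.n_ce),
            ("FC", comp.n_fc),
            ("PL", comp.n_pl),
        ):
            out[lipid] = particle_flux * content
    return out


@dataclass(frozen=True)
class FluxDecomposition:
    """Per-state particle fluxes (particles/h) and lipid fluxes
    (molecules/h) of every process of one sub-model."""

    particle: dict[str, np.ndarray]
    lipid: dict[str, dict[str, np.ndarray]]

    def total_particle_flux(self, process: str) -> float:
        return float(self.particle[process].sum())

    def total_lipid_flux(self, process: str, lipid: str) -> float:
        return float(self.lipid[process][lipid].sum())

    def to_frame(self):
        """Long-format table of all per-state fluxes (one row per grid
        state and process), suitable for TSV export."""
        import pandas as pd

        rows = []
        for process, field in self.particle.items():
            i_max, j_max = field.shape
            ii, jj = np.meshgrid(
                np.arange(1, i_max + 1), np.arange(1, j_max + 1), indexing="ij"
            )
            rec = {
                "process": process,
                "i": ii.ravel(),
                "j": jj.ravel(),
                "particles_per_h": field.ravel(),
            }
            for lipid, lfield in self.lipid[process].items():
                rec[f"{lipid}_molecules_per_h"] = lfield.ravel()
            rows.append(pd.DataFrame(rec))
        return pd.concat(rows, ignore_index=True)


def _decompose(comp: CompositionField, rates: dict, state, production) -> FluxDecomposition:
    state = np.asarray(state, dtype=float)
    if np.any(state < 0):
        raise ValueError("negative state amounts")
    particle = {"prod": production.copy()}
    lipid = {"prod": _lipid_fluxes_for_process(comp, "prod", production)}
    for name, rate in rates.items():
        flux = rate * state
        particle[name] = flux
        lipid[name] = _lipid_fluxes_for_process(comp, name, flux)
    return FluxDecomposition(particle=particle, lipid=lipid)


def hdl_remodelling_fluxes(
    model: Model, state, params: ParameterSet, vldl_pl_release: float
) -> FluxDecomposition:
    """Flux decomposition of the HDL sub-model at the given state."""
    rates = hdl_rate_fields(model, params, vldl_pl_release)
    production = hdl_production_field(model, params)
    return _decompose(model.hdl, rates, state, production)


def vldl_remodelling_and_uptake_fluxes(
    model: Model, state, params: ParameterSet, production=None
) -> FluxDecomposition:
    """Flux decomposition of the VLDL sub-model at the given state."""
    rates = vldl_rate_fields(model, params)
    if production is None:
        production = np.zeros_like(model.vldl.n_tg)
    return _decompose(model.vldl, rates, state, production)


def vldl_surface_release(model: Model, state, params: ParameterSet):
    """Surface-remnant release from VLDL remodelling, in nmol/h.

    When a VLDL particle shrinks (lipolysis or selective uptake), its
    surface shrinks too; the shed PL and FC are the surface remnants that
    drive HDL lipid accumulation.  Returns ``(pl_release, fc_release)``.
    """
    comp = model.vldl
    rates = vldl_rate_fields(model, params)
    pl = comp.n_pl
    fc = comp.n_fc
    q_pl = 0.0
    q_fc = 0.0
    for name in ("lip_universal", "lip_vldl"):
        flux = rates[name] * state
        q_pl += float((flux[1:, :] * (pl[1:, :] - pl[:-1, :])).sum())
        q_fc += float((flux[1:, :] * (fc[1:, :] - fc[:-1, :])).sum())
    flux = rates["sel"] * state
    q_pl += float((flux[:, 1:] * (pl[:, 1:] - pl[:, :-1])).sum())
    q_fc += float((flux[:, 1:] * (fc[:, 1:] - fc[:, :-1])).sum())
    return q_pl * NMOL_PER_MOLECULE, q_fc * NMOL_PER_MOLECULE


# ---------------------------------------------------------------------------
# coupled simulation


@dataclass(frozen=True)
class CoupledSteadyState:
    """Steady states of both sub-models with the scalar coupling."""

    vldl_state: np.ndarray
    hdl_state: np.ndarray
    pl_release: float  # nmol PL/h shed by VLDL remodelling
    fc_release: float
    vldl_production: np.ndarray
    hdl_production: np.ndarray
    vldl_diag: SteadyStateDiagnostics
    hdl_diag: SteadyStateDiagnostics

    @property
    def converged(self) -> bool:
        return self.vldl_diag.converged and self.hdl_diag.converged


def couple_submodels(
    model: Model,
    params: ParameterSet,
    measured_vldl_tg_rate: float,
    rel_tol: float = 1e-8,
) -> CoupledSteadyState:
    """Consecutive simulation: VLDL steady state first, then HDL.

    The VLDL steady-state surface-remnant (PL) release is the scalar input
    that drives HDL TC and TG accumulation.
    """
    override = model.vldl_production_override
    vldl_prod = vldl_production_field(
        model,
        params["vldl_nascent_diameter"] if "vldl_nascent_diameter" in params else 0.0,
        measured_vldl_tg_rate,
        override=override,
    )
    vldl_rates = vldl_rate_fields(model, params)
    vldl_state, vldl_diag = steady_state(vldl_rates, vldl_prod, rel_tol=rel_tol)
    q_pl, q_fc = vldl_surface_release(model, vldl_state, params)
    hdl_rates = hdl_rate_fields(model, params, q_pl)
    hdl_prod = hdl_production_field(model, params)
    hdl_state, hdl_diag = steady_state(hdl_rates, hdl_prod, rel_tol=rel_tol)
    return CoupledSteadyState(
        vldl_state=vldl_state,
        hdl_state=hdl_state,
        pl_release=q_pl,
        fc_release=q_fc,
        vldl_production=vldl_prod,
        hdl_production=hdl_prod,
        vldl_diag=vldl_diag,
        hdl_diag=hdl_diag,
    )


def hdl_joint_rescaling(params: ParameterSet, factor: float) -> ParameterSet:
    """Scale the degenerate HDL rate group jointly by ``factor``.

    Scaling production and all five kinetic HDL rates together rescales
    every HDL flux by the same factor while leaving the steady-state field
    (hence every concentration profile) exactly invariant; this is the
    documented non-identifiability of the individual HDL rates.
    """
    if factor <= 0:
        raise ValueError("scaling factor must be positive")
    return params.scaled({name: factor for name in HDL_SCALING_GROUP})
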
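"""Parameter estimation and identifiability analysis.

The model is fitted to one observed FPLC table (per-fraction TG and TC in
nmol) plus a measured VLDL-TG production rate.  The cost is a weighted
sum of squared residuals over both lipid profiles with two penalty terms
appended: one for failure of a sub-model to reach steady state and one
for particle mass stranded in the unphysiological upper grid boundaries.
Because published fraction tables come without replicate errors, the
per-fraction weights are inverse variances from a literature-style
variability model ``sd_f = floor + cv * observed_f`` (config-overridable).

For optimization the parameters are mapped to a canonical unit box:
kinetic (rate-like) parameters logarithmically, geometric ones linearly,
so all coordinates are of comparable magnitude.  Optimization is bounded
trust-region nonlinear least squares on the residual vector, restarted
from many random initial positions; identifiability is assessed by
profile likelihood (re-optimizing all other parameters while one is
scanned) and by local resampling around an optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .fplc import FractionBoundaries, LipoproteinProfile, apportionment_matrix, combine_profiles, profile_from_state
from .kinetics import CoupledSteadyState, Model, ParameterSet, couple_submodels

__all__ = [
    "ObservedProfileData",
    "CostBreakdown",
    "FitResult",
    "Simulator",
    "transform",
    "untransform",
    "cost",
    "fit_multistart",
    "profile_likelihood",
    "ProfileLikelihoodCurve",
    "resample_around_optimum",
    "ResampleResult",
]

#: Pointwise 95 % likelihood-ratio threshold (chi-square, 1 dof).  An
#: approximation: the weighted SSR is treated as a chi-square deviance,
#: which the absent replicate error model cannot strictly justify.
PL_DELTA_95 = 3.841458820694124

_FAILURE_RESIDUAL = 1.0e6


@dataclass(frozen=True)
class ObservedProfileData:
    """One observed FPLC lipid table plus the measured VLDL-TG production."""

    fractions: np.ndarray
    tg: np.ndarray  # nmol per fraction
    tc: np.ndarray  # nmol per fraction
    vldl_tg_production: float  # nmol/h
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=int)
        tg = np.asarray(self.tg, dtype=float)
        tc = np.asarray(self.tc, dtype=float)
        if f.size != tg.size or f.size != tc.size:
            raise ValueError("fraction, TG and TC columns differ in length")
        if np.any(np.diff(f) != 1):
            raise ValueError("fraction numbers must be contiguous")
        if np.any(tg < 0) or np.any(tc < 0):
            raise ValueError("negative lipid amounts in observed data")
        if self.vldl_tg_production <= 0:
            raise ValueError("measured VLDL-TG production must be positive")
        object.__setattr__(self, "fractions", f)
        object.__setattr__(self, "tg", tg)
        object.__setattr__(self, "tc", tc)


@dataclass(frozen=True)
class CostBreakdown:
    """Additive decomposition of the fitting cost."""

    ssr: float
    steady_state_penalty: float
    boundary_penalty: float

    @property
    def total(self) -> float:
        return self.ssr + self.steady_state_penalty + self.boundary_penalty


@dataclass(frozen=True)
class FitResult:
    """One optimizer start's outcome."""

    params: ParameterSet
    breakdown: CostBreakdown
    converged: bool
    start_index: int
    seed: int
    n_evaluations: int = 0

    @property
    def cost(self) -> float:
        return self.breakdown.total


# ---------------------------------------------------------------------------
# transforms


def transform(pset: ParameterSet, names=None, clip: bool = False) -> np.ndarray:
    """Map parameter values into the canonical unit box.

    Log-transformed parameters land at ``(log10 v - log10 lo) /
    (log10 hi - log10 lo)``, linear ones at ``(v - lo)/(hi - lo)``.
    Out-of-bounds values raise unless ``clip`` is set (optimizer context).
    """
    names = pset.free_names if names is None else list(names)
    out = np.empty(len(names))
    for k, name in enumerate(names):
        p = pset.spec(name)
        lo, hi = p.bounds
        if p.transform == "log":
            t = (np.log10(p.value) - np.log10(lo)) / (np.log10(hi) - np.log10(lo))
        else:
            t = (p.value - lo) / (hi - lo)
        if not 0.0 <= t <= 1.0:
            if clip:
                t = min(max(t, 0.0), 1.0)
            else:
                raise ValueError(f"parameter {name!r}={p.value} outside bounds {p.bounds}")
        out[k] = t
    return out


def untransform(coords, template: ParameterSet, names=None) -> ParameterSet:
    """Inverse of :func:`transform` (bijective on the box)."""
    names = template.free_names if names is None else list(names)
    coords = np.asarray(coords, dtype=float)
    if coords.size != len(names):
        raise ValueError("coordinate vector length does not match parameter names")
    updates = {}
    for t, name in zip(coords, names):
        p = template.spec(name)
        lo, hi = p.bounds
        if p.transform == "log":
            updates[name] = 10 ** (np.log10(lo) + t * (np.log10(hi) - np.log10(lo)))
        else:
            updates[name] = lo + t * (hi - lo)
    return template.with_values(updates)


# ---------------------------------------------------------------------------
# simulation wrapper and cost


class Simulator:
    """Forward simulation onto a fixed fraction grid, with cached
    apportionment matrices (they depend only on geometry)."""

    def __init__(self, model: Model, boundaries: FractionBoundaries):
        self.model = model
        self.boundaries = boundaries
        self._w_hdl = apportionment_matrix(model.hdl.grid, boundaries)
        self._w_vldl = apportionment_matrix(model.vldl.grid, boundaries)

    def profiles(
        self, params: ParameterSet, measured_vldl_tg_rate: float, components=("TG", "TC")
    ) -> tuple[dict[str, LipoproteinProfile], CoupledSteadyState]:
        """Combined (VLDL + HDL) profiles of the requested components."""
        coupled = couple_submodels(self.model, params, measured_vldl_tg_rate)
        out = {}
        for component in components:
            hdl = profile_from_state(
                coupled.hdl_state, self.model.hdl, self.boundaries, component, self._w_hdl
            )
            vldl = profile_from_state(
                coupled.vldl_state, self.model.vldl, self.boundaries, component, self._w_vldl
            )
            out[component] = combine_profiles(hdl, vldl)
        return out, coupled

    def sub_profile(self, state, side: str, component: str) -> LipoproteinProfile:
        comp = self.model.hdl if side == "hdl" else self.model.vldl
        w = self._w_hdl if side == "hdl" else self._w_vldl
        return profile_from_state(state, comp, self.boundaries, component, w)


def _weights(observed: np.ndarray, floor: float, cv: float) -> np.ndarray:
    sd = floor + cv * observed
    return 1.0 / sd**2


def residuals(
    params: ParameterSet,
    data: ObservedProfileData,
    simulator: Simulator,
    opts: dict,
) -> tuple[np.ndarray, CostBreakdown | None]:
    """Weighted residual vector (profiles + penalty residuals).

    Simulation failures yield a large finite constant vector so bounded
    least squares can back away from pathological parameter draws.
    """
    n = data.fractions.size
    try:
        profiles, coupled = simulator.profiles(params, data.vldl_tg_production)
    except (ValueError, FloatingPointError, np.linalg.LinAlgError):
        return np.full(2 * n + 4, _FAILURE_RESIDUAL), None
    sim_tg = profiles["TG"].amounts
    sim_tc = profiles["TC"].amounts
    lo = data.fractions[0] - simulator.boundaries.fractions[0]
    sel = slice(lo, lo + n)
    w_tg = _weights(data.tg, opts["weight_floor"], opts["weight_cv"])
    w_tc = _weights(data.tc, opts["weight_floor"], opts["weight_cv"])
    r_tg = np.sqrt(w_tg) * (sim_tg[sel] - data.tg)
    r_tc = np.sqrt(w_tc) * (sim_tc[sel] - data.tc)
    lam_ss = opts["lambda_steady_state"]
    lam_b = opts["lambda_boundary"]
    r_pen = np.array(
        [
            np.sqrt(lam_ss) * coupled.vldl_diag.rel_residual,
            np.sqrt(lam_ss) * coupled.hdl_diag.rel_residual,
            np.sqrt(lam_b) * coupled.vldl_diag.boundary_mass_fraction,
            np.sqrt(lam_b) * coupled.hdl_diag.boundary_mass_fraction,
        ]
    )
    breakdown = CostBreakdown(
        ssr=float(r_tg @ r_tg + r_tc @ r_tc),
        steady_state_penalty=float(r_pen[0] ** 2 + r_pen[1] ** 2),
        boundary_penalty=float(r_pen[2] ** 2 + r_pen[3] ** 2),
    )
    return np.concatenate([r_tg, r_tc, r_pen]), breakdown


def cost(
    params: ParameterSet,
    data: ObservedProfileData,
    simulator: Simulator,
    opts: dict,
) -> CostBreakdown:
    """Weighted SSR plus steady-state and boundary penalties."""
    vec, breakdown = residuals(params, data, simulator, opts)
    if breakdown is None:
        big = float(vec @ vec)
        return CostBreakdown(ssr=big, steady_state_penalty=0.0, boundary_penalty=0.0)
    return breakdown


# ---------------------------------------------------------------------------
# multi-start optimization


def _optimize_from(
    x0: np.ndarray,
    template: ParameterSet,
    names: list[str],
    data: ObservedProfileData,
    simulator: Simulator,
    opts: dict,
    ls_opts: dict | None = None,
):
    counter = {"n": 0}

    def fun(x):
        counter["n"] += 1
        pset = untransform(x, template, names)
        vec, _ = residuals(pset, data, simulator, opts)
        return vec

    sol = least_squares(
        fun,
        np.clip(x0, 0.0, 1.0),
        bounds=(0.0, 1.0),
        method="trf",
        **(ls_opts or {}),
    )
    return sol, counter["n"]


def fit_multistart(
    data: ObservedProfileData,
    simulator: Simulator,
    base_params: ParameterSet,
    n_starts: int,
    seed: int,
    opts: dict,
    ls_opts: dict | None = None,
    include_base_start: bool = False,
    log=None,
) -> list[FitResult]:
    """Bounded least squares from ``n_starts`` random initial positions.

    Deterministic for a given seed; results are returned sorted by total
    cost.  ``include_base_start`` additionally starts from the template's
    own values (useful for warm restarts).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    names = base_params.free_names
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    starts = [rng.uniform(0.0, 1.0, len(names)) for _ in range(n_starts)]
    if include_base_start:
        starts.insert(0, transform(base_params, names))
    results = []
    failures = []
    for k, x0 in enumerate(starts):
        try:
            sol, nev = _optimize_from(x0, base_params, names, data, simulator, opts, ls_opts)
        except Exception as err:  # pragma: no cover - diagnostic path
            failures.append((k, repr(err)))
            continue
        pset = untransform(sol.x, base_params, names)
        breakdown = cost(pset, data, simulator, opts)
        result = FitResult(
            params=pset,
            breakdown=breakdown,
            converged=bool(sol.success),
            start_index=k,
            seed=seed,
            n_evaluations=nev,
        )
        results.append(result)
        if log is not None:
            log(
                f"start={k} seed={seed} cost={breakdown.total:.6g} "
                f"converged={sol.success}"
            )
    if not results:
        raise RuntimeError(f"all optimizer starts failed: {failures}")
    return sorted(results, key=lambda r: r.cost)


# ---------------------------------------------------------------------------
# identifiability


@dataclass(frozen=True)
class ProfileLikelihoodCurve:
    """Cost as a function of one fixed parameter, others re-optimized."""

    param_name: str
    values: np.ndarray
    costs: np.ndarray
    optimum_cost: float
    failures: list
    #: pointwise 95 % threshold on the cost
    threshold: float

    @property
    def in_interval(self) -> np.ndarray:
        return self.costs <= self.threshold

    @property
    def is_flat(self) -> bool:
        """Flat (non-identifiable) over the scanned range."""
        return bool(np.all(self.costs - self.optimum_cost < PL_DELTA_95))


def profile_likelihood(
    data: ObservedProfileData,
    simulator: Simulator,
    fit: FitResult,
    param_name: str,
    values,
    opts: dict,
    ls_opts: dict | None = None,
) -> ProfileLikelihoodCurve:
    """Scan one parameter, re-optimizing all other free parameters.

    Warm-starts each grid point from the previous solution, walking
    outward from the fitted optimum.
    """
    values = np.asarray(values, dtype=float)
    names = [n for n in fit.params.free_names if n != param_name]
    costs = np.full(values.size, np.nan)
    failures = []
    order = np.argsort(np.abs(values - fit.params[param_name]))
    warm = {}
    for idx in order:
        v = values[idx]
        template = fit.params.with_values({param_name: v}).with_fixed([param_name])
        x0 = warm.get("x", transform(fit.params, names, clip=True))
        try:
            sol, _ = _optimize_from(x0, template, names, data, simulator, opts, ls_opts)
            pset = untransform(sol.x, template, names)
            costs[idx] = cost(pset, data, simulator, opts).total
            warm["x"] = sol.x
        except Exception as err:
            failures.append((float(v), repr(err)))
    return ProfileLikelihoodCurve(
        param_name=param_name,
        values=values,
        costs=costs,
        optimum_cost=fit.cost,
        failures=failures,
        threshold=fit.cost + PL_DELTA_95,
    )


@dataclass(frozen=True)
class ResampleResult:
    costs: np.ndarray
    returned_fraction: float
    escaped_fraction: float
    best: FitResult


def resample_around_optimum(
    data: ObservedProfileData,
    simulator: Simulator,
    fit: FitResult,
    radius: float,
    n: int,
    seed: int,
    opts: dict,
    ls_opts: dict | None = None,
    rel_tol: float = 1e-3,
) -> ResampleResult:
    """Re-optimize from ``n`` perturbed starts around a fitted optimum.

    Starts are drawn uniformly in a cube of the given half-width (in
    transformed coordinates) centred on the optimum and clipped to the
    box.  Reports the fraction of starts returning to the optimum cost
    and the fraction escaping to a strictly better one.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    names = fit.params.free_names
    x_opt = transform(fit.params, names, clip=True)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    costs = np.empty(n)
    best = fit
    for k in range(n):
        x0 = np.clip(x_opt + rng.uniform(-radius, radius, x_opt.size), 0.0, 1.0)
        sol, nev = _optimize_from(x0, fit.params, names, data, simulator, opts, ls_opts)
        pset = untransform(sol.x, fit.params, names)
        breakdown = cost(pset, data, simulator, opts)
        costs[k] = breakdown.total
        if breakdown.total < best.cost:
            best = FitResult(
                params=pset,
                breakdown=breakdown,
                converged=bool(sol.success),
                start_index=k,
                seed=seed,
                n_evaluations=nev,
            )
    scale = max(abs(fit.cost), 1e-12)
    returned = float(np.mean(np.abs(costs - fit.cost) <= rel_tol * scale + 1e-12))
    escaped = float(np.mean(costs < fit.cost - rel_tol * scale))
    return ResampleResult(
        costs=costs, returned_fraction=returned, escaped_fraction=escaped, best=best
    )
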
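"""Size calibration and conversion of grid states to in silico FPLC profiles.

Size-exclusion (gel filtration) columns elute particles in order of
decreasing hydrodynamic diameter; the elution position is conventionally
expressed through the normalized partition coefficient Kav, and over the
separation range log-diameter is affine in Kav.  Fractions are collected
at a constant volume, so Kav is itself affine in fraction number.  The
two-parameter calibration used here is therefore

    log D_h = p1 + p2 * Kav(f),      Kav(f) affine in fraction number f,

fitted by least squares to anchor fractions with experimentally known
particle sizes (the VLDL, LDL and HDL class medians).

A fraction ``f`` owns the diameter interval between the calibration
evaluated at the half-integer edges ``f + 1/2`` (lower diameter) and
``f - 1/2`` (upper diameter); intervals are half-open ``[lower, upper)``
with the upper edge owned by the smaller-numbered fraction.  Grid states
are apportioned to fractions by Gauss-subdividing each unit index cell
``[i - 1/2, i + 1/2) x [j - 1/2, j + 1/2)`` and binning the sub-cell
diameters, which realizes the integration of the particle distribution
between the fraction boundaries without double counting.  Sizes beyond
the modelled fraction range land in explicit underflow/overflow bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .composition import CompositionField, GridSpec, ce_of_index, diameter_of_core, tg_of_index

__all__ = [
    "CalibrationFit",
    "FractionBoundaries",
    "LipoproteinProfile",
    "fit_calibration",
    "fraction_boundaries",
    "apportionment_matrix",
    "profile_from_state",
    "flux_profile",
    "combine_profiles",
]


@dataclass(frozen=True)
class CalibrationFit:
    """Fitted fraction-number <-> diameter mapping.

    ``log(D) = p1 + p2 * kav`` with ``kav = kav_slope * f + kav_offset``.
    The default Kav convention maps fraction 1 to 0 and fraction 40 to 1;
    only the composite affine map matters for the profile machinery.
    """

    p1: float
    p2: float
    kav_slope: float = 1.0 / 39.0
    kav_offset: float = -1.0 / 39.0
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if self.p2 * self.kav_slope >= 0:
            raise ValueError("calibration must be strictly decreasing in fraction")

    def kav_of_fraction(self, fraction):
        return self.kav_slope * np.asarray(fraction, dtype=float) + self.kav_offset

    def diameter_of_fraction(self, fraction):
        """Hydrodynamic diameter (nm) at (real-valued) fraction number."""
        return np.exp(self.p1 + self.p2 * self.kav_of_fraction(fraction))

    def fraction_of_diameter(self, diameter):
        """Inverse mapping; real-valued fraction number."""
        kav = (np.log(np.asarray(diameter, dtype=float)) - self.p1) / self.p2
        return (kav - self.kav_offset) / self.kav_slope


def fit_calibration(peak_fractions, known_diameters) -> CalibrationFit:
    """Least-squares fit of the calibration to (fraction, diameter) anchors."""
    f = np.asarray(peak_fractions, dtype=float)
    d = np.asarray(known_diameters, dtype=float)
    if f.size < 2 or f.size != d.size:
        raise ValueError("need at least two (fraction, diameter) anchor pairs")
    if np.unique(f).size != f.size:
        raise ValueError("degenerate anchors: duplicate fraction numbers")
    if np.any(d <= 0):
        raise ValueError("anchor diameters must be positive")
    kav_slope, kav_offset = 1.0 / 39.0, -1.0 / 39.0
    kav = kav_slope * f + kav_offset
    logd = np.log(d)

    def resid(p):
        return p[0] + p[1] * kav - logd

    # Linear model; least_squares from the normal-equation start converges
    # in one step and returns the residual vector we want to keep.
    a = np.vstack([np.ones_like(kav), kav]).T
    p0, *_ = np.linalg.lstsq(a, logd, rcond=None)
    sol = least_squares(resid, p0)
    p1, p2 = sol.x
    if p2 * kav_slope >= 0:
        raise ValueError("anchors imply non-decreasing diameter with fraction")
    return CalibrationFit(
        p1=float(p1), p2=float(p2), kav_slope=kav_slope, kav_offset=kav_offset,
        residuals=sol.fun,
    )


@dataclass(frozen=True)
class FractionBoundaries:
    """Diameter intervals of contiguous FPLC fractions.

    ``edges[k]`` is the upper diameter of ``fractions[k]`` (the diameter at
    fraction edge ``fractions[k] - 1/2``); ``edges[k+1]`` its lower
    diameter.  Intervals are half-open ``[lower, upper)``.
    """

    fractions: np.ndarray
    edges: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=int)
        e = np.asarray(self.edges, dtype=float)
        if e.size != f.size + 1:
            raise ValueError("need one more edge than fractions")
        if np.any(np.diff(f) != 1):
            raise ValueError("fractions must be contiguous")
        if np.any(np.diff(e) >= 0):
            raise ValueError("edge diameters must decrease with fraction number")
        object.__setattr__(self, "fractions", f)
        object.__setattr__(self, "edges", e)

    @property
    def n_fractions(self) -> int:
        return self.fractions.size

    def bin_index(self, diameter):
        """Bin of each diameter: 0..n-1 for fractions, -1 under, n over.

        'Under' means larger than the largest modelled diameter (elutes
        before the first fraction); 'over' means at or below the smallest.
        """
        d = np.asarray(diameter, dtype=float)
        # edges decreasing; searchsorted on reversed ascending edges.
        asc = self.edges[::-1]
        k = np.searchsorted(asc, d, side="right")  # count of edges <= d... careful below
        # position among decreasing edges: index such that edges[i+1] <= d < edges[i]
        idx = self.edges.size - 1 - k
        return idx  # -1 => d >= edges[0] (underflow); n => d < edges[-1] (overflow)


def fraction_boundaries(calibration: CalibrationFit, fraction_range=(1, 40)) -> FractionBoundaries:
    """Diameter boundaries at the half-integer fraction edges."""
    lo, hi = int(fraction_range[0]), int(fraction_range[1])
    if hi < lo:
        raise ValueError("empty fraction range")
    fracs = np.arange(lo, hi + 1)
    edge_fracs = np.arange(lo, hi + 2) - 0.5
    edges = calibration.diameter_of_fraction(edge_fracs)
    return FractionBoundaries(fractions=fracs, edges=edges)


@dataclass(frozen=True)
class LipoproteinProfile:
    """Per-fraction amounts of one component, plus under/overflow bins.

    ``amounts`` is in nmol for lipid components, particle count for
    'particles', and per-hour rates for flux profiles.
    """

    fractions: np.ndarray
    amounts: np.ndarray
    component: str
    units: str = "nmol"
    underflow: float = 0.0
    overflow: float = 0.0

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=int)
        a = np.asarray(self.amounts, dtype=float)
        if f.size != a.size:
            raise ValueError("fractions and amounts differ in length")
        object.__setattr__(self, "fractions", f)
        object.__setattr__(self, "amounts", a)

    @property
    def total(self) -> float:
        """Grand total including under/overflow bins."""
        return float(self.amounts.sum() + self.underflow + self.overflow)


def apportionment_matrix(
    grid: GridSpec, boundaries: FractionBoundaries, order: int = 8
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fraction-apportionment weights for every grid state.

    Returns ``(w, under, over)`` where ``w`` has shape
    ``(n_fractions, i_max*j_max)`` and column ``s`` gives the share of
    state ``s``'s content landing in each fraction; ``under``/``over``
    (length ``i_max*j_max``) collect the shares whose diameter falls
    outside the modelled range.  Shares per state sum to 1 exactly.

    Integration over the unit index cell is semi-analytic: the diameter
    is strictly increasing in the CE index, so for a fixed TG coordinate
    the positions where the cell crosses each fraction-edge diameter are
    obtained in closed form (inverting the sphere volume and the CE
    ladder); the remaining one-dimensional integral over the TG index is
    done by Gauss-Legendre quadrature of the given order.  Boundary
    half-cells that extend beyond the index ladder take the ladder-edge
    composition (constant continuation).

    The weights depend only on the grid geometry and the boundaries, not
    on the kinetic state, so they are computed once and reused for every
    component and flux profile.
    """
    from .composition import index_of_ce, index_of_tg

    gx, gw = np.polynomial.legendre.leggauss(order)

    nf = boundaries.n_fractions
    edges = boundaries.edges  # decreasing diameters, length nf + 1
    r_edge = edges / 2.0 - grid.surface_thickness
    v_edge = (4.0 / 3.0) * np.pi * np.maximum(r_edge, 0.0) ** 3

    i0 = np.arange(1, grid.i_max + 1, dtype=float)
    j0 = np.arange(1, grid.j_max + 1, dtype=float)
    # CE content at the (ladder-clamped) lower and upper cell edges
    ca = ce_of_index(np.clip(j0 - 0.5, 1.0, grid.j_max), grid)
    cb = ce_of_index(np.clip(j0 + 0.5, 1.0, grid.j_max), grid)
    a_cell = (j0 - 0.5)[None, :]
    ia_cell = (i0 - 0.5)[:, None]
    ib_cell = (i0 + 0.5)[:, None]

    def crossing_index(tg_cross):
        """TG index at which an edge's crossing curve reaches a CE level
        (+/-inf when the level is never reached on the ladder)."""
        out = np.full_like(tg_cross, -np.inf)
        out[tg_cross > grid.tg_max] = np.inf
        ok = (tg_cross >= grid.tg_min) & (tg_cross <= grid.tg_max)
        out[ok] = index_of_tg(tg_cross[ok], grid)
        return out

    def below_measure(v_e):
        """Per-state measure of the index cell with diameter < edge.

        For fixed TG index i the crossing CE position is closed-form, so
        the cell measure below the edge is (i1 - A) + integral of the
        crossing position over the i-range where it lies inside the
        cell.  That i-range is split analytically at the ladder edges
        (where the continuation is constant), leaving only smooth
        monotone segments for Gauss quadrature.
        """
        # i positions where the crossing leaves through the cell top/bottom
        tg_top = (v_e - cb * grid.v_ce) / grid.v_tg  # crossing at j = b
        tg_bot = (v_e - ca * grid.v_ce) / grid.v_tg  # crossing at j = a
        i_top = crossing_index(tg_top)[None, :]  # (1, j)
        i_bot = crossing_index(tg_bot)[None, :]
        i1 = np.clip(i_top, ia_cell, ib_cell)  # (i, j)
        i2 = np.clip(i_bot, ia_cell, ib_cell)
        measure = i1 - ia_cell
        # smooth segments of [i1, i2], split at the ladder edges
        cut1 = np.clip(np.float64(1.0), i1, i2)
        cut2 = np.clip(np.float64(grid.i_max), i1, i2)
        for lo, hi in ((i1, cut1), (cut1, cut2), (cut2, i2)):
            half = (hi - lo) / 2.0
            mid = (hi + lo) / 2.0
            for x, wq in zip(gx, gw):
                iq = np.clip(mid + x * half, 1.0, grid.i_max)
                ce_c = (v_e - tg_of_index(iq, grid) * grid.v_tg) / grid.v_ce
                ce_c = np.clip(ce_c, grid.ce_min, grid.ce_max)
                p = np.clip(index_of_ce(ce_c, grid), a_cell, a_cell + 1.0)
                measure = measure + wq * half * (p - a_cell)
        return measure.ravel()

    f = np.stack([below_measure(v) for v in v_edge])  # (nf+1, n_states)
    w = np.maximum(f[:-1] - f[1:], 0.0)
    under = np.maximum(1.0 - f[0], 0.0)
    over = np.maximum(f[-1], 0.0)
    return w, under, over


def profile_from_state(
    state,
    comp: CompositionField,
    boundaries: FractionBoundaries,
    component: str,
    weights=None,
) -> LipoproteinProfile:
    """In silico FPLC profile of one component from a particle field.

    ``state`` is the per-state particle amount (shape of the grid); the
    per-particle content of ``component`` converts particle shares into
    lipid amounts (reported in nmol).  ``weights`` may carry a
    precomputed :func:`apportionment_matrix` result.
    """
    from .composition import NMOL_PER_MOLECULE

    amounts = np.asarray(state, dtype=float).ravel()
    if amounts.size != comp.grid.n_states:
        raise ValueError("state size does not match grid")
    if weights is None:
        weights = apportionment_matrix(comp.grid, boundaries)
    w, under, over = weights
    content = comp.component(component).ravel()
    if component == "particles":
        scale = 1.0
        units = "particles"
    else:
        scale = NMOL_PER_MOLECULE
        units = "nmol"
    loads = amounts * content * scale
    return LipoproteinProfile(
        fractions=boundaries.fractions,
        amounts=w @ loads,
        component=component,
        units=units,
        underflow=float(under @ loads),
        overflow=float(over @ loads),
    )


def flux_profile(
    flux_field,
    comp: CompositionField,
    boundaries: FractionBoundaries,
    process: str,
    lipid: str,
    weights=None,
) -> LipoproteinProfile:
    """FPLC profile of a process's lipid flux (nmol/h per fraction).

    ``flux_field`` is the per-state lipid flux of one process in
    molecules/h (as produced by the kinetics flux decomposition).
    """
    from .composition import NMOL_PER_MOLECULE

    flux = np.asarray(flux_field, dtype=float).ravel()
    if flux.size != comp.grid.n_states:
        raise ValueError("flux field size does not match grid")
    if weights is None:
        weights = apportionment_matrix(comp.grid, boundaries)
    w, under, over = weights
    loads = flux * NMOL_PER_MOLECULE
    return LipoproteinProfile(
        fractions=boundaries.fractions,
        amounts=w @ loads,
        component=f"{process}:{lipid}",
        units="nmol/h",
        underflow=float(under @ loads),
        overflow=float(over @ loads),
    )


def combine_profiles(*profiles: LipoproteinProfile) -> LipoproteinProfile:
    """Element-wise sum of profiles on identical fractions (HDL + VLDL)."""
    if not profiles:
        raise ValueError("no profiles to combine")
    first = profiles[0]
    for p in profiles[1:]:
        if not np.array_equal(p.fractions, first.fractions):
            raise ValueError("profiles have mismatched fraction ranges")
        if p.units != first.units:
            raise ValueError("profiles have mismatched units")
    return LipoproteinProfile(
        fractions=first.fractions,
        amounts=np.sum([p.amounts for p in profiles], axis=0),
        component=first.component,
        units=first.units,
        underflow=float(sum(p.underflow for p in profiles)),
        overflow=float(sum(p.overflow for p in profiles)),
    )
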
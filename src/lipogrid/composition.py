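"""Lipoprotein composition grid: indices, molecule counts, size, surface lipids.

A circulating lipoprotein is reduced to its two core lipids: triglyceride
(TG) and cholesteryl ester (CE).  Each particle type (HDL or the Apo
B-containing VLDL/LDL continuum, called "VLDL" throughout) lives on a
discrete (i, j) grid: index ``i`` encodes TG content on an exponential
ladder (lipolysis removes TG roughly proportionally, so equal index steps
correspond to equal *relative* TG changes), and index ``j`` encodes CE
content on a ladder built so that, for particles with minimal TG, the
particle diameter is distributed linearly over FPLC fraction number.

From the core contents everything else follows: the core radius from the
summed molecular volumes assuming sphericity, the diameter by adding a
fixed 2 nm surface-layer thickness, and the free-cholesterol (FC) and
phospholipid (PL) surface counts from empirical surface-to-core ratios
interpolated over the logarithm of the core radius.

Indices are real-valued coordinates with model states at integer points;
sub-integer evaluation exists solely so that FPLC fraction boundaries can
be integrated through the interior of a grid cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "LipoType",
    "GridSpec",
    "ParticleComposition",
    "CompositionField",
    "SurfaceRatioTable",
    "growth_factor",
    "tg_of_index",
    "index_of_tg",
    "ce_of_index",
    "index_of_ce",
    "diameter_of_core",
    "core_radius_of_volume",
    "surface_counts",
    "build_grid",
]

#: Avogadro's number, 1/mol.
AVOGADRO = 6.02214076e23

#: nmol per molecule.
NMOL_PER_MOLECULE = 1e9 / AVOGADRO


class LipoType(str, Enum):
    HDL = "HDL"
    VLDL = "VLDL"


def growth_factor(tg_min: float, tg_max: float, i_max: int) -> float:
    """Growth factor ``g`` of the exponential TG ladder.

    ``g`` is fixed by requiring ``tg_min * g**(i_max - 1) == tg_max``.
    """
    if not (tg_max > tg_min > 0):
        raise ValueError(
            f"need tg_max > tg_min > 0, got tg_min={tg_min}, tg_max={tg_max}"
        )
    if i_max < 2:
        raise ValueError(f"need i_max >= 2, got {i_max}")
    return float(np.exp(np.log(tg_max / tg_min) / (i_max - 1)))


@dataclass(frozen=True)
class GridSpec:
    """Static geometry of one lipoprotein composition grid.

    Parameters
    ----------
    lipo_type
        HDL or VLDL (the latter spans VLDL and its LDL derivatives).
    i_max, j_max
        Number of TG and CE index levels.  VLDL uses 40x8, HDL 8x40, so
        each sub-model carries 320 state variables.
    tg_min, tg_max, ce_min, ce_max
        Core-lipid bounds in molecules per particle.
    surface_thickness
        Surface-layer thickness delta in nm (default 2 nm).
    v_tg, v_ce
        Molecular volumes in nm^3.
    """

    lipo_type: LipoType
    i_max: int
    j_max: int
    tg_min: float
    tg_max: float
    ce_min: float
    ce_max: float
    surface_thickness: float = 2.0
    v_tg: float = 1.61
    v_ce: float = 1.17
    growth_factor_g: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.tg_max > self.tg_min > 0):
            raise ValueError("TG bounds must satisfy 0 < tg_min < tg_max")
        if not (self.ce_max > self.ce_min > 0):
            raise ValueError("CE bounds must satisfy 0 < ce_min < ce_max")
        if self.i_max < 2 or self.j_max < 2:
            raise ValueError("grid must have at least 2 levels per index")
        g = growth_factor(self.tg_min, self.tg_max, self.i_max)
        object.__setattr__(self, "growth_factor_g", g)

    @property
    def n_states(self) -> int:
        return self.i_max * self.j_max

    # Diameters of the minimal-TG column endpoints; these define the CE
    # ladder (see ce_of_index).
    @property
    def d_min(self) -> float:
        return diameter_of_core(self.tg_min, self.ce_min, self)

    @property
    def d_max(self) -> float:
        return diameter_of_core(self.tg_min, self.ce_max, self)


@dataclass(frozen=True)
class ParticleComposition:
    """Full composition of one particle (real-valued molecule counts)."""

    n_tg: float
    n_ce: float
    n_fc: float
    n_pl: float
    diameter: float
    core_radius: float

    @property
    def n_tc(self) -> float:
        """Total cholesterol = free + esterified."""
        return self.n_fc + self.n_ce


def tg_of_index(i, grid: GridSpec):
    """TG molecules at (real-valued) TG index ``i``; exponential ladder."""
    i = np.asarray(i, dtype=float)
    if np.any(i < 1 - 1e-9) or np.any(i > grid.i_max + 1e-9):
        raise ValueError(f"TG index out of range [1, {grid.i_max}]")
    return grid.tg_min * grid.growth_factor_g ** (i - 1)


def index_of_tg(n_tg, grid: GridSpec):
    """Inverse of :func:`tg_of_index`."""
    n_tg = np.asarray(n_tg, dtype=float)
    return 1.0 + np.log(n_tg / grid.tg_min) / np.log(grid.growth_factor_g)


def core_radius_of_volume(volume):
    """Radius (nm) of a sphere with the given volume (nm^3)."""
    return (3.0 * np.asarray(volume, dtype=float) / (4.0 * np.pi)) ** (1.0 / 3.0)


def diameter_of_core(n_tg, n_ce, grid: GridSpec):
    """Particle diameter (nm) from core molecule counts.

    Assumes a spherical core of volume ``n_tg*v_tg + n_ce*v_ce`` wrapped in
    a surface layer of fixed thickness, so ``D = 2*(r_core + delta)``.  A
    particle with an empty core has diameter ``2*delta`` (4 nm for the
    default 2 nm layer).
    """
    n_tg = np.asarray(n_tg, dtype=float)
    n_ce = np.asarray(n_ce, dtype=float)
    if np.any(n_tg < 0) or np.any(n_ce < 0):
        raise ValueError("negative core molecule counts")
    volume = n_tg * grid.v_tg + n_ce * grid.v_ce
    r_core = core_radius_of_volume(volume)
    return 2.0 * (r_core + grid.surface_thickness)


def _core_volume_of_diameter(d, grid: GridSpec):
    r_core = np.asarray(d, dtype=float) / 2.0 - grid.surface_thickness
    return (4.0 / 3.0) * np.pi * np.maximum(r_core, 0.0) ** 3


def ce_of_index(j, grid: GridSpec, calibration=None):
    """CE molecules at (real-valued) CE index ``j``.

    The CE ladder is defined on the minimal-TG column of the grid: the
    diameter of the particle (tg_min, ce(j)) interpolates geometrically
    between the diameters at ce_min and ce_max.  Because the size
    calibration maps fraction number affinely onto log-diameter, this makes
    the minimal-TG particles' diameter linear in FPLC fraction number — the
    property the ladder is designed for.

    ``calibration`` is accepted for interface symmetry and, when given,
    used only to validate that the implied fraction numbers are affine in
    ``j`` (it does not change the returned values).
    """
    j = np.asarray(j, dtype=float)
    if np.any(j < 1 - 1e-9) or np.any(j > grid.j_max + 1e-9):
        raise ValueError(f"CE index out of range [1, {grid.j_max}]")
    t = (j - 1.0) / (grid.j_max - 1.0)
    d = grid.d_min * (grid.d_max / grid.d_min) ** t
    n_ce = (_core_volume_of_diameter(d, grid) - grid.tg_min * grid.v_tg) / grid.v_ce
    # Endpoints are exact by construction; guard rounding in between.
    n_ce = np.clip(n_ce, grid.ce_min, grid.ce_max)
    if calibration is not None:
        frac = calibration.fraction_of_diameter(np.atleast_1d(d))
        if frac.size > 2:
            slope = np.diff(frac) / np.diff(np.atleast_1d(j))
            if not np.allclose(slope, slope[0], rtol=1e-6):
                raise ValueError("calibration is not log-affine in fraction number")
    return n_ce


def index_of_ce(n_ce, grid: GridSpec):
    """Inverse of :func:`ce_of_index` (real-valued)."""
    n_ce = np.asarray(n_ce, dtype=float)
    d = diameter_of_core(np.full_like(n_ce, grid.tg_min), n_ce, grid)
    t = np.log(d / grid.d_min) / np.log(grid.d_max / grid.d_min)
    return 1.0 + t * (grid.j_max - 1.0)


@dataclass(frozen=True)
class SurfaceRatioTable:
    """Surface-to-core lipid ratios per core radius.

    ``fc_ratio`` is #FC/(#CE + #TG) and ``pl_ratio`` is #PL/(#CE + #TG),
    tabulated against core radius (nm) and linearly interpolated over the
    logarithm of the radius; outside the table the nearest row's ratios are
    used (constant extrapolation).
    """

    core_radius: np.ndarray
    fc_ratio: np.ndarray
    pl_ratio: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.core_radius, dtype=float)
        fc = np.asarray(self.fc_ratio, dtype=float)
        pl = np.asarray(self.pl_ratio, dtype=float)
        if r.size < 2:
            raise ValueError("surface ratio table needs at least 2 rows")
        if r.size != fc.size or r.size != pl.size:
            raise ValueError("surface ratio table columns differ in length")
        if np.any(np.diff(r) <= 0):
            raise ValueError("core radii must be strictly increasing")
        if np.any(r <= 0) or np.any(fc < 0) or np.any(pl < 0):
            raise ValueError("radii must be positive and ratios non-negative")
        object.__setattr__(self, "core_radius", r)
        object.__setattr__(self, "fc_ratio", fc)
        object.__setattr__(self, "pl_ratio", pl)

    def ratios_at(self, core_radius):
        """(fc_ratio, pl_ratio) at the given core radii."""
        logr = np.log(np.maximum(np.asarray(core_radius, dtype=float), 1e-300))
        logr_t = np.log(self.core_radius)
        # np.interp clamps outside the table: nearest-row extrapolation.
        fc = np.interp(logr, logr_t, self.fc_ratio)
        pl = np.interp(logr, logr_t, self.pl_ratio)
        return fc, pl


def surface_counts(n_tg, n_ce, table: SurfaceRatioTable, grid: GridSpec):
    """FC and PL molecule counts of a particle with the given core."""
    n_tg = np.asarray(n_tg, dtype=float)
    n_ce = np.asarray(n_ce, dtype=float)
    core = n_tg + n_ce
    if np.any(core <= 0):
        raise ValueError("surface_counts requires a non-empty core")
    r_core = core_radius_of_volume(n_tg * grid.v_tg + n_ce * grid.v_ce)
    fc_ratio, pl_ratio = table.ratios_at(r_core)
    return fc_ratio * core, pl_ratio * core


@dataclass(frozen=True)
class CompositionField:
    """Per-state composition arrays over a grid, shape (i_max, j_max)."""

    grid: GridSpec
    n_tg: np.ndarray
    n_ce: np.ndarray
    n_fc: np.ndarray
    n_pl: np.ndarray
    diameter: np.ndarray
    core_radius: np.ndarray

    @property
    def n_tc(self) -> np.ndarray:
        return self.n_fc + self.n_ce

    @property
    def surface_area(self) -> np.ndarray:
        """Particle surface area in nm^2."""
        return np.pi * self.diameter**2

    def component(self, name: str) -> np.ndarray:
        """Per-particle content of a named component ('particles' -> 1)."""
        table = {
            "TG": self.n_tg,
            "CE": self.n_ce,
            "FC": self.n_fc,
            "PL": self.n_pl,
            "TC": self.n_tc,
            "particles": np.ones_like(self.n_tg),
        }
        try:
            return table[name]
        except KeyError:
            raise KeyError(f"unknown component {name!r}; one of {sorted(table)}")

    def at(self, i: int, j: int) -> ParticleComposition:
        return ParticleComposition(
            n_tg=float(self.n_tg[i - 1, j - 1]),
            n_ce=float(self.n_ce[i - 1, j - 1]),
            n_fc=float(self.n_fc[i - 1, j - 1]),
            n_pl=float(self.n_pl[i - 1, j - 1]),
            diameter=float(self.diameter[i - 1, j - 1]),
            core_radius=float(self.core_radius[i - 1, j - 1]),
        )


def build_grid(grid: GridSpec, table: SurfaceRatioTable) -> CompositionField:
    """Precompute composition, size and surface lipids for all grid states."""
    i = np.arange(1, grid.i_max + 1, dtype=float)
    j = np.arange(1, grid.j_max + 1, dtype=float)
    n_tg = np.broadcast_to(tg_of_index(i, grid)[:, None], (grid.i_max, grid.j_max))
    n_ce = np.broadcast_to(ce_of_index(j, grid)[None, :], (grid.i_max, grid.j_max))
    n_tg = np.ascontiguousarray(n_tg)
    n_ce = np.ascontiguousarray(n_ce)
    diameter = diameter_of_core(n_tg, n_ce, grid)
    core_radius = diameter / 2.0 - grid.surface_thickness
    n_fc, n_pl = surface_counts(n_tg, n_ce, table, grid)
    return CompositionField(
        grid=grid,
        n_tg=n_tg,
        n_ce=n_ce,
        n_fc=n_fc,
        n_pl=n_pl,
        diameter=diameter,
        core_radius=core_radius,
    )
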
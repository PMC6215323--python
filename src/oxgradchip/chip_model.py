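"""Finite-volume oxygen diffusion model of the gradient-generating chip.

The chip is a PDMS slab bonded to glass, with a cell-culture chamber and an
oxygen-leaching channel moulded into the bottom 150 um, and a PMMA diffusion
barrier on top.  Perfusing the channel with an oxygen scavenger pins it at
0 % O2 while ambient air (21 % O2) supplies oxygen through the outer PDMS
surfaces, producing a quasi-linear oxygen gradient across the 10 mm chamber.

This module solves the diffusion equation div(D grad C) = dC/dt on a 2D
vertical cross-section perpendicular to the channel axis (x = gradient
direction, z = height).  The cross-section is uniform along the third axis
away from the in/outlets, so the 2D model captures the gradient physics;
deviations near the chip edges are expected.

Units at the interface: lengths in mm, time in hours, concentration in % O2.
Diffusivities are given in m^2/s (the conventional literature unit) and
converted internally to mm^2/h.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import NumericalError, ValidationError

#: conversion factor from m^2/s to mm^2/h
M2_PER_S_TO_MM2_PER_H = 1e6 * 3600.0


class Region(IntEnum):
    """Material label of a grid cell."""

    PDMS = 0
    PMMA = 1
    MEDIUM = 2
    SINK = 3


@dataclass(frozen=True)
class ChipGeometry:
    """Cross-section dimensions of the chip, all in mm.

    Along x (the gradient axis) the chip is: a side wall of solid PDMS
    (``chamber_offset``), the cell chamber, a thin separating wall, the
    leaching channel, and solid PDMS out to the far edge.  Chamber and
    channel are moulded into the bottom ``feature_height`` of the PDMS;
    the PMMA barrier of thickness ``barrier_thickness`` sits on top of the
    ``pdms_height`` slab.
    """

    chip_width: float = 24.6
    pdms_height: float = 2.0
    feature_height: float = 0.15
    barrier_thickness: float = 0.5
    chamber_width: float = 10.0
    channel_width: float = 0.5
    wall_width: float = 0.1
    chamber_offset: float = 4.0

    def __post_init__(self) -> None:
        lengths = {
            "chip_width": self.chip_width,
            "pdms_height": self.pdms_height,
            "feature_height": self.feature_height,
            "barrier_thickness": self.barrier_thickness,
            "chamber_width": self.chamber_width,
            "channel_width": self.channel_width,
            "wall_width": self.wall_width,
            "chamber_offset": self.chamber_offset,
        }
        for name, value in lengths.items():
            if not value > 0:
                raise ValidationError(f"{name} must be positive, got {value!r}")
        occupied = (
            self.chamber_offset
            + self.chamber_width
            + self.wall_width
            + self.channel_width
        )
        if occupied > self.chip_width + 1e-12:
            raise ValidationError(
                "chamber_offset + chamber_width + wall_width + channel_width "
                f"= {occupied} mm exceeds chip_width = {self.chip_width} mm"
            )
        if not self.feature_height < self.pdms_height:
            raise ValidationError(
                "feature_height must be smaller than pdms_height"
            )

    @property
    def total_height(self) -> float:
        """PDMS slab plus PMMA barrier, mm."""
        return self.pdms_height + self.barrier_thickness

    @property
    def channel_offset(self) -> float:
        """x of the channel's near edge (chamber side), mm."""
        return self.chamber_offset + self.chamber_width + self.wall_width


@dataclass(frozen=True)
class MaterialProps:
    """Oxygen diffusivities (m^2/s) and boundary concentrations (% O2)."""

    D_pdms: float = 3e-9
    D_pmma: float = 3.7e-12
    D_medium: float = 3.2e-9
    c_ambient: float = 21.0
    c_sink: float = 0.0

    def __post_init__(self) -> None:
        for name in ("D_pdms", "D_pmma", "D_medium"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 <= self.c_sink < self.c_ambient:
            raise ValidationError("require 0 <= c_sink < c_ambient")

    def diffusivity_mm2_h(self, region: Region) -> float:
        """Diffusivity of a region in mm^2/h (sink cells carry medium)."""
        d = {
            Region.PDMS: self.D_pdms,
            Region.PMMA: self.D_pmma,
            Region.MEDIUM: self.D_medium,
            Region.SINK: self.D_medium,
        }[Region(region)]
        return d * M2_PER_S_TO_MM2_PER_H


@dataclass(frozen=True)
class EdgeCondition:
    """Boundary condition on one outer edge of the domain."""

    kind: str  # "dirichlet" | "no_flux"
    value: float = 0.0


def dirichlet(value: float) -> EdgeCondition:
    return EdgeCondition("dirichlet", float(value))


NO_FLUX = EdgeCondition("no_flux")


@dataclass
class DomainGrid:
    """Cell-centred rectangular grid over the chip cross-section.

    Arrays are indexed ``[z, x]`` with row 0 at the glass bottom.  Cells
    labelled SINK are held at ``sink_concentration`` (Dirichlet); the four
    outer edges carry the conditions in ``edge_bc`` (keys: left, right,
    top, bottom), applied at the cell faces.
    """

    spacing: float
    region: np.ndarray
    diffusivity: np.ndarray  # mm^2/h per cell
    edge_bc: Mapping[str, EdgeCondition]
    sink_concentration: float = 0.0
    geometry: ChipGeometry | None = None
    materials: MaterialProps | None = None

    def __post_init__(self) -> None:
        self.region = np.asarray(self.region, dtype=np.int8)
        self.diffusivity = np.asarray(self.diffusivity, dtype=float)
        if self.region.shape != self.diffusivity.shape:
            raise ValidationError("region and diffusivity shapes differ")
        for key in ("left", "right", "top", "bottom"):
            if key not in self.edge_bc:
                raise ValidationError(f"missing edge condition for {key!r}")

    @property
    def nz(self) -> int:
        return self.region.shape[0]

    @property
    def nx(self) -> int:
        return self.region.shape[1]

    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.spacing

    def z_centers(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.spacing

    def chamber_floor_columns(self) -> np.ndarray:
        """Grid columns whose bottom cell is culture medium (the chamber floor)."""
        return np.flatnonzero(self.region[0, :] == Region.MEDIUM)

    def dirichlet_extremes(self) -> tuple[float, float]:
        """(min, max) of all imposed concentrations (edges and sink)."""
        values = [self.sink_concentration] if np.any(self.region == Region.SINK) else []
        for bc in self.edge_bc.values():
            if bc.kind == "dirichlet":
                values.append(bc.value)
        if not values:
            raise ValidationError("domain has no imposed concentration at all")
        return min(values), max(values)


@dataclass
class ConcentrationField:
    """Oxygen concentration (% O2) on a :class:`DomainGrid`.

    ``time_h`` is None for a steady-state field.
    """

    grid: DomainGrid
    values: np.ndarray
    time_h: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.region.shape:
            raise ValidationError("field shape does not match grid")


def _index(coord: float, spacing: float) -> int:
    return int(round(coord / spacing))


def build_domain(
    geometry: ChipGeometry = ChipGeometry(),
    materials: MaterialProps = MaterialProps(),
    spacing: float = 0.05,
) -> DomainGrid:
    """Discretise the chip cross-section onto a regular grid.

    The thin separating wall between chamber and channel must be resolved by
    at least two cells, so ``spacing`` may not exceed half the wall width.

    Parameters
    ----------
    geometry, materials
        Chip dimensions and material properties.
    spacing
        Grid cell size in mm (default 0.05 mm = 50 um).
    """
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    if spacing > geometry.wall_width / 2 + 1e-12:
        raise ValidationError(
            f"spacing {spacing} mm cannot resolve the {geometry.wall_width} mm "
            "separating wall between chamber and leaching channel "
            "(need at least 2 cells across it)"
        )

    nx = _index(geometry.chip_width, spacing)
    nz = _index(geometry.total_height, spacing)
    region = np.full((nz, nx), Region.PDMS, dtype=np.int8)

    # PMMA barrier on top of the PDMS slab
    region[_index(geometry.pdms_height, spacing):, :] = Region.PMMA

    # chamber and channel moulded into the bottom feature layer
    k_feat = max(_index(geometry.feature_height, spacing), 1)
    i0 = _index(geometry.chamber_offset, spacing)
    i1 = _index(geometry.chamber_offset + geometry.chamber_width, spacing)
    region[:k_feat, i0:i1] = Region.MEDIUM
    j0 = _index(geometry.channel_offset, spacing)
    j1 = _index(geometry.channel_offset + geometry.channel_width, spacing)
    region[:k_feat, j0:j1] = Region.SINK

    diffusivity = np.empty((nz, nx), dtype=float)
    for reg in Region:
        diffusivity[region == reg] = materials.diffusivity_mm2_h(reg)

    edge_bc = {
        "left": dirichlet(materials.c_ambient),
        "right": dirichlet(materials.c_ambient),
        "top": dirichlet(materials.c_ambient),
        "bottom": NO_FLUX,  # glass: zero oxygen flux
    }
    return DomainGrid(
        spacing=spacing,
        region=region,
        diffusivity=diffusivity,
        edge_bc=edge_bc,
        sink_concentration=materials.c_sink,
        geometry=geometry,
        materials=materials,
    )


def _harmonic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Flux-conserving interface diffusivity between adjacent cells."""
    return 2.0 * a * b / (a + b)


def _assemble(domain: DomainGrid) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """Assemble the discrete diffusion operator over non-sink cells.

    Returns ``(A, s, free)`` such that dC/dt = A C + s for the flattened
    free-cell vector C (units %O2 per hour).  Sink cells and Dirichlet edges
    enter through ``s``.
    """
    h2 = domain.spacing**2
    region = domain.region
    D = domain.diffusivity
    nz, nx = region.shape

    free = region != Region.SINK
    ids = -np.ones((nz, nx), dtype=np.int64)
    n_free = int(free.sum())
    ids[free] = np.arange(n_free)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag = np.zeros(n_free)
    s = np.zeros(n_free)

    def couple_pairs(za, xa, zb, xb, g):
        """Conductance g between cells (za,xa) and (zb,xb); adds both directions.

        A free cell facing a sink cell sees the sink concentration imposed at
        the shared face (the scavenged channel liquid is at the sink value up
        to its boundary), so that coupling uses the half-cell conductance of
        the free cell's own material rather than the pairwise harmonic mean.
        """
        ia = ids[za, xa]
        ib = ids[zb, xb]
        for i_from, i_to, z_f, x_f in ((ia, ib, za, xa), (ib, ia, zb, xb)):
            fr = i_from >= 0
            to_free = fr & (i_to >= 0)
            to_sink = fr & (i_to < 0)
            rows.append(i_from[to_free])
            cols.append(i_to[to_free])
            vals.append(g[to_free])
            np.add.at(diag, i_from[to_free], -g[to_free])
            g_face = 2.0 * D[z_f[to_sink], x_f[to_sink]] / h2
            np.add.at(diag, i_from[to_sink], -g_face)
            np.add.at(s, i_from[to_sink], g_face * domain.sink_concentration)

    gx = _harmonic(D[:, :-1], D[:, 1:]) / h2
    zz, xx = np.nonzero(np.ones((nz, nx - 1), dtype=bool))
    couple_pairs(zz, xx, zz, xx + 1, gx[zz, xx])
    gz = _harmonic(D[:-1, :], D[1:, :]) / h2
    zz, xx = np.nonzero(np.ones((nz - 1, nx), dtype=bool))
    couple_pairs(zz, xx, zz + 1, xx, gz[zz, xx])

    # outer edges: Dirichlet applies at the cell face, half a cell away
    def edge(cells_z, cells_x, bc: EdgeCondition):
        if bc.kind != "dirichlet":
            return  # no_flux contributes nothing
        ii = ids[cells_z, cells_x]
        g = 2.0 * D[cells_z, cells_x] / h2
        fr = ii >= 0
        np.add.at(diag, ii[fr], -g[fr])
        np.add.at(s, ii[fr], g[fr] * bc.value)

    edge(np.arange(nz), np.zeros(nz, int), domain.edge_bc["left"])
    edge(np.arange(nz), np.full(nz, nx - 1), domain.edge_bc["right"])
    edge(np.full(nx, nz - 1), np.arange(nx), domain.edge_bc["top"])
    edge(np.zeros(nx, int), np.arange(nx), domain.edge_bc["bottom"])

    rows.append(np.arange(n_free))
    cols.append(np.arange(n_free))
    vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_free, n_free),
    )
    return A, s, free


def _fill(domain: DomainGrid, free_values: np.ndarray, free: np.ndarray) -> np.ndarray:
    out = np.full(domain.region.shape, domain.sink_concentration, dtype=float)
    out[free] = free_values
    return out


def solve_steady_state(domain: DomainGrid, tol: float = 1e-8) -> ConcentrationField:
    """Solve div(D grad C) = 0 on the domain.

    A sparse direct solve of the finite-volume system; the residual is
    verified against ``tol`` (relative to the largest imposed concentration)
    afterwards.
    """
    if not tol > 0:
        raise ValidationError("tol must be positive")
    A, s, free = _assemble(domain)
    c = spla.spsolve(A.tocsc(), -s)
    scale = max(abs(v) for v in domain.dirichlet_extremes()) or 1.0
    diag_scale = float(np.abs(A.diagonal()).max())
    residual = float(np.abs(A @ c + s).max()) / (scale * diag_scale)
    if not np.isfinite(c).all() or residual > tol:
        raise NumericalError(
            f"steady-state solve did not reach tol={tol:g}; final residual {residual:.3e}"
        )
    return ConcentrationField(domain, _fill(domain, c, free), time_h=None)


def solve_transient(
    domain: DomainGrid,
    dt_s: float = 60.0,
    t_end_h: float = 24.0,
    c_initial: float | np.ndarray | ConcentrationField = 21.0,
    output_times_h: Sequence[float] | None = None,
    output_interval_h: float = 1.0,
) -> list[ConcentrationField]:
    """Time-dependent solve with Crank-Nicolson stepping.

    Crank-Nicolson is unconditionally stable, so ``dt_s`` is chosen for
    accuracy, not stability.  Output fields are recorded at the step times
    nearest the requested ``output_times_h`` (default: every
    ``output_interval_h`` up to ``t_end_h``).
    """
    if dt_s <= 0:
        raise ValidationError("dt_s must be positive")
    if t_end_h <= 0:
        raise ValidationError("t_end_h must be positive")
    dt_h = dt_s / 3600.0
    A, s, free = _assemble(domain)
    n_free = A.shape[0]

    if isinstance(c_initial, ConcentrationField):
        c = c_initial.values[free].astype(float)
    elif np.isscalar(c_initial):
        c = np.full(n_free, float(c_initial))
    else:
        arr = np.asarray(c_initial, dtype=float)
        if arr.shape != domain.region.shape:
            raise ValidationError("c_initial array shape does not match grid")
        c = arr[free].copy()

    if output_times_h is None:
        output_times_h = list(np.arange(output_interval_h, t_end_h + 1e-9, output_interval_h))
        if not output_times_h or output_times_h[-1] < t_end_h - 1e-9:
            output_times_h.append(t_end_h)
    output_times_h = sorted(float(t) for t in output_times_h)
    if output_times_h and output_times_h[0] <= 0:
        raise ValidationError("output times must be positive")

    n_steps = int(np.ceil(t_end_h / dt_h - 1e-9))
    out_steps = {max(1, min(n_steps, int(round(t / dt_h)))): t for t in output_times_h}

    eye = sp.identity(n_free, format="csr")
    lhs = spla.splu((eye - (dt_h / 2.0) * A).tocsc())
    rhs_op = (eye + (dt_h / 2.0) * A).tocsr()
    # Rannacher startup: two backward-Euler steps damp the stiff modes that
    # Crank-Nicolson barely attenuates when the initial condition is
    # discontinuous at Dirichlet boundaries (uniform start vs 0% sink).
    n_startup = 2
    lhs_be = spla.splu((eye - dt_h * A).tocsc())

    fields: list[ConcentrationField] = []
    for step in range(1, n_steps + 1):
        if step <= n_startup:
            c = lhs_be.solve(c + dt_h * s)
        else:
            c = lhs.solve(rhs_op @ c + dt_h * s)
        if step in out_steps:
            fields.append(
                ConcentrationField(domain, _fill(domain, c, free), time_h=out_steps[step])
            )
    if not np.isfinite(c).all():
        raise NumericalError("transient solve produced non-finite values")
    return fields


def profile_along_gradient(
    field: ConcentrationField, geometry: ChipGeometry | None = None
) -> pd.DataFrame:
    """Chamber-floor oxygen profile along the gradient axis.

    One value per grid column inside the chamber, sampled at the floor
    layer (the cell row on the glass).  Positions are mm from the chamber
    edge nearest the leaching channel, so the profile runs from hypoxic
    (position 0) to ambient-fed (position = chamber width).

    Returns a DataFrame with columns ``position_mm`` and ``o2_percent``,
    sorted by position.
    """
    grid = field.grid
    geometry = geometry or grid.geometry
    if geometry is None:
        raise ValidationError("no chip geometry associated with this field")
    cols = grid.chamber_floor_columns()
    if cols.size == 0:
        raise ValidationError("domain contains no chamber floor cells")
    x_near_channel = geometry.chamber_offset + geometry.chamber_width
    positions = x_near_channel - grid.x_centers()[cols]
    values = field.values[0, cols]
    order = np.argsort(positions)
    return pd.DataFrame(
        {"position_mm": positions[order], "o2_percent": values[order]}
    ).reset_index(drop=True)


def time_to_equilibrium(
    series: Sequence[ConcentrationField],
    steady: ConcentrationField,
    tol_abs: float = 1.0,
) -> float | None:
    """First output time at which the chamber floor is within ``tol_abs``
    %O2 (max norm) of the steady state; None if never reached."""
    if len(series) == 0:
        raise ValidationError("empty transient series")
    if not tol_abs > 0:
        raise ValidationError("tol_abs must be positive")
    mask = steady.grid.region[0, :] == Region.MEDIUM
    if not mask.any():
        raise ValidationError("steady field has no chamber floor cells")
    times = [f.time_h for f in series]
    if any(t is None for t in times) or list(times) != sorted(times):
        raise ValidationError("series must be time-ordered transient fields")
    target = steady.values[0, mask]
    for f in series:
        if np.abs(f.values[0, mask] - target).max() < tol_abs:
            return float(f.time_h)
    return None


def max_distance_to(
    series: Sequence[ConcentrationField], steady: ConcentrationField
) -> np.ndarray:
    """Max-norm distance of each field in the series to the steady field."""
    return np.array(
        [float(np.abs(f.values - steady.values).max()) for f in series]
    )
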
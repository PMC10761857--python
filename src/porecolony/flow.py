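"""2D steady incompressible Stokes flow on a binary pore mask.

Creeping flow through the pore space is driven by a pressure difference
between ghost reservoirs attached to the left (inlet) and right (outlet)
domain edges; the top and bottom edges are sealed.  The discretization is a
staggered (MAC) finite-difference grid: horizontal velocities u on vertical
cell faces, vertical velocities v on horizontal faces, pressure at pore-cell
centres.  Momentum and continuity are assembled into one sparse saddle-point
system and solved directly, which makes the discrete divergence of every
accepted solution zero to solver precision.  No-slip walls are represented
by mirror ghost values (the wall lies half a cell inside the solid), which
recovers the Poiseuille profile in straight channels to second order.

Stokes flow is linear, so the solution is computed once with unit driving
pressure and rescaled to the requested flow rate Q (converted to a 2D flux
through the chip thickness h) or to a requested mean pore velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from .geometry import PoreMask

__all__ = ["FlowConfig", "VelocityField", "solve_stokes", "shear_rate"]

_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class FlowConfig:
    """Imposed-flow parameters: flow rate Q (µL/min) and chip thickness h (mm)."""

    Q: float = 0.1
    h: float = 0.05
    viscosity: float = 1.0  # scales out of the normalized field

    def __post_init__(self) -> None:
        if self.Q <= 0:
            raise ValueError("flow rate Q must be positive")
        if self.h <= 0:
            raise ValueError("chip thickness h must be positive")


@dataclass
class VelocityField:
    """Divergence-free staggered velocity solution on a pore mask.

    ``u`` has shape (H, W+1) (x-velocity on vertical faces, inlet face at
    column 0, outlet face at column W); ``v`` has shape (H+1, W).  Units are
    µm/s; both are zero on faces touching solid.  ``divergence`` is the
    per-cell residual of the discrete continuity equation (1/s).
    """

    u: np.ndarray
    v: np.ndarray
    pressure: np.ndarray
    pore: np.ndarray
    pixel_size: float
    u_m: float  # mean pore velocity modulus, µm/s

    @property
    def u_cell(self) -> np.ndarray:
        return 0.5 * (self.u[:, :-1] + self.u[:, 1:])

    @property
    def v_cell(self) -> np.ndarray:
        return 0.5 * (self.v[:-1, :] + self.v[1:, :])

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u_cell, self.v_cell)

    @property
    def divergence(self) -> np.ndarray:
        h = self.pixel_size
        div = (self.u[:, 1:] - self.u[:, :-1] + self.v[1:, :] - self.v[:-1, :]) / h
        div[~self.pore] = 0.0
        return div

    @property
    def divergence_max(self) -> float:
        return float(np.abs(self.divergence).max())

    def rescaled(self, factor: float) -> "VelocityField":
        return VelocityField(
            u=self.u * factor,
            v=self.v * factor,
            pressure=self.pressure * factor,
            pore=self.pore,
            pixel_size=self.pixel_size,
            u_m=self.u_m * factor,
        )


class NoFlowError(RuntimeError):
    """Raised when the mask has no percolating inlet-to-outlet pore path."""


def _percolating_pore(grid: np.ndarray) -> np.ndarray:
    comp, _ = ndimage.label(grid, structure=_STRUCT4)
    left = set(np.unique(comp[:, 0])) - {0}
    right = set(np.unique(comp[:, -1])) - {0}
    keep = left & right
    if not keep:
        raise NoFlowError("no pore path connects the inlet edge to the outlet edge")
    return np.isin(comp, sorted(keep))


def solve_stokes(
    mask: PoreMask,
    config: FlowConfig | None = None,
    target_u_m: float | None = None,
) -> VelocityField:
    """Solve creeping flow through the mask and scale to physical units.

    The solution is rescaled so that either the mean pore velocity modulus
    equals ``target_u_m`` (µm/s), or — when ``target_u_m`` is None — the net
    inlet flux matches the 2D flux Q/h of ``config``.  Pore regions not
    connected to both open edges carry exactly zero velocity.
    """
    if config is None:
        config = FlowConfig()
    grid = mask.grid
    flow_pore = _percolating_pore(grid)
    H, W = grid.shape

    # pad one ghost pore column on each side: pressure reservoirs
    P = np.zeros((H, W + 2), dtype=bool)
    P[:, 1:-1] = flow_pore
    P[:, 0] = flow_pore[:, 0]
    P[:, -1] = flow_pore[:, -1]
    Hp, Wp = P.shape

    # face activity: a face is an unknown iff both adjacent cells are pore
    u_active = np.zeros((Hp, Wp + 1), dtype=bool)
    u_active[:, 1:-1] = P[:, :-1] & P[:, 1:]
    v_active = np.zeros((Hp + 1, Wp), dtype=bool)
    v_active[1:-1, :] = P[:-1, :] & P[1:, :]

    u_id = np.full(u_active.shape, -1, dtype=np.int64)
    u_id[u_active] = np.arange(u_active.sum())
    nu = int(u_active.sum())
    v_id = np.full(v_active.shape, -1, dtype=np.int64)
    v_id[v_active] = np.arange(v_active.sum())
    nv = int(v_active.sum())

    # pressure unknowns: interior pore cells; ghost columns have fixed pressure
    interior = P.copy()
    interior[:, 0] = False
    interior[:, -1] = False
    p_id = np.full(P.shape, -1, dtype=np.int64)
    p_id[interior] = np.arange(interior.sum())
    npr = int(interior.sum())
    p_in, p_out = 1.0, 0.0

    rows, cols, vals, rhs_entries = [], [], [], []
    rhs = np.zeros(nu + nv + npr)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    # --- u momentum ---------------------------------------------------
    uy, ux = np.nonzero(u_active)
    for k in range(nu):
        i, j = uy[k], ux[k]
        row = k
        diag = -4.0
        # axial neighbours (j-1, j+1): zero-gradient past the ghost reservoirs
        for jj in (j - 1, j + 1):
            if u_id[i, jj] >= 0 if 0 <= jj <= Wp else False:
                add(row, u_id[i, jj], 1.0)
            elif jj <= 0 or jj >= Wp:
                diag += 1.0  # fully developed beyond the reservoir
            # else: face against solid, value 0
        # tangential neighbours (i-1, i+1): mirror ghost across no-slip walls
        for ii in (i - 1, i + 1):
            if ii < 0 or ii >= Hp or not u_active[ii, j]:
                diag += -1.0  # ghost value -u across the wall
            else:
                add(row, u_id[ii, j], 1.0)
        add(row, row, diag)
        # pressure gradient -(p_E - p_W)
        for cell_j, sign in ((j, -1.0), (j - 1, 1.0)):
            if p_id[i, cell_j] >= 0:
                add(row, nu + nv + p_id[i, cell_j], sign)
            else:
                pval = p_in if cell_j == 0 else p_out
                rhs[row] -= sign * pval

    # --- v momentum ---------------------------------------------------
    vy, vx = np.nonzero(v_active)
    for k in range(nv):
        i, j = vy[k], vx[k]
        row = nu + k
        diag = -4.0
        for ii in (i - 1, i + 1):
            if 0 <= ii <= Hp and v_id[ii, j] >= 0:
                add(row, nu + v_id[ii, j], 1.0)
            # axial neighbour against solid or domain edge: value 0
        for jj in (j - 1, j + 1):
            if jj < 0 or jj >= Wp or not v_active[i, jj]:
                diag += -1.0
            else:
                add(row, nu + v_id[i, jj], 1.0)
        add(row, row, diag)
        for cell_i, sign in ((i, -1.0), (i - 1, 1.0)):
            if p_id[cell_i, j] >= 0:
                add(row, nu + nv + p_id[cell_i, j], sign)
            else:
                # ghost columns are reservoirs; v faces never border them
                # (they are excluded from interior), pressure there is fixed
                pval = p_in if j == 0 else p_out
                rhs[row] -= sign * pval

    # --- continuity on interior pore cells -----------------------------
    cy, cx = np.nonzero(interior)
    for k in range(npr):
        i, j = cy[k], cx[k]
        row = nu + nv + k
        for fid, sign in (
            (u_id[i, j + 1], 1.0),
            (u_id[i, j], -1.0),
        ):
            if fid >= 0:
                add(row, fid, sign)
        for fid, sign in (
            (v_id[i + 1, j], 1.0),
            (v_id[i, j], -1.0),
        ):
            if fid >= 0:
                add(row, nu + fid, sign)

    n = nu + nv + npr
    A = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    try:
        sol = spsolve(A, rhs)
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"Stokes system singular or ill-conditioned ({nu} u, {nv} v, "
            f"{npr} p unknowns): {exc}"
        ) from exc
    if not np.all(np.isfinite(sol)):
        raise RuntimeError("Stokes solve produced non-finite values")

    u_pad = np.zeros(u_active.shape)
    u_pad[u_active] = sol[:nu]
    v_pad = np.zeros(v_active.shape)
    v_pad[v_active] = sol[nu : nu + nv]
    p_pad = np.zeros(P.shape)
    p_pad[interior] = sol[nu + nv :]

    # strip the ghost columns: real-domain faces
    u = u_pad[:, 1:-1]  # shape (H, W+1)
    v = v_pad[:, 1:-1]  # shape (H+1, W)
    pressure = p_pad[:, 1:-1]

    field = VelocityField(
        u=u, v=v, pressure=pressure, pore=grid & flow_pore,
        pixel_size=mask.pixel_size, u_m=1.0,
    )
    speed = field.speed[grid]
    u_m_raw = float(speed.mean()) if speed.size else 0.0
    if u_m_raw == 0.0:
        raise NoFlowError("zero flow solution on a percolating mask")

    if target_u_m is not None:
        factor = target_u_m / u_m_raw
    else:
        # match net inlet flux to the 2D flux Q/h, in pixel units
        q2d = config.Q * 1e9 / 60.0 / (config.h * 1000.0)  # µm²/s
        influx_raw = float(u[:, 0].sum()) * mask.pixel_size  # (raw units)·µm
        if influx_raw == 0:
            raise NoFlowError("no net inlet flux; cannot scale to Q")
        factor = q2d / influx_raw
    scaled = field.rescaled(factor)
    speed = scaled.speed[grid]
    scaled.u_m = float(speed.mean())
    return scaled


def shear_rate(field_or_um: "VelocityField | float", config: FlowConfig) -> float:
    """Average wall shear rate u_m / h in 1/s (u_m in µm/s, h in mm)."""
    if config.h <= 0:
        raise ValueError("chip thickness h must be positive")
    u_m = field_or_um.u_m if isinstance(field_or_um, VelocityField) else float(field_or_um)
    return (u_m * 1e-3) / config.h
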
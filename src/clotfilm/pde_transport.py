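"""2D transport of thrombin into and out of a porous fibrin zone under flow.

A rectangular channel (default 1000×60 μm) carries steady flow at a venous
wall shear rate.  A porous clot zone (250×15 μm, leading edge 150 μm from
the inlet) sits on the bottom wall.  Thrombin enters through the bottom
boundary of the clot footprint as a prescribed flux J(t), advects and
diffuses, and reversibly binds the E-domain and γ′ sites carried by the
intraclot fibrin (site capacities 1.6·fibrin and 0.3·fibrin):

    ∂C/∂t  = ∇·(D∇C) − u·∇C − ∂ES/∂t − ∂γS/∂t
    ∂ES/∂t = k_f^E·C·(θ_E − ES) − k_r^E·ES        (clot cells only)
    ∂γS/∂t = k_f^γ·C·(θ_γ − γS) − k_r^γ·γS

Numerics: cell-centred finite volumes (x downstream, y up from the bottom
wall), conservative first-order upwind advection with central diffusion,
advanced implicitly (backward Euler with a one-time sparse LU of the
constant transport operator, which is an M-matrix, so the update is
unconditionally stable and positivity-preserving), operator-split with a
per-cell backward-Euler solve of the stiff binding kinetics each step.  The velocity field solves steady incompressible
Stokes flow with a Brinkman drag μ/k inside the clot on a staggered MAC
grid via one sparse direct solve; because both the viscous and drag terms
scale with μ, the velocity is independent of the viscosity value.

Boundary conditions: prescribed parabolic inlet profile scaled to the
requested clean-channel wall shear rate, zero-pressure outlet with
∂u/∂x = 0, no-slip walls; for transport, zero concentration carried in at
the inlet, advective outflow with zero diffusive flux at the outlet,
zero flux on the walls except the imposed J(t) on the clot footprint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .observables import HalfLife, elution_halflife
from .parameters import BindingSite, ParameterValidationError, default_parameters
from .reduced_ode import equilibrium_free_fraction

__all__ = [
    "ChannelGeometry",
    "TransportParams",
    "VelocityField",
    "PdeField",
    "PdeHistory",
    "solve_velocity",
    "run_loading",
    "run_elution",
    "ElutionResult",
    "equilibrate_clot",
    "spatial_averages",
]

logger = logging.getLogger(__name__)

DEFAULT_DT = 0.05  # s, transport substep (backward Euler, unconditionally stable)


@dataclass(frozen=True)
class ChannelGeometry:
    """Channel and clot-zone geometry with the finite-volume grid."""

    length: float = 1000.0
    height: float = 60.0
    clot_x0: float = 150.0
    clot_length: float = 250.0
    clot_height: float = 15.0
    nx: int = 50
    ny: int = 30

    def __post_init__(self) -> None:
        if self.nx < 4 or self.ny < 4:
            raise ParameterValidationError("grid must be at least 4×4 cells")
        if not (0 < self.clot_x0 and
                self.clot_x0 + self.clot_length < self.length and
                0 < self.clot_height < self.height):
            raise ParameterValidationError("clot zone must lie strictly inside the channel")
        if self.clot_height / self.dy < 3:
            raise ParameterValidationError(
                f"grid too coarse: clot resolved by {self.clot_height / self.dy:.1f} "
                "cells vertically (need ≥ 3)"
            )

    @property
    def dx(self) -> float:
        return self.length / self.nx

    @property
    def dy(self) -> float:
        return self.height / self.ny

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dy

    def _overlap_x(self) -> np.ndarray:
        """(nx,) fraction of each column overlapped by the clot footprint."""
        lo = np.arange(self.nx) * self.dx
        hi = lo + self.dx
        x1 = self.clot_x0 + self.clot_length
        return np.clip(np.minimum(hi, x1) - np.maximum(lo, self.clot_x0),
                       0.0, None) / self.dx

    def _overlap_y(self) -> np.ndarray:
        lo = np.arange(self.ny) * self.dy
        hi = lo + self.dy
        return np.clip(np.minimum(hi, self.clot_height) - lo, 0.0, None) / self.dy

    @property
    def clot_frac(self) -> np.ndarray:
        """(nx, ny) area fraction of each cell inside the clot rectangle.

        The clot is an immersed rectangle; partial cells carry proportional
        binding-site capacity and Brinkman drag, so the represented clot has
        the exact prescribed footprint and height on every grid.
        """
        return self._overlap_x()[:, None] * self._overlap_y()[None, :]

    @property
    def clot_mask(self) -> np.ndarray:
        """(nx, ny) bool mask of cells with any clot overlap."""
        return self.clot_frac > 1e-12

    @property
    def clot_bottom_frac(self) -> np.ndarray:
        """(nx,) footprint overlap of each bottom-wall column (flux weights)."""
        return self._overlap_x()

    def refined(self, factor: int = 2) -> "ChannelGeometry":
        return replace(self, nx=self.nx * factor, ny=self.ny * factor)


def _default_sites() -> tuple[BindingSite, BindingSite]:
    return default_parameters().sites


@dataclass(frozen=True)
class TransportParams:
    """Transport and binding parameters of the channel simulation.

    ``D_free`` is the free-solution thrombin diffusivity (Stokes–Einstein
    scale for a ~36 kDa protein); ``D_clot`` the effective intraclot value
    after porosity/tortuosity reduction.  ``permeability`` sets the Brinkman
    drag in the clot; at the μm²·10⁻³ default the clot interior is
    effectively diffusion-dominated.
    """

    D_free: float = 60.0        # μm²/s
    D_clot: float = 15.0        # μm²/s
    porosity: float = 0.5
    permeability: float = 1e-3  # μm²
    wall_shear_rate: float = 200.0  # s⁻¹
    sites: tuple[BindingSite, BindingSite] = field(default_factory=_default_sites)

    def __post_init__(self) -> None:
        if self.D_free <= 0 or self.D_clot <= 0:
            raise ParameterValidationError("diffusivities must be positive")
        if self.wall_shear_rate <= 0:
            raise ParameterValidationError("wall shear rate must be positive")
        if self.permeability <= 0:
            raise ParameterValidationError("permeability must be positive")


@dataclass(frozen=True)
class VelocityField:
    """Staggered face velocities (μm/s) from the Stokes–Brinkman solve."""

    geometry: ChannelGeometry
    u: np.ndarray   # (nx+1, ny) x-velocity at x-faces
    v: np.ndarray   # (nx, ny+1) y-velocity at y-faces
    p: np.ndarray   # (nx, ny) pressure (arbitrary viscosity units)
    diagnostics: dict = field(compare=False, default_factory=dict)

    @classmethod
    def zero(cls, geometry: ChannelGeometry) -> "VelocityField":
        """Quiescent (sealed-domain) velocity field."""
        return cls(geometry,
                   np.zeros((geometry.nx + 1, geometry.ny)),
                   np.zeros((geometry.nx, geometry.ny + 1)),
                   np.zeros((geometry.nx, geometry.ny)),
                   {"note": "zero field"})

    def divergence(self) -> np.ndarray:
        g = self.geometry
        return ((self.u[1:, :] - self.u[:-1, :]) / g.dx
                + (self.v[:, 1:] - self.v[:, :-1]) / g.dy)

    def wall_shear(self, x: float) -> float:
        """Bottom-wall shear rate at position ``x`` via a parabolic fit
        through the two near-wall velocities (exact for Poiseuille flow)."""
        g = self.geometry
        i = min(int(x / g.dx), g.nx - 1)
        uc = 0.5 * (self.u[i, :] + self.u[i + 1, :])
        y1, y2 = 0.5 * g.dy, 1.5 * g.dy
        u1, u2 = uc[0], uc[1]
        return float((u1 * y2**2 - u2 * y1**2) / (y1 * y2 * (y2 - y1)))


def _inlet_profile(geom: ChannelGeometry, shear_rate: float) -> np.ndarray:
    y = geom.y_centers
    return shear_rate / geom.height * y * (geom.height - y)


def solve_velocity(geometry: ChannelGeometry,
                   transport_params: TransportParams) -> VelocityField:
    """Steady Stokes flow with Brinkman drag in the clot (direct solve).

    Unknowns are interior/outlet u-faces, interior v-faces and cell
    pressures; the inlet carries a prescribed parabolic profile whose
    clean-channel wall shear equals ``wall_shear_rate``.  The discrete
    divergence of the solution is zero in every cell to solver precision.
    """
    g = geometry
    nx, ny, dx, dy = g.nx, g.ny, g.dx, g.dy
    beta_cell = g.clot_frac / transport_params.permeability
    u_in = _inlet_profile(g, transport_params.wall_shear_rate)

    nu = nx * ny            # u[i,j], i = 1..nx
    nv = nx * (ny - 1)      # v[i,j], j = 1..ny-1
    npp = nx * ny

    def iu(i: int, j: int) -> int:
        return (i - 1) * ny + j

    def iv(i: int, j: int) -> int:
        return nu + i * (ny - 1) + (j - 1)

    def ip(i: int, j: int) -> int:
        return nu + nv + i * ny + j

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    b = np.zeros(nu + nv + npp)

    def add(r: int, c: int, v: float) -> None:
        rows.append(r); cols.append(c); vals.append(v)

    idx2, idy2 = 1.0 / dx**2, 1.0 / dy**2
    # --- u momentum ---
    for i in range(1, nx + 1):
        for j in range(ny):
            r = iu(i, j)
            if i <= nx - 1:
                beta = 0.5 * (beta_cell[i - 1, j] + beta_cell[i, j])
            else:  # outlet face: use last cell
                beta = beta_cell[nx - 1, j]
            diag = -beta
            if i < nx:
                diag -= 2.0 * idx2
                if i + 1 <= nx:
                    add(r, iu(i + 1, j), idx2)
                if i - 1 >= 1:
                    add(r, iu(i - 1, j), idx2)
                else:
                    b[r] -= idx2 * u_in[j]
            else:
                # outlet: ghost u[nx+1] = u[nx]  →  (u[nx-1] - u[nx])/dx²
                diag -= idx2
                add(r, iu(nx - 1, j), idx2)
            # y-direction; no-slip walls use a quadratic ghost
            # (u_ghost = (u_2 − 6·u_1)/3, exact for parabolic profiles)
            if 0 < j < ny - 1:
                diag -= 2.0 * idy2
                add(r, iu(i, j + 1), idy2)
                add(r, iu(i, j - 1), idy2)
            elif j == 0:
                diag -= 4.0 * idy2
                add(r, iu(i, j + 1), (4.0 / 3.0) * idy2)
            else:  # j == ny - 1
                diag -= 4.0 * idy2
                add(r, iu(i, j - 1), (4.0 / 3.0) * idy2)
            add(r, r, diag)
            # pressure gradient
            if i < nx:
                add(r, ip(i, j), -1.0 / dx)
                add(r, ip(i - 1, j), 1.0 / dx)
            else:
                # outlet boundary pressure = 0: ∂p/∂x ≈ (0 − p[nx-1])/(dx/2)
                add(r, ip(nx - 1, j), 2.0 / dx)

    # --- v momentum ---
    for i in range(nx):
        for j in range(1, ny):
            r = iv(i, j)
            beta = 0.5 * (beta_cell[i, j - 1] + beta_cell[i, j])
            diag = -beta - 2.0 * idx2 - 2.0 * idy2
            if i + 1 <= nx - 1:
                add(r, iv(i + 1, j), idx2)
            else:
                diag += idx2        # outlet ghost = v[nx-1,j]
            if i - 1 >= 0:
                add(r, iv(i - 1, j), idx2)
            else:
                diag -= idx2        # inlet ghost = −v[0,j] (v = 0 at inlet)
            if j + 1 <= ny - 1:
                add(r, iv(i, j + 1), idy2)
            if j - 1 >= 1:
                add(r, iv(i, j - 1), idy2)
            add(r, r, diag)
            add(r, ip(i, j), -1.0 / dy)
            add(r, ip(i, j - 1), 1.0 / dy)

    # --- continuity ---
    for i in range(nx):
        for j in range(ny):
            r = ip(i, j)
            if i + 1 <= nx:
                add(r, iu(i + 1, j), 1.0 / dx)
            if i >= 1:
                add(r, iu(i, j), -1.0 / dx)
            else:
                b[r] += u_in[j] / dx
            if j + 1 <= ny - 1:
                add(r, iv(i, j + 1), 1.0 / dy)
            if j >= 1:
                add(r, iv(i, j), -1.0 / dy)

    A = sp.csc_matrix((vals, (rows, cols)), shape=(nu + nv + npp,) * 2)
    sol = spla.spsolve(A, b)
    if not np.all(np.isfinite(sol)):
        raise RuntimeError("Stokes–Brinkman solve produced non-finite values; "
                           f"residual scale {np.abs(A @ sol - b).max():.3e}")

    u = np.zeros((nx + 1, ny))
    u[0, :] = u_in
    for i in range(1, nx + 1):
        u[i, :] = sol[iu(i, 0):iu(i, 0) + ny]
    v = np.zeros((nx, ny + 1))
    for i in range(nx):
        v[i, 1:ny] = sol[iv(i, 1):iv(i, 1) + (ny - 1)]
    p = sol[nu + nv:].reshape(nx, ny)

    vel = VelocityField(g, u, v, p)
    div = vel.divergence()
    scale = max(np.abs(u).max() / dx, 1e-300)
    diag = {"max_abs_divergence": float(np.abs(div).max()),
            "relative_divergence": float(np.abs(div).max() / scale),
            "residual": float(np.abs(A @ sol - b).max())}
    if diag["relative_divergence"] > 1e-8:
        logger.warning("velocity field divergence %.2e exceeds 1e-8 of flow scale",
                       diag["relative_divergence"])
    return VelocityField(g, u, v, p, diag)


@dataclass(frozen=True)
class PdeField:
    """Snapshot of the transport state with running budget totals (μM·μm²)."""

    time: float
    c: np.ndarray
    es: np.ndarray
    gs: np.ndarray
    influx: float = 0.0
    efflux: float = 0.0

    @property
    def total(self) -> np.ndarray:
        return self.c + self.es + self.gs


@dataclass
class PdeHistory:
    """Recorded series and snapshots from a transport run."""

    geometry: ChannelGeometry
    params: TransportParams
    times: np.ndarray
    clot_free: np.ndarray      # clot-averaged concentrations, μM
    clot_e: np.ndarray
    clot_gamma: np.ndarray
    influx: np.ndarray         # cumulative, μM·μm²
    efflux: np.ndarray
    stored: np.ndarray         # total domain mass, μM·μm²
    snapshots: list[PdeField]
    final: PdeField

    @property
    def clot_total(self) -> np.ndarray:
        return self.clot_free + self.clot_e + self.clot_gamma

    def budget_closure(self) -> float:
        """Relative budget error |Δstored − (influx − efflux)| / max influx."""
        gained = self.stored - self.stored[0]
        net = (self.influx - self.influx[0]) - (self.efflux - self.efflux[0])
        denom = max(self.influx[-1] - self.influx[0], self.stored[0], 1e-300)
        return float(np.abs(gained - net).max() / denom)


def _as_callable(series) -> Callable[[float], float]:
    if callable(series):
        return series
    if np.isscalar(series):
        val = float(series)
        return lambda t: val
    raise TypeError("expected a callable, fixture, or scalar")


def _face_diffusivity(geom: ChannelGeometry, tp: TransportParams):
    D = tp.D_free + geom.clot_frac * (tp.D_clot - tp.D_free)
    Dx = np.zeros((geom.nx + 1, geom.ny))
    Dx[1:-1, :] = 2.0 * D[1:, :] * D[:-1, :] / (D[1:, :] + D[:-1, :])
    Dy = np.zeros((geom.nx, geom.ny + 1))
    Dy[:, 1:-1] = 2.0 * D[:, 1:] * D[:, :-1] / (D[:, 1:] + D[:, :-1])
    return Dx, Dy


def _binding_step(c, es, gs, clot, theta_e, theta_g, sites, dt):
    """Backward-Euler update of the two binding ODEs in clot cells.

    Within the split step the local total S = C + ES + γS is conserved, so
    the implicit system reduces to a scalar equation for the new free
    concentration, solved by a clipped Newton iteration (vectorized over
    clot cells)."""
    site_e, site_g = sites
    C0, E0, G0 = c[clot], es[clot], gs[clot]
    S = C0 + E0 + G0
    aE, bE = dt * site_e.kf, 1.0 + dt * site_e.kr
    aG, bG = dt * site_g.kf, 1.0 + dt * site_g.kr
    C = np.minimum(C0, S)
    for _ in range(60):
        dE_den = bE + aE * C
        dG_den = bG + aG * C
        E = (E0 + aE * C * theta_e) / dE_den
        G = (G0 + aG * C * theta_g) / dG_den
        f = C + E + G - S
        dE = (aE * theta_e * dE_den - (E0 + aE * C * theta_e) * aE) / dE_den**2
        dG = (aG * theta_g * dG_den - (G0 + aG * C * theta_g) * aG) / dG_den**2
        step = f / (1.0 + dE + dG)
        C = np.clip(C - step, 0.0, S)
        if np.all(np.abs(f) <= 1e-12 * np.maximum(S, 1e-30)):
            break
    E = (E0 + aE * C * theta_e) / (bE + aE * C)
    G = (G0 + aG * C * theta_g) / (bG + aG * C)
    c[clot], es[clot], gs[clot] = C, E, G


def _transport_operator(geom: ChannelGeometry, tp: TransportParams,
                        vel: VelocityField) -> tuple[sp.csc_matrix, np.ndarray]:
    """Conservative upwind-advection + central-diffusion operator A with
    A·c = outflow divergence, plus the outlet export rates (per column, s⁻¹
    scaled by dx) used for the budget audit.  A is an M-matrix."""
    g = geom
    nx, ny, dx, dy = g.nx, g.ny, g.dx, g.dy
    Dx, Dy = _face_diffusivity(g, tp)
    N = nx * ny

    def k(i, j):  # cell index arrays
        return (i * ny + j).ravel()

    rows, cols, vals = [], [], []

    def add(r, c_, v):
        rows.append(r); cols.append(c_); vals.append(v)

    # interior x faces between (i-1,j) and (i,j), i = 1..nx-1
    ii, jj = np.meshgrid(np.arange(1, nx), np.arange(ny), indexing="ij")
    uf = vel.u[1:nx, :]
    up, um = np.maximum(uf, 0.0), np.minimum(uf, 0.0)
    dif = Dx[1:nx, :] / dx
    L, R = k(ii - 1, jj), k(ii, jj)
    add(L, L, ((up + dif) / dx).ravel())
    add(L, R, ((um - dif) / dx).ravel())
    add(R, L, (-(up + dif) / dx).ravel())
    add(R, R, (-(um - dif) / dx).ravel())
    # inlet face (ghost concentration 0): only backflow export matters
    j0 = np.arange(ny)
    um0 = np.minimum(vel.u[0, :], 0.0)
    add(k(np.zeros(ny, int), j0), k(np.zeros(ny, int), j0), -um0 / dx)
    # outlet face: advective export at the upwind (last-cell) value
    upN = np.maximum(vel.u[nx, :], 0.0)
    last = k(np.full(ny, nx - 1), j0)
    add(last, last, upN / dx)
    # interior y faces between (i,j-1) and (i,j), j = 1..ny-1
    ii, jj = np.meshgrid(np.arange(nx), np.arange(1, ny), indexing="ij")
    vf = vel.v[:, 1:ny]
    vp, vm = np.maximum(vf, 0.0), np.minimum(vf, 0.0)
    dif = Dy[:, 1:ny] / dy
    B, T = k(ii, jj - 1), k(ii, jj)
    add(B, B, ((vp + dif) / dy).ravel())
    add(B, T, ((vm - dif) / dy).ravel())
    add(T, B, (-(vp + dif) / dy).ravel())
    add(T, T, (-(vm - dif) / dy).ravel())

    A = sp.csc_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(N, N))
    return A, upN


def _run_transport(geom: ChannelGeometry, tp: TransportParams, vel: VelocityField,
                   state: PdeField, t_end: float,
                   J: Callable[[float], float],
                   fibrin: Callable[[float], float],
                   record_dt: float = 1.0,
                   snapshot_times: Sequence[float] = (),
                   stop_amount: float | None = None,
                   dt_target: float = DEFAULT_DT) -> PdeHistory:
    g = geom
    dx, dy = g.dx, g.dy
    cell = dx * dy
    clot = g.clot_mask
    n_clot = int(clot.sum())
    frac = g.clot_frac
    frac_cells = frac[clot]
    weight = float(frac.sum())               # clot area / cell area
    bw = g.clot_bottom_frac
    bottom_cols = np.nonzero(bw > 0)[0]
    bottom_w = bw[bottom_cols]
    bottom_flat = bottom_cols * g.ny          # cell index of (i, 0)
    A, out_rate = _transport_operator(g, tp, vel)
    N = g.nx * g.ny
    eye = sp.identity(N, format="csc")
    lu_cache: dict[float, spla.SuperLU] = {}

    def lu_for(dt: float) -> spla.SuperLU:
        key = round(dt, 12)
        if key not in lu_cache:
            lu_cache[key] = spla.splu((eye + dt * A).tocsc())
        return lu_cache[key]

    c = state.c.copy()
    es = state.es.copy()
    gs = state.gs.copy()
    influx, efflux = state.influx, state.efflux
    t = state.time

    rec_t, rec_free, rec_e, rec_g = [], [], [], []
    rec_in, rec_out, rec_stored = [], [], []
    snaps: list[PdeField] = []
    snap_queue = sorted(snapshot_times)

    def record() -> None:
        rec_t.append(t)
        if n_clot:
            rec_free.append(float((c[clot] * frac_cells).sum() / weight))
            rec_e.append(float((es[clot] * frac_cells).sum() / weight))
            rec_g.append(float((gs[clot] * frac_cells).sum() / weight))
        else:
            rec_free.append(0.0); rec_e.append(0.0); rec_g.append(0.0)
        rec_in.append(influx)
        rec_out.append(efflux)
        rec_stored.append(float((c + es + gs).sum() * cell))

    record()
    while t < t_end - 1e-9:
        seg = min(record_dt, t_end - t)
        n_sub = max(int(np.ceil(seg / dt_target - 1e-12)), 1)
        dt = seg / n_sub
        lu = lu_for(dt)
        for _ in range(n_sub):
            tm = t + 0.5 * dt
            rhs = c.reshape(-1).copy()
            j_now = float(J(tm))
            if j_now < 0:
                raise ValueError(f"negative thrombin flux J({tm})={j_now}")
            if j_now > 0 and bottom_cols.size:
                rhs[bottom_flat] += j_now * dt / dy * bottom_w
                influx += j_now * dt * dx * float(bottom_w.sum())
            c = lu.solve(rhs).reshape(g.nx, g.ny)
            efflux += float((out_rate * c[-1, :]).sum() * dy * dt)
            fib = float(fibrin(tm))
            if n_clot and (fib > 0 or es.max() > 0 or gs.max() > 0):
                _binding_step(c, es, gs, clot,
                              tp.sites[0].sites_per_monomer * fib * frac_cells,
                              tp.sites[1].sites_per_monomer * fib * frac_cells,
                              tp.sites, dt)
            if c.min() < -1e-9:
                raise RuntimeError(
                    f"transport step produced c={c.min():.3e} at t={t:.3f}")
            np.clip(c, 0.0, None, out=c)
            t += dt
        record()
        if stop_amount is not None and n_clot:
            amount = (rec_free[-1] + rec_e[-1] + rec_g[-1]) * weight * cell
            if amount <= stop_amount:
                break
        while snap_queue and t >= snap_queue[0] - 1e-9:
            snap_queue.pop(0)
            snaps.append(PdeField(t, c.copy(), es.copy(), gs.copy(), influx, efflux))

    final = PdeField(t, c, es, gs, influx, efflux)
    return PdeHistory(g, tp, np.array(rec_t), np.array(rec_free),
                      np.array(rec_e), np.array(rec_g),
                      np.array(rec_in), np.array(rec_out),
                      np.array(rec_stored), snaps, final)


def run_loading(geometry: ChannelGeometry, params: TransportParams,
                J, fibrin, t_end: float = 800.0,
                velocity: VelocityField | None = None,
                record_dt: float = 1.0,
                snapshot_times: Sequence[float] = ()) -> PdeHistory:
    """Load thrombin into the clot through the bottom boundary for ``t_end`` s.

    ``J`` (μM·μm/s) and ``fibrin`` (μM) may be callables, fixtures from
    :mod:`clotfilm.fixtures`, or scalars.  The velocity field is solved once
    (pass ``VelocityField.zero(geometry)`` for a sealed domain).
    """
    vel = velocity if velocity is not None else solve_velocity(geometry, params)
    empty = PdeField(0.0,
                     np.zeros((geometry.nx, geometry.ny)),
                     np.zeros((geometry.nx, geometry.ny)),
                     np.zeros((geometry.nx, geometry.ny)))
    return _run_transport(geometry, params, vel, empty, t_end,
                          _as_callable(J), _as_callable(fibrin),
                          record_dt, snapshot_times)


@dataclass
class ElutionResult:
    history: PdeHistory
    half_life: HalfLife


def run_elution(state: PdeField | PdeHistory, params: TransportParams,
                t_end: float, geometry: ChannelGeometry | None = None,
                fibrin: float | None = None,
                velocity: VelocityField | None = None,
                record_dt: float = 1.0,
                stop_when_halved: bool = False) -> ElutionResult:
    """Continue from a loaded state with J = 0 and follow clot washout.

    Reports the clot-averaged total thrombin series and its half-life
    (linear interpolation on the recorded series).  ``fibrin`` defaults to
    holding the binding-site load constant; with ``stop_when_halved`` the
    run ends shortly after the amount crosses half its starting value.
    """
    if isinstance(state, PdeHistory):
        geometry = state.geometry
        start = state.final
    else:
        if geometry is None:
            raise ValueError("geometry is required when starting from a PdeField")
        start = state
    vel = velocity if velocity is not None else solve_velocity(geometry, params)
    if fibrin is None:
        if start.es.max() > 0 or start.gs.max() > 0:
            raise ValueError("state carries bound thrombin: pass the fibrin level "
                             "to hold during elution")
        fib = 0.0
    else:
        fib = float(fibrin)
    frac = geometry.clot_frac
    cell = geometry.dx * geometry.dy
    start_amount = float(((start.c + start.es + start.gs) * frac).sum() * cell)
    stop = 0.45 * start_amount if stop_when_halved else None
    hist = _run_transport(geometry, params, vel, start,
                          start.time + t_end,
                          lambda t: 0.0, lambda t: fib,
                          record_dt, stop_amount=stop)
    amounts = hist.clot_total * frac.sum() * cell
    hl = elution_halflife(hist.times, amounts)
    return ElutionResult(hist, hl)


def equilibrate_clot(geometry: ChannelGeometry, params: TransportParams,
                     fibrin: float, total_clot_avg: float) -> PdeField:
    """A clot uniformly pre-loaded with thrombin at binding equilibrium.

    Mirrors the elution-only channel study: total thrombin
    ``total_clot_avg`` (μM) is partitioned between free and the two bound
    pools by the closed-form two-site equilibrium at the given fibrin level.
    """
    w = geometry.clot_frac
    free_frac = equilibrium_free_fraction(total_clot_avg, fibrin, params.sites)
    free = total_clot_avg * free_frac
    bound = total_clot_avg - free
    theta_e = params.sites[0].sites_per_monomer * fibrin
    theta_g = params.sites[1].sites_per_monomer * fibrin
    if bound > 0:
        occ_e = theta_e * free / (params.sites[0].Kd + free)
        occ_g = theta_g * free / (params.sites[1].Kd + free)
        norm = bound / (occ_e + occ_g)
        occ_e, occ_g = occ_e * norm, occ_g * norm
    else:
        occ_e = occ_g = 0.0
    return PdeField(0.0, free * w, occ_e * w, occ_g * w)


def spatial_averages(history: PdeHistory) -> pd.DataFrame:
    """Clot-averaged free/bound/total thrombin and the budget series."""
    return pd.DataFrame({
        "time_s": history.times,
        "free_uM": history.clot_free,
        "e_bound_uM": history.clot_e,
        "gamma_bound_uM": history.clot_gamma,
        "total_uM": history.clot_total,
        "influx_uM_um2": history.influx,
        "efflux_uM_um2": history.efflux,
        "stored_uM_um2": history.stored,
    })
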
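"""Laminar incompressible blood flow in the channel around the catheter.

Chorin pressure-projection on a MAC staggered layout over the
rectilinear grid: u on vertical faces, v on horizontal faces, pressure
in cell centres, with the blood cells as the fluid domain and no-slip
at the tissue and catheter interfaces.  The inlet is driven by the
pulsatile E/A waveform (plug profile) or by a fixed pressure head; the
outlet is a zero-pressure boundary.  The regime is laminar (peak
Reynolds numbers well below 2000), so no turbulence model is involved.

The predictor uses explicit first-order upwind advection and central
diffusion (quadratic wall ghosts, so a fully developed channel profile
is represented exactly); the pressure Poisson operator is factorised
once per geometry and reused every step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .domain import Region, SimMesh
from .materials import MaterialSet

__all__ = [
    "FlowState",
    "FlowSolver",
    "CycleVelocity",
    "CFLError",
    "reynolds",
    "advective_term",
]

MMHG = 133.322  # Pa


class CFLError(RuntimeError):
    """Time step violates the advective stability limit."""

    def __init__(self, dt: float, dt_suggested: float):
        super().__init__(
            f"dt={dt:g} s violates the CFL limit; use dt <= {dt_suggested:g} s"
        )
        self.dt_suggested = dt_suggested


def reynolds(rho: float, speed: float, diameter: float, mu: float) -> float:
    """Reynolds number rho u D / mu; warns when the laminar assumption
    (Re < 2000) does not hold."""
    if rho <= 0 or diameter <= 0 or mu <= 0 or speed < 0:
        raise ValueError("rho, D, mu must be positive and speed nonnegative")
    re = rho * speed * diameter / mu
    if re >= 2000:
        warnings.warn(
            f"Re = {re:.0f} >= 2000: flow may be turbulent, the laminar "
            "model is outside its validity range",
            stacklevel=2,
        )
    return re


@dataclass
class FlowState:
    """Velocity/pressure snapshot of the blood channel."""

    velocity: np.ndarray  # (n_cells, 2) cell-centred, m/s
    pressure: np.ndarray  # (n_cells,) cell-centred, Pa
    time: float
    divergence_norm: float  # max |div u| over fluid cells, 1/s
    face_u: np.ndarray  # (ny, nx+1) MAC x-face velocities
    face_v: np.ndarray  # (ny+1, nx) MAC y-face velocities


@dataclass
class CycleVelocity:
    """Stored periodic velocity fields over one cardiac cycle."""

    times: np.ndarray  # s, within [0, cycle)
    face_u: np.ndarray  # (n_snap, ny, nx+1)
    face_v: np.ndarray  # (n_snap, ny+1, nx)
    cycle_duration: float
    max_speed: float

    def at_time(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Nearest stored snapshot at periodic time ``t``."""
        phase = np.mod(t, self.cycle_duration)
        idx = int(np.argmin(np.abs(self.times - phase)))
        return self.face_u[idx], self.face_v[idx]


class FlowSolver:
    """Incompressible projection solver on the blood cells of one mesh."""

    def __init__(
        self,
        mesh: SimMesh,
        rho: float = 1000.0,
        mu: float = 2.1e-3,
        inlet_mode: str = "velocity",
        inlet_pressure: float = 10 * MMHG,
        match_speed_at_catheter: bool = True,
    ):
        if mesh.dim != 2:
            raise NotImplementedError("flow solve operates on planar sections")
        if inlet_mode not in ("velocity", "pressure"):
            raise ValueError("inlet_mode must be 'velocity' or 'pressure'")
        self.mesh = mesh
        self.rho = rho
        self.mu = mu
        self.nu = mu / rho
        self.inlet_mode = inlet_mode
        self.inlet_pressure = inlet_pressure

        nx, ny = mesh.nx, mesh.ny
        self.nx, self.ny = nx, ny
        self.dx, self.dy = mesh.dx, mesh.dy
        self.xc = 0.5 * (mesh.x_edges[:-1] + mesh.x_edges[1:])
        self.yc = 0.5 * (mesh.y_edges[:-1] + mesh.y_edges[1:])
        fluid = mesh.region_grid == int(Region.BLOOD)
        self.fluid = fluid

        self.U = np.zeros((ny, nx + 1))
        self.V = np.zeros((ny + 1, nx))

        # inlet/outlet face rows
        self.inlet_rows = np.flatnonzero(fluid[:, 0])
        self.outlet_rows = np.flatnonzero(fluid[:, -1])
        if not len(self.inlet_rows) or not len(self.outlet_rows):
            raise ValueError("blood channel must reach both side boundaries")

        # interior unknown u faces: both adjacent cells fluid
        uj, ui = np.nonzero(fluid[:, :-1] & fluid[:, 1:])
        self.uj, self.ui = uj, ui + 1  # face index i in 1..nx-1

        # interior unknown v faces
        vj, vi = np.nonzero(fluid[:-1, :] & fluid[1:, :])
        self.vj, self.vi = vj + 1, vi  # face index j in 1..ny-1

        self._precompute_u_stencil()
        self._precompute_v_stencil()
        self._build_pressure_solver()

        # inlet speed scaling so the cycle-mean above the catheter matches
        # the configured mean (the quantity the CHT coefficients use)
        inlet_open = float(self.dy[self.inlet_rows].sum())
        col_open = np.array([
            float(self.dy[fluid[:, i]].sum()) for i in range(nx)
        ])
        self.inlet_scale = (col_open.min() / inlet_open) if match_speed_at_catheter else 1.0

    # -- stencil precomputation -------------------------------------------

    def _face_exists_u(self, j: np.ndarray, i: np.ndarray) -> np.ndarray:
        """u-face (j, i) carries a meaningful velocity value (not a wall)."""
        nx, ny = self.nx, self.ny
        ok = (j >= 0) & (j < ny) & (i >= 0) & (i <= nx)
        out = np.zeros(len(j), dtype=bool)
        jj, ii = j[ok], i[ok]
        left_ok = np.where(ii > 0, self.fluid[jj, np.maximum(ii - 1, 0)], True)
        right_ok = np.where(ii < nx, self.fluid[jj, np.minimum(ii, nx - 1)], True)
        out[ok] = left_ok & right_ok
        return out

    def _face_exists_v(self, j: np.ndarray, i: np.ndarray) -> np.ndarray:
        nx, ny = self.nx, self.ny
        ok = (j >= 0) & (j <= ny) & (i >= 0) & (i < nx)
        out = np.zeros(len(j), dtype=bool)
        jj, ii = j[ok], i[ok]
        below_ok = np.where(jj > 0, self.fluid[np.maximum(jj - 1, 0), ii], True)
        above_ok = np.where(jj < ny, self.fluid[np.minimum(jj, ny - 1), ii], True)
        out[ok] = below_ok & above_ok
        return out

    def _precompute_u_stencil(self) -> None:
        j, i = self.uj, self.ui
        self.u_h1 = self.dx[i - 1]
        self.u_h2 = self.dx[i]
        # vertical neighbours: normal face or wall mirror
        self.u_up_ok = self._face_exists_u(j + 1, i)
        self.u_dn_ok = self._face_exists_u(j - 1, i)
        self.u_far_up_ok = self._face_exists_u(j + 2, i) & self.u_up_ok
        self.u_far_dn_ok = self._face_exists_u(j - 2, i) & self.u_dn_ok
        yc = self.yc
        self.u_s2 = np.where(self.u_up_ok,
                             yc[np.minimum(j + 1, self.ny - 1)] - yc[j], self.dy[j])
        self.u_s1 = np.where(self.u_dn_ok,
                             yc[j] - yc[np.maximum(j - 1, 0)], self.dy[j])

    def _precompute_v_stencil(self) -> None:
        j, i = self.vj, self.vi
        self.v_h1 = self.dy[j - 1]
        self.v_h2 = self.dy[j]
        self.v_rt_ok = self._face_exists_v(j, i + 1)
        self.v_lt_ok = self._face_exists_v(j, i - 1)
        self.v_far_rt_ok = self._face_exists_v(j, i + 2) & self.v_rt_ok
        self.v_far_lt_ok = self._face_exists_v(j, i - 2) & self.v_lt_ok
        xc = self.xc
        self.v_s2 = np.where(self.v_rt_ok,
                             xc[np.minimum(i + 1, self.nx - 1)] - xc[i], self.dx[i])
        self.v_s1 = np.where(self.v_lt_ok,
                             xc[i] - xc[np.maximum(i - 1, 0)], self.dx[i])

    def _build_pressure_solver(self) -> None:
        nx = self.nx
        fluid = self.fluid
        fid = -np.ones(fluid.shape, dtype=np.int64)
        cells = np.nonzero(fluid)
        n_fluid = len(cells[0])
        fid[cells] = np.arange(n_fluid)
        self.fluid_id = fid
        self.fluid_cells = cells  # (j_arr, i_arr)

        rows, cols, vals = [], [], []
        rhs_fixed = np.zeros(n_fluid)

        jf, if_ = cells
        for dj, di in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            jn, in_ = jf + dj, if_ + di
            inside = (jn >= 0) & (jn < self.ny) & (in_ >= 0) & (in_ < nx)
            area = self.dy[jf] if di else self.dx[if_]
            # neighbouring fluid cell: standard coupling
            nb = inside & fluid[np.clip(jn, 0, self.ny - 1), np.clip(in_, 0, nx - 1)]
            if di:
                dist = np.where(nb, np.abs(
                    self.xc[np.clip(in_, 0, nx - 1)] - self.xc[if_]), 1.0)
            else:
                dist = np.where(nb, np.abs(
                    self.yc[np.clip(jn, 0, self.ny - 1)] - self.yc[jf]), 1.0)
            g = np.where(nb, area / dist, 0.0)
            fid_n = fid[np.clip(jn, 0, self.ny - 1), np.clip(in_, 0, nx - 1)]
            rows.append(fid[jf, if_][nb]); cols.append(fid_n[nb]); vals.append(-g[nb])
            rows.append(fid[jf, if_][nb]); cols.append(fid[jf, if_][nb]); vals.append(g[nb])
        # outlet Dirichlet ghost (p = 0)
        out_cells = fid[self.outlet_rows, nx - 1]
        g = self.dy[self.outlet_rows] / (self.dx[-1] / 2.0)
        rows.append(out_cells); cols.append(out_cells); vals.append(g)
        # inlet Dirichlet ghost in pressure-driven mode
        if self.inlet_mode == "pressure":
            in_cells = fid[self.inlet_rows, 0]
            g = self.dy[self.inlet_rows] / (self.dx[0] / 2.0)
            rows.append(in_cells); cols.append(in_cells); vals.append(g)
            rhs_fixed[in_cells] += g * self.inlet_pressure

        mat = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_fluid, n_fluid),
        )
        self._plu = spla.splu(mat.tocsc())
        self._p_rhs_fixed = rhs_fixed

    # -- stepping ----------------------------------------------------------

    def cfl_dt(self) -> float:
        """Largest stable step for the current velocity field."""
        umax = max(float(np.abs(self.U).max()), float(np.abs(self.V).max()), 1e-12)
        adv = min(self.dx.min(), self.dy.min()) / umax
        visc = min(self.dx.min(), self.dy.min()) ** 2 / (4.0 * self.nu)
        return 0.8 * min(adv, visc)

    def _ghost(self, val_c, val_far, far_ok):
        """Quadratic no-slip ghost (exact for parabolic profiles); falls
        back to linear mirror where no second neighbour exists."""
        return np.where(far_ok, -2.0 * val_c + val_far / 3.0, -val_c)

    def _predict_u(self, dt: float) -> np.ndarray:
        j, i = self.uj, self.ui
        U, V = self.U, self.V
        uc = U[j, i]
        ul = U[j, i - 1]
        ur = U[j, i + 1]
        up_raw = U[np.minimum(j + 1, self.ny - 1), i]
        dn_raw = U[np.maximum(j - 1, 0), i]
        far_up = U[np.minimum(j + 2, self.ny - 1), i]
        far_dn = U[np.maximum(j - 2, 0), i]
        u_up_visc = np.where(self.u_up_ok, up_raw, self._ghost(uc, far_up, self.u_far_up_ok))
        u_dn_visc = np.where(self.u_dn_ok, dn_raw, self._ghost(uc, far_dn, self.u_far_dn_ok))
        u_up_adv = np.where(self.u_up_ok, up_raw, -uc)
        u_dn_adv = np.where(self.u_dn_ok, dn_raw, -uc)

        lap = 2.0 / (self.u_h1 + self.u_h2) * (
            (ur - uc) / self.u_h2 - (uc - ul) / self.u_h1
        ) + 2.0 / (self.u_s1 + self.u_s2) * (
            (u_up_visc - uc) / self.u_s2 - (uc - u_dn_visc) / self.u_s1
        )
        vavg = 0.25 * (V[j, i - 1] + V[j, i] + V[j + 1, i - 1] + V[j + 1, i])
        dudx = np.where(uc > 0, (uc - ul) / self.u_h1, (ur - uc) / self.u_h2)
        dudy = np.where(vavg > 0, (uc - u_dn_adv) / self.u_s1,
                        (u_up_adv - uc) / self.u_s2)
        return uc + dt * (self.nu * lap - uc * dudx - vavg * dudy)

    def _predict_v(self, dt: float) -> np.ndarray:
        j, i = self.vj, self.vi
        U, V = self.U, self.V
        vc = V[j, i]
        vd = V[j - 1, i]
        vu = V[j + 1, i]
        rt_raw = V[j, np.minimum(i + 1, self.nx - 1)]
        lt_raw = V[j, np.maximum(i - 1, 0)]
        far_rt = V[j, np.minimum(i + 2, self.nx - 1)]
        far_lt = V[j, np.maximum(i - 2, 0)]
        v_rt_visc = np.where(self.v_rt_ok, rt_raw, self._ghost(vc, far_rt, self.v_far_rt_ok))
        v_lt_visc = np.where(self.v_lt_ok, lt_raw, self._ghost(vc, far_lt, self.v_far_lt_ok))
        v_rt_adv = np.where(self.v_rt_ok, rt_raw, -vc)
        v_lt_adv = np.where(self.v_lt_ok, lt_raw, -vc)

        lap = 2.0 / (self.v_h1 + self.v_h2) * (
            (vu - vc) / self.v_h2 - (vc - vd) / self.v_h1
        ) + 2.0 / (self.v_s1 + self.v_s2) * (
            (v_rt_visc - vc) / self.v_s2 - (vc - v_lt_visc) / self.v_s1
        )
        uavg = 0.25 * (U[j - 1, i] + U[j - 1, i + 1] + U[j, i] + U[j, i + 1])
        dvdy = np.where(vc > 0, (vc - vd) / self.v_h1, (vu - vc) / self.v_h2)
        dvdx = np.where(uavg > 0, (vc - v_lt_adv) / self.v_s1,
                        (v_rt_adv - vc) / self.v_s2)
        return vc + dt * (self.nu * lap - uavg * dvdx - vc * dvdy)

    def _divergence(self, U: np.ndarray, V: np.ndarray) -> np.ndarray:
        jf, if_ = self.fluid_cells
        return (
            (U[jf, if_ + 1] - U[jf, if_]) * self.dy[jf]
            + (V[jf + 1, if_] - V[jf, if_]) * self.dx[if_]
        )

    def step(self, dt: float, inlet_speed: float = 0.0, time: float = 0.0) -> FlowState:
        """Advance one projection step; raises :class:`CFLError` when the
        explicit predictor would be unstable at this ``dt``."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        limit = self.cfl_dt()
        if dt > limit:
            raise CFLError(dt, limit)

        nx = self.nx
        # boundary values for this step
        if self.inlet_mode == "velocity":
            self.U[self.inlet_rows, 0] = inlet_speed * self.inlet_scale
        else:
            self.U[self.inlet_rows, 0] = self.U[self.inlet_rows, 1]
        self.U[self.outlet_rows, nx] = self.U[self.outlet_rows, nx - 1]

        u_star = self.U.copy()
        v_star = self.V.copy()
        u_star[self.uj, self.ui] = self._predict_u(dt)
        v_star[self.vj, self.vi] = self._predict_v(dt)

        div = self._divergence(u_star, v_star)
        rhs = -(self.rho / dt) * div + self._p_rhs_fixed
        p = self._plu.solve(rhs)

        fid = self.fluid_id
        j, i = self.uj, self.ui
        dpdx = (p[fid[j, i]] - p[fid[j, i - 1]]) / (self.xc[i] - self.xc[i - 1])
        u_star[j, i] -= dt / self.rho * dpdx
        j, i = self.vj, self.vi
        dpdy = (p[fid[j, i]] - p[fid[j - 1, i]]) / (self.yc[j] - self.yc[j - 1])
        v_star[j, i] -= dt / self.rho * dpdy
        # outlet correction against the p = 0 ghost
        jr = self.outlet_rows
        u_star[jr, nx] -= dt / self.rho * (0.0 - p[fid[jr, nx - 1]]) / (self.dx[-1] / 2.0)
        if self.inlet_mode == "pressure":
            jr = self.inlet_rows
            u_star[jr, 0] -= dt / self.rho * (p[fid[jr, 0]] - self.inlet_pressure) / (self.dx[0] / 2.0)

        self.U, self.V = u_star, v_star
        div_after = self._divergence(self.U, self.V)
        jf, if_ = self.fluid_cells
        vol = self.mesh.cell_measures.reshape(self.ny, self.nx)[jf, if_]
        div_norm = float(np.max(np.abs(div_after / vol))) if len(div_after) else 0.0
        return self._state(time + dt, div_norm, p)

    def _state(self, time: float, div_norm: float, p: np.ndarray) -> FlowState:
        n = self.mesh.n_cells
        vel = np.zeros((n, 2))
        pressure = np.zeros(n)
        jf, if_ = self.fluid_cells
        cell = jf * self.nx + if_
        vel[cell, 0] = 0.5 * (self.U[jf, if_] + self.U[jf, if_ + 1])
        vel[cell, 1] = 0.5 * (self.V[jf, if_] + self.V[jf + 1, if_])
        pressure[cell] = p
        return FlowState(velocity=vel, pressure=pressure, time=time,
                         divergence_norm=div_norm,
                         face_u=self.U.copy(), face_v=self.V.copy())

    def kinetic_energy(self) -> float:
        """0.5 rho integral |u|^2 over the fluid cells (per unit depth)."""
        jf, if_ = self.fluid_cells
        uc = 0.5 * (self.U[jf, if_] + self.U[jf, if_ + 1])
        vc = 0.5 * (self.V[jf, if_] + self.V[jf + 1, if_])
        vol = self.mesh.cell_measures.reshape(self.ny, self.nx)[jf, if_]
        return float(0.5 * self.rho * np.sum((uc**2 + vc**2) * vol))

    def inlet_flux(self) -> float:
        return float(np.sum(self.U[self.inlet_rows, 0] * self.dy[self.inlet_rows]))

    def outlet_flux(self) -> float:
        return float(np.sum(self.U[self.outlet_rows, self.nx] * self.dy[self.outlet_rows]))

    def run_steady(self, inlet_speed: float, dt: float | None = None,
                   tol: float = 1e-8, max_steps: int = 200000) -> FlowState:
        """March to steady state at a constant inflow."""
        state = None
        for _ in range(max_steps):
            step_dt = dt if dt is not None else self.cfl_dt_for(inlet_speed)
            prev = self.U.copy()
            state = self.step(step_dt, inlet_speed)
            if np.max(np.abs(self.U - prev)) < tol * max(inlet_speed, 1e-12):
                return state
        warnings.warn("steady flow iteration hit max_steps", stacklevel=2)
        return state

    def cfl_dt_for(self, speed: float) -> float:
        """Stable step for a prospective inflow speed."""
        umax = max(float(np.abs(self.U).max()), float(np.abs(self.V).max()),
                   abs(speed) * self.inlet_scale, 1e-12)
        adv = min(self.dx.min(), self.dy.min()) / umax
        visc = min(self.dx.min(), self.dy.min()) ** 2 / (4.0 * self.nu)
        return 0.8 * min(adv, visc)

    def run_cycle(self, waveform, n_cycles: int = 2, store_dt: float = 5e-3,
                  safety: float = 2.0) -> CycleVelocity:
        """Advance ``n_cycles`` cardiac cycles and store the last one.

        The step size is chosen from the waveform peak with a margin for
        internal acceleration; snapshots of the final cycle are stored
        every ``store_dt`` for periodic replay by the thermal advection.
        """
        cycle = waveform.cycle_duration
        peak = float(np.max(waveform.speeds)) * max(self.inlet_scale, 1.0)
        dmin = min(self.dx.min(), self.dy.min())
        dt = min(0.8 * dmin / (safety * max(peak, 1e-12)),
                 0.2 * dmin**2 / self.nu, store_dt)
        n_steps = int(np.ceil(cycle / dt))
        dt = cycle / n_steps

        times, snaps_u, snaps_v = [], [], []
        max_speed = 0.0
        stride = max(1, int(round(store_dt / dt)))
        t = 0.0
        for c in range(n_cycles):
            for k in range(n_steps):
                self.step(dt, float(waveform(t)), time=t)
                t += dt
                if c == n_cycles - 1 and (k + 1) % stride == 0:
                    times.append(t % cycle if (t % cycle) > 1e-12 else 0.0)
                    snaps_u.append(self.U.copy())
                    snaps_v.append(self.V.copy())
                    speed = max(float(np.abs(self.U).max()), float(np.abs(self.V).max()))
                    max_speed = max(max_speed, speed)
        order = np.argsort(times)
        return CycleVelocity(
            times=np.asarray(times)[order],
            face_u=np.asarray(snaps_u)[order],
            face_v=np.asarray(snaps_v)[order],
            cycle_duration=cycle,
            max_speed=max_speed,
        )


def advective_term(mesh: SimMesh, materials: MaterialSet,
                   velocity: np.ndarray, temp_c: np.ndarray) -> np.ndarray:
    """Convective heat sink rho c (u . grad T) per cell, W/m^3.

    Nonzero only in blood cells; gradients by central differences on the
    cell-centre grid (one-sided at domain edges), exact for linear T.
    """
    nx, ny = mesh.nx, mesh.ny
    t = np.asarray(temp_c, dtype=float).reshape(ny, nx)
    vel = np.asarray(velocity, dtype=float).reshape(ny, nx, 2)
    xc = 0.5 * (mesh.x_edges[:-1] + mesh.x_edges[1:])
    yc = 0.5 * (mesh.y_edges[:-1] + mesh.y_edges[1:])

    def _grad(f, coords, axis):
        # central differences of neighbour values: exact for linear fields
        # and exactly zero for constants (unlike the weighted three-point
        # formula, whose coefficients round unevenly on nonuniform grids)
        f = np.moveaxis(f, axis, 0)
        g = np.empty_like(f)
        g[1:-1] = (f[2:] - f[:-2]) / (coords[2:] - coords[:-2])[:, None]
        g[0] = (f[1] - f[0]) / (coords[1] - coords[0])
        g[-1] = (f[-1] - f[-2]) / (coords[-1] - coords[-2])
        return np.moveaxis(g, 0, axis)

    gx = _grad(t, xc, axis=1)
    gy = _grad(t, yc, axis=0)
    rhoc = materials.blood.volumetric_heat_capacity
    out = rhoc * (vel[:, :, 0] * gx + vel[:, :, 1] * gy)
    out[mesh.region_grid != int(Region.BLOOD)] = 0.0
    return out.ravel()
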
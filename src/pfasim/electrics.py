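"""Quasi-static electric potential solve with nonlinear conductivity.

The potential obeys the generalized Laplace equation div(sigma grad V)=0
with the pulse amplitude applied on the left (active) electrode, ground
on the right, and zero flux elsewhere.  Myocardial conductivity depends
on the local field magnitude (electroporation sigmoid) and temperature,
so the solve is a fixed-point iteration: solve V with frozen per-cell
sigma, recover the per-cell field, update sigma(E, T), repeat.

Discretisation: vertex-centred finite volumes (box scheme) on the
tensor-product grid, with nodal V and piecewise-constant per-cell sigma
and E.  For uniform sigma and spacing the scheme reduces exactly to the
classical 5-point stencil.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .domain import Region, SimMesh
from .materials import MaterialSet

__all__ = ["PotentialSolution", "SolverError", "solve_potential", "joule_source",
           "cell_sigma_map"]


class SolverError(RuntimeError):
    """Nonlinear iteration failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class PotentialSolution:
    """Converged potential field and derived per-cell quantities."""

    V: np.ndarray  # nodal potential, volts
    E_mag: np.ndarray  # per-cell field magnitude, V/m
    sigma_cell: np.ndarray  # per-cell conductivity, S/m
    Q: np.ndarray  # per-cell Joule source, W/m^3
    iterations: int
    residual: float
    amplitude: float


def cell_sigma_map(mesh: SimMesh, materials: MaterialSet,
                   e_mag: np.ndarray | float = 0.0,
                   temp_c: np.ndarray | float = 37.0) -> np.ndarray:
    """Per-cell electrical conductivity for the current field/temperature."""
    sigma = np.empty(mesh.n_cells)
    reg = mesh.region
    sigma[reg == Region.BLOOD] = materials.blood.electrical_conductivity
    sigma[reg == Region.INSULATOR] = materials.insulator.electrical_conductivity
    for r in (Region.ELECTRODE_LEFT, Region.ELECTRODE_RIGHT):
        sigma[reg == r] = materials.electrode.electrical_conductivity
    myo = reg == Region.MYOCARDIUM
    e = np.broadcast_to(np.asarray(e_mag, dtype=float), (mesh.n_cells,))
    t = np.broadcast_to(np.asarray(temp_c, dtype=float), (mesh.n_cells,))
    sigma[myo] = materials.sigma_field_temp(e[myo], t[myo])
    return sigma


def _electrode_nodes(mesh: SimMesh) -> tuple[np.ndarray, np.ndarray]:
    """Node sets of the active (left) and ground (right) electrodes."""
    active = np.unique(mesh.cells[mesh.region == Region.ELECTRODE_LEFT].ravel())
    ground = np.unique(mesh.cells[mesh.region == Region.ELECTRODE_RIGHT].ravel())
    return active, ground


def _assemble(mesh: SimMesh, sigma: np.ndarray) -> sp.csr_matrix:
    """Box-scheme conductance matrix on the tensor grid (nodal unknowns)."""
    nx, ny = mesh.nx, mesh.ny
    dx, dy = mesh.dx, mesh.dy
    sig = sigma.reshape(ny, nx)
    n_nodes = (nx + 1) * (ny + 1)

    def nid(i, j):
        return j * (nx + 1) + i

    rows, cols, vals = [], [], []

    # horizontal links (i,j)-(i+1,j): conductance from the cells above/below
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny + 1))
    g = np.zeros((ny + 1, nx))
    g[1:, :] += sig * (dy[:, None] / 2.0)  # cell below the node row
    g[:-1, :] += sig * (dy[:, None] / 2.0)  # cell above
    g = g / dx[None, :]
    a = nid(ii, jj).ravel()
    b = nid(ii + 1, jj).ravel()
    gv = g.ravel()
    rows += [a, b, a, b]
    cols += [b, a, a, b]
    vals += [-gv, -gv, gv, gv]

    # vertical links (i,j)-(i,j+1)
    ii, jj = np.meshgrid(np.arange(nx + 1), np.arange(ny))
    g = np.zeros((ny, nx + 1))
    g[:, 1:] += sig * (dx[None, :] / 2.0)  # cell left of the node column
    g[:, :-1] += sig * (dx[None, :] / 2.0)  # cell right
    g = g / dy[:, None]
    a = nid(ii, jj).ravel()
    b = nid(ii, jj + 1).ravel()
    gv = g.ravel()
    rows += [a, b, a, b]
    cols += [b, a, a, b]
    vals += [-gv, -gv, gv, gv]

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n_nodes, n_nodes))


def _cell_field(mesh: SimMesh, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (Ex, Ey) from the bilinear interpolant at cell centres."""
    nx, ny = mesh.nx, mesh.ny
    vg = v.reshape(ny + 1, nx + 1)
    dx, dy = mesh.dx, mesh.dy
    ex = -((vg[:-1, 1:] + vg[1:, 1:]) - (vg[:-1, :-1] + vg[1:, :-1])) / (2 * dx[None, :])
    ey = -((vg[1:, :-1] + vg[1:, 1:]) - (vg[:-1, :-1] + vg[:-1, 1:])) / (2 * dy[:, None])
    return ex.ravel(), ey.ravel()


def solve_potential(
    mesh: SimMesh,
    materials: MaterialSet,
    temp_c: np.ndarray | float = 37.0,
    amplitude: float = 1000.0,
    tol: float = 1e-6,
    max_iter: int = 80,
    e_init: np.ndarray | None = None,
) -> PotentialSolution:
    """Solve div(sigma grad V) = 0 with the sigma(E, T) fixed point.

    The iteration starts from sigma(E_init, T) (``e_init`` defaults to
    zero field), solves the linear problem, updates the per-cell field
    and conductivity, and stops when the relative change of the field
    magnitude drops below ``tol``.  The electroporation sigmoid is steep
    enough to make the plain iteration cycle, so the sigma update uses
    Aitken (Irons-Tuck) dynamic relaxation on the sigma residual,
    clipped to [0.05, 1].
    """
    if mesh.dim != 2:
        raise NotImplementedError("potential solve operates on planar sections")
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    temp_c = np.broadcast_to(np.asarray(temp_c, dtype=float), (mesh.n_cells,)).copy()
    if not np.all(np.isfinite(temp_c)):
        raise ValueError("temperature field must be finite")

    active, ground = _electrode_nodes(mesh)
    n_nodes = mesh.node_coords.shape[0]
    fixed = np.zeros(n_nodes, dtype=bool)
    fixed[active] = True
    fixed[ground] = True
    v_fixed = np.zeros(n_nodes)
    v_fixed[active] = amplitude
    free = ~fixed

    e0 = 0.0 if e_init is None else e_init
    sigma = cell_sigma_map(mesh, materials, e0, temp_c)
    e_prev = None
    r_prev = None
    relax = 0.5
    myo = mesh.region == Region.MYOCARDIUM

    v = None
    for it in range(1, max_iter + 1):
        lap = _assemble(mesh, sigma)
        rhs = -lap[:, fixed] @ v_fixed[fixed]
        v = v_fixed.copy()
        if free.any():
            a_ff = lap[free][:, free].tocsc()
            v[free] = spla.spsolve(a_ff, rhs[free])
        ex, ey = _cell_field(mesh, v)
        e_mag = np.hypot(ex, ey)

        if e_prev is None:
            change = np.inf
        else:
            scale = max(float(e_mag.max()), 1e-30)
            change = float(np.max(np.abs(e_mag - e_prev)) / scale)
        if change < tol or amplitude == 0.0:
            break
        sigma_new = sigma.copy()
        sigma_new[myo] = materials.sigma_field_temp(e_mag[myo], temp_c[myo])
        residual = sigma_new - sigma
        if r_prev is not None:
            dr = residual - r_prev
            denom = float(dr @ dr)
            if denom > 0.0:
                relax = float(np.clip(-relax * (r_prev @ dr) / denom, 0.05, 1.0))
        sigma = sigma + relax * residual
        r_prev = residual
        e_prev = e_mag
    else:
        raise SolverError(
            f"sigma(E) fixed point did not converge in {max_iter} iterations",
            residual=change,
        )

    residual = _linear_residual(mesh, sigma, v, free)
    sol = PotentialSolution(
        V=v, E_mag=e_mag, sigma_cell=sigma, Q=sigma * e_mag**2,
        iterations=it, residual=residual, amplitude=amplitude,
    )
    return sol


def _linear_residual(mesh: SimMesh, sigma: np.ndarray, v: np.ndarray,
                     free: np.ndarray) -> float:
    lap = _assemble(mesh, sigma)
    r = lap @ v
    scale = max(float(np.abs(lap.diagonal()).max() * np.abs(v).max()), 1e-30)
    return float(np.max(np.abs(r[free])) / scale)


def joule_source(solution: PotentialSolution) -> np.ndarray:
    """Volumetric Joule heat source Q = sigma |E|^2 per cell (W/m^3)."""
    return solution.sigma_cell * solution.E_mag**2


def electrode_power(mesh: SimMesh, solution: PotentialSolution) -> float:
    """Power delivered through the active electrode, amplitude x current."""
    lap = _assemble(mesh, solution.sigma_cell)
    active, _ = _electrode_nodes(mesh)
    # net nodal current out of the active electrode set
    current = (lap @ solution.V)[active].sum()
    return float(solution.amplitude * current)
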
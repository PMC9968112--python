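"""Synthetic tissue-blood-catheter geometries and pulsatile inflow waveforms.

The full-anatomy left atrium is replaced by a planar-2D longitudinal
section through the catheter axis: a myocardial slab (wall thickness
~2.4 mm) at the bottom, a blood channel above it, and a two-electrode
catheter (7 F, 2 mm electrodes separated by a 2.5 mm insulated gap)
lying parallel to the tissue surface, sunk 1 mm into the endocardium.
"Volumes" reported from a planar mesh are areas times an extrusion
depth (default: the catheter diameter).

Meshes are tensor-product (rectilinear) grids of quadrilateral cells
with local refinement around the catheter, which keeps every downstream
solver a structured sparse problem while the cell sizes near the
catheter honour the 0.4-1.0 mm element-size band of the mesh
sensitivity study.  An optional extruded 3-D slab is provided for
geometry/IO work; the solver stack operates on the planar section.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Region",
    "Boundary",
    "GeometryParams",
    "SimMesh",
    "WaveformProfile",
    "make_domain",
    "make_waveform",
    "uniform_block",
    "GeometryError",
]

FRENCH = 1e-3 / 3.0  # 1 F = 1/3 mm


class GeometryError(ValueError):
    """Invalid or degenerate geometry configuration."""


class Region(enum.IntEnum):
    MYOCARDIUM = 0
    BLOOD = 1
    ELECTRODE_LEFT = 2
    ELECTRODE_RIGHT = 3
    INSULATOR = 4


class Boundary(enum.IntEnum):
    ELECTRODE_ACTIVE = 0
    ELECTRODE_GROUND = 1
    EPICARDIUM = 2
    SHAFT = 3
    BLOOD_MYO_INTERFACE = 4
    BLOOD_CATH_INTERFACE = 5
    INLET = 6
    OUTLET = 7
    WALL = 8


CATHETER_REGIONS = (Region.ELECTRODE_LEFT, Region.ELECTRODE_RIGHT, Region.INSULATOR)


@dataclass(frozen=True)
class GeometryParams:
    """Parametric description of the slab-channel-catheter section.

    Lengths in metres.  ``domain_extent`` is ``(length, height)`` of the
    whole section; when ``None`` the height is wall thickness plus blood
    channel height and the length defaults to 24 mm.
    """

    wall_thickness: float = 2.4e-3
    electrode_length: float = 2e-3
    gap_length: float = 2.5e-3
    catheter_diameter: float = 7 * FRENCH
    insertion_depth: float = 1e-3
    shaft_length: float = 2e-3  # insulated shaft on the proximal side
    tip_electrode: bool = True  # distal electrode is the bare catheter tip
    blood_channel_height: float = 8e-3
    domain_length: float = 24e-3
    target_cell_size: tuple[float, float] = (0.4e-3, 1.0e-3)
    refine_margin: float = 2e-3  # extent of the fine zone around the catheter
    dimensionality: str = "planar2d"  # or "slab3d"
    extrusion_depth: float | None = None  # planar2d volume convention
    n_layers_3d: int = 3

    def __post_init__(self) -> None:
        for name in ("wall_thickness", "electrode_length", "gap_length",
                     "catheter_diameter", "blood_channel_height",
                     "domain_length", "refine_margin", "shaft_length"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.insertion_depth < 0 or self.insertion_depth >= self.wall_thickness:
            raise GeometryError("insertion depth must be in [0, wall thickness)")
        hmin, hmax = self.target_cell_size
        if not (0 < hmin <= hmax):
            raise GeometryError("cell size band must satisfy 0 < min <= max")
        if self.dimensionality not in ("planar2d", "slab3d"):
            raise GeometryError(f"unknown dimensionality {self.dimensionality!r}")
        protrusion = self.catheter_diameter - self.insertion_depth
        if self.blood_channel_height <= protrusion:
            raise GeometryError(
                "blood channel is thinner than the catheter protrusion "
                f"({self.blood_channel_height * 1e3:.2f} mm <= {protrusion * 1e3:.2f} mm)"
            )
        if self.catheter_length + 2 * self.refine_margin >= self.domain_length:
            raise GeometryError("domain length too short for the catheter")

    @property
    def catheter_length(self) -> float:
        n_shafts = 1 if self.tip_electrode else 2
        return n_shafts * self.shaft_length + 2 * self.electrode_length + self.gap_length

    @property
    def domain_extent(self) -> tuple[float, float]:
        return (self.domain_length, self.wall_thickness + self.blood_channel_height)

    @property
    def volume_depth(self) -> float:
        """Out-of-plane depth used to convert planar areas to volumes."""
        return self.extrusion_depth if self.extrusion_depth is not None else self.catheter_diameter


@dataclass
class SimMesh:
    """Discretised simulation domain with region and boundary labels.

    Cells are quadrilaterals (planar2d) or hexahedra (slab3d) of a
    tensor-product grid; ``region`` labels every cell, ``facets`` lists
    exterior edges plus interior interface facets with a
    :class:`Boundary` label each.  The rectilinear edge coordinates are
    retained so structured solvers can work directly on the grid.
    """

    node_coords: np.ndarray  # (n_nodes, dim)
    cells: np.ndarray  # (n_cells, 4) or (n_cells, 8)
    region: np.ndarray  # (n_cells,)
    facets: np.ndarray  # (n_facets, 2) or (n_facets, 4)
    facet_label: np.ndarray  # (n_facets,)
    facet_cells: np.ndarray  # (n_facets, 2), -1 = exterior side
    cell_measures: np.ndarray  # m^2 (2D) or m^3 (3D)
    x_edges: np.ndarray
    y_edges: np.ndarray
    z_edges: np.ndarray | None = None
    extrusion_depth: float = 7 * FRENCH

    @property
    def dim(self) -> int:
        return self.node_coords.shape[1]

    @property
    def nx(self) -> int:
        return len(self.x_edges) - 1

    @property
    def ny(self) -> int:
        return len(self.y_edges) - 1

    @property
    def nz(self) -> int:
        return 0 if self.z_edges is None else len(self.z_edges) - 1

    @property
    def n_cells(self) -> int:
        return len(self.region)

    @property
    def region_grid(self) -> np.ndarray:
        """Region labels as an (ny, nx) [or (nz, ny, nx)] array."""
        if self.dim == 2:
            return self.region.reshape(self.ny, self.nx)
        return self.region.reshape(self.nz, self.ny, self.nx)

    @property
    def dx(self) -> np.ndarray:
        return np.diff(self.x_edges)

    @property
    def dy(self) -> np.ndarray:
        return np.diff(self.y_edges)

    @property
    def cell_centers(self) -> np.ndarray:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        if self.dim == 2:
            gx, gy = np.meshgrid(xc, yc)
            return np.column_stack([gx.ravel(), gy.ravel()])
        zc = 0.5 * (self.z_edges[:-1] + self.z_edges[1:])
        gz, gy, gx = np.meshgrid(zc, yc, xc, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def region_measure(self, region: Region) -> float:
        """Total measure (area or volume) of one region."""
        return float(self.cell_measures[self.region == int(region)].sum())

    def cell_volumes(self) -> np.ndarray:
        """Cell volumes in m^3 (planar cells: area x extrusion depth)."""
        if self.dim == 2:
            return self.cell_measures * self.extrusion_depth
        return self.cell_measures

    def facets_of(self, label: Boundary) -> np.ndarray:
        """Indices of facets carrying the given boundary label."""
        return np.flatnonzero(self.facet_label == int(label))

    def facet_measures(self) -> np.ndarray:
        """Length (2D) or area (3D) of every facet."""
        pts = self.node_coords[self.facets]
        if self.facets.shape[1] == 2:
            return np.linalg.norm(pts[:, 1] - pts[:, 0], axis=1)
        # planar axis-aligned quads: product of the two nonzero extents
        lo = pts.min(axis=1)
        hi = pts.max(axis=1)
        ext = hi - lo
        ext = np.sort(ext, axis=1)[:, 1:]  # drop the zero (in-plane) extent
        return ext[:, 0] * ext[:, 1]

    def validate(self) -> None:
        """Check the structural invariants; raise GeometryError on failure."""
        if np.any(self.cell_measures <= 0):
            raise GeometryError("nonpositive cell measure")
        total = float(self.cell_measures.sum())
        extent = (self.x_edges[-1] - self.x_edges[0]) * (self.y_edges[-1] - self.y_edges[0])
        if self.z_edges is not None:
            extent *= self.z_edges[-1] - self.z_edges[0]
        if abs(total - extent) > 1e-10 * extent:
            raise GeometryError("region measures do not tile the domain")
        interior = self.facet_cells.min(axis=1) >= 0
        pairs = self.facet_cells[interior]
        ra = self.region[pairs[:, 0]]
        rb = self.region[pairs[:, 1]]
        if np.any(ra == rb):
            raise GeometryError("interior facet between same-region cells")


# --------------------------------------------------------------------------
# grid construction


def _subdivide(length: float, target: float, hmin: float, hmax: float) -> int:
    """Number of equal sub-intervals for a segment, keeping h <= hmax and,
    where possible, h >= hmin."""
    if length <= 0:
        return 0
    n = max(1, round(length / target))
    n_min = int(math.ceil(length / hmax - 1e-12))  # ensures h <= hmax
    n_max = int(math.floor(length / hmin + 1e-12))  # ensures h >= hmin
    n = max(n, n_min)
    if n_max >= n_min:
        n = min(n, n_max)
    return max(n, 1)


def _segment_edges(breaks: list[float], fine: list[bool], hmin: float, hmax: float) -> np.ndarray:
    edges = [breaks[0]]
    for a, b, is_fine in zip(breaks[:-1], breaks[1:], fine):
        if b - a <= 1e-12:
            continue
        n = _subdivide(b - a, hmin if is_fine else hmax, hmin, hmax)
        edges.extend(a + (b - a) * k / n for k in range(1, n + 1))
    return np.asarray(edges)


def _classify_pair(ra: int, rb: int) -> int | None:
    """Boundary label of an interior facet between two different regions."""
    if ra == rb:
        return None
    pair = {ra, rb}
    blood, myo = int(Region.BLOOD), int(Region.MYOCARDIUM)
    el, er, ins = int(Region.ELECTRODE_LEFT), int(Region.ELECTRODE_RIGHT), int(Region.INSULATOR)
    if pair == {blood, myo}:
        return int(Boundary.BLOOD_MYO_INTERFACE)
    if pair <= {el, er, ins}:
        return None  # internal catheter joint, not a boundary
    if el in pair:
        return int(Boundary.ELECTRODE_ACTIVE)
    if er in pair:
        return int(Boundary.ELECTRODE_GROUND)
    if pair == {myo, ins}:
        return int(Boundary.SHAFT)
    if pair == {blood, ins}:
        return int(Boundary.BLOOD_CATH_INTERFACE)
    return None


def make_domain(params: GeometryParams | None = None) -> SimMesh:
    """Build the labelled tissue-blood-catheter mesh.

    The catheter axis is horizontal (parallel to the epicardium at the
    bottom of the slab) and sunk ``insertion_depth`` into the tissue;
    grid lines are snapped to every material boundary so region measures
    are exact, and the cells near the catheter honour the configured
    size band.
    """
    p = params if params is not None else GeometryParams()
    hmin, hmax = p.target_cell_size
    lx, ly = p.domain_extent
    wall = p.wall_thickness

    x0 = (lx - p.catheter_length) / 2.0
    segments = [(p.electrode_length, int(Region.ELECTRODE_LEFT)),
                (p.gap_length, int(Region.INSULATOR)),
                (p.electrode_length, int(Region.ELECTRODE_RIGHT)),
                (p.shaft_length, int(Region.INSULATOR))]
    if not p.tip_electrode:
        segments.insert(0, (p.shaft_length, int(Region.INSULATOR)))
    xb = [x0]
    for length, _ in segments:
        xb.append(xb[-1] + length)
    x_breaks = [0.0, max(0.0, x0 - p.refine_margin), *xb,
                min(lx, xb[-1] + p.refine_margin), lx]
    x_fine = [False] + [True] * (len(xb) + 1) + [False]

    y_bot = wall - p.insertion_depth  # catheter underside
    y_top = y_bot + p.catheter_diameter  # catheter top
    y_breaks = [0.0, y_bot, wall, y_top, min(ly, y_top + p.refine_margin), ly]
    y_fine = [True, True, True, True, False]
    # deduplicate (insertion_depth = 0 makes y_bot == wall)
    yb, yf = [y_breaks[0]], []
    for b, f in zip(y_breaks[1:], y_fine):
        if b - yb[-1] > 1e-12:
            yb.append(b)
            yf.append(f)

    x_edges = _segment_edges(x_breaks, x_fine, hmin, hmax)
    y_edges = _segment_edges(yb, yf, hmin, hmax)
    nx, ny = len(x_edges) - 1, len(y_edges) - 1

    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    region = np.empty((ny, nx), dtype=np.int32)
    in_cath_x = (xc >= xb[0]) & (xc <= xb[-1])
    seg = np.full(nx, -1, dtype=np.int32)
    for (length, label), a, b in zip(segments, xb[:-1], xb[1:]):
        seg[(xc > a) & (xc < b)] = label
    for j in range(ny):
        y = yc[j]
        if y < y_bot:
            region[j, :] = int(Region.MYOCARDIUM)
        elif y < y_top:
            base = int(Region.MYOCARDIUM) if y < wall else int(Region.BLOOD)
            row = np.where(in_cath_x & (seg >= 0), seg, base)
            region[j, :] = row
        else:
            region[j, :] = int(Region.BLOOD)

    mesh = _assemble_2d(x_edges, y_edges, region, p.volume_depth)
    if p.dimensionality == "slab3d":
        mesh = _extrude(mesh, p)

    present = set(np.unique(mesh.region).tolist())
    missing = [r.name for r in Region if int(r) not in present]
    if missing:
        raise GeometryError(f"regions missing from mesh: {missing}")
    mesh.validate()
    return mesh


def _assemble_2d(x_edges: np.ndarray, y_edges: np.ndarray,
                 region: np.ndarray, extrusion: float) -> SimMesh:
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    gx, gy = np.meshgrid(x_edges, y_edges)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])

    def nid(i, j):
        return j * (nx + 1) + i

    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny))
    ii, jj = ii.ravel(), jj.ravel()
    cells = np.column_stack([nid(ii, jj), nid(ii + 1, jj),
                             nid(ii + 1, jj + 1), nid(ii, jj + 1)])
    dx = np.diff(x_edges)
    dy = np.diff(y_edges)
    measures = np.outer(dy, dx).ravel()

    facets, labels, adj = [], [], []

    def cid(i, j):
        return j * nx + i

    blood = int(Region.BLOOD)
    # vertical faces (normal along x)
    for j in range(ny):
        for i in range(nx + 1):
            a, b = nid(i, j), nid(i, j + 1)
            if i == 0:
                lab = Boundary.INLET if region[j, 0] == blood else Boundary.WALL
                facets.append((a, b)); labels.append(int(lab)); adj.append((-1, cid(0, j)))
            elif i == nx:
                lab = Boundary.OUTLET if region[j, nx - 1] == blood else Boundary.WALL
                facets.append((a, b)); labels.append(int(lab)); adj.append((cid(nx - 1, j), -1))
            else:
                lab = _classify_pair(region[j, i - 1], region[j, i])
                if lab is not None:
                    facets.append((a, b)); labels.append(lab)
                    adj.append((cid(i - 1, j), cid(i, j)))
    # horizontal faces (normal along y)
    for j in range(ny + 1):
        for i in range(nx):
            a, b = nid(i, j), nid(i + 1, j)
            if j == 0:
                facets.append((a, b)); labels.append(int(Boundary.EPICARDIUM))
                adj.append((-1, cid(i, 0)))
            elif j == ny:
                facets.append((a, b)); labels.append(int(Boundary.WALL))
                adj.append((cid(i, ny - 1), -1))
            else:
                lab = _classify_pair(region[j - 1, i], region[j, i])
                if lab is not None:
                    facets.append((a, b)); labels.append(lab)
                    adj.append((cid(i, j - 1), cid(i, j)))

    return SimMesh(
        node_coords=nodes,
        cells=cells.astype(np.int64),
        region=region.ravel().astype(np.int32),
        facets=np.asarray(facets, dtype=np.int64),
        facet_label=np.asarray(labels, dtype=np.int32),
        facet_cells=np.asarray(adj, dtype=np.int64),
        cell_measures=measures,
        x_edges=x_edges,
        y_edges=y_edges,
        extrusion_depth=extrusion,
    )


def _extrude(mesh2d: SimMesh, p: GeometryParams) -> SimMesh:
    """Extrude the planar section into a coarse 3-D slab of hexahedra."""
    nz = max(1, p.n_layers_3d)
    depth = p.volume_depth
    z_edges = np.linspace(0.0, depth, nz + 1)
    nx, ny = mesh2d.nx, mesh2d.ny
    x_edges, y_edges = mesh2d.x_edges, mesh2d.y_edges

    gx = np.tile(np.tile(x_edges, ny + 1), nz + 1)
    gy = np.tile(np.repeat(y_edges, nx + 1), nz + 1)
    gz = np.repeat(z_edges, (nx + 1) * (ny + 1))
    nodes = np.column_stack([gx, gy, gz])
    npl = (nx + 1) * (ny + 1)  # nodes per layer

    def nid(i, j, k):
        return k * npl + j * (nx + 1) + i

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    ii, jj, kk = ii.ravel(), jj.ravel(), kk.ravel()
    # cell id = k*nx*ny + j*nx + i
    order = np.argsort(kk * nx * ny + jj * nx + ii)
    ii, jj, kk = ii[order], jj[order], kk[order]
    cells = np.column_stack([
        nid(ii, jj, kk), nid(ii + 1, jj, kk), nid(ii + 1, jj + 1, kk), nid(ii, jj + 1, kk),
        nid(ii, jj, kk + 1), nid(ii + 1, jj, kk + 1), nid(ii + 1, jj + 1, kk + 1),
        nid(ii, jj + 1, kk + 1),
    ])
    region3 = np.tile(mesh2d.region, nz)
    dz = np.diff(z_edges)
    measures = (np.tile(mesh2d.cell_measures, nz).reshape(nz, -1) * dz[:, None]).ravel()

    # facets: extrude every 2-D facet through each layer, plus front/back walls
    facets, labels, adj = [], [], []
    n2 = nx * ny
    for k in range(nz):
        for (a, b), lab, (ca, cb) in zip(mesh2d.facets, mesh2d.facet_label, mesh2d.facet_cells):
            ia, ja = a % (nx + 1), a // (nx + 1)
            ib, jb = b % (nx + 1), b // (nx + 1)
            facets.append((nid(ia, ja, k), nid(ib, jb, k), nid(ib, jb, k + 1), nid(ia, ja, k + 1)))
            labels.append(int(lab))
            adj.append((ca + k * n2 if ca >= 0 else -1, cb + k * n2 if cb >= 0 else -1))
    for j in range(ny):
        for i in range(nx):
            facets.append((nid(i, j, 0), nid(i + 1, j, 0), nid(i + 1, j + 1, 0), nid(i, j + 1, 0)))
            labels.append(int(Boundary.WALL)); adj.append((-1, j * nx + i))
            facets.append((nid(i, j, nz), nid(i + 1, j, nz), nid(i + 1, j + 1, nz), nid(i, j + 1, nz)))
            labels.append(int(Boundary.WALL)); adj.append(((nz - 1) * n2 + j * nx + i, -1))

    return SimMesh(
        node_coords=nodes,
        cells=cells.astype(np.int64),
        region=region3.astype(np.int32),
        facets=np.asarray(facets, dtype=np.int64),
        facet_label=np.asarray(labels, dtype=np.int32),
        facet_cells=np.asarray(adj, dtype=np.int64),
        cell_measures=measures,
        x_edges=x_edges,
        y_edges=y_edges,
        z_edges=z_edges,
        extrusion_depth=depth,
    )


def uniform_block(
    nx: int,
    ny: int,
    lx: float,
    ly: float,
    region: Region | np.ndarray = Region.MYOCARDIUM,
    extrusion_depth: float = 7 * FRENCH,
) -> SimMesh:
    """Uniform rectangular mesh of a single region (or a given label grid).

    A minimal fixture builder: exterior facets are labelled (epicardium
    at the bottom, walls or inlet/outlet at the sides following the
    same rules as :func:`make_domain`); interior interfaces are derived
    from the label grid.
    """
    x_edges = np.linspace(0.0, lx, nx + 1)
    y_edges = np.linspace(0.0, ly, ny + 1)
    if isinstance(region, Region) or np.isscalar(region):
        grid = np.full((ny, nx), int(region), dtype=np.int32)
    else:
        grid = np.asarray(region, dtype=np.int32)
        if grid.shape != (ny, nx):
            raise GeometryError("region grid shape must be (ny, nx)")
    return _assemble_2d(x_edges, y_edges, grid, extrusion_depth)


# --------------------------------------------------------------------------
# pulsatile inflow waveform


@dataclass(frozen=True)
class WaveformProfile:
    """Sampled pulsatile speed over one cardiac cycle.

    Biphasic E-wave / A-wave character: two smooth peaks per cycle with
    the early-diastolic E-peak at least as high as the atrial A-peak.
    ``speeds`` are uniform samples on [0, cycle); interpolation is
    periodic linear.
    """

    cycle_duration: float  # s
    times: np.ndarray  # s, uniform on [0, cycle)
    speeds: np.ndarray  # m/s
    mean_speed: float  # m/s, cycle average

    @property
    def samples(self) -> list[tuple[float, float]]:
        return list(zip(self.times.tolist(), self.speeds.tolist()))

    def __call__(self, t) -> float | np.ndarray:
        """Periodic linear interpolation of the speed at time(s) ``t``."""
        tt = np.mod(np.asarray(t, dtype=float), self.cycle_duration)
        tp = np.concatenate([self.times, [self.cycle_duration]])
        sp = np.concatenate([self.speeds, [self.speeds[0]]])
        out = np.interp(tt, tp, sp)
        return out if out.ndim else float(out)

    def local_maxima_count(self) -> int:
        """Number of strict local maxima of the cyclic sample sequence."""
        s = self.speeds
        return int(np.sum((s > np.roll(s, 1)) & (s > np.roll(s, -1))))

    def peak_speeds(self) -> np.ndarray:
        """Speeds at the strict local maxima, descending."""
        s = self.speeds
        m = (s > np.roll(s, 1)) & (s > np.roll(s, -1))
        return np.sort(s[m])[::-1]

    def rescaled(self, factor: float) -> "WaveformProfile":
        return WaveformProfile(self.cycle_duration, self.times,
                               self.speeds * factor, self.mean_speed * factor)

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.times, self.speeds])
        np.savetxt(path, arr, delimiter=",", header="time_s,speed_m_per_s", comments="")

    @classmethod
    def from_csv(cls, path) -> "WaveformProfile":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        times, speeds = arr[:, 0], arr[:, 1]
        dt = times[1] - times[0]
        cycle = times[-1] + dt
        return cls(cycle, times, speeds, float(speeds.mean()))


def make_waveform(
    cycle_duration: float = 0.8,
    mean_speed: float = 0.1522,
    e_to_a_ratio: float = 1.5,
    n_samples: int = 64,
) -> WaveformProfile:
    """Synthesize a biphasic E/A pulsatile speed profile.

    Two periodic smooth bumps (von-Mises shape) centred in early and
    late diastole, with peak-height ratio ``e_to_a_ratio`` (E over A)
    and the requested cycle-mean speed (default 15.22 cm/s, the mean
    speed at the ablation site over a cardiac cycle).  The functional
    form is a modelling choice: only the biphasic character and the
    cycle mean are constrained by the physiology being emulated.
    """
    if mean_speed <= 0:
        raise ValueError("mean speed must be positive")
    if e_to_a_ratio < 1:
        raise ValueError("E/A ratio must be >= 1")
    if n_samples < 8:
        raise ValueError("n_samples must be >= 8")

    t = np.arange(n_samples) * (cycle_duration / n_samples)
    phase = 2 * np.pi * t / cycle_duration
    # E-wave: broad bump in early diastole; A-wave: narrow late bump
    c_e, kappa_e = 2 * np.pi * 0.45, 6.0
    c_a, kappa_a = 2 * np.pi * 0.85, 14.0
    bump_e = np.exp(kappa_e * (np.cos(phase - c_e) - 1.0))
    bump_a = np.exp(kappa_a * (np.cos(phase - c_a) - 1.0))
    raw = bump_e + bump_a / e_to_a_ratio
    speeds = raw * (mean_speed / raw.mean())
    return WaveformProfile(cycle_duration, t, speeds, mean_speed)
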
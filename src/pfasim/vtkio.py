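"""Mesh and field I/O in legacy VTK ASCII (UNSTRUCTURED_GRID).

Volume cells (quads / hexahedra) and labelled boundary facets (lines /
quads) are stored together; per-entity integer arrays ``region`` and
``boundary`` carry the labels (-1 where not applicable), and the
rectilinear edge coordinates travel in a FIELD block so the structured
view of the mesh survives a round trip exactly.  Numbers are written
with 17 significant digits, so coordinates round-trip bit-exactly.
"""

from __future__ import annotations

import numpy as np

from .domain import SimMesh

__all__ = ["write_mesh", "read_mesh", "write_fields", "MeshFormatError"]

VTK_LINE = 3
VTK_QUAD = 9
VTK_HEX = 12


class MeshFormatError(ValueError):
    """Malformed or incomplete mesh file."""


def _fmt(arr: np.ndarray) -> str:
    return "\n".join(" ".join(f"{v:.17g}" for v in row) for row in arr)


def write_mesh(mesh: SimMesh, path) -> None:
    """Write a labelled mesh as legacy VTK ASCII."""
    pts = mesh.node_coords
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    n_cells, n_fac = len(mesh.cells), len(mesh.facets)
    cell_type = VTK_QUAD if mesh.cells.shape[1] == 4 else VTK_HEX
    facet_type = VTK_LINE if mesh.facets.shape[1] == 2 else VTK_QUAD

    lines = [
        "# vtk DataFile Version 3.0",
        "pfasim mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(pts)} double",
        _fmt(pts),
    ]
    total = n_cells + n_fac
    size = n_cells * (mesh.cells.shape[1] + 1) + n_fac * (mesh.facets.shape[1] + 1)
    lines.append(f"CELLS {total} {size}")
    for row in mesh.cells:
        lines.append(f"{len(row)} " + " ".join(map(str, row)))
    for row in mesh.facets:
        lines.append(f"{len(row)} " + " ".join(map(str, row)))
    lines.append(f"CELL_TYPES {total}")
    lines.extend([str(cell_type)] * n_cells)
    lines.extend([str(facet_type)] * n_fac)

    region = np.concatenate([mesh.region, np.full(n_fac, -1, dtype=np.int64)])
    boundary = np.concatenate([np.full(n_cells, -1, dtype=np.int64), mesh.facet_label])
    fc_minus = np.concatenate([np.full(n_cells, -2, dtype=np.int64), mesh.facet_cells[:, 0]])
    fc_plus = np.concatenate([np.full(n_cells, -2, dtype=np.int64), mesh.facet_cells[:, 1]])
    lines.append(f"CELL_DATA {total}")
    for name, arr in (("region", region), ("boundary", boundary),
                      ("facet_cell_minus", fc_minus), ("facet_cell_plus", fc_plus)):
        lines.append(f"SCALARS {name} int 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(map(str, arr.tolist()))

    z = mesh.z_edges if mesh.z_edges is not None else np.empty(0)
    lines.append("FIELD grid 4")
    for name, arr in (("x_edges", mesh.x_edges), ("y_edges", mesh.y_edges), ("z_edges", z)):
        lines.append(f"{name} 1 {len(arr)} double")
        if len(arr):
            lines.append(" ".join(f"{v:.17g}" for v in arr))
    lines.append("extrusion_depth 1 1 double")
    lines.append(f"{mesh.extrusion_depth:.17g}")

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_tokens(path) -> list[str]:
    with open(path) as fh:
        text = fh.read()
    return text.split()


def read_mesh(path) -> SimMesh:
    """Read a mesh written by :func:`write_mesh`."""
    tok = _read_tokens(path)
    pos = 0

    def find(keyword: str) -> int:
        try:
            return tok.index(keyword, pos)
        except ValueError as exc:
            raise MeshFormatError(f"missing {keyword} section") from exc

    pos = find("POINTS")
    n_pts = int(tok[pos + 1])
    coords = np.array(tok[pos + 3: pos + 3 + 3 * n_pts], dtype=float).reshape(n_pts, 3)
    pos = find("CELLS")
    total = int(tok[pos + 1])
    p = pos + 3
    conn = []
    for _ in range(total):
        n = int(tok[p])
        conn.append([int(v) for v in tok[p + 1: p + 1 + n]])
        p += n + 1
    pos = find("CELL_TYPES")
    types = np.array(tok[pos + 2: pos + 2 + total], dtype=int)

    def read_scalar(name: str) -> np.ndarray:
        try:
            i = tok.index(name)
        except ValueError as exc:
            raise MeshFormatError(f"missing '{name}' cell data array") from exc
        # tokens: <name> int 1 LOOKUP_TABLE default <values...>
        start = i + 5
        return np.array(tok[start: start + total], dtype=np.int64)

    region_all = read_scalar("region")
    boundary_all = read_scalar("boundary")
    fcm = read_scalar("facet_cell_minus")
    fcp = read_scalar("facet_cell_plus")

    def read_field(name: str) -> np.ndarray:
        i = tok.index(name)
        n = int(tok[i + 2])
        return np.array(tok[i + 4: i + 4 + n], dtype=float)

    x_edges = read_field("x_edges")
    y_edges = read_field("y_edges")
    z_edges = read_field("z_edges")
    extrusion = float(read_field("extrusion_depth")[0])

    is_volume = (types == VTK_HEX) if VTK_HEX in types else (types == VTK_QUAD)
    if VTK_HEX not in types and VTK_LINE in types:
        is_volume = types == VTK_QUAD
    vol_idx = np.flatnonzero(is_volume)
    fac_idx = np.flatnonzero(~is_volume)
    cells = np.array([conn[i] for i in vol_idx], dtype=np.int64)
    facets = np.array([conn[i] for i in fac_idx], dtype=np.int64)
    region = region_all[vol_idx].astype(np.int32)
    facet_label = boundary_all[fac_idx].astype(np.int32)
    facet_cells = np.column_stack([fcm[fac_idx], fcp[fac_idx]])
    if np.any(region < 0):
        raise MeshFormatError("volume cells without region labels")

    dim = 3 if len(z_edges) else 2
    node_coords = coords[:, :dim] if dim == 2 else coords
    dx = np.diff(x_edges)
    dy = np.diff(y_edges)
    measures = np.outer(dy, dx).ravel()
    if dim == 3:
        dz = np.diff(z_edges)
        measures = (np.tile(measures, len(dz)).reshape(len(dz), -1) * dz[:, None]).ravel()
    return SimMesh(
        node_coords=node_coords,
        cells=cells,
        region=region,
        facets=facets,
        facet_label=facet_label,
        facet_cells=facet_cells,
        cell_measures=measures,
        x_edges=x_edges,
        y_edges=y_edges,
        z_edges=z_edges if dim == 3 else None,
        extrusion_depth=extrusion,
    )


def write_fields(mesh: SimMesh, path, cell_data: dict[str, np.ndarray] | None = None,
                 point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write a field snapshot (volume cells only) as legacy VTK ASCII.

    ``cell_data`` arrays are per volume cell (e.g. ``E_mag``, ``Q``,
    ``sigma``, ``T``, ``omega``, masks); ``point_data`` per node (``V``).
    """
    pts = mesh.node_coords
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    n_cells = len(mesh.cells)
    cell_type = VTK_QUAD if mesh.cells.shape[1] == 4 else VTK_HEX
    lines = [
        "# vtk DataFile Version 3.0",
        "pfasim fields",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(pts)} double",
        _fmt(pts),
        f"CELLS {n_cells} {n_cells * (mesh.cells.shape[1] + 1)}",
    ]
    for row in mesh.cells:
        lines.append(f"{len(row)} " + " ".join(map(str, row)))
    lines.append(f"CELL_TYPES {n_cells}")
    lines.extend([str(cell_type)] * n_cells)
    if cell_data:
        lines.append(f"CELL_DATA {n_cells}")
        for name, arr in cell_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.17g}" for v in np.asarray(arr, dtype=float))
    if point_data:
        lines.append(f"POINT_DATA {len(pts)}")
        for name, arr in point_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.17g}" for v in np.asarray(arr, dtype=float))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
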
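"""Tetrahedral meshes for the perfusion solver.

Structured unit-cube / box meshes use the Kuhn (Freudenthal) six-tetrahedra
subdivision of each lattice cube with a single consistent diagonal, so that
continuous P1 spaces have exactly (n_edge+1)^3 vertices per compartment and
P2 spaces (2 n_edge+1)^3 nodes — the DoF counts a structured grid-convergence
study expects.

Boundary facets carry integer region labels (pial/ventricular analogues on a
box are TOP and BOTTOM); cells carry subdomain labels (GREY/WHITE).  Meshes
round-trip losslessly through Gmsh MSH 2.2 ASCII and VTU ASCII files, with
labels stored as physical tags / cell-data arrays.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# -- label registry ----------------------------------------------------------

#: cell (subdomain) labels
GREY, WHITE = 1, 2

#: facet (boundary region) labels; TOP doubles as the pial analogue and
#: BOTTOM as the ventricular analogue on box fixtures.
TOP, BOTTOM, XMIN, XMAX, YMIN, YMAX = 1, 2, 3, 4, 5, 6
#: auxiliary label used by occlusion fixtures (half of the TOP face)
TOP_OCCLUDED = 7

FACET_NAMES = {
    TOP: "TOP", BOTTOM: "BOTTOM", XMIN: "XMIN", XMAX: "XMAX",
    YMIN: "YMIN", YMAX: "YMAX", TOP_OCCLUDED: "TOP_OCCLUDED",
}
CELL_NAMES = {GREY: "GREY", WHITE: "WHITE"}

_GEOM_TOL = 1e-10

#: local faces of a tetrahedron (v0,v1,v2,v3); face i is opposite vertex i
TET_FACES = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])


class MeshError(ValueError):
    """Raised for invalid meshes or unreadable mesh files."""


@dataclass
class Mesh:
    """Tetrahedral mesh with boundary facet labels and cell subdomain labels."""

    vertices: np.ndarray          # (nv, 3) float
    cells: np.ndarray             # (nc, 4) int, positively oriented
    facets: np.ndarray            # (nf, 3) int, boundary triangles
    facet_labels: np.ndarray      # (nf,) int
    cell_labels: np.ndarray       # (nc,) int

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_volumes(self) -> np.ndarray:
        v = self.vertices[self.cells]
        e = v[:, 1:] - v[:, :1]
        return np.linalg.det(e) / 6.0

    def facet_areas(self) -> np.ndarray:
        p = self.vertices[self.facets]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(n, axis=1)

    def facets_with_label(self, label: int) -> np.ndarray:
        if label not in self.facet_labels:
            raise MeshError(f"no boundary facets carry label {label}")
        return self.facets[self.facet_labels == label]

    def validate(self) -> None:
        if self.cells.min() < 0 or self.cells.max() >= self.n_vertices:
            raise MeshError("cell vertex index out of range")
        vol = self.cell_volumes()
        if np.any(vol <= 0):
            raise MeshError("mesh contains non-positively oriented tetrahedra")
        # labelled facets must tile the topological boundary exactly once
        bfaces = _boundary_faces(self.cells)
        have = {tuple(sorted(f)) for f in self.facets}
        want = {tuple(sorted(f)) for f in bfaces}
        if have != want:
            raise MeshError("facet labels do not tile the mesh boundary")

    def with_facet_relabel(self, mapping) -> "Mesh":
        """Return a copy with facet labels changed through ``mapping``.

        ``mapping`` maps (old_label, facet_centroid) -> new_label; plain
        dict lookups are supported through ``mapping.get``.
        """
        new = self.facet_labels.copy()
        cent = self.vertices[self.facets].mean(axis=1)
        for i, lab in enumerate(self.facet_labels):
            new[i] = mapping(lab, cent[i]) if callable(mapping) else mapping.get(lab, lab)
        return Mesh(self.vertices, self.cells, self.facets, new, self.cell_labels)


def _boundary_faces(cells: np.ndarray) -> np.ndarray:
    faces = cells[:, TET_FACES].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def _orient(vertices: np.ndarray, cells: np.ndarray) -> np.ndarray:
    v = vertices[cells]
    det = np.linalg.det(v[:, 1:] - v[:, :1])
    flip = det < 0
    cells = cells.copy()
    cells[flip, 2], cells[flip, 3] = cells[flip, 3], cells[flip, 2].copy()
    return cells


# -- structured box / unit-cube meshes --------------------------------------

_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def build_box_mesh(n=(2, 2, 2), lower=(0.0, 0.0, 0.0), upper=(1.0, 1.0, 1.0),
                   grey_above_z=None) -> Mesh:
    """Structured Kuhn-subdivided tetrahedral mesh of an axis-aligned box.

    Each lattice cube is split into six tetrahedra sharing the main diagonal,
    with the same diagonal orientation in every cube.  Faces are labelled
    TOP (z=z_max), BOTTOM (z=z_min) and XMIN/XMAX/YMIN/YMAX.  Cells are
    labelled GREY above ``grey_above_z`` (WHITE below); with the default
    ``None`` every cell is GREY.
    """
    if np.isscalar(n):
        n = (n, n, n)
    nx, ny, nz = (int(v) for v in n)
    if min(nx, ny, nz) < 1:
        raise MeshError("need at least one element per edge")
    lo = np.asarray(lower, dtype=float)
    hi = np.asarray(upper, dtype=float)

    xs = [np.linspace(lo[d], hi[d], (nx, ny, nz)[d] + 1) for d in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    base = np.column_stack([I.ravel(), J.ravel(), K.ravel()])
    cells = []
    for perm in _KUHN_PERMS:
        # cumulative unit steps along the permuted axes: the lattice path
        # (0,0,0) -> (1,1,1) shared by all six tetrahedra of a cube
        path = np.zeros((4, 3), dtype=int)
        for step, axis in enumerate(perm):
            path[step + 1:, axis] += 1
        corners = base[:, None, :] + path[None, :, :]
        cells.append(vid(corners[..., 0], corners[..., 1], corners[..., 2]))
    cells = np.concatenate(cells, axis=0)
    cells = _orient(vertices, cells)

    mesh = Mesh(vertices, cells, *_label_box_boundary(vertices, cells, lo, hi),
                cell_labels=np.zeros(len(cells), dtype=int))
    if grey_above_z is None:
        mesh.cell_labels[:] = GREY
    else:
        zc = mesh.vertices[mesh.cells][:, :, 2].mean(axis=1)
        mesh.cell_labels[:] = np.where(zc > grey_above_z, GREY, WHITE)
    return mesh


def _label_box_boundary(vertices, cells, lo, hi):
    faces = _boundary_faces(cells)
    cent = vertices[faces].mean(axis=1)
    tol = _GEOM_TOL * max(1.0, np.abs(np.concatenate([lo, hi])).max())
    labels = np.full(len(faces), -1, dtype=int)
    labels[np.abs(cent[:, 2] - hi[2]) < tol] = TOP
    labels[np.abs(cent[:, 2] - lo[2]) < tol] = BOTTOM
    labels[np.abs(cent[:, 0] - lo[0]) < tol] = XMIN
    labels[np.abs(cent[:, 0] - hi[0]) < tol] = XMAX
    labels[np.abs(cent[:, 1] - lo[1]) < tol] = YMIN
    labels[np.abs(cent[:, 1] - hi[1]) < tol] = YMAX
    if np.any(labels < 0):
        raise MeshError("boundary facet could not be assigned a box face label")
    return faces, labels


def build_unit_cube_mesh(n_edge: int) -> Mesh:
    """Uniform Kuhn tetrahedral mesh of the unit cube with n_edge^3 cubes."""
    if n_edge < 1:
        raise MeshError("n_edge must be at least 1")
    return build_box_mesh((n_edge, n_edge, n_edge))


# -- uniform (red) refinement ------------------------------------------------

def refine_uniform(mesh: Mesh) -> Mesh:
    """Split every tetrahedron into eight (Bey's red refinement).

    Cell and facet labels are inherited by the children; each boundary
    triangle is split into its four midpoint children.
    """
    edges = np.concatenate([mesh.cells[:, e] for e in
                            [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]])
    key = np.sort(edges, axis=1)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    mid_of = {tuple(e): mesh.n_vertices + i for i, e in enumerate(uniq)}
    midpoints = mesh.vertices[uniq].mean(axis=1)
    vertices = np.vstack([mesh.vertices, midpoints])

    def m(a, b):
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        return np.array([mid_of[(x, y)] for x, y in zip(lo, hi)])

    c = mesh.cells
    v0, v1, v2, v3 = c[:, 0], c[:, 1], c[:, 2], c[:, 3]
    m01, m02, m03 = m(v0, v1), m(v0, v2), m(v0, v3)
    m12, m13, m23 = m(v1, v2), m(v1, v3), m(v2, v3)
    children = [
        (v0, m01, m02, m03), (v1, m01, m12, m13),
        (v2, m02, m12, m23), (v3, m03, m13, m23),
        # octahedron, diagonal m02-m13
        (m01, m02, m03, m13), (m01, m02, m12, m13),
        (m02, m03, m13, m23), (m02, m12, m13, m23),
    ]
    new_cells = np.concatenate([np.column_stack(ch) for ch in children])
    new_cells = _orient(vertices, new_cells)
    new_cell_labels = np.tile(mesh.cell_labels, 8)

    f = mesh.facets
    a, b, cc = f[:, 0], f[:, 1], f[:, 2]
    mab, mac, mbc = m(a, b), m(a, cc), m(b, cc)
    fchildren = [(a, mab, mac), (b, mab, mbc), (cc, mac, mbc), (mab, mbc, mac)]
    new_facets = np.concatenate([np.column_stack(fc) for fc in fchildren])
    new_facet_labels = np.tile(mesh.facet_labels, 4)

    return Mesh(vertices, new_cells, new_facets, new_facet_labels, new_cell_labels)


# -- 1D two-layer tissue column ----------------------------------------------

@dataclass
class ColumnMesh:
    """1D interval mesh of a grey+white tissue column, pial end at x=0."""

    vertices: np.ndarray       # (nv,) float, increasing
    cell_labels: np.ndarray    # (nv-1,) int, GREY left of the interface

    @property
    def n_cells(self) -> int:
        return len(self.vertices) - 1

    @property
    def length(self) -> float:
        return float(self.vertices[-1] - self.vertices[0])


def two_layer_column_mesh(l_G: float, l_W: float, n_cells: int = 100) -> ColumnMesh:
    """Interval [0, l_G+l_W] with a vertex placed exactly at x = l_G.

    Cells left of the grey/white interface are labelled GREY.  Cell counts
    are split proportionally to the layer lengths (at least one per layer).
    """
    if l_G <= 0 or l_W <= 0:
        raise MeshError("layer lengths must be positive")
    if n_cells < 2:
        raise MeshError("need at least two cells")
    n_g = int(round(n_cells * l_G / (l_G + l_W)))
    n_g = min(max(n_g, 1), n_cells - 1)
    xg = np.linspace(0.0, l_G, n_g + 1)
    xw = np.linspace(l_G, l_G + l_W, (n_cells - n_g) + 1)
    vertices = np.concatenate([xg, xw[1:]])
    labels = np.concatenate([np.full(n_g, GREY), np.full(n_cells - n_g, WHITE)])
    return ColumnMesh(vertices, labels)


# -- Gmsh MSH 2.2 ASCII I/O --------------------------------------------------

def write_msh(mesh: Mesh, path) -> None:
    """Write a labelled tetrahedral mesh as Gmsh MSH 2.2 ASCII."""
    out = io.StringIO()
    out.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
    out.write(f"$Nodes\n{mesh.n_vertices}\n")
    for i, p in enumerate(mesh.vertices, start=1):
        out.write(f"{i} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
    out.write("$EndNodes\n")
    n_elem = len(mesh.facets) + mesh.n_cells
    out.write(f"$Elements\n{n_elem}\n")
    eid = 1
    for f, lab in zip(mesh.facets, mesh.facet_labels):
        out.write(f"{eid} 2 2 {lab} {lab} {f[0]+1} {f[1]+1} {f[2]+1}\n")
        eid += 1
    for c, lab in zip(mesh.cells, mesh.cell_labels):
        out.write(f"{eid} 4 2 {lab} {lab} {c[0]+1} {c[1]+1} {c[2]+1} {c[3]+1}\n")
        eid += 1
    out.write("$EndElements\n")
    Path(path).write_text(out.getvalue())


def read_msh(path) -> Mesh:
    """Read a Gmsh MSH 2.2 ASCII file with triangle/tet physical labels."""
    lines = Path(path).read_text().splitlines()
    it = iter(lines)

    def expect(tag):
        for line in it:
            if line.strip() == tag:
                return
        raise MeshError(f"{path}: missing section {tag}")

    expect("$MeshFormat")
    fmt = next(it).split()
    if not fmt or not fmt[0].startswith("2.2"):
        raise MeshError(f"{path}: unsupported MSH version {fmt[:1]}; only 2.2 ASCII is readable")
    expect("$EndMeshFormat")
    expect("$Nodes")
    n_nodes = int(next(it))
    ids = np.empty(n_nodes, dtype=int)
    coords = np.empty((n_nodes, 3))
    for row in range(n_nodes):
        parts = next(it).split()
        ids[row] = int(parts[0])
        coords[row] = [float(x) for x in parts[1:4]]
    expect("$EndNodes")
    id_map = {node_id: row for row, node_id in enumerate(ids)}
    expect("$Elements")
    n_elem = int(next(it))
    tris, tri_labels, tets, tet_labels = [], [], [], []
    for _ in range(n_elem):
        parts = [int(x) for x in next(it).split()]
        etype, ntags = parts[1], parts[2]
        tags = parts[3:3 + ntags]
        conn = [id_map[v] for v in parts[3 + ntags:]]
        phys = tags[0] if tags else 0
        if etype == 2:
            tris.append(conn)
            tri_labels.append(phys)
        elif etype == 4:
            tets.append(conn)
            tet_labels.append(phys)
        elif etype in (1, 15):
            continue  # lines / points are ignored
        else:
            raise MeshError(f"{path}: unsupported element type {etype} "
                            "(only triangles and tetrahedra are tetrahedral-mesh cells)")
    if not tets:
        raise MeshError(f"{path}: no tetrahedral cell block found")
    vertices = coords
    cells = _orient(vertices, np.asarray(tets, dtype=int))
    mesh = Mesh(vertices, cells, np.asarray(tris, dtype=int),
                np.asarray(tri_labels, dtype=int),
                np.asarray(tet_labels, dtype=int))
    return mesh


# -- VTU (ASCII XML) I/O -----------------------------------------------------

def write_vtu(mesh: Mesh, path, point_data=None, cell_vectors=None) -> None:
    """Write mesh (plus optional per-vertex scalars / per-cell vectors) as VTU.

    ``point_data`` maps field name -> (n_vertices,) array; ``cell_vectors``
    maps name -> (n_cells, 3) array.  Facets are stored as triangle cells
    after the tetrahedra, with labels in the "label" cell array.
    """
    nv = mesh.n_vertices
    n_tet, n_tri = mesh.n_cells, len(mesh.facets)
    conn = np.concatenate([mesh.cells.ravel(), mesh.facets.ravel()])
    offsets = np.concatenate([4 * np.arange(1, n_tet + 1),
                              4 * n_tet + 3 * np.arange(1, n_tri + 1)])
    types = np.concatenate([np.full(n_tet, 10), np.full(n_tri, 5)])
    labels = np.concatenate([mesh.cell_labels, mesh.facet_labels])

    def arr(a, fmt="{:d}"):
        return " ".join(fmt.format(x) for x in np.asarray(a).ravel().tolist())

    out = io.StringIO()
    out.write('<?xml version="1.0"?>\n')
    out.write('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n')
    out.write(f'<UnstructuredGrid><Piece NumberOfPoints="{nv}" NumberOfCells="{n_tet + n_tri}">\n')
    out.write('<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">\n')
    out.write(arr(mesh.vertices, "{:.17g}"))
    out.write('\n</DataArray></Points>\n')
    out.write('<Cells>\n')
    out.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
    out.write(arr(conn) + '\n</DataArray>\n')
    out.write('<DataArray type="Int64" Name="offsets" format="ascii">\n')
    out.write(arr(offsets) + '\n</DataArray>\n')
    out.write('<DataArray type="UInt8" Name="types" format="ascii">\n')
    out.write(arr(types) + '\n</DataArray>\n')
    out.write('</Cells>\n')
    out.write('<CellData Scalars="label">\n')
    out.write('<DataArray type="Int64" Name="label" format="ascii">\n')
    out.write(arr(labels) + '\n</DataArray>\n')
    if cell_vectors:
        for name, vec in cell_vectors.items():
            pad = np.zeros((n_tet + n_tri, 3))
            pad[:len(vec)] = vec
            out.write(f'<DataArray type="Float64" Name="{name}" '
                      'NumberOfComponents="3" format="ascii">\n')
            out.write(arr(pad, "{:.17g}") + '\n</DataArray>\n')
    out.write('</CellData>\n')
    if point_data:
        out.write('<PointData>\n')
        for name, vals in point_data.items():
            out.write(f'<DataArray type="Float64" Name="{name}" format="ascii">\n')
            out.write(arr(vals, "{:.17g}") + '\n</DataArray>\n')
        out.write('</PointData>\n')
    out.write('</Piece></UnstructuredGrid></VTKFile>\n')
    Path(path).write_text(out.getvalue())


def read_vtu(path) -> Mesh:
    """Read a VTU file written by :func:`write_vtu` (ASCII, inline arrays)."""
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as exc:
        raise MeshError(f"{path}: not a readable VTU file ({exc})") from exc
    piece = root.find(".//Piece")
    if piece is None:
        raise MeshError(f"{path}: no UnstructuredGrid piece")

    def get_array(parent_tag, name=None, dtype=float):
        for da in piece.iter("DataArray"):
            parent = da.attrib.get("Name")
            if name is None or parent == name:
                if name is None and da.attrib.get("NumberOfComponents") != "3":
                    continue
                if da.attrib.get("format", "ascii") != "ascii":
                    raise MeshError(f"{path}: only ascii-format arrays are supported")
                return np.fromstring(da.text.replace("\n", " "), sep=" ", dtype=dtype)
        raise MeshError(f"{path}: missing data array {name!r}")

    points = piece.find("Points/DataArray")
    vertices = np.fromstring(points.text.replace("\n", " "), sep=" ").reshape(-1, 3)
    conn = get_array("Cells", "connectivity", dtype=float).astype(int)
    offsets = get_array("Cells", "offsets", dtype=float).astype(int)
    types = get_array("Cells", "types", dtype=float).astype(int)
    labels = get_array("CellData", "label", dtype=float).astype(int)
    bad = set(types) - {5, 10}
    if bad:
        raise MeshError(f"{path}: unsupported VTK cell types {sorted(bad)} "
                        "(only tetrahedra and boundary triangles)")
    starts = np.concatenate([[0], offsets[:-1]])
    tets, tet_labels, tris, tri_labels = [], [], [], []
    for s, e, t, lab in zip(starts, offsets, types, labels):
        if t == 10:
            tets.append(conn[s:e])
            tet_labels.append(lab)
        else:
            tris.append(conn[s:e])
            tri_labels.append(lab)
    if not tets:
        raise MeshError(f"{path}: no tetrahedral cells found")
    cells = _orient(vertices, np.asarray(tets, dtype=int))
    return Mesh(vertices, cells, np.asarray(tris, dtype=int),
                np.asarray(tri_labels, dtype=int), np.asarray(tet_labels, dtype=int))


def read_mesh(path) -> Mesh:
    """Dispatch on file extension (.msh -> Gmsh 2.2, .vtu -> VTU)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".msh":
        return read_msh(path)
    if suffix == ".vtu":
        return read_vtu(path)
    raise MeshError(f"unknown mesh format {suffix!r} (supported: .msh, .vtu)")


def write_mesh(mesh: Mesh, path) -> None:
    suffix = Path(path).suffix.lower()
    if suffix == ".msh":
        write_msh(mesh, path)
    elif suffix == ".vtu":
        write_vtu(mesh, path)
    else:
        raise MeshError(f"unknown mesh format {suffix!r} (supported: .msh, .vtu)")
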
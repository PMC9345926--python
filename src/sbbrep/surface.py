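"""Triangulated surface meshes: neighbourhood structure, connected components,
and graph-based scalar smoothing.

A cortical hemisphere is represented as an undirected graph over vertex
indices ``0..n_vertices-1``.  All spatial operations downstream (cluster
formation, TFCE, synthetic noise smoothing) are defined purely on this
graph; vertex coordinates are optional metadata.  Hemispheres are
independent meshes with no cross-hemisphere adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc


class MeshError(ValueError):
    """Raised for structurally invalid meshes or mesh/data mismatches."""


@dataclass
class SurfaceMesh:
    """An undirected vertex graph for one hemisphere.

    Parameters
    ----------
    hemisphere:
        Label such as ``"lh"`` or ``"rh"``.
    n_vertices:
        Number of vertices; indices run ``0..n_vertices-1``.
    edges:
        ``(E, 2)`` integer array of unique undirected edges with
        ``edges[:, 0] < edges[:, 1]``; no self-edges.
    coordinates:
        Optional ``(n_vertices, 3)`` vertex positions in mm.
    """

    hemisphere: str
    n_vertices: int
    edges: np.ndarray
    coordinates: np.ndarray | None = None
    _adj: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_vertices < 1:
            raise MeshError("mesh must have at least one vertex")
        e = np.asarray(self.edges, dtype=np.int64)
        if e.size == 0:
            e = e.reshape(0, 2)
        if e.ndim != 2 or e.shape[1] != 2:
            raise MeshError("edges must be an (E, 2) array")
        if e.size and (e.min() < 0 or e.max() >= self.n_vertices):
            raise MeshError("edge endpoint outside vertex range")
        if np.any(e[:, 0] == e[:, 1]):
            raise MeshError("self-edges are not allowed")
        e = np.sort(e, axis=1)
        e = np.unique(e, axis=0)
        self.edges = e
        if self.coordinates is not None:
            c = np.asarray(self.coordinates, dtype=float)
            if c.shape != (self.n_vertices, 3):
                raise MeshError("coordinates must be (n_vertices, 3)")
            self.coordinates = c

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric boolean adjacency in CSR form (built lazily)."""
        if self._adj is None:
            u, v = self.edges[:, 0], self.edges[:, 1]
            data = np.ones(2 * len(u), dtype=np.int8)
            rows = np.concatenate([u, v])
            cols = np.concatenate([v, u])
            self._adj = sp.csr_matrix(
                (data, (rows, cols)), shape=(self.n_vertices, self.n_vertices)
            )
        return self._adj

    def neighbors(self, v: int) -> np.ndarray:
        a = self.adjacency
        return a.indices[a.indptr[v] : a.indptr[v + 1]]

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()


@dataclass
class ScalarMap:
    """One real value per vertex of a mesh (mm for thickness, unitless for
    statistics)."""

    mesh: SurfaceMesh
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.mesh.n_vertices,):
            raise MeshError(
                f"scalar map has {v.shape} values for a "
                f"{self.mesh.n_vertices}-vertex mesh"
            )
        self.values = v


def _values(mesh: SurfaceMesh, data) -> np.ndarray:
    """Accept a ScalarMap or a bare array; return validated values."""
    if isinstance(data, ScalarMap):
        if data.mesh.n_vertices != mesh.n_vertices:
            raise MeshError("scalar map belongs to a different mesh")
        return data.values
    v = np.asarray(data, dtype=float)
    if v.shape[-1] != mesh.n_vertices:
        raise MeshError("value array length does not match mesh size")
    return v


# ---------------------------------------------------------------------------
# Test meshes
# ---------------------------------------------------------------------------


def build_test_mesh(kind: str, resolution: int, hemisphere: str = "lh") -> SurfaceMesh:
    """Build a small standard mesh for testing and synthetic cohorts.

    ``icosphere`` with subdivision ``k`` has ``10 * 4**k + 2`` vertices and is
    a reasonable miniature of a registered cortical hemisphere (closed,
    roughly uniform degree).  ``grid`` with side ``m`` is an ``m x m``
    4-connected lattice with ``m**2`` vertices, convenient for hand-checkable
    fixtures.

    ``resolution`` means the subdivision level for ``icosphere`` (level 0 is
    the icosahedron itself) and the side length for ``grid``.
    """
    if kind == "icosphere":
        if resolution < 0:
            raise ValueError("icosphere subdivision must be >= 0")
        import trimesh

        ico = trimesh.creation.icosphere(subdivisions=resolution, radius=100.0)
        faces = np.asarray(ico.faces, dtype=np.int64)
        edges = np.concatenate(
            [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [0, 2]]], axis=0
        )
        return SurfaceMesh(
            hemisphere=hemisphere,
            n_vertices=len(ico.vertices),
            edges=edges,
            coordinates=np.asarray(ico.vertices, dtype=float),
        )
    if kind == "grid":
        m = int(resolution)
        if m < 1:
            raise ValueError("grid side must be >= 1")
        idx = np.arange(m * m).reshape(m, m)
        right = np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1)
        down = np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()], axis=1)
        edges = np.concatenate([right, down], axis=0)
        xy = np.stack(
            [np.repeat(np.arange(m), m), np.tile(np.arange(m), m)], axis=1
        ).astype(float)
        coords = np.concatenate([xy, np.zeros((m * m, 1))], axis=1)
        return SurfaceMesh(
            hemisphere=hemisphere, n_vertices=m * m, edges=edges, coordinates=coords
        )
    raise ValueError(f"unknown test mesh kind: {kind!r}")


# ---------------------------------------------------------------------------
# Components and smoothing
# ---------------------------------------------------------------------------


def connected_components(mesh: SurfaceMesh, mask) -> list[np.ndarray]:
    """Connected components of the subgraph induced by a boolean vertex mask.

    Returns a list of sorted vertex-index arrays, ordered by the smallest
    index each component contains.  Two masked vertices share a component
    iff a path of masked vertices connects them.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (mesh.n_vertices,):
        raise ValueError("mask length does not match mesh size")
    sel = np.flatnonzero(mask)
    if sel.size == 0:
        return []
    e = mesh.edges
    keep = mask[e[:, 0]] & mask[e[:, 1]]
    ek = e[keep]
    # relabel to the submesh
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[sel] = np.arange(sel.size)
    rows = remap[ek[:, 0]]
    cols = remap[ek[:, 1]]
    sub = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(sel.size, sel.size)
    )
    n_comp, labels = _cc(sub, directed=False)
    comps = [np.sort(sel[labels == i]) for i in range(n_comp)]
    comps.sort(key=lambda c: int(c[0]))
    return comps


def smooth_scalars(
    mesh: SurfaceMesh,
    data,
    iterations: int,
    self_weight: float = 0.5,
):
    """Iterated weighted neighbour averaging on the mesh graph.

    Each iteration maps ``x(v)`` to
    ``self_weight * x(v) + (1 - self_weight) * mean(x(u) for u in N(v))``.
    Vertices with no neighbours keep their value.  Constant maps are fixed
    points; non-constant maps lose variance on connected meshes.  This is a
    graph-diffusion analogue of Gaussian surface smoothing: the effective
    kernel width grows with ``iterations``.

    ``data`` may be a ``ScalarMap``, a length-``n_vertices`` array, or a
    ``(n_maps, n_vertices)`` matrix (all rows smoothed at once).  Returns the
    same type as given.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if not 0.0 <= self_weight <= 1.0:
        raise ValueError("self_weight must lie in [0, 1]")
    x = _values(mesh, data)
    if iterations == 0:
        out = x.copy()
    else:
        deg = mesh.degrees()
        inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
        row_norm = sp.diags(inv) @ mesh.adjacency.astype(float)
        isolated = deg == 0
        out = x.astype(float).copy()
        for _ in range(iterations):
            nb_mean = out @ row_norm.T if out.ndim == 2 else row_norm @ out
            nxt = self_weight * out + (1.0 - self_weight) * nb_mean
            if isolated.any():
                nxt[..., isolated] = out[..., isolated]
            out = nxt
    if isinstance(data, ScalarMap):
        return ScalarMap(mesh=mesh, values=out)
    return out


def contiguous_patch(mesh: SurfaceMesh, seed_vertex: int, size: int) -> np.ndarray:
    """Grow a connected vertex patch of ``size`` vertices from a seed by
    breadth-first search (deterministic: neighbours visited in index order)."""
    if not 0 <= seed_vertex < mesh.n_vertices:
        raise ValueError("seed vertex outside mesh")
    if size < 1 or size > mesh.n_vertices:
        raise ValueError("patch size out of range")
    visited = np.zeros(mesh.n_vertices, dtype=bool)
    order: list[int] = []
    queue = [int(seed_vertex)]
    visited[seed_vertex] = True
    while queue and len(order) < size:
        v = queue.pop(0)
        order.append(v)
        for u in np.sort(mesh.neighbors(v)):
            if not visited[u]:
                visited[u] = True
                queue.append(int(u))
    if len(order) < size:
        raise MeshError("patch size exceeds the reachable component")
    return np.array(sorted(order[:size]), dtype=np.int64)


# ---------------------------------------------------------------------------
# I/O: plain-text dialects plus optional GIFTI / FreeSurfer readers
# ---------------------------------------------------------------------------


def write_edge_list(mesh: SurfaceMesh, path) -> None:
    """Write the mesh as a two-column TSV of undirected edges (0-based)."""
    np.savetxt(path, mesh.edges, fmt="%d", delimiter="\t", header="u\tv", comments="")


def read_edge_list(
    path, hemisphere: str = "lh", n_vertices: int | None = None, one_based: bool = False
) -> SurfaceMesh:
    """Read a mesh from an edge-list TSV (columns u, v; optional header).

    External 1-based dialects are converted here; everything downstream is
    0-based.
    """
    arr = np.loadtxt(path, dtype=np.int64, delimiter="\t", skiprows=_header_rows(path))
    arr = arr.reshape(-1, 2)
    if one_based:
        arr = arr - 1
    n = int(arr.max()) + 1 if n_vertices is None else n_vertices
    return SurfaceMesh(hemisphere=hemisphere, n_vertices=n, edges=arr)


def _header_rows(path) -> int:
    with open(path) as fh:
        first = fh.readline()
    token = first.split("\t")[0].strip()
    try:
        int(token)
        return 0
    except ValueError:
        return 1


def write_scalar_tsv(values: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(values, dtype=float), fmt="%.10g")


def read_scalar_tsv(path) -> np.ndarray:
    return np.loadtxt(path, dtype=float).ravel()


def write_matrix_tsv(matrix: np.ndarray, path) -> None:
    """Write a subjects x vertices matrix as TSV (no header)."""
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.10g", delimiter="\t")


def read_matrix_tsv(path) -> np.ndarray:
    arr = np.loadtxt(path, dtype=float, delimiter="\t")
    return arr.reshape(1, -1) if arr.ndim == 1 else arr


def read_gifti_surface(path, hemisphere: str = "lh") -> SurfaceMesh:
    """Read a GIFTI surface (.surf.gii) into a SurfaceMesh via nibabel."""
    import nibabel as nib

    img = nib.load(str(path))
    coords = faces = None
    for da in img.darrays:
        code = da.intent
        if code == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            coords = np.asarray(da.data, dtype=float)
        elif code == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            faces = np.asarray(da.data, dtype=np.int64)
    if coords is None or faces is None:
        raise MeshError("GIFTI file lacks pointset/triangle arrays")
    edges = np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [0, 2]]], axis=0
    )
    return SurfaceMesh(
        hemisphere=hemisphere, n_vertices=len(coords), edges=edges, coordinates=coords
    )


def read_gifti_func(path) -> np.ndarray:
    """Read per-vertex scalars from a GIFTI func/shape file (first array)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.darrays[0].data, dtype=float).ravel()


def read_freesurfer_curv(path) -> np.ndarray:
    """Read a FreeSurfer curv-format per-vertex scalar file."""
    import nibabel.freesurfer as fsio

    return np.asarray(fsio.read_morph_data(str(path)), dtype=float)
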
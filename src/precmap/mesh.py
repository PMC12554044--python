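"""Triangulated cortical-surface meshes and discrete differential operators.

All per-vertex maps in this package live on a :class:`SurfaceMesh`: a closed
triangulated 2-manifold with barycentric (lumped) vertex areas in mm².  The
synthetic stand-in for a cortical atlas surface is a subdivided icosahedron
(:func:`make_icosphere`), which gives a closed sphere with nearly uniform
triangle quality at every resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import sparse
from scipy.sparse.csgraph import dijkstra


@dataclass
class SurfaceMesh:
    """A closed triangulated surface.

    Attributes
    ----------
    vertex_coords : (V, 3) float array
        Vertex positions in mm.
    triangles : (F, 3) int array
        Vertex-index triples, consistently oriented.
    vertex_area : (V,) float array
        Barycentric vertex area in mm² (one third of each incident
        triangle's area).  Sums exactly to the total surface area.
    neighbor_lists : list of int arrays
        One-ring vertex adjacency.
    """

    vertex_coords: np.ndarray
    triangles: np.ndarray
    vertex_area: np.ndarray = field(init=False)
    neighbor_lists: list = field(init=False)

    def __post_init__(self) -> None:
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.triangles.max() >= len(self.vertex_coords):
            raise ValueError("triangle index exceeds vertex count")
        self.vertex_area = self._barycentric_areas()
        self.neighbor_lists = self._neighbors()

    # -- basic quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_coords)

    def triangle_areas(self) -> np.ndarray:
        p = self.vertex_coords[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def total_area(self) -> float:
        return float(self.triangle_areas().sum())

    def _barycentric_areas(self) -> np.ndarray:
        tri_area = self.triangle_areas()
        area = np.zeros(self.n_vertices)
        for k in range(3):
            np.add.at(area, self.triangles[:, k], tri_area / 3.0)
        return area

    def _neighbors(self) -> list:
        adj = self.adjacency_matrix()
        indptr, indices = adj.indptr, adj.indices
        return [indices[indptr[v]:indptr[v + 1]] for v in range(self.n_vertices)]

    def adjacency_matrix(self) -> sparse.csr_matrix:
        """Unweighted symmetric vertex adjacency (CSR, 0/1 entries)."""
        i = np.concatenate([self.triangles[:, k] for k in (0, 1, 2, 0, 1, 2)])
        j = np.concatenate([self.triangles[:, k] for k in (1, 2, 0, 2, 0, 1)])
        a = sparse.coo_matrix(
            (np.ones_like(i, dtype=float), (i, j)),
            shape=(self.n_vertices, self.n_vertices),
        ).tocsr()
        a.data[:] = 1.0
        return a

    # -- operators ---------------------------------------------------------

    def edge_length_graph(self) -> sparse.csr_matrix:
        """Adjacency weighted by Euclidean edge length (for graph geodesics)."""
        adj = self.adjacency_matrix().tocoo()
        d = np.linalg.norm(
            self.vertex_coords[adj.row] - self.vertex_coords[adj.col], axis=1
        )
        return sparse.csr_matrix((d, (adj.row, adj.col)), shape=adj.shape)

    def geodesic_distances(self, sources) -> np.ndarray:
        """Graph-geodesic distance (Dijkstra over mesh edges) from `sources`.

        Returns an (len(sources), V) array in mm.  On well-refined meshes this
        overestimates true geodesic distance by a few percent at most, which is
        adequate for seeding templates and fitting smoothing-kernel widths.
        """
        sources = np.atleast_1d(np.asarray(sources, dtype=int))
        return dijkstra(self.edge_length_graph(), directed=False, indices=sources)

    def cotangent_laplacian(self) -> sparse.csr_matrix:
        """Symmetric cotangent-weighted stiffness matrix (positive semidefinite).

        Rows sum to zero; used with the lumped mass matrix (vertex areas) for
        heat-diffusion smoothing.
        """
        tri = self.triangles
        p = self.vertex_coords
        rows, cols, vals = [], [], []
        for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
            # cotangent at corner `a` weights edge (b, c)
            u = p[tri[:, b]] - p[tri[:, a]]
            v = p[tri[:, c]] - p[tri[:, a]]
            cos = np.einsum("ij,ij->i", u, v)
            sin = np.linalg.norm(np.cross(u, v), axis=1)
            cot = cos / np.maximum(sin, 1e-300)
            w = 0.5 * cot
            rows.extend([tri[:, b], tri[:, c]])
            cols.extend([tri[:, c], tri[:, b]])
            vals.extend([-w, -w])
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        L = sparse.coo_matrix((vals, (rows, cols)), shape=(self.n_vertices,) * 2)
        L = L.tocsr()
        L = L - sparse.diags(np.asarray(L.sum(axis=1)).ravel())
        return L

    def mass_matrix(self) -> sparse.dia_matrix:
        return sparse.diags(self.vertex_area)

    def is_closed(self) -> bool:
        """True when every edge is shared by exactly two triangles."""
        edges = np.sort(
            np.concatenate(
                [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]],
                 self.triangles[:, [2, 0]]]
            ),
            axis=1,
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))


def make_icosphere(subdivision_level: int, radius_mm: float = 50.0) -> SurfaceMesh:
    """Build a subdivided-icosahedron sphere mesh.

    Parameters
    ----------
    subdivision_level : int in [0, 6]
        Level 0 is the icosahedron (12 vertices); each level quadruples the
        triangle count.  Vertex count is ``10 * 4**level + 2``.
    radius_mm : float
        Sphere radius in mm.

    Returns
    -------
    SurfaceMesh
    """
    if not (0 <= int(subdivision_level) <= 6):
        raise ValueError(
            f"subdivision_level must be in [0, 6], got {subdivision_level}"
        )
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    ico = trimesh.creation.icosphere(subdivisions=int(subdivision_level), radius=1.0)
    verts = np.asarray(ico.vertices, dtype=float)
    # re-project exactly onto the sphere of the requested radius
    verts = radius_mm * verts / np.linalg.norm(verts, axis=1, keepdims=True)
    return SurfaceMesh(vertex_coords=verts, triangles=np.asarray(ico.faces))


def farthest_point_sample(mesh: SurfaceMesh, n_points: int, seed: int = 0) -> np.ndarray:
    """Pick `n_points` mutually distant vertices by greedy farthest-point sampling
    under graph-geodesic distance.  Deterministic given `seed` (first point)."""
    if n_points > mesh.n_vertices:
        raise ValueError("more sample points than vertices")
    rng = np.random.default_rng(seed)
    first = int(rng.integers(mesh.n_vertices))
    chosen = [first]
    dmin = mesh.geodesic_distances([first])[0]
    for _ in range(n_points - 1):
        nxt = int(np.argmax(dmin))
        chosen.append(nxt)
        dmin = np.minimum(dmin, mesh.geodesic_distances([nxt])[0])
    return np.array(chosen, dtype=int)
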
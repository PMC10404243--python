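"""Triangulated meshes and P1 finite-element assembly.

The spatial Gaussian field is represented on a triangulation of the observation
window (plus an outer extension ring that pushes boundary artefacts of the
stochastic-PDE approximation away from the data).  This module builds the mesh,
assembles the P1 mass and stiffness matrices, evaluates the piecewise-linear
basis at arbitrary points (barycentric projection), and computes the dual-cell
quadrature weights used to approximate the intensity integral of the Cox
likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon

from .errors import (
    AssemblyError,
    InvalidGeometryError,
    MeshResourceError,
    PointLocationError,
)

__all__ = [
    "Mesh",
    "FEMMatrices",
    "build_mesh",
    "regular_mesh",
    "assemble_fem",
    "projection_matrix",
    "dual_weights",
]

#: relative snap tolerance for point location, times the window diameter
SNAP_REL = 1e-9


@dataclass
class Mesh:
    """Triangulation of the (possibly extended) observation window.

    Attributes
    ----------
    vertices : (N, 2) float array
        Planar coordinates, km.
    triangles : (M, 3) int array
        Vertex index triples, counter-clockwise.
    boundary : shapely Polygon
        The original observation window (not the extension).
    interior_mask : (N,) bool array
        True for vertices inside (or on) the original window.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    boundary: Polygon
    interior_mask: np.ndarray
    _vertex_tree: cKDTree | None = field(default=None, repr=False, compare=False)
    _vertex_tris: list | None = field(default=None, repr=False, compare=False)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def triangle_areas(self) -> np.ndarray:
        """Signed areas of all triangles (positive for CCW orientation)."""
        p = self.vertices[self.triangles]
        return 0.5 * (
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def diameter(self) -> float:
        mn = self.vertices.min(axis=0)
        mx = self.vertices.max(axis=0)
        return float(np.hypot(*(mx - mn)))

    def _ensure_location_index(self):
        if self._vertex_tree is None:
            self._vertex_tree = cKDTree(self.vertices)
            vt: list[list[int]] = [[] for _ in range(self.n_vertices)]
            for ti, tri in enumerate(self.triangles):
                for v in tri:
                    vt[v].append(ti)
            self._vertex_tris = vt


@dataclass
class FEMMatrices:
    """P1 finite-element matrices of a mesh.

    ``C_exact`` is the consistent mass matrix ⟨φ_i, φ_j⟩, ``C_lumped`` its
    row-sum (diagonal) lumping ⟨φ_i, 1⟩, and ``G`` the stiffness matrix
    ⟨∇φ_i, ∇φ_j⟩.  Lumping is what makes the precision of the discretised
    Matérn field sparse (the Markov approximation).
    """

    C_exact: sp.csr_matrix
    C_lumped: np.ndarray
    G: sp.csr_matrix


def _validate_boundary(boundary: Polygon) -> Polygon:
    if not isinstance(boundary, Polygon):
        boundary = Polygon(boundary)
    if boundary.is_empty or boundary.area <= 0:
        raise InvalidGeometryError("window polygon is empty or has zero area")
    if not boundary.is_valid:
        raise InvalidGeometryError("window polygon is invalid (self-intersecting?)")
    if boundary.interiors:
        raise InvalidGeometryError("window polygons with holes are not supported")
    return boundary


def _densify_ring(coords: np.ndarray, h: float) -> np.ndarray:
    """Points along a closed ring with spacing at most h."""
    pts = []
    for a, b in zip(coords[:-1], coords[1:]):
        seg = np.asarray(b) - np.asarray(a)
        length = float(np.hypot(*seg))
        n = max(1, int(np.ceil(length / h)))
        for k in range(n):
            pts.append(np.asarray(a) + seg * (k / n))
    return np.array(pts)


def _hex_grid(bounds, h: float) -> np.ndarray:
    """Hexagonal point lattice with nearest-neighbour spacing h covering bounds."""
    minx, miny, maxx, maxy = bounds
    dy = h * np.sqrt(3) / 2
    ys = np.arange(miny, maxy + dy, dy)
    pts = []
    for i, y in enumerate(ys):
        off = 0.5 * h if i % 2 else 0.0
        xs = np.arange(minx + off, maxx + h, h)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    return np.vstack(pts)


def build_mesh(
    boundary,
    max_edge_inner: float,
    max_edge_outer: float | None = None,
    extension_fraction: float = 0.2,
    max_vertices: int = 50_000,
) -> Mesh:
    """Triangulate the window plus an outer extension ring.

    Parameters
    ----------
    boundary : shapely Polygon (or coordinate sequence)
        Simple polygon with positive area; holes are not supported.
    max_edge_inner : float
        Target maximum edge length inside the window.
    max_edge_outer : float, optional
        Target edge length in the extension ring; default 3 × inner.
    extension_fraction : float
        Width of the extension ring as a fraction of the window diameter.
        Zero disables the ring.
    max_vertices : int
        Resource cap on the number of mesh vertices.

    Returns
    -------
    Mesh

    Notes
    -----
    The mesh is a Delaunay triangulation of a hexagonal interior lattice plus
    densified boundary rings, restricted to the extended window.  It is not a
    constrained Delaunay triangulation, which is adequate here because the
    extension ring keeps the window boundary strictly inside the meshed region.
    """
    boundary = _validate_boundary(boundary)
    if max_edge_inner <= 0:
        raise ValueError("max_edge_inner must be positive")
    if max_edge_outer is None:
        max_edge_outer = 3.0 * max_edge_inner

    minx, miny, maxx, maxy = boundary.bounds
    diameter = float(np.hypot(maxx - minx, maxy - miny))
    ext = extension_fraction * diameter
    outer = boundary.buffer(ext, quad_segs=4) if ext > 0 else boundary

    # crude vertex-count estimate before doing any work
    est = outer.area / (0.5 * max_edge_inner**2 * np.sqrt(3) / 2)
    if est > 4 * max_vertices:
        raise MeshResourceError(
            f"requested resolution implies ~{int(est)} vertices (cap {max_vertices})"
        )

    h_in, h_out = float(max_edge_inner), float(max_edge_outer)
    pts = [_densify_ring(np.asarray(boundary.exterior.coords), h_in)]
    if ext > 0:
        pts.append(_densify_ring(np.asarray(outer.exterior.coords), h_out))

    grid = _hex_grid(boundary.bounds, h_in)
    inside = shapely.contains_xy(boundary, grid[:, 0], grid[:, 1])
    # keep lattice points clear of the boundary ring to avoid slivers
    near = shapely.dwithin(shapely.points(grid), boundary.exterior, 0.45 * h_in)
    pts.append(grid[inside & ~near])

    if ext > 0:
        ogrid = _hex_grid(outer.bounds, h_out)
        in_outer = shapely.contains_xy(outer, ogrid[:, 0], ogrid[:, 1])
        in_inner = shapely.contains_xy(
            boundary.buffer(0.45 * h_out), ogrid[:, 0], ogrid[:, 1]
        )
        near_out = shapely.dwithin(shapely.points(ogrid), outer.exterior, 0.45 * h_out)
        pts.append(ogrid[in_outer & ~in_inner & ~near_out])

    points = np.vstack(pts)

    # deduplicate: snap-merge anything closer than a small fraction of h_in
    tree = cKDTree(points)
    pairs = tree.query_pairs(0.25 * h_in, output_type="ndarray")
    drop = np.zeros(len(points), dtype=bool)
    for i, j in pairs:
        if not drop[i]:
            drop[j] = True
    points = points[~drop]

    if len(points) > max_vertices:
        raise MeshResourceError(
            f"mesh has {len(points)} vertices, exceeding the cap {max_vertices}"
        )

    tri = Delaunay(points)
    simplices = tri.simplices
    cent = points[simplices].mean(axis=1)
    keep = shapely.contains_xy(outer.buffer(1e-9 * max(diameter, 1.0)), cent[:, 0], cent[:, 1])
    # drop degenerate slivers
    p = points[simplices]
    areas = 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    keep &= areas > 1e-12 * h_in**2
    simplices = simplices[keep]

    used = np.unique(simplices)
    remap = -np.ones(len(points), dtype=int)
    remap[used] = np.arange(len(used))
    vertices = points[used]
    triangles = remap[simplices]

    # enforce CCW orientation
    p = vertices[triangles]
    signed = 0.5 * (
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    flip = signed < 0
    triangles[flip] = triangles[flip][:, [0, 2, 1]]

    snap = SNAP_REL * max(diameter, 1.0)
    interior = shapely.contains_xy(boundary.buffer(snap), vertices[:, 0], vertices[:, 1])
    return Mesh(vertices=vertices, triangles=triangles, boundary=boundary,
                interior_mask=np.asarray(interior, dtype=bool))


def regular_mesh(xmax: float, ymax: float, spacing: float) -> Mesh:
    """Structured triangulation of the rectangle [0,xmax]×[0,ymax].

    Useful for convergence studies against analytic Matérn correlations,
    where a perfectly regular lattice removes mesh-quality confounders.
    """
    gx = np.arange(0.0, xmax + spacing / 2, spacing)
    gy = np.arange(0.0, ymax + spacing / 2, spacing)
    X, Y = np.meshgrid(gx, gy)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    tri = Delaunay(pts).simplices.copy()
    boundary = Polygon([(0, 0), (xmax, 0), (xmax, ymax), (0, ymax)])
    mesh = Mesh(vertices=pts, triangles=tri, boundary=boundary,
                interior_mask=np.ones(len(pts), dtype=bool))
    flip = mesh.triangle_areas() < 0
    mesh.triangles[flip] = mesh.triangles[flip][:, [0, 2, 1]]
    return mesh


def assemble_fem(mesh: Mesh, area_tol: float = 1e-14) -> FEMMatrices:
    """Assemble P1 mass and stiffness matrices.

    Per triangle of area A the consistent mass block is A/12 · (2 on the
    diagonal, 1 off), the lumped mass contribution A/3 per vertex, and the
    stiffness block K_ij = (e_i · e_j) / (4A) with e_i the edge vector
    opposite vertex i.
    """
    areas = mesh.triangle_areas()
    bad = np.where(areas <= area_tol)[0]
    if bad.size:
        raise AssemblyError(f"degenerate triangle(s) {bad.tolist()} with area <= {area_tol}")

    N, M = mesh.n_vertices, mesh.n_triangles
    tri = mesh.triangles
    p = mesh.vertices[tri]  # (M,3,2)

    # opposite edge vectors e_i = p_{i+2} - p_{i+1}
    e = p[:, [2, 0, 1], :] - p[:, [1, 2, 0], :]  # e[:,i,:] opposite vertex i

    rows, cols = np.broadcast_arrays(tri[:, :, None], tri[:, None, :])
    mass_local = (np.full((3, 3), 1.0) + np.eye(3))[None, :, :] / 12.0 * areas[:, None, None]
    stiff_local = np.einsum("mik,mjk->mij", e, e) / (4.0 * areas)[:, None, None]

    C = sp.coo_matrix((mass_local.ravel(), (rows.ravel(), cols.ravel())), shape=(N, N)).tocsr()
    G = sp.coo_matrix((stiff_local.ravel(), (rows.ravel(), cols.ravel())), shape=(N, N)).tocsr()
    C_lumped = np.zeros(N)
    np.add.at(C_lumped, tri.ravel(), np.repeat(areas / 3.0, 3))
    return FEMMatrices(C_exact=C, C_lumped=C_lumped, G=G)


def _barycentric(mesh: Mesh, ti: int, xy: np.ndarray) -> np.ndarray:
    a, b, c = mesh.vertices[mesh.triangles[ti]]
    T = np.column_stack([b - a, c - a])
    lam = np.linalg.solve(T, xy - a)
    return np.array([1.0 - lam[0] - lam[1], lam[0], lam[1]])


def locate_points(mesh: Mesh, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Containing triangle index and barycentric coordinates for each point.

    Points on shared edges/vertices are assigned to the lowest containing
    triangle index; points within the snap tolerance of the mesh are snapped.
    """
    mesh._ensure_location_index()
    points = np.atleast_2d(np.asarray(points, dtype=float))
    snap = SNAP_REL * max(mesh.diameter(), 1.0)
    n = len(points)
    tri_idx = np.full(n, -1, dtype=int)
    bary = np.zeros((n, 3))

    for i, xy in enumerate(points):
        found = None
        for k in (1, 8, 32):
            _, nearest = mesh._vertex_tree.query(xy, k=min(k, mesh.n_vertices))
            nearest = np.atleast_1d(nearest)
            cand = sorted({t for v in nearest for t in mesh._vertex_tris[v]})
            for ti in cand:
                lam = _barycentric(mesh, ti, xy)
                if lam.min() >= -1e-12 - snap:
                    found = (ti, np.clip(lam, 0.0, None))
                    break
            if found:
                break
        if found is None:
            # exhaustive fallback before declaring the point outside
            for ti in range(mesh.n_triangles):
                lam = _barycentric(mesh, ti, xy)
                if lam.min() >= -1e-12 - snap:
                    found = (ti, np.clip(lam, 0.0, None))
                    break
        if found is None:
            raise PointLocationError(f"point {i} at {tuple(xy)} lies outside the mesh", i)
        tri_idx[i] = found[0]
        bary[i] = found[1] / found[1].sum()
    return tri_idx, bary


def projection_matrix(mesh: Mesh, points: np.ndarray) -> sp.csr_matrix:
    """Sparse (P × N) matrix of P1 basis values at the given points.

    Row p holds the barycentric coordinates of point p within its containing
    triangle; a point coincident with vertex l gets the indicator row e_l.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri_idx, bary = locate_points(mesh, points)
    rows = np.repeat(np.arange(len(points)), 3)
    cols = mesh.triangles[tri_idx].ravel()
    vals = bary.ravel()
    A = sp.coo_matrix((vals, (rows, cols)), shape=(len(points), mesh.n_vertices))
    A.sum_duplicates()
    A = A.tocsr()
    A.eliminate_zeros()
    return A


def dual_weights(mesh: Mesh, window: Polygon | None = None) -> np.ndarray:
    """Barycentric dual-cell quadrature weights clipped to the window.

    Weight k is the area of the dual cell of vertex k (union over incident
    triangles of the vertex–edge-midpoint–centroid quadrilaterals) intersected
    with ``window``.  The weights are non-negative, sum to area(window), and
    integrate piecewise-linear-at-vertices fields exactly for constants.
    """
    if window is None:
        window = mesh.boundary
    window = _validate_boundary(window)
    from shapely.prepared import prep

    prepared = prep(window)

    N = mesh.n_vertices
    w = np.zeros(N)
    areas = mesh.triangle_areas()
    verts = mesh.vertices

    for ti, tri in enumerate(mesh.triangles):
        a, b, c = verts[tri]
        tri_poly = Polygon([a, b, c])
        if prepared.contains(tri_poly):
            w[tri] += areas[ti] / 3.0
            continue
        if not prepared.intersects(tri_poly):
            continue
        cent = (a + b + c) / 3.0
        mids = [(a + b) / 2.0, (b + c) / 2.0, (c + a) / 2.0]
        quads = [
            Polygon([a, mids[0], cent, mids[2]]),
            Polygon([b, mids[1], cent, mids[0]]),
            Polygon([c, mids[2], cent, mids[1]]),
        ]
        for v, q in zip(tri, quads):
            w[v] += q.intersection(window).area
    return w
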
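"""Triangulated spherical shells and the two-shell membrane skeleton.

The membrane of the polymersome is represented by two concentric closed
triangular meshes ("skeletons"). Each mesh node is a finite-size blob;
corresponding nodes of the two shells are tethered radially so the
inter-shell gap stays near its equilibrium value. Nodes are placed by a
Fibonacci-spiral lattice (quasi-uniform for arbitrary node counts) and
triangulated by the convex hull, which for points on a sphere is the unique
closed genus-0 triangulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "TriangulatedShell",
    "ShellPair",
    "fibonacci_sphere",
    "make_sphere_mesh",
    "pair_shells",
    "layer_thickness",
]


@dataclass
class TriangulatedShell:
    """A closed triangulated sphere with per-node kinematics.

    Attributes
    ----------
    positions, velocities : (V, 3) float arrays, reduced units.
    triangles : (F, 3) int array
        Node indices with consistent outward orientation.
    edges : (E, 2) int array
        Unique undirected edges, each row sorted (i < j).
    r0_edge : (E,) float
        Equilibrium (as-built) edge lengths.
    S0_tri : (F,) float
        Equilibrium (as-built) triangle areas.
    blob_diameter : float
        Soft-sphere diameter ascribed to every node of this shell.
    """

    positions: np.ndarray
    triangles: np.ndarray
    edges: np.ndarray
    r0_edge: np.ndarray
    S0_tri: np.ndarray
    blob_diameter: float
    velocities: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.velocities is None:
            self.velocities = np.zeros_like(self.positions)
        v, e, f = self.n_nodes, len(self.edges), len(self.triangles)
        if v - e + f != 2:
            raise ValueError(f"not a closed genus-0 surface: V-E+F = {v - e + f}")
        if np.any(self.S0_tri <= 0):
            raise ValueError("degenerate triangle with non-positive equilibrium area")

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    def triangle_areas(self, positions: np.ndarray | None = None) -> np.ndarray:
        pos = self.positions if positions is None else positions
        p = pos[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def area(self) -> float:
        """Total current surface area of the mesh."""
        return float(self.triangle_areas().sum())

    def enclosed_volume(self) -> float:
        """Signed volume from the divergence theorem; positive for outward faces."""
        p = self.positions[self.triangles]
        return float(np.einsum("ij,ij->", p[:, 0], np.cross(p[:, 1], p[:, 2])) / 6.0)

    def edge_lengths(self, positions: np.ndarray | None = None) -> np.ndarray:
        pos = self.positions if positions is None else positions
        d = pos[self.edges[:, 1]] - pos[self.edges[:, 0]]
        return np.linalg.norm(d, axis=1)


@dataclass
class ShellPair:
    """Two concentric shells with a node-to-node radial correspondence.

    ``correspondence[i]`` is the inner-shell node tethered to outer node
    ``i``; the map is a bijection. ``r0_tether`` holds the equilibrium
    radial distances, (Dout - Din)/2 for a concentric as-built pair.
    """

    outer: TriangulatedShell
    inner: TriangulatedShell
    correspondence: np.ndarray
    r0_tether: np.ndarray

    def __post_init__(self) -> None:
        if self.outer.n_nodes != self.inner.n_nodes:
            raise ValueError("shells must have equal node counts")
        if len(np.unique(self.correspondence)) != self.outer.n_nodes:
            raise ValueError("correspondence is not a bijection")


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points on the Fibonacci (golden-angle) spiral."""
    if n < 12:
        raise ValueError(f"need at least 12 nodes for a sensible closed mesh, got {n}")
    i = np.arange(n, dtype=float)
    # offset 0.5 avoids polar clustering (Marques-Bouville spacing)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _oriented_hull(points: np.ndarray) -> np.ndarray:
    """Convex-hull triangles of points on a sphere, oriented outward."""
    try:
        hull = ConvexHull(points)
    except QhullError as exc:  # coplanar / degenerate input
        raise ValueError(f"degenerate node set, cannot triangulate: {exc}") from exc
    tri = hull.simplices.copy()
    p = points[tri]
    normals = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    centroids = p.mean(axis=1)  # hull of sphere points is centred at origin
    flip = np.einsum("ij,ij->i", normals, centroids) < 0
    tri[flip] = tri[flip][:, [0, 2, 1]]
    return tri


def _edges_from_triangles(triangles: np.ndarray) -> np.ndarray:
    e = np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


def make_sphere_mesh(n_nodes: int, diameter: float, blob_diameter: float) -> TriangulatedShell:
    """Build one closed quasi-uniform triangulated sphere.

    Parameters are in reduced units; the as-built edge lengths and triangle
    areas become the stress-free reference state of the elastic network.
    """
    if not diameter > 0:
        raise ValueError(f"diameter must be > 0, got {diameter}")
    pts = fibonacci_sphere(n_nodes) * (diameter / 2.0)
    tri = _oriented_hull(pts)
    edges = _edges_from_triangles(tri)
    shell = TriangulatedShell(
        positions=pts,
        triangles=tri,
        edges=edges,
        r0_edge=np.linalg.norm(pts[edges[:, 1]] - pts[edges[:, 0]], axis=1),
        S0_tri=np.full(len(tri), np.nan),
        blob_diameter=blob_diameter,
    )
    # fill S0 from the as-built geometry (post-init checks need it > 0)
    shell.S0_tri = shell.triangle_areas()
    if np.any(shell.S0_tri <= 0):
        raise ValueError("hull produced a degenerate triangle")
    return shell


def pair_shells(outer: TriangulatedShell, inner: TriangulatedShell) -> ShellPair:
    """Match each outer node to the best radially aligned inner node.

    Uses an optimal assignment on direction cosines, which reduces to the
    identity map when the inner shell was built by radially scaling the
    outer one.
    """
    if outer.n_nodes != inner.n_nodes:
        raise ValueError(
            f"shells must have equal node counts, got {outer.n_nodes} and {inner.n_nodes}"
        )
    u_out = outer.positions / np.linalg.norm(outer.positions, axis=1, keepdims=True)
    u_in = inner.positions / np.linalg.norm(inner.positions, axis=1, keepdims=True)
    alignment = u_out @ u_in.T
    rows, cols = linear_sum_assignment(-alignment)
    corr = np.empty(outer.n_nodes, dtype=np.int64)
    corr[rows] = cols
    r0 = np.linalg.norm(outer.positions - inner.positions[corr], axis=1)
    return ShellPair(outer=outer, inner=inner, correspondence=corr, r0_tether=r0)


def layer_thickness(Dout: float, dout: float, Din: float, din: float) -> float:
    """Width of the intra-membrane layer accessible to nanoparticles.

    ``l = (Dout - dout - Din - din) / 2``: the radial gap between the shell
    mid-surfaces minus the blob radii on either side. Must be positive for
    the layer to hold particles at all (and >= the particle diameter for a
    monolayer to fit).
    """
    ell = 0.5 * (Dout - dout - Din - din)
    if ell <= 0:
        raise ValueError(
            f"layer cannot accommodate particles: thickness {ell} <= 0 "
            f"for Dout={Dout}, dout={dout}, Din={Din}, din={din}"
        )
    return ell
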
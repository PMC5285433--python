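"""Triangulation of the dermal slice: generation, quality and motion.

The mesh generator follows the force-equilibrium idea of Persson & Strang
(DistMesh): points start on a structured equilateral-row layout, every
Delaunay edge acts as a slightly compressed bar pushing its endpoints apart,
and points leaving the rectangle are projected back onto its boundary.  On
the rectangular slice the interior relaxes to (near-)equilateral triangles;
only the triangles adjacent to the lateral edges remain merely close to
equilateral.

Mesh motion is Lagrangian: nodes carry the material displacement, and the
element quality/orientation is monitored so that an inverting element can
signal a time-step rejection instead of silently corrupting the transport
operators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .geometry import BOUNDARY_TAGS, DomainSpec

__all__ = [
    "TriMesh",
    "triangle_quality",
    "structured_points",
    "generate_mesh",
    "move_mesh",
    "MeshingError",
    "MeshInversionError",
]


class MeshingError(RuntimeError):
    """Mesh generation failed to reach the requested quality/resolution."""


class MeshInversionError(RuntimeError):
    """An element inverted during mesh motion (time-step rejection signal)."""


def triangle_quality(A, B, C):
    """Quality measure ``alpha = 2 sqrt(3) |CA x CB| / (|CA|^2+|AB|^2+|BC|^2)``.

    ``alpha`` is 1 exactly for equilateral triangles, 0 for collinear points,
    and is invariant under similarity transforms.  Vectorized over leading
    axes; coincident points give 0 (collinear limit), never an error.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    C = np.asarray(C, dtype=float)
    CA = A - C
    CB = B - C
    AB = B - A
    cross = np.abs(CA[..., 0] * CB[..., 1] - CA[..., 1] * CB[..., 0])
    denom = (CA**2).sum(-1) + (AB**2).sum(-1) + (CB**2).sum(-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(denom > 0, 2.0 * np.sqrt(3.0) * cross / np.where(denom > 0, denom, 1.0), 0.0)
    return alpha if np.ndim(alpha) else float(alpha)


@dataclass
class TriMesh:
    """Conforming triangulation in reference and current coordinates.

    ``nodes_ref`` are Lagrangian coordinates (fixed), ``nodes_cur`` Eulerian
    ones (``nodes_cur = nodes_ref + displacement``).  Boundary edges carry one
    of the tags B.I-B.IV.  ``velocity`` is the grid velocity of the last
    accepted step (cm/day).
    """

    nodes_ref: np.ndarray                 # (n, 2)
    triangles: np.ndarray                 # (m, 3) CCW
    boundary_edges: np.ndarray            # (k, 2) node indices
    boundary_tags: np.ndarray             # (k,) entries from BOUNDARY_TAGS
    nodes_cur: np.ndarray = field(default=None)  # type: ignore[assignment]
    velocity: np.ndarray = field(default=None)   # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.nodes_ref = np.asarray(self.nodes_ref, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.nodes_cur is None:
            self.nodes_cur = self.nodes_ref.copy()
        if self.velocity is None:
            self.velocity = np.zeros_like(self.nodes_ref)

    @property
    def n_nodes(self) -> int:
        return self.nodes_ref.shape[0]

    @property
    def displacement(self) -> np.ndarray:
        return self.nodes_cur - self.nodes_ref

    def signed_areas(self, current: bool = True) -> np.ndarray:
        p = self.nodes_cur if current else self.nodes_ref
        a, b, c = (p[self.triangles[:, i]] for i in range(3))
        return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                      - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0]))

    def qualities(self, current: bool = False) -> np.ndarray:
        p = self.nodes_cur if current else self.nodes_ref
        t = self.triangles
        return triangle_quality(p[t[:, 0]], p[t[:, 1]], p[t[:, 2]])

    def edge_lengths(self, current: bool = False) -> np.ndarray:
        p = self.nodes_cur if current else self.nodes_ref
        e = _unique_edges(self.triangles)
        return np.linalg.norm(p[e[:, 0]] - p[e[:, 1]], axis=1)

    def boundary_nodes(self, tag: str | None = None) -> np.ndarray:
        if tag is None:
            return np.unique(self.boundary_edges)
        return np.unique(self.boundary_edges[self.boundary_tags == tag])


def _unique_edges(tri: np.ndarray) -> np.ndarray:
    e = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    return np.unique(np.sort(e, axis=1), axis=0)


def _boundary_edges(tri: np.ndarray) -> np.ndarray:
    """Directed boundary edges traversed CCW (outward normal = (dy, -dx))."""
    e = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    es = np.sort(e, axis=1)
    uniq, inv, counts = np.unique(es, axis=0, return_inverse=True, return_counts=True)
    return e[counts[inv] == 1]


def _tag_edges(points: np.ndarray, edges: np.ndarray, domain: DomainSpec, tol: float):
    mid = 0.5 * (points[edges[:, 0]] + points[edges[:, 1]])
    tags = np.empty(edges.shape[0], dtype=object)
    tags[:] = ""
    tags[np.abs(mid[:, 1] - domain.z_min) < tol] = "B.I"
    tags[np.abs(mid[:, 1] - domain.z_max) < tol] = "B.III"
    tags[np.abs(mid[:, 0] - domain.y_max) < tol] = "B.II"
    tags[np.abs(mid[:, 0] - domain.y_min) < tol] = "B.IV"
    if np.any(tags == ""):
        raise MeshingError("untagged boundary edges: boundary is not rectangular")
    return tags.astype(str)


def structured_points(domain: DomainSpec, h: float):
    """Equilateral-row point layout snapped to the rectangle.

    Row spacing is ``h * sqrt(3)/2`` rounded so an integer number of rows
    spans the thickness; odd rows are offset by half a column and completed
    with the two lateral end points.  Returns ``(points, n_fixed_corners)``
    with the four corners placed first.
    """
    W, H = domain.width, domain.thickness
    nrow = max(1, round(H / (h * np.sqrt(3.0) / 2.0)))
    ncol = max(2, round(W / h))
    dy = H / nrow
    dx = W / ncol
    rows = []
    for j in range(nrow + 1):
        y = domain.z_min + j * dy
        if j % 2 == 0:
            x = domain.y_min + dx * np.arange(ncol + 1)
        else:
            x = np.concatenate((
                [domain.y_min],
                domain.y_min + dx * (0.5 + np.arange(ncol)),
                [domain.y_max],
            ))
        rows.append(np.column_stack([x, np.full(x.size, y)]))
    pts = np.vstack(rows)
    corners = np.array([
        [domain.y_min, domain.z_min], [domain.y_max, domain.z_min],
        [domain.y_max, domain.z_max], [domain.y_min, domain.z_max],
    ])
    # put corners first and drop duplicates of them
    d = np.min(np.linalg.norm(pts[:, None, :] - corners[None, :, :], axis=2), axis=1)
    pts = np.vstack([corners, pts[d > 1e-12 * max(W, H)]])
    return pts, 4


def _triangulate(points: np.ndarray) -> np.ndarray:
    tri = Delaunay(points).simplices
    a, b, c = points[tri[:, 0]], points[tri[:, 1]], points[tri[:, 2]]
    area2 = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    flip = area2 < 0
    tri[flip] = tri[flip][:, ::-1]
    # drop degenerate slivers from collinear boundary points
    q = triangle_quality(points[tri[:, 0]], points[tri[:, 1]], points[tri[:, 2]])
    return tri[q > 1e-12]


def generate_mesh(
    domain: DomainSpec,
    target_edge_length: float,
    seed: int = 0,
    max_iter: int = 200,
    fscale: float = 1.2,
    deltat: float = 0.2,
    dptol: float = 1e-3,
    ttol: float = 0.1,
    jitter: float = 0.0,
    min_quality: float | None = None,
) -> TriMesh:
    """Force-equilibrium (DistMesh-style) triangulation of the dermal slice.

    Parameters mirror the classical algorithm: ``fscale`` is the bar
    pre-compression, ``deltat`` the pseudo-time step of the point relaxation,
    ``dptol`` the convergence threshold on interior point motion (in units of
    the target edge length).  ``seed`` controls the optional symmetry-breaking
    jitter of the initial interior points (``jitter`` as a fraction of the
    edge length, 0 disables it); the algorithm is deterministic given the
    seed.  Raises :class:`MeshingError` if the resolution cannot be meshed or
    ``min_quality`` is not attained.
    """
    h0 = float(target_edge_length)
    if h0 <= 0:
        raise MeshingError("target edge length must be positive")
    if h0 > domain.thickness:
        raise MeshingError(
            f"target edge length {h0} exceeds the slice thickness "
            f"{domain.thickness}; need at least one element across"
        )
    pts, nfix = structured_points(domain, h0)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        interior = (
            (pts[:, 0] > domain.y_min + 1e-12) & (pts[:, 0] < domain.y_max - 1e-12)
            & (pts[:, 1] > domain.z_min + 1e-12) & (pts[:, 1] < domain.z_max - 1e-12)
        )
        pts[interior] += jitter * h0 * (rng.random((interior.sum(), 2)) - 0.5)

    geps = 1e-9 * h0
    pold = np.full_like(pts, np.inf)
    bars = None
    for _ in range(max_iter):
        if np.max(np.linalg.norm(pts - pold, axis=1)) > ttol * h0:
            tri = _triangulate(pts)
            bars = _unique_edges(tri)
            pold = pts.copy()
        vec = pts[bars[:, 0]] - pts[bars[:, 1]]
        L = np.linalg.norm(vec, axis=1)
        L0 = fscale * np.sqrt((L**2).sum() / len(L))
        Fmag = np.maximum(L0 - L, 0.0)
        Fvec = (Fmag / np.maximum(L, geps))[:, None] * vec
        force = np.zeros_like(pts)
        np.add.at(force, bars[:, 0], Fvec)
        np.add.at(force, bars[:, 1], -Fvec)
        force[:nfix] = 0.0
        pts = pts + deltat * force
        np.clip(pts[:, 0], domain.y_min, domain.y_max, out=pts[:, 0])
        np.clip(pts[:, 1], domain.z_min, domain.z_max, out=pts[:, 1])
        on_bnd = (
            (pts[:, 0] <= domain.y_min + geps) | (pts[:, 0] >= domain.y_max - geps)
            | (pts[:, 1] <= domain.z_min + geps) | (pts[:, 1] >= domain.z_max - geps)
        )
        moved = np.linalg.norm(deltat * force[~on_bnd], axis=1)
        if moved.size == 0 or moved.max() < dptol * h0:
            break

    tri = _triangulate(pts)
    bedges = _boundary_edges(tri)
    tags = _tag_edges(pts, bedges, domain, tol=1e-6 * max(domain.width, domain.thickness))
    mesh = TriMesh(nodes_ref=pts, triangles=tri, boundary_edges=bedges, boundary_tags=tags)
    if min_quality is not None:
        q = mesh.qualities().min()
        if q < min_quality:
            raise MeshingError(
                f"minimum triangle quality {q:.3f} below requested {min_quality}"
            )
    return mesh


def move_mesh(mesh: TriMesh, increment: np.ndarray, dt: float) -> TriMesh:
    """Advance the current configuration by a nodal displacement increment.

    Stores the grid velocity ``increment / dt`` and raises
    :class:`MeshInversionError` if any element loses its positive orientation
    (the caller treats this as a time-step rejection).
    """
    increment = np.asarray(increment, dtype=float)
    if increment.shape != mesh.nodes_cur.shape:
        raise ValueError("increment must be defined at all nodes")
    new = TriMesh(
        nodes_ref=mesh.nodes_ref,
        triangles=mesh.triangles,
        boundary_edges=mesh.boundary_edges,
        boundary_tags=mesh.boundary_tags,
        nodes_cur=mesh.nodes_cur + increment,
        velocity=increment / dt if dt > 0 else np.zeros_like(increment),
    )
    if np.any(new.signed_areas(current=True) <= 0.0):
        raise MeshInversionError("element inverted during mesh motion")
    return new
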
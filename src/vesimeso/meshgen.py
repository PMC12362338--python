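"""Closed triangulated reference surfaces for shells.

Microbubbles are meshed as icospheres (icosahedral subdivision), gas vesicles
as a cylinder of staggered vertex rings tapered into conical end caps.  Every
mesh carries its undeformed reference geometry: per-face reference areas and
2D edge frames (used by the constant-strain-triangle elasticity) and per-edge
reference dihedral angles (used by the dihedral bending energy).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np


# ---------------------------------------------------------------------------
# Core container
# ---------------------------------------------------------------------------

@dataclass
class TriMesh:
    """Closed orientable triangulated surface with reference configuration.

    ``vertices`` is the current (deformed) geometry; ``reference_vertices``
    the undeformed one.  Faces are counter-clockwise seen from outside.
    """

    vertices: np.ndarray          # (V, 3) float64
    faces: np.ndarray             # (F, 3) int64
    reference_vertices: np.ndarray = None  # (V, 3)
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.reference_vertices is None:
            self.reference_vertices = self.vertices.copy()
        else:
            self.reference_vertices = np.ascontiguousarray(
                self.reference_vertices, dtype=np.float64)

    # -- basic counts ------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriMesh":
        m = TriMesh(self.vertices.copy(), self.faces.copy(),
                    self.reference_vertices.copy())
        return m

    def with_vertices(self, verts: np.ndarray) -> "TriMesh":
        """Same topology and reference, different deformed positions."""
        m = TriMesh(verts, self.faces, self.reference_vertices)
        m._cache = self._cache  # reference-derived tables are shared
        return m

    # -- reference-derived tables (computed once, shared) ------------------
    def _ref_tables(self):
        if "ref" not in self._cache:
            self._cache["ref"] = _build_reference_tables(
                self.reference_vertices, self.faces)
        return self._cache["ref"]

    @property
    def inv_dm(self) -> np.ndarray:
        """(F, 2, 2) inverse reference edge matrices in the local face frame."""
        return self._ref_tables()["inv_dm"]

    @property
    def ref_area(self) -> np.ndarray:
        """(F,) reference triangle areas."""
        return self._ref_tables()["area"]

    @property
    def ref_frames(self) -> np.ndarray:
        """(F, 2, 3) orthonormal in-plane frame (u, v) of each reference face."""
        return self._ref_tables()["frame"]

    @property
    def edges(self) -> np.ndarray:
        """(E, 4) int: [a, b, c, d] — edge a-b, opposite vertices c, d."""
        return self._ref_tables()["edges"]

    @property
    def theta0(self) -> np.ndarray:
        """(E,) reference dihedral angles."""
        return self._ref_tables()["theta0"]

    # -- geometry ----------------------------------------------------------
    def face_normals(self, reference: bool = False) -> np.ndarray:
        x = self.reference_vertices if reference else self.vertices
        v0, v1, v2 = (x[self.faces[:, k]] for k in range(3))
        n = np.cross(v1 - v0, v2 - v0)
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def face_areas(self, reference: bool = False) -> np.ndarray:
        x = self.reference_vertices if reference else self.vertices
        v0, v1, v2 = (x[self.faces[:, k]] for k in range(3))
        return 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)

    def total_area(self, reference: bool = False) -> float:
        return float(self.face_areas(reference).sum())

    def validate(self) -> None:
        """Assert closed orientable 2-manifold with consistent orientation."""
        directed = set()
        for f in self.faces:
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                if (a, b) in directed:
                    raise ValueError(f"duplicated directed edge {(a, b)}")
                directed.add((int(a), int(b)))
        for a, b in directed:
            if (b, a) not in directed:
                raise ValueError(f"boundary or inconsistently oriented edge {(a, b)}")
        V, F = self.n_vertices, self.n_faces
        E = len(directed) // 2
        if V - E + F != 2:
            raise ValueError(f"Euler characteristic {V - E + F} != 2")
        if np.any(self.face_areas(reference=True) <= 0):
            raise ValueError("degenerate reference face")
        if enclosed_volume(self) <= 0:
            raise ValueError("inward orientation: enclosed volume is negative")


def _build_reference_tables(ref: np.ndarray, faces: np.ndarray) -> dict:
    v0 = ref[faces[:, 0]]
    e1 = ref[faces[:, 1]] - v0
    e2 = ref[faces[:, 2]] - v0
    n = np.cross(e1, e2)
    nrm = np.linalg.norm(n, axis=1, keepdims=True)
    if np.any(nrm == 0):
        raise ValueError("degenerate reference triangle")
    nhat = n / nrm
    u = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
    v = np.cross(nhat, u)
    frame = np.stack([u, v], axis=1)  # (F,2,3)
    dm = np.empty((len(faces), 2, 2))
    dm[:, 0, 0] = np.einsum("ij,ij->i", e1, u)
    dm[:, 0, 1] = np.einsum("ij,ij->i", e2, u)
    dm[:, 1, 0] = np.einsum("ij,ij->i", e1, v)
    dm[:, 1, 1] = np.einsum("ij,ij->i", e2, v)
    area = 0.5 * (dm[:, 0, 0] * dm[:, 1, 1] - dm[:, 0, 1] * dm[:, 1, 0])
    inv_dm = np.linalg.inv(dm)
    edges, theta0 = _edge_table(ref, faces)
    return {"inv_dm": np.ascontiguousarray(inv_dm),
            "area": np.ascontiguousarray(area),
            "frame": np.ascontiguousarray(frame),
            "edges": edges, "theta0": theta0}


def _edge_table(ref: np.ndarray, faces: np.ndarray):
    """Unique interior edges with their two opposite vertices.

    Row [a, b, c, d]: edge a->b is traversed in this direction by the face
    containing opposite vertex c; the adjacent face (traversing b->a)
    contributes opposite vertex d.
    """
    half = {}
    for f in faces:
        tri = (int(f[0]), int(f[1]), int(f[2]))
        for i in range(3):
            a, b = tri[i], tri[(i + 1) % 3]
            half[(a, b)] = tri[(i + 2) % 3]
    rows = []
    for (a, b), c in half.items():
        if a < b:
            d = half.get((b, a))
            if d is None:
                raise ValueError("open mesh: edge without partner face")
            rows.append((a, b, c, d))
    edges = np.array(sorted(rows), dtype=np.int64)
    theta0 = dihedral_angles(ref, edges)
    return edges, theta0


def dihedral_angles(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Signed dihedral angle across each edge (0 for coplanar faces)."""
    xa, xb, xc, xd = (x[edges[:, k]] for k in range(4))
    e = xb - xa
    n1 = np.cross(xb - xa, xc - xa)
    n2 = np.cross(xd - xa, xb - xa)
    n1h = n1 / np.linalg.norm(n1, axis=1, keepdims=True)
    n2h = n2 / np.linalg.norm(n2, axis=1, keepdims=True)
    eh = e / np.linalg.norm(e, axis=1, keepdims=True)
    sin = np.einsum("ij,ij->i", np.cross(n1h, n2h), eh)
    cos = np.einsum("ij,ij->i", n1h, n2h)
    return np.arctan2(sin, cos)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def icosphere(subdivisions: int, R0: float) -> TriMesh:
    """Icosahedrally subdivided sphere with 10*4^s + 2 vertices at radius R0."""
    if not (0 <= subdivisions <= 7):
        raise ValueError("subdivisions must be in [0, 7]")
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    t = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array([
        (-1, t, 0), (1, t, 0), (-1, -t, 0), (1, -t, 0),
        (0, -1, t), (0, 1, t), (0, -1, -t), (0, 1, -t),
        (t, 0, -1), (t, 0, 1), (-t, 0, -1), (-t, 0, 1)], dtype=float)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1)]
    verts = list(verts / np.linalg.norm(verts, axis=1, keepdims=True))
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                p = verts[i] + verts[j]
                verts.append(p / np.linalg.norm(p))
                cache[key] = len(verts) - 1
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    x = np.asarray(verts) * R0
    mesh = TriMesh(x, np.asarray(faces, dtype=np.int64))
    if enclosed_volume(mesh) < 0:
        mesh = TriMesh(x, mesh.faces[:, ::-1].copy())
    return mesh


def _ring(n: int, radius: float, z: float, phase: float) -> np.ndarray:
    ang = phase + 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.full(n, z)])


def _bridge(lower_idx, lower_ang, upper_idx, upper_ang, flip=False):
    """Triangulate between two vertex rings by merging sorted angles.

    Emits outward-oriented faces for an upper ring above a lower ring on a
    surface of revolution about +z.
    """
    n0, n1 = len(lower_idx), len(upper_idx)
    faces = []
    # rotate the upper ring so both sweeps start at nearly the same angle
    j0 = int(np.argmin(np.abs(np.angle(np.exp(1j * (upper_ang - lower_ang[0]))))))
    li = list(lower_idx) + [lower_idx[0]]
    ui = [upper_idx[(j0 + k) % n1] for k in range(n1)] + [upper_idx[j0]]
    la = [0.0]
    for k in range(1, n0 + 1):
        d = float(np.angle(np.exp(1j * (lower_ang[k % n0] - lower_ang[k - 1]))))
        la.append(la[-1] + (d if d > 0 else d + 2 * np.pi))
    off = float(np.angle(np.exp(1j * (upper_ang[j0] - lower_ang[0]))))
    ua = [off]
    for k in range(1, n1 + 1):
        d = float(np.angle(np.exp(1j * (upper_ang[(j0 + k) % n1]
                                        - upper_ang[(j0 + k - 1) % n1]))))
        ua.append(ua[-1] + (d if d > 0 else d + 2 * np.pi))
    i, j = 0, 0
    while i < n0 or j < n1:
        if (j >= n1) or (i < n0 and la[i + 1] <= ua[j + 1]):
            faces.append((li[i], li[i + 1], ui[j]))
            i += 1
        else:
            faces.append((li[i], ui[j + 1], ui[j]))
            j += 1
    if flip:
        faces = [(a, c, b) for (a, b, c) in faces]
    return faces


def gv_capsule(R: float, L_cyl: float, n_ring: int, ring_spacing: float,
               *, cone_height: float | None = None,
               cone_ring_sizes: tuple[int, ...] = (20, 10, 5)) -> TriMesh:
    """Gas-vesicle mesh: staggered-ring cylinder with tapered conical caps.

    Cylinder rings of ``n_ring`` vertices are stacked every ``ring_spacing``
    along z (adjacent rings rotated by half the angular spacing); each cap
    tapers through rings of ``cone_ring_sizes`` vertices to an apex point.
    """
    if R <= 0 or L_cyl < 0 or n_ring < 3:
        raise ValueError("need R > 0, L_cyl >= 0, n_ring >= 3")
    if cone_height is None:
        cone_height = R
    n_cyl = int(round(L_cyl / ring_spacing)) + 1
    if n_cyl < 2:
        raise ValueError("cylinder must contain at least two rings")
    verts: list[np.ndarray] = []
    ring_indices: list[np.ndarray] = []
    ring_angles: list[np.ndarray] = []

    def add_ring(n, radius, z, phase):
        if radius <= 0:
            raise ValueError("degenerate taper: ring radius <= 0 before apex")
        start = sum(len(v) for v in verts)
        verts.append(_ring(n, radius, z, phase))
        ring_indices.append(np.arange(start, start + n))
        ring_angles.append(phase + 2 * np.pi * np.arange(n) / n)

    half_step = np.pi / n_ring
    # bottom cone rings (from near-apex upward), then cylinder, then top cone
    zs_cyl = np.linspace(-L_cyl / 2.0, L_cyl / 2.0, n_cyl)
    m = len(cone_ring_sizes)
    taper_t = [(k + 1) / (m + 1) for k in range(m)]  # 0 < t < 1, t=1 is apex
    for k in reversed(range(m)):
        t = taper_t[k]
        add_ring(cone_ring_sizes[k], R * (1 - t), -L_cyl / 2.0 - cone_height * t,
                 phase=half_step * k)
    for j, z in enumerate(zs_cyl):
        add_ring(n_ring, R, z, phase=half_step * (j % 2))
    for k in range(m):
        t = taper_t[k]
        add_ring(cone_ring_sizes[k], R * (1 - t), L_cyl / 2.0 + cone_height * t,
                 phase=half_step * k)

    faces: list[tuple[int, int, int]] = []
    for r in range(len(ring_indices) - 1):
        faces += _bridge(ring_indices[r], ring_angles[r],
                         ring_indices[r + 1], ring_angles[r + 1])
    # apexes
    x = np.vstack(verts)
    apex_bot = len(x)
    apex_top = len(x) + 1
    x = np.vstack([x, [0.0, 0.0, -L_cyl / 2.0 - cone_height],
                   [0.0, 0.0, L_cyl / 2.0 + cone_height]])
    bot = ring_indices[0]
    for k in range(len(bot)):
        faces.append((int(bot[(k + 1) % len(bot)]), int(bot[k]), apex_bot))
    top = ring_indices[-1]
    for k in range(len(top)):
        faces.append((int(top[k]), int(top[(k + 1) % len(top)]), apex_top))
    mesh = TriMesh(x, np.asarray(faces, dtype=np.int64))
    mesh.validate()
    return mesh


def gv_mesh_preset(R: float = 2.0, L_cyl: float = 12.0) -> TriMesh:
    """Production GV mesh: 37 cylinder rings x 36 + 2x(20+10+5) + 2 apexes = 1404."""
    return gv_capsule(R, L_cyl, n_ring=36, ring_spacing=L_cyl / 36.0,
                      cone_height=R, cone_ring_sizes=(20, 10, 5))


# ---------------------------------------------------------------------------
# Rib direction field
# ---------------------------------------------------------------------------

@dataclass
class RibField:
    """Per-face in-plane unit vector m (the orthotropy axis, perpendicular
    to the protein ribs), in 3D and in local 2D face-frame coordinates."""

    m3: np.ndarray   # (F, 3)
    m2: np.ndarray   # (F, 2) components in the reference face frame
    n_fallback: int = 0


def rib_direction_field(mesh: TriMesh, axis: np.ndarray) -> RibField:
    """Project ``axis`` into each reference face plane and normalize.

    Ribs run nearly perpendicular to the shell axis, so the orthotropy axis m
    is the in-plane projection of the axis.  Faces nearly perpendicular to the
    axis (cone apex fans) fall back to the azimuth-orthogonal direction.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    n = mesh.face_normals(reference=True)
    proj = axis[None, :] - np.einsum("ij,j->i", n, axis)[:, None] * n
    norm = np.linalg.norm(proj, axis=1)
    fallback = norm < 1e-8
    if np.any(fallback):
        centroids = mesh.reference_vertices[mesh.faces].mean(axis=1)
        for idx in np.nonzero(fallback)[0]:
            e_phi = np.cross(axis, centroids[idx])
            if np.linalg.norm(e_phi) < 1e-12:
                e_phi = np.array([1.0, 0.0, 0.0])
            m = np.cross(n[idx], e_phi / np.linalg.norm(e_phi))
            proj[idx] = m
            norm[idx] = np.linalg.norm(m)
        warnings.warn(f"rib field fell back to azimuth-orthogonal direction on "
                      f"{int(fallback.sum())} faces")
    m3 = proj / norm[:, None]
    frames = mesh.ref_frames  # (F,2,3)
    m2 = np.einsum("fkj,fj->fk", frames, m3)
    m2 /= np.linalg.norm(m2, axis=1, keepdims=True)
    return RibField(m3=m3, m2=np.ascontiguousarray(m2),
                    n_fallback=int(fallback.sum()))


# ---------------------------------------------------------------------------
# Measures and I/O
# ---------------------------------------------------------------------------

def enclosed_volume(mesh: TriMesh, reference: bool = False) -> float:
    """Signed divergence-theorem volume (positive for outward orientation)."""
    x = mesh.reference_vertices if reference else mesh.vertices
    v0, v1, v2 = (x[mesh.faces[:, k]] for k in range(3))
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def save_obj(mesh: TriMesh, path: str) -> None:
    import trimesh as _tm
    _tm.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                process=False).export(path, file_type="obj")


def load_obj(path: str) -> TriMesh:
    import trimesh as _tm
    tm = _tm.load(path, file_type="obj", process=False)
    return TriMesh(np.asarray(tm.vertices, dtype=float),
                   np.asarray(tm.faces, dtype=np.int64))
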
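"""Minimal triangulated-surface container with exact closest-point queries.

The surface-matching registration needs the exact closest point on a mesh
for ~20 digitized points per iteration.  For meshes of a few thousand
triangles a fully vectorized point-vs-all-triangles evaluation (Ericson's
closest-point-on-triangle region decomposition) is faster and more
predictable than spatial indexing, and is what is implemented here.
trimesh is used for PLY import/export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TriangleMesh", "closest_point_on_triangles"]


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each query point.

    Parameters
    ----------
    points : (n, 3)
    triangles : (m, 3, 3)  vertex coordinates a, b, c per triangle

    Returns
    -------
    (n, m, 3) array of closest points.
    """
    p = np.asarray(points, dtype=float)[:, None, :]          # (n, 1, 3)
    a = np.asarray(triangles, dtype=float)[None, :, 0, :]    # (1, m, 3)
    b = np.asarray(triangles, dtype=float)[None, :, 1, :]
    c = np.asarray(triangles, dtype=float)[None, :, 2, :]

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)

    bp = p - b
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)

    cp = p - c
    d5 = np.sum(ab * cp, axis=-1)
    d6 = np.sum(ac * cp, axis=-1)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(np.abs(d1 - d3) > 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where(np.abs(d2 - d6) > 0, d2 / (d2 - d6), 0.0)
        den_bc = (d4 - d3) + (d5 - d6)
        w_bc = np.where(np.abs(den_bc) > 0, (d4 - d3) / den_bc, 0.0)
        denom = va + vb + vc
        inv = np.where(np.abs(denom) > 0, 1.0 / denom, 0.0)
    v_in = vb * inv
    w_in = vc * inv

    # candidates per barycentric region
    cand_a = a + np.zeros_like(p)
    cand_b = b + np.zeros_like(p)
    cand_c = c + np.zeros_like(p)
    cand_ab = a + v_ab[..., None] * ab
    cand_ac = a + w_ac[..., None] * ac
    cand_bc = b + w_bc[..., None] * (c - b)
    cand_in = a + v_in[..., None] * ab + w_in[..., None] * ac

    out = cand_in
    # apply in reverse precedence so earlier (vertex) regions win
    m_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    m_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    m_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    m_c = (d6 >= 0) & (d5 <= d6)
    m_b = (d3 >= 0) & (d4 <= d3)
    m_a = (d1 <= 0) & (d2 <= 0)
    out = np.where(m_bc[..., None], cand_bc, out)
    out = np.where(m_ac[..., None], cand_ac, out)
    out = np.where(m_ab[..., None], cand_ab, out)
    out = np.where(m_c[..., None], cand_c, out)
    out = np.where(m_b[..., None], cand_b, out)
    out = np.where(m_a[..., None], cand_a, out)
    return out


@dataclass
class TriangleMesh:
    """Triangle mesh: ``vertices`` (n, 3) float mm, ``faces`` (m, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        self._triangles = None
        self._vertex_normals = None

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    @property
    def triangles(self) -> np.ndarray:
        if self._triangles is None:
            self._triangles = self.vertices[self.faces]
        return self._triangles

    @property
    def vertex_normals(self) -> np.ndarray:
        """Area-weighted, unit vertex normals."""
        if self._vertex_normals is None:
            tri = self.triangles
            fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            vn = np.zeros_like(self.vertices)
            for k in range(3):
                np.add.at(vn, self.faces[:, k], fn)
            norms = np.linalg.norm(vn, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            self._vertex_normals = vn / norms
        return self._vertex_normals

    def closest_points(self, points: np.ndarray):
        """Exact closest surface points.

        Returns ``(closest (n,3), distances (n,), face_indices (n,))``.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        cand = closest_point_on_triangles(points, self.triangles)  # (n, m, 3)
        d2 = np.sum((cand - points[:, None, :]) ** 2, axis=-1)
        idx = np.argmin(d2, axis=1)
        rows = np.arange(points.shape[0])
        closest = cand[rows, idx]
        return closest, np.sqrt(d2[rows, idx]), idx

    def distances(self, points: np.ndarray) -> np.ndarray:
        return self.closest_points(points)[1]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangleMesh":
        return TriangleMesh(self.vertices @ np.asarray(rotation).T + translation, self.faces)

    # -- I/O -----------------------------------------------------------
    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    def export_ply(self, path) -> None:
        self.to_trimesh().export(str(path), encoding="ascii")

    @classmethod
    def from_ply(cls, path) -> "TriangleMesh":
        import trimesh

        tm = trimesh.load(str(path), process=False)
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))
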
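"""Triangle-mesh container and geometry primitives.

A :class:`SurfaceMesh` is a role-tagged triangle mesh in head-frame
coordinates (micrometres).  Roles name the anatomical interface the mesh
represents: the outer corneal surface, the front of the crystalline cones,
the front of the retina, and the retina/lamina interface.

Only what the pipeline needs is implemented: areas, divergence-theorem
volume, area-weighted vertex normals, nearest-vertex queries, and
Moller-Trumbore ray casting used by the thickness tracer.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

#: Interface roles, outermost first.
ROLES = ("cornea_outer", "cone_front", "retina_front", "lamina_front")


@dataclasses.dataclass
class SurfaceMesh:
    """A triangle mesh for one anatomical interface.

    Parameters
    ----------
    vertices : (n, 3) float array, μm, head frame.
    faces : (m, 3) int array of vertex indices, consistently wound so that
        triangle normals point outward (away from the eye interior).
    role : one of :data:`ROLES`, or "generic".
    """

    vertices: np.ndarray
    faces: np.ndarray
    role: str = "generic"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if not np.isfinite(self.vertices).all():
            raise ValueError("non-finite vertex coordinates")
        self._tree: cKDTree | None = None

    # -- basic derived quantities -------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """Return the (m, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self, normalized: bool = True) -> np.ndarray:
        tri = self.triangles()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        if normalized:
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            n = n / norm
        return n

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals(normalized=False), axis=1)

    def area(self) -> float:
        """Total surface area in μm²."""
        return float(self.face_areas().sum())

    def volume(self) -> float:
        """Enclosed volume in μm³ by the divergence theorem.

        Meaningful only for closed, outward-oriented meshes; the signed
        tetrahedron sum is returned as-is so orientation errors surface
        as negative volumes rather than being silently absorbed.
        """
        tri = self.triangles()
        return float(np.einsum("ij,ij->i", tri[:, 0],
                               np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)

    def edge_lengths(self) -> np.ndarray:
        tri = self.triangles()
        e = np.concatenate([tri[:, 1] - tri[:, 0],
                            tri[:, 2] - tri[:, 1],
                            tri[:, 0] - tri[:, 2]])
        return np.linalg.norm(e, axis=1)

    def centroid(self) -> np.ndarray:
        """Area-weighted surface centroid."""
        tri = self.triangles()
        c = tri.mean(axis=1)
        w = self.face_areas()
        return (c * w[:, None]).sum(axis=0) / w.sum()

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length."""
        fn = self.face_normals(normalized=False)  # length == 2*area
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return vn / norm

    # -- queries ------------------------------------------------------------

    def vertex_tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.vertices)
        return self._tree

    def transformed(self, matrix: np.ndarray) -> "SurfaceMesh":
        """Apply a 4x4 homogeneous transform; reflections flip the winding
        so the mesh stays outward-oriented."""
        matrix = np.asarray(matrix, dtype=np.float64)
        v = self.vertices @ matrix[:3, :3].T + matrix[:3, 3]
        f = self.faces
        if np.linalg.det(matrix[:3, :3]) < 0:
            f = f[:, ::-1]
        return SurfaceMesh(v, f, role=self.role)

    def ray_intersections(self, origin: np.ndarray, direction: np.ndarray,
                          eps: float = 1e-9) -> np.ndarray:
        """Sorted positive ray parameters t of all triangle hits.

        Moller-Trumbore over every face; fine at the mesh sizes this
        pipeline uses (≲1e5 faces per interface).
        """
        origin = np.asarray(origin, dtype=np.float64)
        d = np.asarray(direction, dtype=np.float64)
        tri = self.triangles()
        e1 = tri[:, 1] - tri[:, 0]
        e2 = tri[:, 2] - tri[:, 0]
        p = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, p)
        ok = np.abs(det) > eps
        inv = np.zeros_like(det)
        inv[ok] = 1.0 / det[ok]
        s = origin - tri[:, 0]
        u = np.einsum("ij,ij->i", s, p) * inv
        q = np.cross(s, e1)
        v = np.einsum("j,ij->i", d, q) * inv
        t = np.einsum("ij,ij->i", e2, q) * inv
        hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t > eps)
        ts = np.sort(t[hit])
        if len(ts) > 1:
            # merge duplicate hits on shared triangle edges
            keep = np.concatenate([[True], np.diff(ts) > 1e-7 * (1 + ts[:-1])])
            ts = ts[keep]
        return ts

    # -- IO -----------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        write_mesh(self, path)


# ---------------------------------------------------------------------------
# ASCII mesh IO (PLY / OBJ / STL).  Hand-rolled because no triangle-mesh
# library ships in the runtime environment; formats are the trivial ASCII
# variants only.

def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        _write_ply(mesh, path)
    elif suffix == ".obj":
        _write_obj(mesh, path)
    elif suffix == ".stl":
        _write_stl(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format: {suffix}")


def read_mesh(path: str | Path, role: str = "generic") -> SurfaceMesh:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        v, f = _read_ply(path)
    elif suffix == ".obj":
        v, f = _read_obj(path)
    elif suffix == ".stl":
        v, f = _read_stl(path)
    else:
        raise ValueError(f"unsupported mesh format: {suffix}")
    return SurfaceMesh(v, f, role=role)


def _write_ply(mesh: SurfaceMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment eyemap role={mesh.role}\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.10g} {v[1]:.10g} {v[2]:.10g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path}: not a PLY file")
        n_vert = n_face = None
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated PLY header")
            line = line.strip()
            if line.startswith("format") and "ascii" not in line:
                raise ValueError(f"{path}: only ASCII PLY supported")
            if line.startswith("element vertex"):
                n_vert = int(line.split()[-1])
            elif line.startswith("element face"):
                n_face = int(line.split()[-1])
            elif line == "end_header":
                break
        if n_vert is None or n_face is None:
            raise ValueError(f"{path}: missing vertex/face elements")
        verts = np.array([fh.readline().split()[:3] for _ in range(n_vert)],
                         dtype=np.float64)
        faces = np.array([fh.readline().split()[1:4] for _ in range(n_face)],
                         dtype=np.int64)
    return verts, faces


def _write_obj(mesh: SurfaceMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# eyemap role={mesh.role}\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.10g} {v[1]:.10g} {v[2]:.10g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def _read_obj(path: Path) -> tuple[np.ndarray, np.ndarray]:
    verts, faces = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
                for k in range(1, len(idx) - 1):  # fan-triangulate
                    faces.append([idx[0], idx[k], idx[k + 1]])
    return np.asarray(verts, dtype=np.float64), np.asarray(faces, dtype=np.int64)


def _write_stl(mesh: SurfaceMesh, path: Path) -> None:
    tri = mesh.triangles()
    normals = mesh.face_normals()
    with open(path, "w") as fh:
        fh.write(f"solid eyemap_{mesh.role}\n")
        for t, n in zip(tri, normals):
            fh.write(f"facet normal {n[0]:.10g} {n[1]:.10g} {n[2]:.10g}\n")
            fh.write("outer loop\n")
            for v in t:
                fh.write(f"vertex {v[0]:.10g} {v[1]:.10g} {v[2]:.10g}\n")
            fh.write("endloop\nendfacet\n")
        fh.write(f"endsolid eyemap_{mesh.role}\n")


def _read_stl(path: Path) -> tuple[np.ndarray, np.ndarray]:
    verts = []
    with open(path) as fh:
        first = fh.readline()
        if not first.lstrip().startswith("solid"):
            raise ValueError(f"{path}: only ASCII STL supported")
        for line in fh:
            parts = line.split()
            if parts and parts[0] == "vertex":
                verts.append([float(x) for x in parts[1:4]])
    verts = np.asarray(verts, dtype=np.float64)
    if len(verts) % 3:
        raise ValueError(f"{path}: vertex count not a multiple of 3")
    # weld duplicate vertices so the mesh is connected again
    uniq, inverse = np.unique(verts.round(decimals=6), axis=0,
                              return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return uniq.astype(np.float64), faces.astype(np.int64)
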
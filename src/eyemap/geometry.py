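"""Corneal surface geometry.

Extracts anatomical interface meshes from a labeled tomogram, spreads
sampling points evenly across the cornea, and estimates the local
quantities the optics depend on: outward normals (the local viewing
direction of an apposition eye), the local radius of curvature ``R``
from a least-squares sphere fit, surface area, enclosed volume, and the
orthographic silhouette ("projected") area that 2D photographs of eyes
actually measure.

All lengths are micrometres; the head frame has +x anterior, +z dorsal,
-y toward the animal's left.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from skimage import measure
import shapely
from shapely.geometry import Polygon

from .mesh import SurfaceMesh

logger = logging.getLogger(__name__)

#: label codes of a segmented eye volume
LABELS = {"background": 0, "lens": 1, "cone": 2, "retina": 3, "lamina": 4}

# each interface separates a shallow label from the set of labels at or
# below it; the pair pins which part of the marching-cubes surface to keep
_INTERFACES = {
    "cornea_outer": (0, 1, (1, 2, 3, 4)),
    "cone_front": (1, 2, (2, 3, 4)),
    "retina_front": (2, 3, (3, 4)),
    "lamina_front": (3, 4, (4,)),
}


@dataclasses.dataclass
class CornealSample:
    """One sampling point on the cornea and every local scalar measured there.

    Missing values are NaN; missingness propagates through derived metrics
    and is never imputed.
    """

    position: np.ndarray          # μm, head frame
    normal: np.ndarray            # outward unit normal (the local NV)
    azimuth: float = np.nan       # viewing direction, degrees
    elevation: float = np.nan
    radius: float = np.nan        # local radius of curvature R, μm
    facet_diameter: float = np.nan  # D, μm
    if_angle: float = np.nan      # inter-facet angle ΔΦ, degrees
    lens_thickness: float = np.nan    # L_lens, μm
    cone_thickness: float = np.nan    # L_cone, μm
    retina_thickness: float = np.nan  # L_retina, μm
    eye_parameter: float = np.nan     # P = ΔΦ[rad]·D, μm·rad
    sensitivity: float = np.nan       # S, μm²·sr
    radius_reliable: bool = True
    geometry_valid: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64)
        self.normal = np.asarray(self.normal, dtype=np.float64)


_FRAME_COLS = [
    "x", "y", "z", "nx", "ny", "nz", "azimuth", "elevation", "radius",
    "facet_diameter", "if_angle", "lens_thickness", "cone_thickness",
    "retina_thickness", "eye_parameter", "sensitivity",
    "radius_reliable", "geometry_valid",
]


def samples_to_frame(samples: list[CornealSample]):
    """Flatten samples into a pandas DataFrame (one row per sample)."""
    import pandas as pd

    rows = []
    for s in samples:
        rows.append([*s.position, *s.normal, s.azimuth, s.elevation,
                     s.radius, s.facet_diameter, s.if_angle,
                     s.lens_thickness, s.cone_thickness, s.retina_thickness,
                     s.eye_parameter, s.sensitivity,
                     s.radius_reliable, s.geometry_valid])
    return pd.DataFrame(rows, columns=_FRAME_COLS)


def frame_to_samples(df) -> list[CornealSample]:
    out = []
    for row in df.itertuples(index=False):
        out.append(CornealSample(
            position=np.array([row.x, row.y, row.z]),
            normal=np.array([row.nx, row.ny, row.nz]),
            azimuth=row.azimuth, elevation=row.elevation,
            radius=row.radius, facet_diameter=row.facet_diameter,
            if_angle=row.if_angle, lens_thickness=row.lens_thickness,
            cone_thickness=row.cone_thickness,
            retina_thickness=row.retina_thickness,
            eye_parameter=row.eye_parameter, sensitivity=row.sensitivity,
            radius_reliable=bool(row.radius_reliable),
            geometry_valid=bool(row.geometry_valid)))
    return out


# ---------------------------------------------------------------------------
# interface extraction


def _largest_component(verts: np.ndarray, faces: np.ndarray):
    """Keep the largest edge-connected face component.

    Returns (verts, faces, n_components, dropped_fraction)."""
    if len(faces) == 0:
        return verts, faces, 1, 0.0
    i = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2]])
    j = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0]])
    g = coo_matrix((np.ones(len(i)), (i, j)), shape=(len(verts), len(verts)))
    n_comp, lab = connected_components(g, directed=False)
    if n_comp <= 1:
        return verts, faces, 1, 0.0
    sizes = np.bincount(lab, minlength=n_comp)
    keep = lab == np.argmax(sizes)
    fkeep = keep[faces[:, 0]]
    dropped = 1.0 - fkeep.mean()
    faces = faces[fkeep]
    used = np.unique(faces)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return verts[used], remap[faces], n_comp, dropped


def _exits_into(data: np.ndarray, points: np.ndarray, normals: np.ndarray,
                from_label: int, into: tuple, max_steps: int = 200):
    """Walk inward (−normal) from each point through ``from_label`` voxels.

    Returns (exits_into_mask, steps): whether the first different label
    is in ``into``, and how many voxel steps the walk took."""
    shape = np.array(data.shape)
    result = np.zeros(len(points), dtype=bool)
    steps = np.full(len(points), max_steps, dtype=np.int32)
    active = np.ones(len(points), dtype=bool)
    pos = points.copy()
    for k in range(max_steps):
        if not active.any():
            break
        pos[active] -= normals[active]
        ijk = np.clip(pos[active].round().astype(int), 0, shape - 1)
        lab = data[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
        done = lab != from_label
        idx = np.flatnonzero(active)
        result[idx[done]] = np.isin(lab[done], into)
        steps[idx[done]] = k + 1
        active[idx[done]] = False
    return result, steps


def _trim_open_boundary(mesh: SurfaceMesh, distance: float) -> SurfaceMesh:
    """Drop faces within ``distance`` of the mesh's open boundary.

    Marching-cubes surfaces curl around label cut edges over a couple of
    voxels; normals there point sideways and would smear any quantity
    derived from them (most visibly the corneal projection)."""
    edges = np.sort(np.concatenate([mesh.faces[:, [0, 1]],
                                    mesh.faces[:, [1, 2]],
                                    mesh.faces[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    rim_verts = np.unique(uniq[counts == 1])
    if len(rim_verts) == 0:
        return mesh
    rim_tree = cKDTree(mesh.vertices[rim_verts])
    cent = mesh.triangles().mean(axis=1)
    d, _ = rim_tree.query(cent)
    faces = mesh.faces[d > distance]
    used = np.unique(faces)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(mesh.vertices[used], remap[faces], role=mesh.role)


def extract_interfaces(volume, smooth_sigma: float = 1.0,
                       trim_boundary_voxels: float = 0.0
                       ) -> dict[str, SurfaceMesh]:
    """Extract the four anatomical interface meshes from a labeled volume.

    For each interface the indicator of "label at or below this depth" is
    smoothed by ``smooth_sigma`` voxels and contoured at 0.5 with marching
    cubes; triangles are kept only where the shallow/deep voxel labels on
    either side match that interface, and only the largest connected
    component survives (a second lens component, e.g. an ocellus stub,
    is dropped with a warning).  Missing labels simply yield no mesh for
    the corresponding interface.

    ``trim_boundary_voxels`` > 0 additionally removes the band of faces
    within that many voxels of each mesh's open (cut) boundary, where the
    isosurface rounds the label edge and normals tilt sideways; trimming
    shrinks the reported area by roughly perimeter × trim, so leave it
    at 0 when the area itself is the quantity of interest.
    """
    data = np.asarray(volume.data)
    vs = float(volume.voxel_size)
    origin = np.asarray(getattr(volume, "origin", (0.0, 0.0, 0.0)))
    present = set(np.unique(data).tolist())
    if LABELS["lens"] not in present:
        raise ValueError("volume has no lens label; cannot extract cornea")
    if not ({2, 3, 4} & present):
        raise ValueError("volume has no inner-layer labels")

    meshes: dict[str, SurfaceMesh] = {}
    shape = np.array(data.shape)
    for role, (shallow, deep, deep_set) in _INTERFACES.items():
        if deep not in present:
            continue
        indicator = np.isin(data, deep_set).astype(np.float32)
        if smooth_sigma > 0:
            indicator = ndimage.gaussian_filter(indicator, smooth_sigma)
        if indicator.max() <= 0.5 or indicator.min() >= 0.5:
            continue
        verts, faces, _, _ = measure.marching_cubes(indicator, level=0.5)

        # orient every face so its normal points toward the shallow side
        # (decreasing indicator)
        tri = verts[faces]
        cent = tri.mean(axis=1)
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        nn = n / np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-30)
        probe = np.clip((cent + 1.0 * nn).round().astype(int), 0, shape - 1)
        val_plus = indicator[probe[:, 0], probe[:, 1], probe[:, 2]]
        probe = np.clip((cent - 1.0 * nn).round().astype(int), 0, shape - 1)
        val_minus = indicator[probe[:, 0], probe[:, 1], probe[:, 2]]
        flip = val_plus > val_minus
        faces[flip] = faces[flip][:, ::-1]
        nn[flip] *= -1.0

        # keep faces whose shallow-side voxel is `shallow` and deep-side
        # voxel is `deep` — this isolates e.g. the outer cornea from the
        # back of the same labeled region
        probe_s = np.clip((cent + 1.2 * nn).round().astype(int), 0, shape - 1)
        probe_d = np.clip((cent - 1.2 * nn).round().astype(int), 0, shape - 1)
        lab_s = data[probe_s[:, 0], probe_s[:, 1], probe_s[:, 2]]
        lab_d = data[probe_d[:, 0], probe_d[:, 1], probe_d[:, 2]]
        keep = (lab_s == shallow) & (lab_d == deep)
        if role == "cornea_outer" and ({2, 3, 4} & present):
            # the lateral rim of the lens shell (a cut eye's edge) also
            # borders background; true corneal faces exit the lens into a
            # deeper layer when walked inward, rim faces exit into
            # background or graze the lens sideways far longer than the
            # lens is thick
            exits, steps = _exits_into(data, cent, nn, from_label=deep,
                                       into=(2, 3, 4))
            keep &= exits
            if keep.any():
                keep &= steps <= 2 * np.median(steps[keep])
        if not keep.any():
            continue
        faces = faces[keep]
        used = np.unique(faces)
        remap = -np.ones(len(verts), dtype=np.int64)
        remap[used] = np.arange(len(used))
        v, f = verts[used], remap[faces]
        v, f, n_comp, dropped = _largest_component(v, f)
        if n_comp > 1:
            logger.debug("%s: %d disconnected components, keeping largest",
                         role, n_comp)
            if dropped > 0.01:  # speckle is silent; a real second
                # structure (e.g. an ocellus stub) is worth a warning
                warnings.warn(f"{role}: kept largest of {n_comp} components "
                              f"({100 * dropped:.1f}% of faces dropped)")
        mesh = SurfaceMesh(v * vs + origin, f, role=role)
        if trim_boundary_voxels > 0:
            mesh = _trim_open_boundary(mesh, trim_boundary_voxels * vs)
        meshes[role] = mesh
    return meshes


# ---------------------------------------------------------------------------
# corneal sampling

HEX_CELL = np.sqrt(3.0) / 2.0  # hexagon area factor: A_hex = (√3/2)·D²


def sample_cornea(mesh: SurfaceMesh, spacing: float = 25.0,
                  seed: int = 0, lloyd_iterations: int = 4,
                  oversample: float = 1.10) -> list[CornealSample]:
    """Spread sampling points evenly over the cornea at ``spacing`` μm.

    Seeded blue-noise construction: farthest-point sampling over the
    mesh vertices down to slightly more than the hexagonal-packing count
    area/((√3/2)·spacing²), a few area-weighted Lloyd relaxation passes
    (centroids re-projected onto the local tangent plane, staying within
    ~0.05 μm of the surface), then greedy thinning of any pair closer
    than 0.7·spacing.  The result keeps the packing count within ~12%
    and guarantees the minimum pairwise distance.  Normals are
    area-weighted vertex normals averaged over a 2·spacing radius, never
    flipped by smoothing.
    """
    area = mesh.area()
    n_hex = max(1, int(round(area / (HEX_CELL * spacing ** 2))))
    verts = mesh.vertices
    vn = mesh.vertex_normals()
    if n_hex == 1 or len(verts) < 4:
        warnings.warn("mesh smaller than one spacing; single centroid sample")
        c = mesh.centroid()
        i = int(mesh.vertex_tree().query(c)[1])
        return [CornealSample(position=verts[i], normal=vn[i])]
    med_edge = float(np.median(mesh.edge_lengths()))
    if spacing <= med_edge:
        raise ValueError(
            f"spacing {spacing} μm not above mesh edge resolution "
            f"({med_edge:.2f} μm)")

    rng = np.random.default_rng(seed)
    n_target = min(int(round(oversample * n_hex)), len(verts))
    start = int(rng.integers(len(verts)))
    chosen = np.empty(n_target, dtype=np.int64)
    chosen[0] = start
    dist = np.linalg.norm(verts - verts[start], axis=1)
    for k in range(1, n_target):
        nxt = int(np.argmax(dist))
        chosen[k] = nxt
        np.minimum(dist, np.linalg.norm(verts - verts[nxt], axis=1), out=dist)
    pos = verts[chosen].copy()

    # Lloyd relaxation: move each sample to the area-weighted centroid of
    # the mesh vertices it owns, re-projected to the tangent plane
    va = np.zeros(len(verts))
    fa = mesh.face_areas()
    for k in range(3):
        np.add.at(va, mesh.faces[:, k], fa / 3.0)
    vtree = mesh.vertex_tree()
    for _ in range(lloyd_iterations):
        _, owner = cKDTree(pos).query(verts)
        cent = np.zeros_like(pos)
        wsum = np.zeros(len(pos))
        np.add.at(cent, owner, verts * va[:, None])
        np.add.at(wsum, owner, va)
        ok = wsum > 0
        cent[ok] /= wsum[ok, None]
        cent[~ok] = pos[~ok]
        _, near = vtree.query(cent)
        v, n = verts[near], vn[near]
        pos = cent - np.einsum("ij,ij->i", cent - v, n)[:, None] * n

    # enforce the minimum pairwise distance
    pairs = cKDTree(pos).query_pairs(0.7 * spacing, output_type="ndarray")
    removed = np.zeros(len(pos), dtype=bool)
    for i, j in pairs:
        if not removed[i] and not removed[j]:
            removed[j] = True
    pos = pos[~removed]

    samples = []
    sigma = 0.75 * spacing  # Gaussian falloff limits one-sided boundary tilt
    for p in pos:
        neigh = vtree.query_ball_point(p, 2.0 * spacing)
        i_near = int(vtree.query(p)[1])
        n_raw = vn[i_near]
        if neigh:
            d2 = np.sum((verts[neigh] - p) ** 2, axis=1)
            w = np.exp(-d2 / (2.0 * sigma * sigma))
            n_smooth = (vn[neigh] * w[:, None]).sum(axis=0)
        else:
            n_smooth = n_raw
        norm = np.linalg.norm(n_smooth)
        n_smooth = n_smooth / norm if norm > 0 else n_raw
        if np.dot(n_smooth, n_raw) < 0:  # smoothing must never flip
            n_smooth = n_raw
        samples.append(CornealSample(position=p.copy(), normal=n_smooth))
    return samples


# ---------------------------------------------------------------------------
# curvature


def sphere_fit(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares sphere fit.

    Returns (center, radius, rms residual).  Solves the linear system
    ``2 p·c + d = |p|²`` for center c and d = R² − |c|².
    """
    points = np.asarray(points, dtype=np.float64)
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    b = np.einsum("ij,ij->i", points, points)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    radius = float(np.sqrt(max(r2, 0.0)))
    resid = np.linalg.norm(points - center, axis=1) - radius
    return center, radius, float(np.sqrt(np.mean(resid ** 2)))


def fit_local_radius(mesh: SurfaceMesh, sample: CornealSample,
                     neighborhood_radius: float = 125.0,
                     min_vertices: int = 10) -> float:
    """Local radius of curvature from a sphere fit in a geodesic-scale
    neighborhood (Euclidean ball, valid for neighborhoods ≪ R).

    Sets ``sample.radius`` (NaN when fewer than ``min_vertices`` vertices
    are in range) and clears ``sample.radius_reliable`` when the fit RMS
    exceeds 5% of R.  R is reported positive when the fitted center lies
    on the inward side of the surface (convex cornea).
    """
    idx = mesh.vertex_tree().query_ball_point(sample.position,
                                              neighborhood_radius)
    if len(idx) < min_vertices:
        sample.radius = np.nan
        return np.nan
    center, radius, rms = sphere_fit(mesh.vertices[idx])
    if np.dot(center - sample.position, sample.normal) > 0:
        radius = -radius  # concave: center on the outward side
    sample.radius = radius
    sample.radius_reliable = bool(rms <= 0.05 * abs(radius))
    return radius


# ---------------------------------------------------------------------------
# areas and volumes


def surface_area(mesh: SurfaceMesh) -> float:
    """Total mesh area, μm²."""
    return mesh.area()


def enclosed_volume(volume=None, mesh: SurfaceMesh | None = None) -> float:
    """Eye volume EV in μm³.

    Volume route: voxel count over the lens ∪ cone ∪ retina labels times
    voxel_size³.  Mesh route: divergence-theorem volume of a closed mesh.
    """
    if volume is not None:
        data = np.asarray(volume.data)
        count = int(np.isin(data, (LABELS["lens"], LABELS["cone"],
                                   LABELS["retina"])).sum())
        return count * float(volume.voxel_size) ** 3
    if mesh is None:
        raise ValueError("need a labeled volume or a closed mesh")
    v = mesh.volume()
    if v <= 0:
        raise ValueError("mesh volume non-positive; mesh is open or "
                         "inward-oriented — use the labeled-volume route")
    # closedness check: every edge must be shared by exactly two faces
    edges = np.sort(np.concatenate([mesh.faces[:, [0, 1]],
                                    mesh.faces[:, [1, 2]],
                                    mesh.faces[:, [2, 0]]]), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if not (counts == 2).all():
        raise ValueError("open mesh; use the labeled-volume route for EV")
    return v


def principal_axis(mesh: SurfaceMesh) -> np.ndarray:
    """Dominant eigenvector of the vertex covariance."""
    v = mesh.vertices - mesh.vertices.mean(axis=0)
    cov = v.T @ v
    w, vecs = np.linalg.eigh(cov)
    return vecs[:, -1]


def projected_area(mesh: SurfaceMesh, axis: np.ndarray | None = None) -> float:
    """Silhouette area of the mesh viewed orthographically along ``axis``.

    The union (not the sum) of the projected triangles: overlapping front
    and back surfaces collapse, exactly as in a photograph.  This is the
    quantity 2D studies report as "eye area", and it understates the true
    surface area of any curved eye.
    """
    if axis is None:
        axis = principal_axis(mesh)
    axis = np.asarray(axis, dtype=np.float64)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("projection axis must be nonzero")
    axis = axis / norm
    # orthonormal basis of the projection plane
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    w = np.cross(axis, u)
    pts2 = np.column_stack([mesh.vertices @ u, mesh.vertices @ w])
    tri2 = pts2[mesh.faces]
    # drop edge-on triangles: they contribute no silhouette area
    twice_area = np.abs(
        (tri2[:, 1, 0] - tri2[:, 0, 0]) * (tri2[:, 2, 1] - tri2[:, 0, 1])
        - (tri2[:, 2, 0] - tri2[:, 0, 0]) * (tri2[:, 1, 1] - tri2[:, 0, 1]))
    keep = twice_area > 1e-12
    polys = [Polygon(t) for t in tri2[keep]]
    return float(shapely.union_all([shapely.make_valid(p) for p in polys]).area)
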
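"""Parametric eyes with analytic ground truth.

Every downstream stage of the pipeline — interface extraction, corneal
sampling, curvature fitting, facet fields, CP masks, thickness tracing,
allometric maps — is testable against eyes generated here, because each
generated eye carries closed-form truth: the cornea is a spherical or
ellipsoidal cap, the inner interfaces are constant-offset surfaces along
the inward normal (so every layer thickness equals its offset exactly),
the facet-diameter field is a stated function of position, and per-eye
areas, volumes, corneal-projection solid angles and facet counts are
computed by quadrature of closed-form curvature integrands (exact up to
quadrature error ≪ any test tolerance), never by measuring the meshes.

The head frame is +x anterior, +z dorsal, −y toward the animal's left;
the default optic axis points where a bee's left eye does (azimuth −60°,
elevation +10°).
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
from scipy import ndimage

from .facets import FacetMeasurement
from .geometry import HEX_CELL
from .io import EyeRecord, LabeledVolume
from .mesh import SurfaceMesh

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation taking +z to ``axis`` (unit)."""
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(z @ axis)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


@dataclasses.dataclass
class SyntheticEyeSpec:
    """Parameters of one synthetic eye.

    shape : "sphere_cap" or "ellipsoid_cap".
    radius_or_semiaxes : sphere radius R, or (a, b, c) semi-axes, μm.
        The cap pole sits on the local +z (c) axis before rotation.
    cap_half_angle : parametric polar half-angle of the cap, degrees,
        in (0, 90].
    shell_offsets : (lens, cone, retina) thicknesses along the inward
        normal, μm.
    facet_field : across-flats facet diameter D — a constant (μm) or a
        function of an (n, 3) array of head-frame positions.
    optic_axis : cap axis direction in the head frame.
    lamina_thickness : thickness of the lamina label shell in the
        voxelized volume (it only needs enough substance for its front
        interface to be extractable), μm.
    """

    shape: str = "sphere_cap"
    radius_or_semiaxes: float | tuple = 1000.0
    cap_half_angle: float = 90.0
    shell_offsets: tuple = (40.0, 60.0, 200.0)
    facet_field: float | Callable = 25.0
    optic_axis: tuple = (0.5, -np.sqrt(3) / 2 * np.cos(np.radians(10)),
                         np.sin(np.radians(10)))
    lamina_thickness: float = 40.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("sphere_cap", "ellipsoid_cap"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if not 0.0 < self.cap_half_angle <= 90.0:
            raise ValueError("cap_half_angle must be in (0°, 90°]")
        if len(self.shell_offsets) != 3 or min(self.shell_offsets) <= 0:
            raise ValueError("shell offsets must be three positive values")
        axes = self.semiaxes
        if min(axes) <= 0:
            raise ValueError("radius/semi-axes must be positive")
        total = sum(self.shell_offsets) + self.lamina_thickness
        # min principal radius of an ellipsoid is min(b c/a-type ratios);
        # a conservative self-intersection guard: offsets must stay below
        # the smallest curvature radius min(axes)²/max(axes)
        if total >= min(axes) ** 2 / max(axes):
            raise ValueError(
                f"shell offsets total {total} μm exceed the smallest local "
                "radius of curvature; offset surfaces would self-intersect")

    @property
    def semiaxes(self) -> np.ndarray:
        if np.ndim(self.radius_or_semiaxes) == 0:
            r = float(self.radius_or_semiaxes)
            return np.array([r, r, r])
        return np.asarray(self.radius_or_semiaxes, dtype=np.float64)

    @property
    def rotation(self) -> np.ndarray:
        return _rotation_to(np.asarray(self.optic_axis, dtype=np.float64))

    def facet_diameter_at(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        if callable(self.facet_field):
            D = np.asarray(self.facet_field(points), dtype=np.float64)
            D = np.broadcast_to(D, (len(points),)).astype(np.float64)
        else:
            D = np.full(len(points), float(self.facet_field))
        if np.any(D <= 0):
            raise ValueError("facet_field must be positive everywhere")
        return D

    # -- parametric surface --------------------------------------------------

    def surface_point(self, theta, phi, offset: float = 0.0):
        """Head-frame point(s) on the offset surface at parametric
        (theta, phi); theta is the polar angle from the cap axis."""
        theta = np.asarray(theta, dtype=np.float64)
        phi = np.asarray(phi, dtype=np.float64)
        a, b, c = self.semiaxes
        st, ct = np.sin(theta), np.cos(theta)
        local = np.stack([a * st * np.cos(phi), b * st * np.sin(phi),
                          c * ct], axis=-1)
        n = self._local_normal(local)
        return (local - offset * n) @ self.rotation.T

    def _local_normal(self, local: np.ndarray) -> np.ndarray:
        a, b, c = self.semiaxes
        n = local / np.array([a * a, b * b, c * c])
        return n / np.linalg.norm(n, axis=-1, keepdims=True)

    def surface_normal(self, theta, phi) -> np.ndarray:
        """Outward unit normal(s) in the head frame (offset surfaces
        share the base surface's normal by construction)."""
        theta = np.asarray(theta, dtype=np.float64)
        phi = np.asarray(phi, dtype=np.float64)
        a, b, c = self.semiaxes
        st, ct = np.sin(theta), np.cos(theta)
        local = np.stack([a * st * np.cos(phi), b * st * np.sin(phi),
                          c * ct], axis=-1)
        return self._local_normal(local) @ self.rotation.T

    def curvatures(self, theta, phi):
        """Gaussian and mean curvature of the outer surface (closed
        forms for an implicit ellipsoid; exact)."""
        theta = np.asarray(theta, dtype=np.float64)
        phi = np.asarray(phi, dtype=np.float64)
        a, b, c = self.semiaxes
        st, ct = np.sin(theta), np.cos(theta)
        x, y, z = a * st * np.cos(phi), b * st * np.sin(phi), c * ct
        h2 = x ** 2 / a ** 4 + y ** 2 / b ** 4 + z ** 2 / c ** 4
        K = 1.0 / (a ** 2 * b ** 2 * c ** 2 * h2 ** 2)
        s_inv = 1 / a ** 2 + 1 / b ** 2 + 1 / c ** 2
        s6 = x ** 2 / a ** 6 + y ** 2 / b ** 6 + z ** 2 / c ** 6
        H = (h2 * s_inv - s6) / (2.0 * h2 ** 1.5)
        return K, H

    def area_element(self, theta, phi) -> np.ndarray:
        """|∂X/∂θ × ∂X/∂φ| of the outer surface."""
        a, b, c = self.semiaxes
        st, ct = np.sin(theta), np.cos(theta)
        cp, sp = np.cos(phi), np.sin(phi)
        xt = np.stack([a * ct * cp, b * ct * sp, -c * st], axis=-1)
        xp = np.stack([-a * st * sp, b * st * cp, np.zeros_like(st)], axis=-1)
        return np.linalg.norm(np.cross(xt, xp), axis=-1)


# ---------------------------------------------------------------------------
# truth


@dataclasses.dataclass
class TruthTable:
    """Analytic ground truth for one synthetic eye.

    Per-eye scalars plus truth fields evaluated at arbitrary parametric
    points; thickness truths are the shell offsets themselves (inward
    normal offsetting makes every layer constant-thickness by
    construction).
    """

    spec: SyntheticEyeSpec
    surface_area: float          # outer corneal cap area, μm²
    enclosed_volume: float       # lens+cone+retina shell volume, μm³
    cp_solid_angle: float        # Gauss-map area of the cap, sr
    facet_count: float           # ∫ dA / ((√3/2)·D²)
    thicknesses: tuple           # (L_lens, L_cone, L_retina) truth, μm

    def radius_at(self, theta, phi):
        """Principal radii (r_min, r_max) and Gaussian radius 1/√K."""
        K, H = self.spec.curvatures(theta, phi)
        disc = np.sqrt(np.maximum(H * H - K, 0.0))
        return 1.0 / (H + disc), 1.0 / np.maximum(H - disc, 1e-300), \
            1.0 / np.sqrt(K)

    def facet_diameter_at(self, points):
        return self.spec.facet_diameter_at(points)

    def if_angle_at(self, theta, phi):
        """True ΔΦ in degrees: D divided by the Gaussian radius (equals
        D/R exactly on a sphere)."""
        p = self.spec.surface_point(theta, phi)
        D = self.spec.facet_diameter_at(p)
        _, _, rg = self.radius_at(theta, phi)
        return np.degrees(D / rg)

    def viewing_direction_at(self, theta, phi):
        n = self.spec.surface_normal(theta, phi)
        n = np.atleast_2d(n)
        el = np.degrees(np.arcsin(np.clip(n[:, 2], -1, 1)))
        az = np.degrees(np.arctan2(n[:, 1], n[:, 0]))
        return az, el


def _cap_quadrature(spec: SyntheticEyeSpec, n_theta: int = 400,
                    n_phi: int = 400):
    """Gauss-Legendre × trapezoid quadrature grid over the cap."""
    cap = np.radians(spec.cap_half_angle)
    nodes, weights = np.polynomial.legendre.leggauss(n_theta)
    theta = 0.5 * cap * (nodes + 1.0)
    wt = 0.5 * cap * weights
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    wp = 2.0 * np.pi / n_phi
    T, P = np.meshgrid(theta, phi, indexing="ij")
    W = wt[:, None] * wp
    return T, P, W


def compute_truth(spec: SyntheticEyeSpec) -> TruthTable:
    T, P, W = _cap_quadrature(spec)
    dA = spec.area_element(T, P)
    K, H = spec.curvatures(T, P)
    area = float((dA * W).sum())
    # tube formula: shell volume between the surface and its inward
    # offset at depth T0 is ∫ (T0 − H·T0² + K·T0³/3) dA
    T0 = float(sum(spec.shell_offsets))
    vol = float(((T0 - H * T0 ** 2 + K * T0 ** 3 / 3.0) * dA * W).sum())
    # the CP is the Gauss-map image of the cap; its solid angle is the
    # total Gaussian curvature ∫ K dA (injective on a convex cap)
    cp = float((K * dA * W).sum())
    pts = spec.surface_point(T.ravel(), P.ravel())
    D = spec.facet_diameter_at(pts).reshape(T.shape)
    nfac = float((dA / (HEX_CELL * D ** 2) * W).sum())
    return TruthTable(spec=spec, surface_area=area, enclosed_volume=vol,
                      cp_solid_angle=cp, facet_count=nfac,
                      thicknesses=tuple(spec.shell_offsets))


# ---------------------------------------------------------------------------
# meshes


def _cap_mesh(spec: SyntheticEyeSpec, offset: float, role: str,
              edge_length: float) -> SurfaceMesh:
    """Triangulated cap of the offset surface with ~edge_length μm edges,
    outward-oriented."""
    cap = np.radians(spec.cap_half_angle)
    rmax = float(spec.semiaxes.max())
    n_theta = max(3, int(np.ceil(rmax * cap / edge_length)))
    verts = [spec.surface_point(0.0, 0.0, offset)]
    normals_theta_phi = [(0.0, 0.0)]
    rings: list[np.ndarray] = []
    for j in range(1, n_theta + 1):
        theta = cap * j / n_theta
        ring_r = rmax * np.sin(theta)
        n_phi = max(6, int(np.ceil(2.0 * np.pi * ring_r / edge_length)))
        phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
        idx = np.arange(len(verts), len(verts) + n_phi)
        pts = spec.surface_point(np.full(n_phi, theta), phi, offset)
        verts.extend(pts)
        normals_theta_phi.extend((theta, p) for p in phi)
        rings.append(idx)
    faces: list[tuple[int, int, int]] = []
    first = rings[0]
    for i in range(len(first)):  # pole fan
        faces.append((0, first[i], first[(i + 1) % len(first)]))
    for j in range(len(rings) - 1):
        a, b = rings[j], rings[j + 1]
        na, nb = len(a), len(b)
        # stitch rings of different sizes by walking both in angle order
        ia = ib = 0
        while ia < na or ib < nb:
            fa = (ia + 1) / na if ia < na else 2.0
            fb = (ib + 1) / nb if ib < nb else 2.0
            if fb <= fa:
                faces.append((a[ia % na], b[ib % nb], b[(ib + 1) % nb]))
                ib += 1
            else:
                faces.append((a[ia % na], b[ib % nb], a[(ia + 1) % na]))
                ia += 1
    mesh = SurfaceMesh(np.array(verts), np.array(faces), role=role)
    # enforce outward winding against the analytic normal
    tp = np.array(normals_theta_phi)
    n_true = spec.surface_normal(tp[:, 0], tp[:, 1])
    fn = mesh.face_normals()
    flip = np.einsum("ij,ij->i", fn, n_true[mesh.faces[:, 0]]) < 0
    mesh.faces[flip] = mesh.faces[flip][:, ::-1]
    return SurfaceMesh(mesh.vertices, mesh.faces, role=role)


# ---------------------------------------------------------------------------
# voxelization


def voxelize(spec: SyntheticEyeSpec, voxel_size: float,
             margin: float = 3.0) -> LabeledVolume:
    """Label a voxel grid with the nested shells of the eye.

    Depth below the outer surface is exact (R − r) for spheres and a
    Euclidean distance transform for ellipsoids; shells are depth bins
    (lens, cone, retina, lamina), restricted to the cap's angular
    region.
    """
    a, b, c = spec.semiaxes
    rmax = float(spec.semiaxes.max())
    lo = -rmax - margin * voxel_size
    n = int(np.ceil(2 * (rmax + margin * voxel_size) / voxel_size))
    coords = lo + (np.arange(n) + 0.5) * voxel_size
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1) @ spec.rotation  # head → local
    xl, yl, zl = pts[..., 0], pts[..., 1], pts[..., 2]
    rho = np.sqrt((xl / a) ** 2 + (yl / b) ** 2 + (zl / c) ** 2)
    inside = rho <= 1.0
    if spec.shape == "sphere_cap" or (a == b == c):
        depth = np.where(inside, a * (1.0 - rho), -1.0)
    else:
        depth = ndimage.distance_transform_edt(inside) * voxel_size
        depth = np.where(inside, depth, -1.0)
    polar = np.arccos(np.clip(zl / np.maximum(rho, 1e-12) / c, -1, 1))
    # parametric cap angle: tan(theta_param) relates to spatial angle via
    # the axis scaling; use the parametric angle of the radial projection
    theta_par = np.arctan2(np.sqrt((xl / a) ** 2 + (yl / b) ** 2),
                           zl / c)
    in_cap = theta_par <= np.radians(spec.cap_half_angle)
    o1, o2, o3 = spec.shell_offsets
    edges = np.cumsum([o1, o2, o3, spec.lamina_thickness])
    labels = np.zeros(depth.shape, dtype=np.int16)
    labels[in_cap & (depth >= 0) & (depth <= edges[0])] = 1
    labels[in_cap & (depth > edges[0]) & (depth <= edges[1])] = 2
    labels[in_cap & (depth > edges[1]) & (depth <= edges[2])] = 3
    labels[in_cap & (depth > edges[2]) & (depth <= edges[3])] = 4
    return LabeledVolume(labels, voxel_size,
                         origin=(lo + 0.5 * voxel_size,) * 3)


# ---------------------------------------------------------------------------
# landmarks


def _cap_sites(spec: SyntheticEyeSpec, n_sites: int) -> tuple[np.ndarray,
                                                              np.ndarray]:
    """Quasi-uniform (theta, phi) sites over the cap (Fibonacci lattice
    in cos(theta))."""
    cap = np.radians(spec.cap_half_angle)
    i = np.arange(n_sites) + 0.5
    ct = 1.0 - (1.0 - np.cos(cap)) * i / n_sites
    theta = np.arccos(ct)
    phi = np.mod(i * GOLDEN_ANGLE, 2.0 * np.pi)
    return theta, phi


def _project_to_surface(spec: SyntheticEyeSpec, pts_head: np.ndarray
                        ) -> np.ndarray:
    """Radially project head-frame points onto the outer surface."""
    local = pts_head @ spec.rotation
    a, b, c = spec.semiaxes
    rho = np.sqrt((local[:, 0] / a) ** 2 + (local[:, 1] / b) ** 2
                  + (local[:, 2] / c) ** 2)
    return (local / rho[:, None]) @ spec.rotation.T


def generate_landmarks(spec: SyntheticEyeSpec, n_sites: int = 60,
                       noise_sd: float = 0.0,
                       eye_id: str = "synthetic") -> list[FacetMeasurement]:
    """Six-point facet landmark sets on a tangent-plane hexagonal layout.

    At each site the three across-flats axes of the local hexagonal
    lattice are laid in the tangent plane 60° apart; the six border
    points sit on the outer borders of the opposing surrounding facets,
     1.5·D from the center along ± each axis, then are projected onto
    the surface (curvature distortion < 0.1% for D ≪ R).  Optional
    Gaussian click noise is seeded from the spec.
    """
    rng = np.random.default_rng(spec.rng_seed)
    theta, phi = _cap_sites(spec, n_sites)
    out = []
    for k in range(n_sites):
        c = spec.surface_point(theta[k], phi[k])
        n = spec.surface_normal(theta[k], phi[k])
        D = float(spec.facet_diameter_at(c[None])[0])
        t1 = np.cross(n, [0.0, 0.0, 1.0])
        if np.linalg.norm(t1) < 1e-9:
            t1 = np.cross(n, [0.0, 1.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(n, t1)
        borders = []
        for j in range(3):
            ang = np.radians(60.0 * j)
            axis = np.cos(ang) * t1 + np.sin(ang) * t2
            borders.append(c + 1.5 * D * axis)
            borders.append(c - 1.5 * D * axis)
        borders = _project_to_surface(spec, np.array(borders))
        if noise_sd > 0:
            borders = borders + rng.normal(0.0, noise_sd, borders.shape)
        out.append(FacetMeasurement(center=c, borders=borders,
                                    eye_id=eye_id, facet_id=k))
    return out


# ---------------------------------------------------------------------------
# top-level generators


@dataclasses.dataclass
class SyntheticEye:
    """Everything the pipeline consumes for one generated eye."""

    spec: SyntheticEyeSpec
    volume: LabeledVolume | None
    meshes: dict[str, SurfaceMesh]
    landmarks: list[FacetMeasurement]
    truth: TruthTable


def generate_eye(spec: SyntheticEyeSpec, voxel_size: float | None = None,
                 mesh_edge_length: float = 12.0, n_landmarks: int = 60,
                 landmark_noise_sd: float = 0.0,
                 with_volume: bool = True) -> SyntheticEye:
    """Generate one synthetic eye: labeled volume, the four interface
    meshes, facet landmarks, and its analytic truth table."""
    truth = compute_truth(spec)
    o1, o2, o3 = spec.shell_offsets
    offsets = {"cornea_outer": 0.0, "cone_front": o1,
               "retina_front": o1 + o2, "lamina_front": o1 + o2 + o3}
    meshes = {role: _cap_mesh(spec, off, role, mesh_edge_length)
              for role, off in offsets.items()}
    volume = None
    if with_volume:
        if voxel_size is None:
            voxel_size = float(spec.semiaxes.max()) / 100.0
        volume = voxelize(spec, voxel_size)
    landmarks = generate_landmarks(spec, n_sites=n_landmarks,
                                   noise_sd=landmark_noise_sd)
    return SyntheticEye(spec=spec, volume=volume, meshes=meshes,
                        landmarks=landmarks, truth=truth)


@dataclasses.dataclass
class AllometricEye:
    """One member of a synthetic growth series: its metadata and its
    projected variable layers on a shared world grid."""

    record: EyeRecord
    layers: dict[str, np.ndarray]
    cp_mask: np.ndarray


@dataclasses.dataclass
class AllometricSeriesTruth:
    """The generating power law of a synthetic series on the grid."""

    alpha: np.ndarray     # α(az, el) per cell
    b: np.ndarray
    sizes: np.ndarray     # the size measures x_i


def generate_allometric_series(n_eyes: int = 6, size_range: float = 1.57,
                               exponent_field=0.7, b_field=2.0,
                               noise_sd: float = 0.0, rng_seed: int = 0,
                               grid=None, variable: str = "facet_diameter",
                               base_size: float = 400.0,
                               cap_half_angles: tuple = (50.0, 70.0),
                               center=(-60.0, 10.0)):
    """Synthetic growth series with a known, possibly spatially varying,
    power law.

    Eye i has linear size x_i log-spaced over ``size_range`` (default
    ×1.57, the cube root of the ×3.9 eye-volume span of a wild worker
    cohort); its CP is a cap of directions around ``center`` whose
    half-angle grows linearly from ``cap_half_angles[0]`` to ``[1]`` with
    size (so the map periphery is seen by fewer individuals, exercising
    the ≥ 4-individual mask).  Within the CP the variable at world cell
    (az, el) is b(az, el)·x_i^α(az, el)·(1 + ε), ε ~ N(0, noise_sd),
    seeded.

    Returns (list of AllometricEye, AllometricSeriesTruth, grid).
    """
    from .projection import WorldGrid, direction_vector

    if n_eyes < 2:
        raise ValueError("a power-law fit needs at least 2 eyes")
    if size_range < 1:
        raise ValueError("size_range must be ≥ 1")
    grid = grid or WorldGrid(cell_size=2.0)
    rng = np.random.default_rng(rng_seed)
    sizes = base_size * size_range ** (np.arange(n_eyes) / max(n_eyes - 1, 1))

    az_g = grid.az_centers[None, :] * np.ones(grid.shape)
    el_g = grid.el_centers[:, None] * np.ones(grid.shape)
    alpha = (exponent_field(az_g, el_g) if callable(exponent_field)
             else np.full(grid.shape, float(exponent_field)))
    bmap = (b_field(az_g, el_g) if callable(b_field)
            else np.full(grid.shape, float(b_field)))

    cvec = direction_vector(*center)
    cell_vec = grid.center_vectors()
    ang = np.degrees(np.arccos(np.clip(cell_vec @ cvec, -1.0, 1.0)))

    eyes = []
    lo, hi = cap_half_angles
    for i, x in enumerate(sizes):
        frac = (np.log(x / base_size) / np.log(size_range)
                if size_range > 1 else 1.0)
        half = lo + (hi - lo) * frac
        cp = ang <= half
        layer = np.full(grid.shape, np.nan)
        noise = 1.0 + rng.normal(0.0, noise_sd, grid.shape) \
            if noise_sd > 0 else 1.0
        vals = bmap * x ** alpha * noise
        layer[cp] = vals[cp] if np.ndim(vals) else vals
        record = EyeRecord(individual_id=f"synthetic-{i}",
                           species="synthetic",
                           itw_mm=3.0 * x / base_size,
                           ev_um3=float(x) ** 3)
        eyes.append(AllometricEye(record=record, layers={variable: layer},
                                  cp_mask=cp))
    truth = AllometricSeriesTruth(alpha=alpha, b=bmap, sizes=sizes)
    return eyes, truth, grid
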
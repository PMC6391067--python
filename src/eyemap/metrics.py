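"""Local visual metrics of an apposition compound eye.

The inter-facet angle ΔΦ = D/R (in radians; reported in degrees) is the
corneal-geometry proxy for the inter-ommatidial angle and sets local
resolution.  Ray-traced layer thicknesses give the lens, crystalline-cone
and retinal depths under each sampling point; retinal thickness stands in
for rhabdom length.  The eye parameter P = ΔΦ[rad]·D separates
resolution-optimized facets (P near the 0.29 μm·rad diffraction limit
for green light) from sensitivity-optimized ones (P ≥ 1).  Optical
sensitivity follows the standard apposition-eye photon-catch expression

    S = (π/4)² · D² · Δρ² · k·l / (2.3 + k·l)   [μm²·sr]

with the acceptance angle Δρ taken equal to ΔΦ and the rhabdom length l
equal to the traced retinal thickness — both declared approximations:
crystalline-cone skew can make the true optical axes diverge from the
corneal normals, which this corneal method cannot see.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .geometry import CornealSample, samples_to_frame
from .mesh import SurfaceMesh

RAD2DEG = 180.0 / np.pi


@dataclasses.dataclass
class OpticsConfig:
    """Constants of the sensitivity model.

    absorption_coefficient : rhabdom absorption k, μm⁻¹ (default 0.0067).
    wavelength : context wavelength for the eye-parameter diffraction
        limit, μm (0.5 = green; not used in any formula here).
    acceptance_denominator : the 2.3 in the absorption term
        k·l/(2.3 + k·l).
    """

    absorption_coefficient: float = 0.0067
    wavelength: float = 0.5
    acceptance_denominator: float = 2.3

    def __post_init__(self) -> None:
        if self.absorption_coefficient <= 0:
            raise ValueError("absorption coefficient must be positive")


def if_angle(D: float, R: float) -> float:
    """Inter-facet angle ΔΦ in degrees: (180/π)·D/R."""
    D = np.asarray(D, dtype=np.float64)
    R = np.asarray(R, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where((D > 0) & (R > 0), RAD2DEG * D / R, np.nan)
    return float(out) if out.ndim == 0 else out


def if_angle_numeric(mesh: SurfaceMesh, sample: CornealSample,
                     D: float) -> float:
    """Two-point numeric ΔΦ: the angle between surface normals at two
    points one facet diameter apart along the surface.

    Cross-check oracle for the analytic D/R form; noisier, kept for
    validation only.
    """
    p = sample.position
    n = sample.normal
    # step D along a tangent direction, re-project to the nearest vertex
    t = np.cross(n, [0.0, 0.0, 1.0])
    if np.linalg.norm(t) < 1e-6:
        t = np.cross(n, [0.0, 1.0, 0.0])
    t /= np.linalg.norm(t)
    q = p + D * t
    tree = mesh.vertex_tree()
    iq = int(tree.query(q)[1])
    nq = mesh.vertex_normals()[iq]
    cosang = np.clip(np.dot(n, nq), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def trace_thicknesses(sample: CornealSample,
                      cone_front: SurfaceMesh | None,
                      retina_front: SurfaceMesh | None = None,
                      lamina_front: SurfaceMesh | None = None,
                      ) -> tuple[float, float, float]:
    """Trace the corneal normal into the eye and measure layer depths.

    A ray is cast from the sample position along −normal; the first
    intersections with the cone front, retina front and lamina interface
    at distances d₁ ≤ d₂ ≤ d₃ give L_lens = d₁, L_cone = d₂−d₁,
    L_retina = d₃−d₂.  A missed interface leaves that thickness and all
    deeper ones NaN; an ordering violation flags the sample's geometry
    invalid.  Results are written onto the sample and returned.
    """
    if cone_front is None:
        raise ValueError("at least the cone front interface is required")
    p, n = sample.position, sample.normal
    d = -n

    def first_hit(m: SurfaceMesh | None) -> float:
        if m is None:
            return np.nan
        t = m.ray_intersections(p, d)
        return float(t[0]) if len(t) else np.nan

    d1 = first_hit(cone_front)
    d2 = first_hit(retina_front) if np.isfinite(d1) else np.nan
    d3 = first_hit(lamina_front) if np.isfinite(d2) else np.nan
    L_lens = d1
    L_cone = d2 - d1 if np.isfinite(d2) else np.nan
    L_retina = d3 - d2 if np.isfinite(d3) else np.nan
    if (np.isfinite(L_cone) and L_cone < 0) or \
       (np.isfinite(L_retina) and L_retina < 0):
        sample.geometry_valid = False
        warnings.warn("interface intersection order violated; sample flagged")
        L_cone = L_retina = np.nan
    sample.lens_thickness = L_lens
    sample.cone_thickness = L_cone
    sample.retina_thickness = L_retina
    return L_lens, L_cone, L_retina


def eye_parameter(if_angle_deg: float, D: float) -> float:
    """Eye parameter P = ΔΦ[rad] · D, in μm·rad."""
    a = np.asarray(if_angle_deg, dtype=np.float64)
    D = np.asarray(D, dtype=np.float64)
    out = np.radians(a) * D
    return float(out) if out.ndim == 0 else out


def optical_sensitivity(D: float, acceptance_rad: float, l: float,
                        cfg: OpticsConfig | None = None) -> float:
    """Photon-catch sensitivity S in μm²·sr (see module docstring)."""
    cfg = cfg or OpticsConfig()
    D = np.asarray(D, dtype=np.float64)
    rho = np.asarray(acceptance_rad, dtype=np.float64)
    l = np.asarray(l, dtype=np.float64)
    k = cfg.absorption_coefficient
    absorb = k * l / (cfg.acceptance_denominator + k * l)
    out = (np.pi / 4.0) ** 2 * D ** 2 * rho ** 2 * absorb
    return float(out) if out.ndim == 0 else out


def compute_sample_metrics(samples: list[CornealSample],
                           cfg: OpticsConfig | None = None) -> None:
    """Fill ΔΦ, P and S on every sample from its D, R and L_retina.

    Missing ingredients propagate to missing outputs, never imputed.
    """
    cfg = cfg or OpticsConfig()
    for s in samples:
        s.if_angle = if_angle(s.facet_diameter, s.radius)
        s.eye_parameter = eye_parameter(s.if_angle, s.facet_diameter)
        s.sensitivity = optical_sensitivity(
            s.facet_diameter, np.radians(s.if_angle), s.retina_thickness, cfg)


def behavioral_min_angle(itw_mm: float, intercept: float = 17.6,
                         slope: float = -3.1) -> float:
    """Minimum detectable visual angle (degrees) predicted from body size.

    Published behavioural regression for bumblebee target discrimination:
    Angle(°) = 17.6 − 3.1·ITW(mm).  Useful for comparing anatomical
    IF-angle maps against behaviourally measured acuity.
    """
    return intercept + slope * itw_mm


# ---------------------------------------------------------------------------
# facet-number-based IF-angle approximations

_PACKING = {
    # per-facet solid angle ω → angular pitch; hexagonal: ω = (√3/2)·ΔΦ²
    "hexagonal": lambda w: np.sqrt(2.0 * w / np.sqrt(3.0)),
    "square": lambda w: np.sqrt(w),
    "circular": lambda w: 2.0 * np.sqrt(w / np.pi),
}


def hemi_approx_if(n_facets: int, convention: str = "hexagonal") -> float:
    """Average IF angle predicted by dividing a hemisphere (2π sr) by the
    facet number — the classical resolution estimate."""
    return fov_approx_if(2.0 * np.pi, n_facets, convention)


def fov_approx_if(cp_solid_angle: float, n_facets: int,
                  convention: str = "hexagonal") -> float:
    """Average IF angle from dividing the eye's own angular CP by its
    facet number, under a lattice-packing convention."""
    if n_facets < 1:
        raise ValueError("facet count must be ≥ 1")
    if not 0.0 < cp_solid_angle <= 4.0 * np.pi + 1e-9:
        raise ValueError("CP solid angle must be in (0, 4π]")
    try:
        pitch = _PACKING[convention]
    except KeyError:
        raise ValueError(f"unknown packing convention {convention!r}") from None
    return RAD2DEG * float(pitch(cp_solid_angle / n_facets))


# ---------------------------------------------------------------------------
# summaries

_LOCAL_VARS = ["radius", "facet_diameter", "if_angle", "lens_thickness",
               "cone_thickness", "retina_thickness", "eye_parameter",
               "sensitivity"]


def summarize_eye(samples: list[CornealSample], eye_id: str = "",
                  bins: int = 20, min_samples: int = 10):
    """Facet-wise mean, sd and histogram of each local variable.

    Returns (summary DataFrame, {variable: (counts, bin_edges)}).
    """
    import pandas as pd

    df = samples_to_frame(samples)
    if len(df) < min_samples:
        raise ValueError(f"need ≥ {min_samples} samples, got {len(df)}")
    rows, hists = [], {}
    for var in _LOCAL_VARS:
        vals = df[var].to_numpy()
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            warnings.warn(f"{var}: all values missing, excluded from summary")
            continue
        rows.append({"eye_id": eye_id, "variable": var, "n": len(vals),
                     "mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                     "min": float(vals.min()), "max": float(vals.max())})
        if np.ptp(vals) <= 1e-9 * max(1.0, abs(vals.mean())):
            # (near-)constant variable: single bin
            hists[var] = np.histogram(vals, bins=1,
                                      range=(vals[0] - 0.5, vals[0] + 0.5))
        else:
            hists[var] = np.histogram(vals, bins=bins)
    return pd.DataFrame(rows), hists


def pairwise_correlations(samples: list[CornealSample],
                          variables: list[str] | None = None):
    """Pearson correlation matrix of the local variables, pooled over
    samples, pairwise-complete.  Constant variables yield NaN rows."""
    df = samples_to_frame(samples)
    variables = variables or _LOCAL_VARS
    return df[variables].corr(method="pearson", min_periods=3)
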
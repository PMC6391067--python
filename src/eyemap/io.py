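"""File formats for every artifact in the pipeline.

Labeled tomograms travel as TIFF stacks (integer labels, isotropic voxel
size in μm recorded in the image description); meshes as ASCII PLY/OBJ/STL
(μm, head frame); facet landmarks, sample tables, profiles and world
grids as CSV; rigid/mirror alignment transforms as JSON 4×4 matrices.
Every writer stamps a format-version header and every reader rejects
versions it does not know.

Angles are serialized in degrees and lengths in μm, except the
intertegular width ITW, which follows field convention in mm.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .facets import FacetMeasurement
from .geometry import LABELS, frame_to_samples, samples_to_frame
from .mesh import SurfaceMesh, read_mesh, write_mesh  # noqa: F401  (re-export)

FORMAT_VERSION = 1
_MAGIC = "eyemap-format"


@dataclasses.dataclass
class LabeledVolume:
    """Integer-labeled voxel volume with isotropic voxel size in μm.

    Labels: 0 background, 1 lens, 2 crystalline cone, 3 retina,
    4 lamina/optic-lobe interface, ≥5 other head tissue.  ``origin`` is
    the head-frame position (μm) of the center of voxel (0, 0, 0), so
    meshes extracted from the volume land in the head frame.
    """

    data: np.ndarray
    voxel_size: float
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.origin = tuple(float(v) for v in self.origin)
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("labeled volume must have an integer dtype")
        if self.data.ndim != 3:
            raise ValueError("labeled volume must be 3D")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive (μm)")

    def label_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.data, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclasses.dataclass
class RigidTransform:
    """4×4 homogeneous head-frame transform.

    ``kind`` is "rigid" (rotation determinant +1) or "mirror"
    (reflection, determinant −1 — used to place a labeled left eye on
    the right side of the head).  Transforms compose right-to-left on
    column vectors.
    """

    matrix: np.ndarray
    kind: str = "rigid"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform must be a 4×4 matrix")
        R = self.matrix[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation block is not orthogonal")
        det = np.linalg.det(R)
        expected = {"rigid": 1.0, "mirror": -1.0}
        if self.kind not in expected:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if not np.isclose(det, expected[self.kind], atol=1e-8):
            raise ValueError(
                f"{self.kind} transform must have determinant "
                f"{expected[self.kind]:+g}, got {det:+.6f}")

    @classmethod
    def sagittal_mirror(cls) -> "RigidTransform":
        """Reflection across the head's sagittal plane y = 0."""
        m = np.eye(4)
        m[1, 1] = -1.0
        return cls(m, kind="mirror")

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return points @ self.matrix[:3, :3].T + self.matrix[:3, 3]


@dataclasses.dataclass
class EyeRecord:
    """Per-individual metadata and eye-wide measurements."""

    individual_id: str
    species: str = ""
    itw_mm: float | None = None        # intertegular width, mm
    ev_um3: float | None = None        # eye volume, μm³
    area_um2: float | None = None      # eye surface area, μm²
    facet_count: int | None = None

    def __post_init__(self) -> None:
        for name in ("itw_mm", "ev_um3", "area_um2", "facet_count"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")

    @property
    def ev_cbrt_um(self) -> float | None:
        """EV^(1/3) in μm — the linear eye-size measure."""
        return None if self.ev_um3 is None else float(self.ev_um3) ** (1 / 3)


# ---------------------------------------------------------------------------
# volumes (TIFF stacks)


def write_labeled_volume(volume: LabeledVolume, path: str | Path) -> None:
    meta = {"format": _MAGIC, "version": FORMAT_VERSION,
            "voxel_size_um": volume.voxel_size,
            "origin_um": list(volume.origin)}
    tifffile.imwrite(path, volume.data.astype(np.uint8),
                     description=json.dumps(meta))


def read_labeled_volume(path: str | Path,
                        voxel_size: float | None = None) -> LabeledVolume:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    origin = (0.0, 0.0, 0.0)
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
        if meta.get("format") == _MAGIC:
            if meta.get("version") != FORMAT_VERSION:
                raise ValueError(f"{path}: unknown format version "
                                 f"{meta.get('version')}")
            voxel_size = meta["voxel_size_um"]
            origin = tuple(meta.get("origin_um", origin))
    if voxel_size is None:
        raise ValueError(f"{path}: voxel size missing; pass voxel_size=")
    data = np.asarray(data)
    known = set(LABELS.values())
    bad = [int(v) for v in np.unique(data) if v not in known and v < 5]
    if bad:
        raise ValueError(f"{path}: unknown label values {bad}")
    return LabeledVolume(data.astype(np.int16), voxel_size, origin=origin)


# ---------------------------------------------------------------------------
# CSV helpers


def _write_csv(df: pd.DataFrame, path: Path, kind: str,
               extra: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_MAGIC} {FORMAT_VERSION} {kind}\n")
        for k, v in (extra or {}).items():
            fh.write(f"# {k} {v}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_csv(path: Path, kind: str) -> tuple[pd.DataFrame, dict]:
    extra = {}
    with open(path) as fh:
        header = fh.readline().strip()
        parts = header.lstrip("# ").split()
        if len(parts) < 3 or parts[0] != _MAGIC or parts[2] != kind:
            raise ValueError(f"{path}: not an eyemap {kind} CSV")
        if int(parts[1]) != FORMAT_VERSION:
            raise ValueError(f"{path}: unknown format version {parts[1]}")
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            k, _, v = line.lstrip("# ").strip().partition(" ")
            extra[k] = v
            pos = fh.tell()
        df = pd.read_csv(fh)
    return df, extra


# ---------------------------------------------------------------------------
# landmarks

_ROLES = ["center"] + [f"b{i}" for i in range(1, 7)]


def write_landmarks(measurements: list[FacetMeasurement],
                    path: str | Path) -> None:
    rows = []
    for m in measurements:
        rows.append([m.eye_id, m.facet_id, "center", *m.center])
        for i, b in enumerate(m.borders, start=1):
            rows.append([m.eye_id, m.facet_id, f"b{i}", *b])
    df = pd.DataFrame(rows, columns=["eye_id", "facet_id", "point_role",
                                     "x", "y", "z"])
    _write_csv(df, Path(path), "landmarks")


def read_landmarks(path: str | Path) -> list[FacetMeasurement]:
    df, _ = _read_csv(Path(path), "landmarks")
    out = []
    for (eye_id, facet_id), g in df.groupby(["eye_id", "facet_id"],
                                            sort=False):
        roles = dict(zip(g["point_role"], g[["x", "y", "z"]].to_numpy()))
        unknown = set(roles) - set(_ROLES)
        if unknown:
            raise ValueError(f"{path}: facet {facet_id}: unknown point "
                             f"roles {sorted(unknown)}")
        if "center" not in roles:
            raise ValueError(f"{path}: facet {facet_id}: missing center point")
        borders = [roles[r] for r in _ROLES[1:] if r in roles]
        if len(borders) != 6:
            raise ValueError(f"{path}: facet {facet_id}: expected 6 border "
                             f"points, got {len(borders)}")
        if not np.isfinite(np.array(borders)).all():
            raise ValueError(f"{path}: facet {facet_id}: non-finite "
                             "coordinates")
        out.append(FacetMeasurement(center=roles["center"],
                                    borders=np.array(borders),
                                    eye_id=str(eye_id),
                                    facet_id=int(facet_id)))
    return out


# ---------------------------------------------------------------------------
# transforms


def write_transform(transform: RigidTransform, path: str | Path) -> None:
    payload = {"format": _MAGIC, "version": FORMAT_VERSION,
               "kind": transform.kind,
               "matrix": transform.matrix.tolist()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_transform(path: str | Path) -> RigidTransform:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != _MAGIC:
        raise ValueError(f"{path}: not an eyemap transform file")
    if payload.get("version") != FORMAT_VERSION:
        raise ValueError(f"{path}: unknown format version "
                         f"{payload.get('version')}")
    return RigidTransform(np.array(payload["matrix"]), kind=payload["kind"])


# ---------------------------------------------------------------------------
# sample tables


def write_sample_table(samples, path: str | Path) -> None:
    _write_csv(samples_to_frame(samples), Path(path), "samples")


def read_sample_table(path: str | Path):
    df, _ = _read_csv(Path(path), "samples")
    return frame_to_samples(df)


# ---------------------------------------------------------------------------
# eye records


def write_eye_records(records: list[EyeRecord], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    _write_csv(df, Path(path), "eyerecords")


def read_eye_records(path: str | Path) -> list[EyeRecord]:
    df, _ = _read_csv(Path(path), "eyerecords")
    out = []
    for row in df.to_dict("records"):
        clean = {k: (None if pd.isna(v) else v) for k, v in row.items()}
        if clean.get("facet_count") is not None:
            clean["facet_count"] = int(clean["facet_count"])
        out.append(EyeRecord(**clean))
    return out


# ---------------------------------------------------------------------------
# world grids (long CSV: az, el, masks, layers)


def write_grid(grid, path: str | Path,
               layer_names: list[str] | None = None) -> None:
    layer_names = (list(grid.layers) if layer_names is None
                   else list(layer_names))
    nel, naz = grid.shape
    el_idx, az_idx = np.meshgrid(np.arange(nel), np.arange(naz),
                                 indexing="ij")
    cols = {"azimuth": np.repeat(grid.az_centers[None, :], nel, 0).ravel(),
            "elevation": np.repeat(grid.el_centers[:, None], naz, 1).ravel()}
    for name, mask in grid.masks.items():
        cols[f"mask:{name}"] = mask.ravel().astype(int)
    for name in layer_names:
        cols[f"layer:{name}"] = grid.layers[name].ravel()
    _write_csv(pd.DataFrame(cols), Path(path), "worldgrid",
               extra={"cell_size": grid.cell_size})


def read_grid(path: str | Path):
    from .projection import WorldGrid

    df, extra = _read_csv(Path(path), "worldgrid")
    grid = WorldGrid(cell_size=float(extra["cell_size"]))
    nel, naz = grid.shape
    if len(df) != nel * naz:
        raise ValueError(f"{path}: grid size mismatch")
    for col in df.columns:
        if col.startswith("mask:"):
            grid.masks[col[5:]] = (
                df[col].to_numpy().reshape(nel, naz).astype(bool))
        elif col.startswith("layer:"):
            grid.layers[col[6:]] = (
                df[col].to_numpy(dtype=np.float64).reshape(nel, naz))
    return grid
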
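"""Shared synthetic-eye fixtures.

Everything is generated at test time from the synthetic module; sizes
are chosen to keep the whole suite fast while staying in the geometric
regime of real bee eyes (facet diameter ≪ radius of curvature).
"""

import numpy as np
import pytest

from eyemap import (SyntheticEyeSpec, assign_viewing_directions,
                    generate_eye, sample_cornea)


@pytest.fixture(scope="session")
def small_eye():
    """R = 400 μm, 60° cap, shells 20/30/80 μm, D = 20 μm, with volume.

    Small enough for ray tracing every sample against every interface.
    """
    spec = SyntheticEyeSpec(shape="sphere_cap", radius_or_semiaxes=400.0,
                            cap_half_angle=60.0, shell_offsets=(20, 30, 80),
                            facet_field=20.0, lamina_thickness=20.0,
                            rng_seed=7)
    return generate_eye(spec, voxel_size=5.0, mesh_edge_length=8.0,
                        n_landmarks=50)


@pytest.fixture(scope="session")
def small_eye_samples(small_eye):
    samples = sample_cornea(small_eye.meshes["cornea_outer"], spacing=40.0,
                            seed=3)
    assign_viewing_directions(samples)
    return samples


@pytest.fixture(scope="session")
def paper_scale_eye():
    """R = 1 mm, 60° cap — the size regime of a bumblebee eye; mesh only."""
    spec = SyntheticEyeSpec(shape="sphere_cap", radius_or_semiaxes=1000.0,
                            cap_half_angle=60.0, rng_seed=1)
    return generate_eye(spec, with_volume=False, mesh_edge_length=12.0,
                        n_landmarks=60)


@pytest.fixture(scope="session")
def paper_scale_samples(paper_scale_eye):
    """25 μm blue-noise samples on the 1 mm cornea (the stated interval)."""
    samples = sample_cornea(paper_scale_eye.meshes["cornea_outer"],
                            spacing=25.0, seed=1)
    assign_viewing_directions(samples)
    return samples


@pytest.fixture(scope="session")
def hemisphere_mesh():
    """Open hemisphere of R = 1 mm pointing along +z, coarse mesh."""
    spec = SyntheticEyeSpec(shape="sphere_cap", radius_or_semiaxes=1000.0,
                            cap_half_angle=90.0, optic_axis=(0, 0, 1.0))
    return generate_eye(spec, with_volume=False, mesh_edge_length=25.0,
                        n_landmarks=4).meshes["cornea_outer"]


def planar_patch(width: float, height: float, nx: int = 20, ny: int = 20):
    """Rectangular flat mesh in the z = 0 plane, +z oriented."""
    from eyemap import SurfaceMesh

    xs = np.linspace(0, width, nx)
    ys = np.linspace(0, height, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return SurfaceMesh(np.array(verts), np.array(faces), role="generic")
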
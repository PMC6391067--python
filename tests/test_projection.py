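"""Viewing directions, CP masks, world-grid interpolation, profiles."""

import numpy as np
import pytest

from eyemap import (RigidTransform, WorldGrid, build_cp_mask,
                    binocular_overlap, complete_cp, direction_vector,
                    map_coordinates, mirror_eye, profiles, project_scalar,
                    viewing_direction)
from eyemap.geometry import CornealSample


def cap_samples(center_az, center_el, half_angle, n=3000, seed=0):
    """Synthetic samples whose normals fill a cap of directions uniformly."""
    rng = np.random.default_rng(seed)
    axis = direction_vector(center_az, center_el)
    # uniform in solid angle over the cap
    ct = rng.uniform(np.cos(np.radians(half_angle)), 1.0, n)
    st = np.sqrt(1 - ct ** 2)
    phi = rng.uniform(0, 2 * np.pi, n)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    dirs = (ct[:, None] * axis + st[:, None]
            * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v))
    out = []
    for d in dirs:
        s = CornealSample(position=1000.0 * d, normal=d)
        s.azimuth, s.elevation = viewing_direction(d)
        out.append(s)
    return out


class TestViewingDirection:
    def test_frontal(self):
        assert viewing_direction([1.0, 0.0, 0.0]) == (0.0, 0.0)

    def test_pole_azimuth_zero(self):
        az, el = viewing_direction([0.0, 0.0, 1.0])
        assert az == 0.0 and el == pytest.approx(90.0)

    def test_left_lateral_negative_azimuth(self):
        """The animal's left (−y) is negative azimuth by convention."""
        az, el = viewing_direction([0.0, -1.0, 0.0])
        assert az == pytest.approx(-90.0)

    def test_roundtrip(self):
        n = direction_vector(-60.0, 30.0)
        az, el = viewing_direction(n)
        assert az == pytest.approx(-60.0, abs=1e-9)
        assert el == pytest.approx(30.0, abs=1e-9)
        np.testing.assert_allclose(direction_vector(az, el), n, atol=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            viewing_direction([0.0, 0.0, 0.0])


class TestMirror:
    def test_sagittal_reflection_of_direction(self):
        """az −60°, el 30° mirrors to az +60°, el 30°."""
        s = CornealSample(position=np.zeros(3),
                          normal=direction_vector(-60.0, 30.0))
        s.azimuth, s.elevation = viewing_direction(s.normal)
        (m,) = mirror_eye([s], RigidTransform.sagittal_mirror())
        assert m.azimuth == pytest.approx(60.0, abs=1e-9)
        assert m.elevation == pytest.approx(30.0, abs=1e-9)

    def test_involution(self):
        s = CornealSample(position=np.array([3.0, -4.0, 5.0]),
                          normal=direction_vector(-42.0, 17.0))
        s.azimuth, s.elevation = viewing_direction(s.normal)
        t = RigidTransform.sagittal_mirror()
        (back,) = mirror_eye(mirror_eye([s], t), t)
        np.testing.assert_allclose(back.position, s.position, atol=1e-12)
        np.testing.assert_allclose(back.normal, s.normal, atol=1e-12)

    def test_rigid_transform_rejected(self):
        with pytest.raises(ValueError, match="mirror"):
            mirror_eye([], RigidTransform(np.eye(4), kind="rigid"))

    def test_binocular_mask_symmetric(self):
        """Binocular overlap of an eye and its mirror is symmetric in az."""
        left = cap_samples(-40.0, 0.0, 60.0, seed=5)
        right = mirror_eye(left, RigidTransform.sagittal_mirror())
        grid = WorldGrid(2.0)
        cl = build_cp_mask(left, grid, name="left")
        cr = build_cp_mask(right, grid, name="right")
        bino = binocular_overlap(cl, cr)
        np.testing.assert_array_equal(bino.mask, bino.mask[:, ::-1])


class TestCpMask:
    def test_hemisphere_cap(self):
        """Hemispherical normals → 2π sr (50% of sphere) within 2%."""
        samples = cap_samples(0.0, 0.0, 90.0, n=12000, seed=1)
        grid = WorldGrid(1.0)
        cp = build_cp_mask(samples, grid)
        assert cp.solid_angle == pytest.approx(2 * np.pi, rel=0.02)
        assert cp.percent_of_sphere == pytest.approx(50.0, rel=0.02)

    def test_60deg_cap(self):
        samples = cap_samples(-60.0, 10.0, 60.0, n=8000, seed=2)
        grid = WorldGrid(1.0)
        cp = build_cp_mask(samples, grid)
        assert cp.solid_angle == pytest.approx(np.pi, rel=0.02)

    def test_closing_insensitive_when_dense(self):
        """With dense sampling, closing changes the solid angle < 1%."""
        samples = cap_samples(0.0, 0.0, 60.0, n=40000, seed=3)
        grid1, grid2 = WorldGrid(2.0), WorldGrid(2.0)
        on = build_cp_mask(samples, grid1, closing_radius=2)
        off = build_cp_mask(samples, grid2, closing_radius=0)
        assert abs(on.solid_angle / off.solid_angle - 1) < 0.01

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            build_cp_mask([], WorldGrid(5.0))


class TestBinocular:
    def test_identical_caps(self):
        s = cap_samples(0.0, 0.0, 50.0, seed=4)
        g = WorldGrid(2.0)
        a = build_cp_mask(s, g, name="l")
        b = build_cp_mask(s, g, name="r")
        bino = binocular_overlap(a, b)
        np.testing.assert_array_equal(bino.mask, a.mask)

    def test_disjoint_caps(self):
        g = WorldGrid(2.0)
        a = build_cp_mask(cap_samples(-120.0, 0.0, 20.0, seed=5), g, name="l")
        b = build_cp_mask(cap_samples(120.0, 0.0, 20.0, seed=6), g, name="r")
        assert binocular_overlap(a, b).solid_angle == 0.0

    def test_inclusion_exclusion_exact(self):
        g = WorldGrid(2.0)
        a = build_cp_mask(cap_samples(-30.0, 0.0, 60.0, seed=7), g, name="l")
        b = build_cp_mask(cap_samples(30.0, 0.0, 60.0, seed=8), g, name="r")
        bino = binocular_overlap(a, b)
        comp = complete_cp(a, b)
        assert comp.solid_angle == pytest.approx(
            a.solid_angle + b.solid_angle - bino.solid_angle, abs=1e-12)

    def test_monte_carlo_oracle(self):
        """Overlap of 60° caps at az ±30°: grid AND mask vs seeded
        Monte-Carlo integration over 10⁶ directions, within 1%."""
        g = WorldGrid(1.0)
        # analytic masks (no sampling noise): cells within 60° of each axis
        vec = g.center_vectors()
        for name, az in (("l", -30.0), ("r", 30.0)):
            axis = direction_vector(az, 0.0)
            g.masks[name] = vec @ axis >= np.cos(np.radians(60.0))
        from eyemap.projection import CornealProjectionMask

        bino = binocular_overlap(CornealProjectionMask(g, g.masks["l"]),
                                 CornealProjectionMask(g, g.masks["r"]))
        rng = np.random.default_rng(12345)
        d = rng.normal(size=(10 ** 6, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        la = direction_vector(-30.0, 0.0)
        ra = direction_vector(30.0, 0.0)
        c60 = np.cos(np.radians(60.0))
        frac = np.mean((d @ la >= c60) & (d @ ra >= c60))
        assert bino.solid_angle == pytest.approx(4 * np.pi * frac, rel=0.01)

    def test_grid_mismatch_rejected(self):
        a = build_cp_mask(cap_samples(0, 0, 30, seed=9), WorldGrid(2.0))
        b = build_cp_mask(cap_samples(0, 0, 30, seed=9), WorldGrid(1.0))
        with pytest.raises(ValueError, match="grid"):
            binocular_overlap(a, b)


class TestProjectScalar:
    def test_constant_field(self):
        samples = cap_samples(0.0, 0.0, 40.0, seed=10)
        g = WorldGrid(2.0)
        cp = build_cp_mask(samples, g)
        layer = project_scalar(samples, np.full(len(samples), 7.5), g, cp)
        vals = layer[cp.mask]
        np.testing.assert_allclose(vals, 7.5, rtol=1e-9)

    def test_elevation_gradient(self):
        """A field linear in elevation re-projects within 3% per cell."""
        samples = cap_samples(0.0, 0.0, 50.0, n=8000, seed=11)
        vals = np.array([30.0 + 0.2 * s.elevation for s in samples])
        g = WorldGrid(2.0)
        cp = build_cp_mask(samples, g)
        layer = project_scalar(samples, vals, g, cp)
        el = g.el_centers[:, None] * np.ones(g.shape)
        expected = 30.0 + 0.2 * el
        err = np.abs(layer[cp.mask] / expected[cp.mask] - 1)
        assert np.nanmax(err) < 0.03

    def test_bounded_by_inputs(self):
        samples = cap_samples(0.0, 0.0, 40.0, seed=12)
        rng = np.random.default_rng(0)
        vals = rng.uniform(10.0, 20.0, len(samples))
        g = WorldGrid(2.0)
        cp = build_cp_mask(samples, g)
        layer = project_scalar(samples, vals, g, cp)
        inside = layer[cp.mask]
        assert inside.min() >= 10.0 - 1e-9 and inside.max() <= 20.0 + 1e-9

    def test_mostly_missing_rejected(self):
        samples = cap_samples(0.0, 0.0, 40.0, seed=13)
        vals = np.full(len(samples), np.nan)
        vals[: len(vals) // 3] = 1.0  # only 33% defined
        g = WorldGrid(2.0)
        cp = build_cp_mask(samples, g)
        with pytest.raises(ValueError, match="50%"):
            project_scalar(samples, vals, g, cp)

    def test_commutes_with_mirroring(self):
        samples = cap_samples(-45.0, 10.0, 40.0, seed=14)
        vals = np.array([5.0 + 0.1 * abs(s.azimuth) for s in samples])
        g1 = WorldGrid(2.0)
        cp1 = build_cp_mask(samples, g1)
        layer = project_scalar(samples, vals, g1, cp1)
        mirrored = mirror_eye(samples, RigidTransform.sagittal_mirror())
        g2 = WorldGrid(2.0)
        cp2 = build_cp_mask(mirrored, g2)
        layer_m = project_scalar(mirrored, vals, g2, cp2)
        np.testing.assert_allclose(layer_m, layer[:, ::-1], equal_nan=True,
                                   atol=1e-9)


class TestMapCoordinates:
    def test_origin(self):
        for proj in ("equirect", "sinusoidal"):
            x, y = map_coordinates(0.0, 0.0, proj)
            assert (x, y) == (0.0, 0.0)

    def test_sinusoidal_cos_factor(self):
        x, y = map_coordinates(60.0, 60.0, "sinusoidal")
        assert x == pytest.approx(30.0) and y == pytest.approx(60.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            map_coordinates(190.0, 0.0)

    def test_equal_area_property(self):
        """Sinusoidal pixel count of a cap / full sphere = sr / 4π."""
        g = WorldGrid(1.0)
        vec = g.center_vectors()
        axis = direction_vector(20.0, 15.0)
        cap = vec @ axis >= np.cos(np.radians(55.0))
        az = g.az_centers[None, :] * np.ones(g.shape)
        el = g.el_centers[:, None] * np.ones(g.shape)

        def pixel_count(mask):
            x, y = map_coordinates(az[mask], el[mask], "sinusoidal")
            ix = np.floor(x + 180.0).astype(int)
            iy = np.floor(y + 90.0).astype(int)
            return len(set(zip(ix.tolist(), iy.tolist())))

        full = np.ones(g.shape, dtype=bool)
        ratio = pixel_count(cap) / pixel_count(full)
        truth = g.solid_angle(cap) / (4 * np.pi)
        assert ratio == pytest.approx(truth, rel=0.01)


class TestProfiles:
    def _grid_with_cap(self):
        g = WorldGrid(1.0)
        vec = g.center_vectors()
        axis = direction_vector(0.0, 0.0)
        g.masks["cp"] = vec @ axis >= np.cos(np.radians(60.0))
        return g

    def test_uniform_layer_flat_profile(self):
        g = self._grid_with_cap()
        layer = np.full(g.shape, np.nan)
        layer[g.masks["cp"]] = 3.25
        g.layers["v"] = layer
        prof = profiles(g, "v", axis="elevation", band=10.0)
        vals = prof["mean"].to_numpy()
        np.testing.assert_allclose(vals[np.isfinite(vals)], 3.25, rtol=1e-12)

    def test_cp_integral_sums_to_100(self):
        g = self._grid_with_cap()
        for axis in ("elevation", "azimuth"):
            prof = profiles(g, "cp", axis=axis, band=10.0)
            assert np.nansum(prof["percent_of_cp"]) == pytest.approx(100.0)

    def test_elevation_layer_self_consistency(self):
        """Profiling the elevation coordinate returns band centers."""
        g = self._grid_with_cap()
        layer = np.full(g.shape, np.nan)
        el = g.el_centers[:, None] * np.ones(g.shape)
        layer[g.masks["cp"]] = el[g.masks["cp"]]
        g.layers["el"] = layer
        prof = profiles(g, "el", axis="elevation", band=10.0)
        ok = np.isfinite(prof["mean"])
        assert (np.abs(prof["mean"][ok] - prof["elevation"][ok]) <= 5.0).all()

    def test_empty_band_missing_not_zero(self):
        g = self._grid_with_cap()
        layer = np.full(g.shape, np.nan)
        layer[g.masks["cp"]] = 1.0
        g.layers["v"] = layer
        prof = profiles(g, "v", axis="elevation", band=10.0)
        assert np.isnan(prof["mean"].iloc[0])  # no CP at el −90…−80

    def test_bad_band_rejected(self):
        g = self._grid_with_cap()
        g.layers["v"] = np.ones(g.shape)
        with pytest.raises(ValueError, match="band"):
            profiles(g, "v", axis="elevation", band=7.0)


def test_grid_solid_angle_sums_to_sphere():
    """Σ cell solid angles = 4π within 0.1% at 1° resolution."""
    g = WorldGrid(1.0)
    assert g.omega.sum() == pytest.approx(4 * np.pi, rel=1e-3)
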
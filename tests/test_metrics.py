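"""Inter-facet angle, thickness tracing, eye parameter, sensitivity."""

import numpy as np
import pytest

from eyemap import (OpticsConfig, behavioral_min_angle,
                    compute_sample_metrics, eye_parameter, fov_approx_if,
                    hemi_approx_if, if_angle, optical_sensitivity,
                    pairwise_correlations, summarize_eye, trace_thicknesses)
from eyemap.geometry import CornealSample
from eyemap.metrics import if_angle_numeric


class TestIfAngle:
    def test_arithmetic(self):
        assert if_angle(20.0, 1000.0) == pytest.approx(1.1459, abs=1e-4)
        assert if_angle(25.0, 954.93) == pytest.approx(1.5000, abs=1e-4)

    def test_missing_propagates(self):
        assert np.isnan(if_angle(np.nan, 1000.0))
        assert np.isnan(if_angle(25.0, np.nan))
        assert np.isnan(if_angle(-5.0, 1000.0))

    def test_numeric_oracle_on_sphere(self, paper_scale_eye,
                                      paper_scale_samples):
        """Two-point numeric ΔΦ agrees with D/R within 2% on spheres."""
        mesh = paper_scale_eye.meshes["cornea_outer"]
        D = 25.0
        rel_errs = []
        for s in paper_scale_samples[::100]:
            analytic = if_angle(D, 1000.0)
            numeric = if_angle_numeric(mesh, s, D)
            rel_errs.append(numeric / analytic - 1)
        assert np.abs(np.median(rel_errs)) < 0.02


class TestTraceThicknesses:
    def test_concentric_shells_exact(self, small_eye, small_eye_samples):
        """Constant-offset shells: L = (20, 30, 80) μm at every sample,
        to the 0.5 μm ray–mesh tolerance."""
        cone = small_eye.meshes["cone_front"]
        retina = small_eye.meshes["retina_front"]
        lamina = small_eye.meshes["lamina_front"]
        for s in small_eye_samples:
            L = trace_thicknesses(s, cone, retina, lamina)
            np.testing.assert_allclose(L, (20.0, 30.0, 80.0), atol=0.5)

    def test_partial_result_when_deep_miss(self, small_eye):
        """A ray that misses the lamina keeps L_lens and L_cone."""
        # a sample near the cap rim whose inward ray exits the side
        mesh = small_eye.meshes["cornea_outer"]
        rim = mesh.vertices[np.argmin(mesh.vertices @ np.array(
            small_eye.spec.optic_axis))]
        n = rim / np.linalg.norm(rim)
        # tilt the normal so the ray exits laterally after the cone
        tangent = np.cross(n, [0.0, 0.0, 1.0])
        tangent /= np.linalg.norm(tangent)
        s = CornealSample(position=rim, normal=(0.2 * n + 0.98 * tangent)
                          / np.linalg.norm(0.2 * n + 0.98 * tangent))
        L = trace_thicknesses(s, small_eye.meshes["cone_front"],
                              small_eye.meshes["retina_front"],
                              small_eye.meshes["lamina_front"])
        # whatever is hit first must be reported; deeper misses are NaN
        finite = np.isfinite(L)
        assert not finite.all()
        if finite.any():
            assert finite[: int(np.flatnonzero(finite)[-1]) + 1].all()

    def test_missing_interface_propagates(self, small_eye,
                                          small_eye_samples):
        s = small_eye_samples[0]
        L = trace_thicknesses(s, small_eye.meshes["cone_front"],
                              small_eye.meshes["retina_front"], None)
        assert np.isfinite(L[0]) and np.isfinite(L[1]) and np.isnan(L[2])

    def test_requires_cone(self, small_eye_samples):
        with pytest.raises(ValueError, match="cone"):
            trace_thicknesses(small_eye_samples[0], None)


class TestEyeParameter:
    def test_worked_value(self):
        """ΔΦ = 1.5°, D = 25 μm → P = 0.6545 μm·rad."""
        assert eye_parameter(1.5, 25.0) == pytest.approx(0.6545, abs=1e-4)

    def test_zero_angle(self):
        assert eye_parameter(0.0, 25.0) == 0.0

    def test_bilinearity(self):
        assert eye_parameter(3.0, 50.0) == pytest.approx(
            4 * eye_parameter(1.5, 25.0))


class TestSensitivity:
    def test_hand_computed_value(self):
        """D=25, Δρ=1.5°, l=220, k=0.0067 → S = 0.1032 μm²·sr."""
        s = optical_sensitivity(25.0, np.radians(1.5), 220.0)
        assert s == pytest.approx(0.1032, abs=2e-4)

    def test_long_rhabdom_limit(self):
        """l → ∞: absorption factor → 1, S → (π/4)²·D²·Δρ²."""
        s = optical_sensitivity(25.0, 0.02, 1e9)
        assert s == pytest.approx((np.pi / 4) ** 2 * 625 * 4e-4, rel=1e-4)

    def test_zero_rhabdom(self):
        assert optical_sensitivity(25.0, 0.02, 0.0) == 0.0

    def test_monotonic_in_each_argument(self):
        base = optical_sensitivity(25.0, 0.02, 200.0)
        for kwargs in (dict(D=30.0, rho=0.02, l=200.0),
                       dict(D=25.0, rho=0.03, l=200.0),
                       dict(D=25.0, rho=0.02, l=300.0)):
            s = optical_sensitivity(kwargs["D"], kwargs["rho"], kwargs["l"])
            assert s > base

    def test_config_constants_exposed(self):
        cfg = OpticsConfig(absorption_coefficient=0.01,
                           acceptance_denominator=3.0)
        s = optical_sensitivity(25.0, 0.02, 200.0, cfg)
        expected = (np.pi / 4) ** 2 * 625 * 4e-4 * (2.0 / 5.0)
        assert s == pytest.approx(expected, rel=1e-9)
        with pytest.raises(ValueError):
            OpticsConfig(absorption_coefficient=0.0)


class TestFacetNumberApproximations:
    def test_hemi_approx_conventions(self):
        """N = 5440 facets over 2π sr: ΔΦ 2.093° (hexagonal packing),
        1.947° (square)."""
        assert hemi_approx_if(5440, "hexagonal") == pytest.approx(2.093,
                                                                  abs=2e-3)
        assert hemi_approx_if(5440, "square") == pytest.approx(1.947,
                                                               abs=2e-3)

    def test_fov_equals_hemi_at_2pi(self):
        assert fov_approx_if(2 * np.pi, 5440) == hemi_approx_if(5440)

    def test_quadruple_facets_halves_angle(self):
        assert hemi_approx_if(4 * 5440) == pytest.approx(
            hemi_approx_if(5440) / 2, rel=1e-12)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            hemi_approx_if(0)
        with pytest.raises(ValueError):
            fov_approx_if(-1.0, 100)
        with pytest.raises(ValueError):
            hemi_approx_if(100, "triangular")


class TestPipelineConsistency:
    def test_metrics_match_direct_formulas(self, small_eye_samples):
        """Pipeline P and S equal direct formula evaluation per sample."""
        samples = [s for s in small_eye_samples[:50]]
        for s in samples:
            s.facet_diameter = 20.0
            s.radius = 400.0
            s.retina_thickness = 80.0
        compute_sample_metrics(samples)
        for s in samples:
            assert s.if_angle == pytest.approx(np.degrees(20.0 / 400.0))
            assert s.eye_parameter == pytest.approx(
                np.radians(s.if_angle) * 20.0)
            assert s.sensitivity == pytest.approx(optical_sensitivity(
                20.0, np.radians(s.if_angle), 80.0))

    def test_mean_if_angle_on_cap(self, paper_scale_eye,
                                  paper_scale_samples):
        """Mean pipeline ΔΦ equals (180/π)·D̄/R within 2% on a sphere cap."""
        from eyemap import fit_local_radius, interpolate_facet_field

        mesh = paper_scale_eye.meshes["cornea_outer"]
        samples = paper_scale_samples[::5]
        interpolate_facet_field(paper_scale_eye.landmarks, samples)
        for s in samples:
            fit_local_radius(mesh, s, neighborhood_radius=125.0)
        compute_sample_metrics(samples)
        vals = np.array([s.if_angle for s in samples])
        D = np.array([s.facet_diameter for s in samples])
        expected = np.degrees(np.nanmean(D) / 1000.0)
        assert np.nanmean(vals) == pytest.approx(expected, rel=0.02)


class TestSummaries:
    def _samples(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            s = CornealSample(position=rng.normal(size=3),
                              normal=np.array([1.0, 0.0, 0.0]))
            s.radius = rng.uniform(800.0, 1200.0)
            s.facet_diameter = 25.0
            s.if_angle = np.degrees(s.facet_diameter / s.radius)
            out.append(s)
        return out

    def test_constant_variable_sd_zero(self):
        table, hists = summarize_eye(self._samples(), eye_id="e1")
        row = table[table.variable == "facet_diameter"].iloc[0]
        assert row["sd"] == 0.0
        assert "facet_diameter" in hists

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            summarize_eye(self._samples(5))

    def test_if_angle_anticorrelates_with_radius(self):
        """Constant D with varying R: r(ΔΦ, R) strongly negative."""
        corr = pairwise_correlations(self._samples(200),
                                     ["if_angle", "radius"])
        assert corr.loc["if_angle", "radius"] < -0.8

    def test_identical_variables_r_one(self):
        samples = self._samples(50)
        for s in samples:
            s.lens_thickness = s.radius
        corr = pairwise_correlations(samples, ["radius", "lens_thickness"])
        assert corr.loc["radius", "lens_thickness"] == pytest.approx(1.0)

    def test_constant_variable_r_missing(self):
        corr = pairwise_correlations(self._samples(50),
                                     ["facet_diameter", "radius"])
        assert np.isnan(corr.loc["facet_diameter", "radius"])


def test_behavioral_regression_worked_value():
    """Angle(°) = 17.6 − 3.1·ITW: 8.4° at 3.0 mm, 5.2° at 4.0 mm."""
    assert behavioral_min_angle(3.0) == pytest.approx(8.3, abs=0.11)
    assert behavioral_min_angle(4.0) == pytest.approx(5.2, abs=1e-9)
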
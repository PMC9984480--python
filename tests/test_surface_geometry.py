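"""Exact differential geometry of the six substrate families."""

import numpy as np
import pytest

from curvescape.surface_geometry import (
    AXISYMMETRIC, SubstrateSpec, apply_convexity, make_generatrix, make_patch,
    normalize_curvature, revolve, scale_substrate, sweep_sinusoid)
from conftest import fd_fundamental_forms


def interior(patch, trim=3):
    """Mask of unflagged samples away from grid edges."""
    m = ~patch.flagged
    m[:trim, :] = m[-trim:, :] = False
    m[:, :trim] = m[:, -trim:] = False
    return m


class TestGeneratrix:
    def test_spheres_is_semicircle_string(self):
        spec = SubstrateSpec("spheres", n_periods=2)
        g = make_generatrix(spec, 128)
        R = spec.sphere_radius
        assert R == 180.0
        # every sample lies on a circle of radius 180 around its period center
        centers = (np.floor(np.clip(g.axial, 0, 4 * R - 1e-6) / (2 * R))
                   + 0.5) * 2 * R
        d = np.hypot(g.axial - centers, g.radial)
        on_own = np.isclose(d, R, atol=1e-9 * R)
        # period-boundary samples (pinches) belong to either neighbor
        assert (on_own | np.isclose(g.radial, 0.0, atol=1e-9)).all()

    def test_cylinder_is_straight_line(self):
        spec = SubstrateSpec("cylinder")
        g = make_generatrix(spec, 64)
        assert np.ptp(g.radial) == 0.0
        assert np.all(np.diff(g.axial) >= 0)  # duplicates at period joins
        assert g.axial[-1] - g.axial[0] == pytest.approx(
            spec.n_periods * 2 * spec.sphere_radius)

    def test_catenoid_profile_is_cosh(self):
        spec = SubstrateSpec("catenoids", n_periods=1)
        p = spec.shape_params()
        c = p["neck_radius"]
        g = make_generatrix(spec, 256)
        z0 = c * np.arccosh(p["rim_radius"] / c)   # neck position
        assert np.allclose(g.radial, c * np.cosh((g.axial - z0) / c), rtol=1e-10)

    def test_radial_nonnegative_everywhere(self):
        for fam in AXISYMMETRIC:
            g = make_generatrix(SubstrateSpec(fam), 64)
            assert g.radial.min() >= 0

    def test_rejects_sinusoid_and_bad_inputs(self):
        with pytest.raises(ValueError):
            make_generatrix(SubstrateSpec("sinusoidal_cylinder"), 64)
        with pytest.raises(ValueError):
            make_generatrix(SubstrateSpec("spheres"), 8)
        with pytest.raises(ValueError):
            SubstrateSpec("hyperboloid")
        with pytest.raises(ValueError):
            SubstrateSpec("spheres", scale=-1.0)


class TestRevolve:
    def test_sphere_curvatures_equal_one_over_R(self):
        spec = SubstrateSpec("spheres", n_periods=1)
        patch = revolve(make_generatrix(spec, 128), 65)
        ok = ~patch.flagged
        assert np.allclose(patch.kappa1[ok], 1 / 180.0, rtol=1e-12)
        assert np.allclose(patch.kappa2[ok], 1 / 180.0, rtol=1e-12)

    def test_cylinder_K_and_kappa2_zero(self):
        patch = make_patch(SubstrateSpec("cylinder"), 64, 33)
        assert np.abs(patch.K).max() == 0.0
        assert np.abs(patch.kappa2).max() == 0.0
        assert np.allclose(patch.kappa1, 1 / 90.0)

    def test_catenoid_is_minimal_surface(self):
        spec = SubstrateSpec("catenoids")
        patch = make_patch(spec, 256, 33)
        assert np.abs(normalize_curvature(patch.H, spec)).max() < 1e-6

    def test_unduloid_H_constant(self):
        patch = make_patch(SubstrateSpec("unduloid"), 256, 33)
        H = patch.H
        assert H.std() / abs(H.mean()) < 1e-6

    def test_pseudosphere_K_constant_negative(self):
        spec = SubstrateSpec("pseudospheres")
        patch = make_patch(spec, 256, 33)
        K = patch.K
        assert K.mean() < 0
        assert K.std() / abs(K.mean()) < 1e-6
        c = spec.shape_params()["c"]
        assert np.allclose(K, -1.0 / c**2, rtol=1e-9)

    def test_constant_H_family_shares_H(self):
        Hs = []
        for fam in ("cylinder", "unduloid", "spheres"):
            patch = make_patch(SubstrateSpec(fam, n_periods=1), 128, 17)
            H = patch.H[~patch.flagged]
            assert H.std() / abs(H.mean()) < 1e-6
            Hs.append(H.mean())
        assert np.ptp(Hs) / abs(np.mean(Hs)) < 1e-6

    def test_sphere_string_pinch_flagged(self):
        patch = revolve(make_generatrix(SubstrateSpec("spheres", n_periods=2), 65))
        assert patch.flagged.any()
        assert np.isfinite(patch.kappa1).all()

    def test_principal_frames_orthonormal(self):
        for fam in ("cylinder", "unduloid", "catenoids", "pseudospheres"):
            patch = make_patch(SubstrateSpec(fam), 64, 17)
            ok = ~(patch.umbilic | patch.flagged)
            pd1, pd2, nrm = patch.pd1[ok], patch.pd2[ok], patch.normal[ok]
            assert np.allclose(np.linalg.norm(nrm, axis=-1), 1, atol=1e-9)
            assert np.allclose((pd1 * pd2).sum(-1), 0, atol=1e-9)
            assert np.allclose((pd1 * nrm).sum(-1), 0, atol=1e-9)
            assert np.allclose((pd2 * nrm).sum(-1), 0, atol=1e-9)

    def test_umbilics_have_undefined_directions(self):
        patch = make_patch(SubstrateSpec("spheres", n_periods=1), 64, 17)
        ok = ~patch.flagged
        assert patch.umbilic[ok].all()
        assert np.isnan(patch.pd1[ok]).all()


class TestFiniteDifferenceOracle:
    """Analytic curvatures vs central-difference fundamental forms."""

    @pytest.mark.parametrize("family", AXISYMMETRIC)
    def test_axisymmetric_families(self, family):
        spec = SubstrateSpec(family, n_periods=1)
        # the pseudosphere needs a finer grid near its truncated cusp for
        # second-order differences to reach the tolerance
        n = 2048 if family == "pseudospheres" else 1024
        patch = make_patch(spec, n, 257)
        Hf, Kf = fd_fundamental_forms(patch.xyz)
        m = interior(patch, 5)
        if family == "pseudospheres":
            # the string mirrors at the rim (a designed C0 join); central
            # differences across that row are meaningless
            mid = patch.K.shape[0] // 2
            m[mid - 3:mid + 4, :] = False
        # common curvature scale; H of minimal surfaces is ~0, so relative
        # error is taken against the principal-curvature magnitude
        scale = max(np.abs(patch.kappa1[m]).max(), np.abs(patch.kappa2[m]).max())
        assert np.abs(patch.K[m] - Kf[m]).max() / scale**2 < 1e-4
        assert np.abs(np.abs(patch.H[m]) - np.abs(Hf[m])).max() / scale < 1e-4

    def test_sinusoidal_cylinder(self):
        patch = sweep_sinusoid(90.0, 80.0, 720.0, n_periods=1,
                               n_s=1024, n_angles=257)
        Hf, Kf = fd_fundamental_forms(patch.xyz)
        m = interior(patch, 5)
        scaleK = np.abs(patch.K[m]).max()
        assert np.abs(patch.K[m] - Kf[m]).max() / scaleK < 1e-4


class TestSweepSinusoid:
    def test_zero_amplitude_reduces_to_cylinder(self):
        patch = sweep_sinusoid(90.0, 0.0, 720.0, n_periods=1)
        assert np.abs(patch.K).max() < 1e-15
        assert np.allclose(patch.kappa1, 1 / 90.0)

    def test_K_zero_on_crest_at_inflections(self):
        patch = sweep_sinusoid(90.0, 80.0, 720.0, n_periods=1, n_s=721,
                               n_angles=181)
        # inflection at s = 0 and s = lambda/2; crest at phi = pi/2
        K = patch.K
        i_inflect = [0, 360, 720]
        for i in i_inflect:
            assert np.abs(K[i, :]).max() < 1e-12

    def test_K_alternates_sign_across_bends(self):
        patch = sweep_sinusoid(90.0, 80.0, 720.0, n_periods=1, n_s=721,
                               n_angles=181)
        K = patch.K
        # max path curvature at s = lambda/4 (i=180) and 3 lambda/4 (i=540);
        # the sides of the tube (phi near 0 and pi) carry opposite K there,
        # and the pattern flips between successive bends (torus-like signs)
        assert K[180, 2] * K[180, -3] < 0
        assert K[180, 2] * K[540, 2] < 0

    def test_torus_consistent_signs(self):
        # bend toward the left normal (k > 0): the inner side of the bend
        # (phi = 0, toward the curvature center) is saddle-shaped, K < 0,
        # like a torus inner equator
        patch = sweep_sinusoid(90.0, 80.0, 720.0, n_periods=1, n_s=721,
                               n_angles=181)
        # at s = lambda/4 the path bends with k < 0 (x = A sin peaks)
        w = 2 * np.pi / 720.0
        k_path = -80.0 * w**2  # signed curvature at the crest of the sinusoid
        expected_inner = -k_path / (1 - 90.0 * k_path)  # kappa at phi=pi side
        K_inner = patch.K[180, -1]
        assert np.sign(K_inner) == np.sign(expected_inner * (1 / 90.0))

    def test_self_intersection_rejected(self):
        with pytest.raises(ValueError):
            sweep_sinusoid(90.0, 500.0, 300.0)


class TestConvexity:
    def test_concave_sphere_flips_sign(self):
        spec = SubstrateSpec("spheres", n_periods=1)
        conv = make_patch(spec, 64, 17)
        conc = apply_convexity(conv, "concave")
        ok = ~conv.flagged
        assert np.allclose(conc.kappa1[ok], -1 / 180.0)
        assert np.allclose(conc.kappa2[ok], -1 / 180.0)

    def test_K_identical_H_antisymmetric(self):
        conv = make_patch(SubstrateSpec("unduloid"), 128, 17)
        conc = apply_convexity(conv, "concave")
        assert np.array_equal(conv.K, conc.K)
        assert np.array_equal(conv.H, -conc.H)
        # ordering preserved
        assert np.all(conc.kappa1 >= conc.kappa2)

    def test_involution(self):
        patch = make_patch(SubstrateSpec("catenoids"), 64, 17)
        twice = apply_convexity(apply_convexity(patch, "concave"), "concave")
        assert np.array_equal(patch.kappa1, twice.kappa1)
        assert np.array_equal(patch.kappa2, twice.kappa2)
        assert np.array_equal(patch.xyz, twice.xyz)


class TestScaling:
    def test_half_scale_sphere_radius_90(self):
        spec = scale_substrate(SubstrateSpec("spheres"), 0.5)
        assert spec.sphere_radius == 90.0

    def test_double_scale_radius_360_diameter_720(self):
        spec = scale_substrate(SubstrateSpec("spheres", convexity="concave"), 2.0)
        assert spec.sphere_radius == 360.0
        assert 2 * spec.sphere_radius == 720.0

    def test_identity_scale(self):
        spec = SubstrateSpec("spheres")
        assert scale_substrate(spec, 1.0) == spec

    def test_curvature_inverse_scaling(self):
        for f in (0.5, 2.0):
            base = SubstrateSpec("unduloid")
            scaled = scale_substrate(base, f)
            p0 = make_patch(base, 64, 9)
            p1 = make_patch(scaled, 64, 9)
            assert np.allclose(p1.kappa1, p0.kappa1 / f, rtol=1e-9)
            # normalized curvature is scale-free
            assert np.allclose(normalize_curvature(p1.kappa1, scaled),
                               normalize_curvature(p0.kappa1, base), rtol=1e-9)

    def test_rejects_nonpositive_factor(self):
        with pytest.raises(ValueError):
            scale_substrate(SubstrateSpec("spheres"), 0.0)


class TestNormalizeCurvature:
    def test_sphere_normalizes_to_one(self):
        spec = SubstrateSpec("spheres", n_periods=1)
        patch = make_patch(spec, 64, 17)
        ok = ~patch.flagged
        assert np.allclose(normalize_curvature(patch.kappa1, spec)[ok], 1.0)

    def test_flat_is_zero(self):
        assert normalize_curvature(0.0, SubstrateSpec("cylinder")) == 0.0

    def test_constant_H_cylinder_normalizes_to_two(self):
        spec = SubstrateSpec("cylinder")
        patch = make_patch(spec, 64, 17)
        assert np.allclose(normalize_curvature(patch.kappa1, spec), 2.0)
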
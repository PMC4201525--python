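import math

import numpy as np
import pytest
from scipy.integrate import quad

from corneamorph import morphometry as mm
from corneamorph.fitting import FitConfig, fit_surface
from corneamorph.io import PointCloud, polar_to_cartesian
from corneamorph.solid import build_solid
from corneamorph.synthetic import (
    CorneaParams,
    anterior_height,
    generate_cornea,
    posterior_height,
    ground_truth,
)

RTOL = 1e-3  # 0.1 % default-density agreement with closed forms


class TestPillboxClosedForms:
    def test_volume(self, pillbox_solid):
        assert mm.total_volume(pillbox_solid) == pytest.approx(math.pi * 16 * 0.55, rel=RTOL)

    def test_areas(self, pillbox_solid):
        a, p, peri, total = mm.surface_areas(pillbox_solid)
        assert a == pytest.approx(math.pi * 16, rel=RTOL)
        assert p == pytest.approx(math.pi * 16, rel=RTOL)
        assert peri == pytest.approx(2 * math.pi * 4 * 0.55, rel=RTOL)
        assert total == pytest.approx(a + p + peri, rel=1e-12)

    def test_sagittal_section_is_diametral_rectangle(self, pillbox_solid):
        assert mm.sagittal_section_area(pillbox_solid, 0.0) == pytest.approx(4.40, rel=RTOL)
        assert mm.sagittal_section_area(pillbox_solid, 1.1) == pytest.approx(4.40, rel=RTOL)

    def test_center_of_mass_at_mid_height(self, pillbox_solid):
        (x, y, z), dev = mm.center_of_mass(pillbox_solid)
        assert abs(x) < 1e-12 and abs(y) < 1e-12
        assert z == pytest.approx(0.275, rel=1e-12)
        assert dev < 1e-12

    def test_cylinder_volume(self, pillbox_surfaces):
        v = mm.cylinder_intersection_volume(*pillbox_surfaces, (0.0, 0.0), 1.0)
        assert v == pytest.approx(math.pi * 0.55, rel=1e-9)

    def test_constant_thickness_ties_to_axis(self, pillbox_surfaces):
        info = mm.min_thickness(*pillbox_surfaces)
        assert info.minimum == pytest.approx(0.55, abs=1e-12)
        assert info.anterior_deviation == 0.0
        assert info.posterior_deviation == 0.0

    def test_flat_apex_ties_to_axis(self, pillbox_surfaces):
        apex = mm.find_apex(pillbox_surfaces[0])
        assert apex.deviation == 0.0


class TestTwoSphereOracles:
    def test_volume_against_radial_quadrature(self, two_sphere_solid):
        f = lambda r: r * (math.sqrt(7.8**2 - r * r) - math.sqrt(6.5**2 - r * r))
        closed = math.pi * 16 * (0.55 + 6.5 - 7.8) + 2 * math.pi * quad(f, 0, 4)[0]
        assert closed == pytest.approx(33.88, abs=0.05)  # sanity of the oracle itself
        assert mm.total_volume(two_sphere_solid) == pytest.approx(closed, rel=RTOL)

    def test_volume_against_monte_carlo(self, two_sphere_solid, two_sphere_params):
        rng = np.random.default_rng(42)
        n = 1_000_000
        zlo, zhi = 0.0, float(posterior_height(4.0, 0.0, two_sphere_params))
        pts = rng.uniform([-4, -4, zlo], [4, 4, zhi], size=(n, 3))
        r2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
        inside = r2 <= 16.0
        za = anterior_height(pts[inside, 0], pts[inside, 1], two_sphere_params)
        zp = posterior_height(pts[inside, 0], pts[inside, 1], two_sphere_params)
        hit = (pts[inside, 2] >= za) & (pts[inside, 2] <= zp)
        p_hat = hit.sum() / n
        box = 64.0 * (zhi - zlo)
        est = box * p_hat
        sigma = box * math.sqrt(p_hat * (1 - p_hat) / n)
        assert abs(mm.total_volume(two_sphere_solid) - est) < 3 * sigma

    def test_centroid_against_monte_carlo(self, two_sphere_solid, two_sphere_params):
        rng = np.random.default_rng(7)
        n = 1_000_000
        zhi = float(posterior_height(4.0, 0.0, two_sphere_params))
        pts = rng.uniform([-4, -4, 0.0], [4, 4, zhi], size=(n, 3))
        inside = pts[:, 0] ** 2 + pts[:, 1] ** 2 <= 16.0
        p = pts[inside]
        hit = (p[:, 2] >= anterior_height(p[:, 0], p[:, 1], two_sphere_params)) & (
            p[:, 2] <= posterior_height(p[:, 0], p[:, 1], two_sphere_params)
        )
        zs = p[hit, 2]
        (cx, cy, cz), dev = mm.center_of_mass(two_sphere_solid)
        se = zs.std(ddof=1) / math.sqrt(len(zs))
        assert abs(cz - zs.mean()) < 3 * se
        assert abs(cx) < 1e-10 and abs(cy) < 1e-10 and dev < 1e-10
        assert 0.0 < cz < zhi

    def test_anterior_cap_area(self, two_sphere_solid):
        cap = 2 * math.pi * 7.8 * (7.8 - math.sqrt(7.8**2 - 16))
        assert cap == pytest.approx(54.091, abs=5e-3)
        assert two_sphere_solid.label_area("anterior") == pytest.approx(cap, rel=RTOL)

    def test_sections_axisymmetric_and_match_quadrature(self, two_sphere_solid):
        areas = [mm.sagittal_section_area(two_sphere_solid, az) for az in (0.0, 0.8, 2.1)]
        t = lambda r: (0.55 + (6.5 - math.sqrt(6.5**2 - r * r))
                       - (7.8 - math.sqrt(7.8**2 - r * r)))
        oracle = 2 * quad(t, 0, 4)[0]
        for a in areas:
            assert a == pytest.approx(oracle, rel=RTOL)

    def test_min_thickness_at_center(self, two_sphere_surfaces):
        info = mm.min_thickness(*two_sphere_surfaces)
        assert info.minimum == pytest.approx(0.55, abs=1e-4)
        assert info.anterior_deviation < 1e-6
        assert info.posterior_deviation < 1e-6

    def test_normal_mode_close_to_axial_at_center(self, two_sphere_surfaces):
        axial = mm.min_thickness(*two_sphere_surfaces, mode="axial")
        normal = mm.min_thickness(*two_sphere_surfaces, mode="normal")
        # minimum sits on the axis where the normal is vertical
        assert normal.minimum == pytest.approx(axial.minimum, abs=1e-3)

    def test_cylinder_volume_against_quadrature(self, two_sphere_surfaces):
        t = lambda r: r * (0.55 + (6.5 - math.sqrt(6.5**2 - r * r))
                           - (7.8 - math.sqrt(7.8**2 - r * r)))
        oracle = 2 * math.pi * quad(t, 0, 2)[0]
        v = mm.cylinder_intersection_volume(*two_sphere_surfaces, (0.0, 0.0), 2.0)
        assert v == pytest.approx(oracle, rel=RTOL)

    def test_symmetric_apexes_on_axis(self, two_sphere_surfaces):
        for s in two_sphere_surfaces:
            assert mm.find_apex(s).deviation < 1e-6


class TestEctaticEye:
    def test_apex_matches_line_search_oracle(self, kc_params, kc_surfaces):
        # by reflection symmetry the true apex lies on the bump azimuth;
        # a 1D golden-section search on the closed form is the oracle
        from scipy.optimize import minimize_scalar

        ang = math.atan2(kc_params.bump_center[1], kc_params.bump_center[0])
        f = lambda s: float(anterior_height(s * math.cos(ang), s * math.sin(ang), kc_params))
        res = minimize_scalar(f, bounds=(0.0, 4.0), method="bounded",
                              options={"xatol": 1e-12})
        apex = mm.find_apex(kc_surfaces[0])
        assert apex.deviation == pytest.approx(res.x, abs=1e-4)

    def test_apex_deviation_shrinks_with_bump_amplitude(self):
        devs = []
        for amp in (0.12, 0.06, 0.02):
            params = CorneaParams(bump_amplitude=amp, bump_center=(0.9, 1.2),
                                  bump_sigma=0.8, thinning_fraction=0.5)
            ant, _, _ = generate_cornea(params)
            s = fit_surface(polar_to_cartesian(ant), FitConfig(spans_u=32, spans_v=32))
            devs.append(mm.find_apex(s).deviation)
        assert devs[0] > devs[1] > devs[2] > 0

    def test_min_thickness_recovers_ground_truth(self, kc_params, kc_surfaces, kc_eye):
        truth = kc_eye[2]
        info = mm.min_thickness(*kc_surfaces)
        d = math.hypot(info.anterior_point[0] - truth.min_thickness_xy[0],
                       info.anterior_point[1] - truth.min_thickness_xy[1])
        assert d < 0.2  # within one lattice step
        assert info.minimum == pytest.approx(truth.min_thickness_mm, abs=1e-3)

    def test_apex_plane_section_differs_from_orthogonal(self, kc_surfaces):
        solid = build_solid(*kc_surfaces, density=(64, 256))
        apex = mm.find_apex(kc_surfaces[0])
        az = math.atan2(apex.position[1], apex.position[0])
        a_apex = mm.sagittal_section_area(solid, az)
        a_orth = mm.sagittal_section_area(solid, az + math.pi / 2)
        assert abs(a_apex - a_orth) / a_orth > 1e-3

    def test_deviations_invariant_under_quarter_turn(self, kc_eye):
        ant, _, _ = kc_eye
        cloud = polar_to_cartesian(ant)
        cfg = FitConfig(spans_u=24, spans_v=24)
        dev0 = mm.find_apex(fit_surface(cloud, cfg)).deviation
        rot = cloud.points.copy()
        rot[:, 0], rot[:, 1] = -cloud.points[:, 1], cloud.points[:, 0]
        dev90 = mm.find_apex(fit_surface(PointCloud("anterior", rot), cfg)).deviation
        assert dev90 == pytest.approx(dev0, abs=1e-6)


class TestFullRecord:
    def test_record_has_18_variables(self, two_sphere_surfaces):
        rec = mm.compute_morphometry(*two_sphere_surfaces)
        assert len(mm.MorphometryRecord.field_names()) == 18
        assert len(rec.to_dict()) == 18
        assert all(np.isfinite(v) for v in rec.to_dict().values())

    def test_healthy_record_geometry(self, two_sphere_surfaces):
        rec = mm.compute_morphometry(*two_sphere_surfaces)
        assert rec.anterior_apex_deviation < 0.05
        assert rec.posterior_apex_deviation < 0.05
        assert rec.total_area == pytest.approx(
            rec.anterior_area + rec.posterior_area
            + (rec.total_area - rec.anterior_area - rec.posterior_area),
            rel=1e-6,
        )
        cyl = [rec.cyl_volume_r05, rec.cyl_volume_r10, rec.cyl_volume_r15,
               rec.cyl_volume_r20]
        assert cyl == sorted(cyl)  # nested cylinders
        assert cyl[-1] < rec.total_volume
        assert rec.com_z > 0

    def test_kc_posterior_apex_deviation_exceeds_healthy(self, two_sphere_surfaces,
                                                         kc_surfaces):
        healthy = mm.compute_morphometry(*two_sphere_surfaces)
        kc = mm.compute_morphometry(*kc_surfaces)
        assert kc.posterior_apex_deviation > healthy.posterior_apex_deviation
        assert kc.anterior_apex_deviation > healthy.anterior_apex_deviation
        assert kc.cyl_volume_r20 < healthy.cyl_volume_r20

    def test_noise_free_apex_matches_ground_truth_optimizer(self, kc_params,
                                                            kc_surfaces):
        truth = ground_truth(kc_params)
        rec_dev = mm.find_apex(kc_surfaces[0]).deviation
        true_dev = math.hypot(*truth.anterior_apex_xy)
        assert rec_dev == pytest.approx(true_dev, abs=1e-3)
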
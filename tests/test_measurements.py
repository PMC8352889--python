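import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from footmetry.frames import FootFrame
from footmetry.measurements import (
    ArchLandmarks,
    AXIS_CODES,
    CATALOG,
    CODES,
    ProjectionDegenerateError,
    compute_all,
    fao_from_points,
    lateral_inclination,
    mcb_angle,
    spatial_angle,
    spatial_inclination_axis,
    transverse_inclination,
    wrap_angle,
)
from footmetry.mesh_core import FootModel, GroundPlane

FRAME = FootFrame(origin=np.zeros(3), ap=np.array([1.0, 0, 0]),
                  up=np.array([0.0, 0, 1]), ml=np.array([0.0, -1, 0]),
                  foot_length=146.0)


def axis(il=0.0, it=0.0):
    u = np.array([1.0, math.tan(math.radians(it)), -math.tan(math.radians(il))])
    return u / np.linalg.norm(u)


class TestCatalog:
    def test_exactly_32_codes_with_family_counts(self):
        assert len(CODES) == 32
        fams = {}
        for e in CATALOG:
            fams[e.family] = fams.get(e.family, 0) + 1
        assert fams == {"I": 5, "R": 14, "3": 8, "H": 3, "FAO": 2}


class TestInclinations:
    def test_axis_along_ap_is_zero_in_both_planes(self):
        assert lateral_inclination(FRAME.ap, FRAME) == pytest.approx(0.0)
        assert transverse_inclination(FRAME.ap, FRAME) == pytest.approx(0.0)

    def test_plantar_declined_axis_is_positive(self):
        u = math.cos(math.radians(24.33)) * FRAME.ap \
            - math.sin(math.radians(24.33)) * FRAME.up
        assert lateral_inclination(u, FRAME) == pytest.approx(24.33)

    def test_spatial_inclination_examples(self):
        assert spatial_inclination_axis(FRAME.ap, FRAME) == pytest.approx(0.0)
        u = np.array([math.cos(math.radians(21.29)), 0.0,
                      -math.sin(math.radians(21.29))])
        assert spatial_inclination_axis(u, FRAME) == pytest.approx(21.29)
        assert spatial_inclination_axis(FRAME.up, FRAME) == pytest.approx(-90.0)

    def test_lateral_dominates_spatial_inclination(self):
        # |IL| >= |I3|: projecting onto the sagittal plane can only shorten
        # the horizontal component of the axis
        rng = np.random.default_rng(5)
        for _ in range(500):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            if abs(u[0]) < 1e-6:
                continue
            if u[0] < 0:
                u = -u
            assert abs(lateral_inclination(u, FRAME)) + 1e-9 >= \
                abs(spatial_inclination_axis(u, FRAME))

    def test_degenerate_projection_raises(self):
        with pytest.raises(ProjectionDegenerateError):
            lateral_inclination(np.array([0.0, 1.0, 0.0]), FRAME)


class TestRelativeAngles:
    def test_identical_axes_zero_everywhere(self, template_foot):
        foot, _ = template_foot
        ms = compute_all(foot)
        # internal identities of the catalog conventions
        assert ms["RL_TACA"] == pytest.approx(ms["IL_TA"] - ms["IL_CA"], abs=1e-9)
        assert abs(ms["RT_TACA"]) == pytest.approx(
            abs(ms["IT_TA"] - ms["IT_CA"]), abs=1e-9)
        assert ms["RL_TAM1"] == pytest.approx(
            -(ms["RL_CAM1"] - 180.0) - (ms["IL_TA"] - ms["IL_CA"]), abs=1e-9)

    def test_reference_identity_values(self):
        # axes constructed to the reference cohort's printed inclinations
        vals = {}
        ta, ca = axis(il=24.33), axis(il=-8.83)
        vals["RL_TACA"] = lateral_inclination(ta, FRAME) - \
            lateral_inclination(ca, FRAME)
        assert vals["RL_TACA"] == pytest.approx(33.16, abs=1e-9)

    def test_spatial_angle_matches_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            u, v = rng.standard_normal(3), rng.standard_normal(3)
            u, v = u / np.linalg.norm(u), v / np.linalg.norm(v)
            expected = math.degrees(math.atan2(np.linalg.norm(np.cross(u, v)),
                                               float(u @ v)))
            assert spatial_angle(u, v) == pytest.approx(expected, abs=1e-9)

    def test_perpendicular_axes(self):
        assert spatial_angle(FRAME.ap, FRAME.up) == pytest.approx(90.0)


class TestArchAngles:
    def test_hibb_from_reference_inclinations(self):
        il_m1 = lateral_inclination(axis(il=12.30), FRAME)
        il_ca = lateral_inclination(axis(il=-8.83), FRAME)
        assert 180.0 - (il_m1 - il_ca) == pytest.approx(158.87, abs=1e-9)

    def test_hibb_flat_arch_limit(self, template_foot):
        # coaxial CA and M1 axes give the obtuse limit of 180 degrees
        from footmetry.measurements import hibb_angle
        from footmetry.frames import BoneFrame

        def fake(label, u):
            return BoneFrame(label=label, centroid=np.zeros(3), longitudinal=u,
                             mediolateral=np.array([0.0, -1, 0]),
                             dorsoplantar=np.cross(u, [0, -1, 0]),
                             eigenvalues=np.array([3.0, 2.0, 1.0]),
                             elongation=1.5)
        ca, m1 = fake("CA", FRAME.ap), fake("M1", FRAME.ap)
        assert hibb_angle(ca, m1, "L", FRAME) == pytest.approx(180.0)
        assert hibb_angle(ca, m1, "3D", FRAME) == pytest.approx(180.0)

    def test_mcb_collinear_is_180(self):
        lm = ArchLandmarks(ca_plantar=[0, 0, 0], talus_apex=[50, 0, 0],
                           m1_plantar=[140, 0, 0])
        assert mcb_angle(lm, "3D") == pytest.approx(180.0)
        assert mcb_angle(lm, "L", FRAME) == pytest.approx(180.0)

    def test_mcb_planar_construction(self):
        # isoceles 140-degree sagittal triangle
        half = math.radians((180.0 - 140.0) / 2.0)
        h = 50.0 * math.tan(half)
        lm = ArchLandmarks(ca_plantar=[0, 0, 0], talus_apex=[50, 0, h],
                           m1_plantar=[100, 0, 0])
        assert mcb_angle(lm, "L", FRAME) == pytest.approx(140.0, abs=1e-9)

    def test_mcb_3d_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b, c = rng.uniform(-50, 50, (3, 3))
            if min(np.linalg.norm(a - b), np.linalg.norm(b - c),
                   np.linalg.norm(a - c)) < 2.0:
                continue
            lm = ArchLandmarks(ca_plantar=a, talus_apex=b, m1_plantar=c)
            r1, r2 = a - b, c - b
            expected = math.degrees(math.acos(np.clip(
                r1 @ r2 / np.linalg.norm(r1) / np.linalg.norm(r2), -1, 1)))
            assert mcb_angle(lm, "3D") == pytest.approx(expected, abs=1e-9)

    def test_landmarks_too_close_rejected(self):
        with pytest.raises(ValueError):
            ArchLandmarks(ca_plantar=[0, 0, 0], talus_apex=[0.5, 0, 0],
                          m1_plantar=[100, 0, 0])


class TestFao:
    def test_ankle_on_tripod_axis_is_zero(self):
        pct, mm = fao_from_points([0, 0, 0], [140, 20, 5], [140, -20, 5],
                                  [70, 0, 40], FRAME)
        assert mm == pytest.approx(0.0, abs=1e-9)
        assert pct == pytest.approx(0.0, abs=1e-9)

    def test_offset_ratio(self):
        # ankle 19.45 mm medial of the axis, foot length 146 -> 13.32 %
        pct, mm = fao_from_points([0, 0, 0], [146, 20, 5], [146, -20, 5],
                                  [73, 19.45, 40], FRAME)
        assert mm == pytest.approx(19.45, abs=1e-9)
        assert pct == pytest.approx(100 * 19.45 / 146.0, abs=1e-6)
        assert pct == pytest.approx(13.32, abs=0.01)

    def test_mirroring_flips_sign_before_harmonisation(self, template_foot):
        from footmetry.mesh_core import reflect_foot
        from footmetry.frames import build_foot_frame
        from footmetry.measurements import compute_fao

        foot, truth = template_foot
        frame = build_foot_frame(foot)
        pct0, mm0 = compute_fao(foot["TA"], foot["CA"], foot["M1"],
                                foot["M5"], foot.ground, frame)
        left = reflect_foot(foot)
        lframe = build_foot_frame(left)
        pct1, mm1 = compute_fao(left["TA"], left["CA"], left["M1"],
                                left["M5"], left.ground, lframe)
        assert mm1 == pytest.approx(-mm0, abs=1e-6)
        # harmonised pipeline restores the right-convention sign
        assert compute_all(left)["FAO_mm"] == pytest.approx(mm0, abs=1e-6)

    def test_collinear_tripod_rejected(self):
        with pytest.raises(ValueError):
            fao_from_points([0, 0, 0], [0, 0, 0], [0, 0, 0], [10, 0, 0], FRAME)


class TestComputeAll:
    def test_returns_32_finite_values(self, template_foot):
        foot, _ = template_foot
        ms = compute_all(foot, method="semi-auto-like")
        assert set(ms.values) == set(CODES)
        assert ms.finite()

    def test_rigid_motion_invariance(self, template_foot):
        foot, _ = template_foot
        R = Rotation.from_euler("zyx", [31, -14, 52], degrees=True).as_matrix()
        t = np.array([7.0, -13.0, 29.0])
        bones = {c: m.transformed(R, t) for c, m in foot.bones.items()}
        moved = FootModel(foot.foot_id, foot.side, bones,
                          GroundPlane(R @ foot.ground.point + t,
                                      R @ foot.ground.up))
        a, b = compute_all(foot), compute_all(moved)
        for code in CODES:
            assert b[code] == pytest.approx(a[code], abs=1e-6), code

    def test_mirrored_left_equals_right_twin(self, template_foot):
        from footmetry.mesh_core import reflect_foot

        foot, _ = template_foot
        left = reflect_foot(foot)
        a, b = compute_all(foot), compute_all(left)
        for code in CODES:
            assert b[code] == pytest.approx(a[code], abs=1e-6), code

    def test_requested_meary_recovered(self, flat_template):
        from dataclasses import replace
        from footmetry.synthetic_foot import generate_foot

        params = replace(flat_template, talar_declination=24.0,
                         m1_declination=12.0)
        foot, truth = generate_foot(params)
        ms = compute_all(foot)
        assert ms["RL_TAM1"] == pytest.approx(truth.expected["RL_TAM1"], abs=1.0)
        assert truth.expected["RL_TAM1"] == pytest.approx(12.0 - 24.0, abs=1e-9)

    def test_missing_m5_drops_fao_only(self, template_foot):
        foot, _ = template_foot
        bones = {c: m for c, m in foot.bones.items() if c != "M5"}
        partial = FootModel(foot.foot_id, foot.side, bones, foot.ground)
        ms = compute_all(partial)
        assert math.isnan(ms["FAO_%"]) and math.isnan(ms["FAO_mm"])
        assert all(np.isfinite(ms[c]) for c in CODES
                   if c not in ("FAO_%", "FAO_mm"))
        assert any("M5" in w for w in ms.warnings)

    def test_heights_translation_equivariant(self, template_foot):
        foot, _ = template_foot
        lifted = FootModel(
            foot.foot_id, foot.side,
            {c: m.transformed(translation=[0, 0, 3.0])
             for c, m in foot.bones.items()},
            foot.ground)
        a, b = compute_all(foot), compute_all(lifted)
        for code in ("Hg_NA", "Hg_CU", "Hg_CM"):
            assert b[code] == pytest.approx(a[code] + 3.0, abs=1e-9)


class TestWrapProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.floats(min_value=-3600, max_value=3600,
                     allow_nan=False, allow_infinity=False))
    @settings(max_examples=200, derandomize=True)
    def test_wrap_is_periodic_and_in_range(self, x):
        w = wrap_angle(x)
        assert -180.0 < w <= 180.0
        assert abs((w - x) % 360.0) < 1e-6 or abs((w - x) % 360.0 - 360.0) < 1e-6

    @given(st.lists(st.floats(min_value=-1, max_value=1), min_size=6,
                    max_size=6))
    @settings(max_examples=200, derandomize=True)
    def test_spatial_angle_symmetric_and_bounded(self, coords):
        u = np.asarray(coords[:3])
        v = np.asarray(coords[3:])
        if np.linalg.norm(u) < 1e-3 or np.linalg.norm(v) < 1e-3:
            return
        u, v = u / np.linalg.norm(u), v / np.linalg.norm(v)
        a = spatial_angle(u, v)
        assert 0.0 <= a <= 180.0
        assert spatial_angle(v, u) == pytest.approx(a, abs=1e-9)
        assert spatial_angle(u, -v) == pytest.approx(180.0 - a, abs=1e-9)


class TestWrap:
    @pytest.mark.parametrize("x,expected", [
        (0.0, 0.0), (180.0, 180.0), (-180.0, 180.0), (190.0, -170.0),
        (-190.0, 170.0), (360.0, 0.0), (540.0, 180.0),
    ])
    def test_wrap_examples(self, x, expected):
        assert wrap_angle(x) == pytest.approx(expected)

    def test_wrap_range_and_periodicity(self):
        rng = np.random.default_rng(9)
        for x in rng.uniform(-1000, 1000, 200):
            w = wrap_angle(x)
            assert -180.0 < w <= 180.0
            assert wrap_angle(x + 360.0) == pytest.approx(w, abs=1e-9)
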
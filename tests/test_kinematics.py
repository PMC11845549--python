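import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vrgaze.errors import ConfigError
from vrgaze.io import GazeSample
from vrgaze.kinematics import (
    VelocitySeries,
    angular_velocity,
    angular_velocity_step,
    condition_velocity,
    eye_in_head,
    head_angular_velocity,
    head_rotation_matrix,
    hit_shift,
    in_plane_component,
    saccade_amplitude,
)

from conftest import make_recording


def sample(t, origin, hit, eye_dir=None):
    origin = np.asarray(origin, dtype=float)
    hit = np.asarray(hit, dtype=float)
    if eye_dir is None:
        eye_dir = (hit - origin) / np.linalg.norm(hit - origin)
    return GazeSample(
        t=t,
        eye_origin=origin,
        eye_dir=np.asarray(eye_dir, dtype=float),
        head_pos=origin,
        head_dir=np.asarray(eye_dir, dtype=float),
        hit_point=hit,
    )


class TestHitShift:
    def test_identical_points_zero(self):
        np.testing.assert_array_equal(hit_shift([1, 2, 3], [1, 2, 3]), np.zeros(3))

    def test_unit_displacement(self):
        np.testing.assert_array_equal(hit_shift([0, 0, 1], [1, 0, 1]), [1, 0, 0])

    @given(st.lists(st.floats(-10, 10), min_size=6, max_size=6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetry(self, vals):
        a, b = np.array(vals[:3]), np.array(vals[3:])
        np.testing.assert_allclose(hit_shift(a, b), -hit_shift(b, a))


class TestInPlaneComponent:
    @pytest.mark.parametrize(
        "v,eye,expected",
        [
            ((1, 0, 0), (0, 0, 1), (1, 0, 0)),
            ((0, 0, 2), (0, 0, 1), (0, 0, 0)),
            ((3, 4, 5), (0, 0, 1), (3, 4, 0)),
        ],
    )
    def test_rejection(self, v, eye, expected):
        out = in_plane_component(np.array(v, float), np.array(eye, float))
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_result_orthogonal_to_eye(self, rng):
        for _ in range(20):
            v = rng.normal(size=3)
            e = rng.normal(size=3)
            e /= np.linalg.norm(e)
            assert abs(np.dot(in_plane_component(v, e), e)) < 1e-9

    def test_non_unit_eye_vec_rejected(self):
        with pytest.raises(ValueError):
            in_plane_component(np.ones(3), np.array([0.0, 0.0, 2.0]))


class TestAngularVelocityStep:
    def test_translation_with_fixed_hit_point_is_zero(self):
        hit = np.array([0.0, 0.0, 5.0])
        s1 = sample(0.0, [0, 0, 0], hit)
        s2 = sample(1 / 90, [0.1, 0, 0], hit)
        assert angular_velocity_step(s1, s2) == 0.0

    def test_one_degree_shift_at_90hz(self):
        # hit moves by tan(1 deg) orthogonally at unit distance over one frame
        s1 = sample(0.0, [0, 0, 0], [0, 0, 1])
        s2 = sample(1 / 90, [0, 0, 0], [np.tan(np.radians(1.0)), 0, 1])
        assert angular_velocity_step(s1, s2) == pytest.approx(90.0, rel=1e-9)

    def test_matches_intervector_angle_for_static_observer(self, rng):
        # displacements <= 10 deg at matched distances: within 5% of the
        # direct arccos-dot angle between the two eye vectors
        for _ in range(500):
            d1 = rng.normal(size=3)
            d1 /= np.linalg.norm(d1)
            ang = np.radians(rng.uniform(0.1, 10.0))
            ax = np.cross(d1, rng.normal(size=3))
            ax /= np.linalg.norm(ax)
            d2 = d1 * np.cos(ang) + np.cross(ax, d1) * np.sin(ang)
            dist = rng.uniform(1.0, 30.0)
            s1 = sample(0.0, np.zeros(3), d1 * dist)
            s2 = sample(1.0, np.zeros(3), d2 * dist)
            w = angular_velocity_step(s1, s2)
            direct = np.degrees(ang)
            assert abs(w - direct) / direct < 0.05

    def test_zero_distance_to_hit_is_error(self):
        s1 = sample(0.0, [0, 0, 1], [0, 0, 1], eye_dir=[0, 0, 1])
        s2 = sample(1 / 90, [0, 0, 0], [0, 0, 2])
        with pytest.raises(ValueError):
            angular_velocity_step(s1, s2)


class TestAngularVelocitySeries:
    def test_pure_translation_all_zero(self, rng):
        n = 50
        t = np.arange(n) / 90.0
        origins = np.cumsum(rng.normal(0, 0.02, (n, 3)), axis=0)
        hits = np.tile([0.0, 0.0, 10.0], (n, 1))
        rec = make_recording(t, hit_points=hits, eye_origin=origins)
        vs = angular_velocity(rec)
        assert vs.valid.all()
        np.testing.assert_allclose(vs.w, 0.0, atol=1e-9)

    def test_translation_with_frozen_direction_detected(self):
        # observer slides sideways with a frozen allocentric direction: the
        # hit point sweeps along the wall and the velocity must be positive
        n = 10
        t = np.arange(n) / 90.0
        x = 0.05 * np.arange(n)
        origins = np.column_stack([x, np.zeros(n), np.zeros(n)])
        hits = np.column_stack([x, np.zeros(n), np.full(n, 10.0)])
        eye_dir = np.tile([0.0, 0.0, 1.0], (n, 1))
        rec = make_recording(t, hit_points=hits, eye_origin=origins, eye_dir=eye_dir)
        vs = angular_velocity(rec)
        assert np.all(vs.w[vs.valid] > 0)

    def test_absent_hit_marks_interval_invalid(self):
        hits = np.tile([0.0, 0.0, 5.0], (4, 1))
        hits[2] = np.nan
        rec = make_recording(np.arange(4) / 90.0, hit_points=hits)
        vs = angular_velocity(rec)
        assert not vs.valid[1] and not vs.valid[2]
        assert vs.valid[0]


class TestConditionVelocity:
    def _vs(self, w):
        w = np.asarray(w, dtype=float)
        return VelocitySeries(
            t=np.arange(w.size) / 90.0, w=w, valid=np.ones(w.size, bool)
        )

    def test_clip_at_1000(self):
        out = condition_velocity(self._vs([10.0] * 6 + [1500.0] + [10.0] * 6))
        assert out.w.max() <= 1000.0

    def test_constant_series_unchanged(self):
        out = condition_velocity(self._vs(np.full(20, 55.0)))
        np.testing.assert_allclose(out.w, 55.0)

    def test_quadratic_reproduced_exactly_by_order2(self):
        x = np.arange(20, dtype=float)
        w = 0.5 * x**2 + 2 * x + 3
        out = condition_velocity(self._vs(w), clip=1e6)
        np.testing.assert_allclose(out.w, w, rtol=1e-9)

    def test_invalid_intervals_break_filter_windows(self):
        w = np.full(20, 10.0)
        w[10] = np.nan
        valid = np.ones(20, bool)
        valid[10] = False
        vs = VelocitySeries(t=np.arange(20) / 90.0, w=w, valid=valid)
        out = condition_velocity(vs)
        assert np.isnan(out.w[10])
        np.testing.assert_allclose(out.w[:10], 10.0)

    def test_even_window_is_config_error(self):
        with pytest.raises(ConfigError):
            condition_velocity(self._vs(np.zeros(10)), sg_window=4)


class TestHeadVelocity:
    def test_constant_direction_zero(self):
        rec = make_recording(np.arange(5) / 90.0)
        vs = head_angular_velocity(rec)
        np.testing.assert_allclose(vs.w, 0.0, atol=1e-9)

    def test_nine_degrees_over_100ms(self):
        t = [0.0, 0.1]
        rec = make_recording(t)
        rec.head_dir[0] = [0, 0, 1]
        ang = np.radians(9.0)
        rec.head_dir[1] = [np.sin(ang), 0, np.cos(ang)]
        vs = head_angular_velocity(rec)
        assert vs.w[0] == pytest.approx(90.0, rel=1e-9)

    def test_symmetric_under_reversal(self, rng):
        rec = make_recording(np.arange(3) / 90.0)
        d = rng.normal(size=(3, 3))
        rec.head_dir = d / np.linalg.norm(d, axis=1, keepdims=True)
        fwd = head_angular_velocity(rec)
        rec2 = make_recording(np.arange(3) / 90.0)
        rec2.head_dir = rec.head_dir[::-1].copy()
        rev = head_angular_velocity(rec2)
        np.testing.assert_allclose(fwd.w, rev.w[::-1], rtol=1e-9)


class TestEyeInHead:
    def test_identity_rotation(self):
        v = np.array([0.6, 0.0, 0.8])
        np.testing.assert_allclose(eye_in_head(v, np.eye(3)), v)

    def test_yawed_head_sees_world_x_as_forward(self):
        R = head_rotation_matrix([1.0, 0.0, 0.0])  # head facing world +x
        out = eye_in_head(np.array([1.0, 0.0, 0.0]), R)
        np.testing.assert_allclose(out, [0.0, 0.0, 1.0], atol=1e-12)

    def test_norm_preserved(self, rng):
        for _ in range(10):
            fwd = rng.normal(size=3)
            R = head_rotation_matrix(fwd)
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            assert np.linalg.norm(eye_in_head(v, R)) == pytest.approx(1.0)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValueError):
            eye_in_head(np.array([0.0, 0, 1]), np.eye(3) * 2)


class TestSaccadeAmplitude:
    def test_identical_centroids_zero(self):
        c = np.array([0.0, 0.0, 5.0])
        assert saccade_amplitude(c, c, np.zeros(3), [0, 0, 1]) == 0.0

    def test_five_degree_displacement(self):
        d = 8.0
        c1 = np.array([0.0, 0.0, d])
        c2 = np.array([d * np.tan(np.radians(5.0)), 0.0, d])
        amp = saccade_amplitude(c1, c2, np.zeros(3), [0, 0, 1])
        assert amp == pytest.approx(5.0, rel=1e-9)

    def test_independent_of_duration(self):
        # amplitude is a pure geometry quantity; no time enters
        c1 = np.array([0.0, 0.0, 5.0])
        c2 = np.array([1.0, 0.0, 5.0])
        a = saccade_amplitude(c1, c2, np.zeros(3), [0, 0, 1])
        assert a == pytest.approx(np.degrees(np.arctan2(1.0, 5.0)))
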
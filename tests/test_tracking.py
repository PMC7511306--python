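"""Tracker unit behaviour: orientation selection, stepping, termination,
whole-mask runs and streamline file round trips."""

import math

import numpy as np
import pytest

import tractquant as tq
from tractquant.tracking import TerminationReason

from conftest import in_bundle_mask


def vec_at(theta_deg, phi_deg=0.0):
    """Unit vector at polar angle theta from +z (azimuth phi)."""
    t, p = math.radians(theta_deg), math.radians(phi_deg)
    return np.array([math.sin(t) * math.cos(p), math.sin(t) * math.sin(p),
                     math.cos(t)])


def uniform_field(shape, direction, qa_value, voxel_size=1.0):
    """Single-orientation field with constant direction and QA."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    dirs = np.tile(direction, (*shape, 1, 1))
    qa = np.full((*shape, 1), qa_value)
    affine = np.diag([voxel_size] * 3 + [1.0])
    return tq.OrientationField(dirs, qa, affine)


def oracle_select(incoming, candidates, qa, params):
    """Brute-force selection over candidates and both polarities."""
    best = None
    best_angle = params.angle_threshold_deg
    best_qa = -1.0
    for d, q in zip(candidates, qa):
        if q < params.qa_threshold:
            continue
        for s in (1.0, -1.0):
            v = s * np.asarray(d, float)
            ang = math.degrees(math.acos(np.clip(v @ incoming, -1, 1)))
            if ang < best_angle or (ang == best_angle and q > best_qa):
                if ang < params.angle_threshold_deg:
                    best, best_angle, best_qa = v, ang, q
    return best


class TestSelectOrientation:
    def test_identity(self, params):
        out = tq.select_orientation([0, 0, 1], [[0, 0, 1]], [0.5], params)
        assert np.allclose(out, [0, 0, 1])

    def test_beyond_turning_angle_rejected(self, params):
        # 80 degrees >= the 75 degree threshold
        out = tq.select_orientation([0, 0, 1], [vec_at(80)], [0.5], params)
        assert out is None

    def test_most_congruent_candidate_wins(self, params):
        cands = [vec_at(40), vec_at(10)]
        out = tq.select_orientation([0, 0, 1], cands, [0.5, 0.5], params)
        assert np.allclose(out, vec_at(10))

    def test_polarity_resolved_against_incoming(self, params):
        out = tq.select_orientation([0, 0, 1], [[0, 0, -1]], [0.5], params)
        assert np.allclose(out, [0, 0, 1])

    def test_subthreshold_qa_never_selectable(self, params):
        out = tq.select_orientation([0, 0, 1], [[0, 0, 1]], [0.05], params)
        assert out is None

    def test_empty_candidates(self, params):
        assert tq.select_orientation([0, 0, 1], np.empty((0, 3)), [], params) is None

    def test_equal_angle_tie_breaks_to_higher_qa(self, params):
        cands = [vec_at(20, 0), vec_at(20, 180)]
        out = tq.select_orientation([0, 0, 1], cands, [0.3, 0.7], params)
        assert np.allclose(out, vec_at(20, 180))

    def test_matches_brute_force_oracle(self, params):
        rng = np.random.default_rng(123)
        for _ in range(300):
            k = rng.integers(1, 4)
            cands = rng.standard_normal((k, 3))
            cands /= np.linalg.norm(cands, axis=1, keepdims=True)
            qa = rng.uniform(0.0, 1.0, k)
            incoming = rng.standard_normal(3)
            incoming /= np.linalg.norm(incoming)
            got = tq.select_orientation(incoming, cands, qa, params)
            expected = oracle_select(incoming, cands, qa, params)
            if expected is None:
                assert got is None
            else:
                assert got is not None
                assert np.allclose(got, expected, atol=1e-12)


class TestPropagateStep:
    def test_straight_step_advances_08mm(self, params):
        field = uniform_field((10, 10, 10), [1, 0, 0], 0.5)
        pos, d = tq.propagate_step([4.0, 4.0, 4.0], [1, 0, 0], field, params)
        assert np.allclose(d, [1, 0, 0])
        assert np.allclose(pos, [4.8, 4.0, 4.0])

    def test_fifty_fifty_smoothing(self):
        # incoming x, selected y: smoothed direction bisects at 45 degrees
        # (threshold widened past 90 degrees so the orthogonal candidate is
        # selectable and the smoothing rule is isolated)
        params = tq.TrackingParams(angle_threshold_deg=100.0)
        field = uniform_field((10, 10, 10), [0, 1, 0], 0.5)
        pos, d = tq.propagate_step([4.0, 4.0, 4.0], [1, 0, 0], field, params)
        expected = np.array([1.0, 1.0, 0.0]) / math.sqrt(2)
        assert np.allclose(d, expected)
        assert np.allclose(pos, np.array([4.0, 4.0, 4.0]) + 0.8 * expected)

    def test_qa_below_threshold_terminates(self, params):
        field = uniform_field((10, 10, 10), [0, 0, 1], 0.05)
        out = tq.propagate_step([4.0, 4.0, 4.0], [0, 0, 1], field, params)
        assert out is TerminationReason.QA_BELOW_THRESHOLD

    def test_position_outside_grid_terminates(self, params):
        field = uniform_field((10, 10, 10), [0, 0, 1], 0.5)
        out = tq.propagate_step([40.0, 4.0, 4.0], [0, 0, 1], field, params)
        assert out is TerminationReason.LEFT_FIELD

    def test_incongruent_field_terminates(self, params):
        field = uniform_field((10, 10, 10), [0, 0, 1], 0.5)
        out = tq.propagate_step([4.0, 4.0, 4.0], vec_at(89.0, 0.0), field, params)
        assert out is TerminationReason.NO_CONGRUENT_ORIENTATION


class TestTrackFromSeed:
    def test_spans_bundle_and_stops_at_qa_drop(self, straight_phantom, params):
        field, _ = straight_phantom
        s = tq.track_from_seed(np.array([10.0, 10.0, 30.0]), field, params)
        assert s is not None
        assert s.termination_reasons == (
            TerminationReason.QA_BELOW_THRESHOLD,
            TerminationReason.QA_BELOW_THRESHOLD,
        )
        # bundle extends 48 mm plus spherical ends; allow 2 steps slack
        extent = 48.0 + 2 * 3.0
        assert abs(s.length_mm - extent) <= 2 * params.step_size_mm + 1.0

    def test_seed_in_zero_qa_voxel_returns_none(self, straight_phantom, params):
        field, _ = straight_phantom
        assert tq.track_from_seed(np.array([3.0, 3.0, 3.0]), field, params) is None

    def test_short_bundle_fails_min_length(self, params):
        spec = tq.BundleSpec(
            "short", ((8.0, 8.0, 6.0), (8.0, 8.0, 18.0)), 1.5, 0.6, 0.0, "A", "B"
        )
        field, _ = tq.make_straight_bundle((16, 16, 24), 1.0, spec)
        # total reachable extent ~ 12 + 2*1.5 + 2 steps < 20 mm minimum
        assert tq.track_from_seed(np.array([8.0, 8.0, 12.0]), field, params) is None

    def test_seed_outside_grid_rejected(self, straight_phantom, params):
        field, _ = straight_phantom
        with pytest.raises(ValueError):
            tq.track_from_seed(np.array([100.0, 0.0, 0.0]), field, params)

    def test_max_length_truncation(self, straight_phantom):
        field, _ = straight_phantom
        p = tq.TrackingParams(min_length_mm=20.0, max_length_mm=30.0)
        s = tq.track_from_seed(np.array([10.0, 10.0, 30.0]), field, p)
        assert s is not None
        assert s.length_mm <= 30.0 + 1e-9
        assert TerminationReason.MAX_LENGTH in s.termination_reasons


class TestWholeBrainTrack:
    def test_zero_seeds_empty_set(self, straight_phantom, params):
        field, _ = straight_phantom
        out = tq.whole_brain_track(
            field, in_bundle_mask(field, params), 0, params, rng_seed=0
        )
        assert len(out) == 0

    def test_empty_mask_rejected(self, straight_phantom, params):
        field, _ = straight_phantom
        with pytest.raises(ValueError):
            tq.whole_brain_track(
                field, np.zeros(field.shape, bool), 10, params, rng_seed=0
            )

    def test_seed_budget_enforced(self, straight_phantom, params):
        field, _ = straight_phantom
        with pytest.raises(ValueError):
            tq.whole_brain_track(
                field,
                in_bundle_mask(field, params),
                params.max_seeds + 1,
                params,
                rng_seed=0,
            )

    def test_identical_seeds_give_identical_output(self, straight_phantom, params):
        field, _ = straight_phantom
        mask = in_bundle_mask(field, params)
        a = tq.whole_brain_track(field, mask, 100, params, rng_seed=9)
        b = tq.whole_brain_track(field, mask, 100, params, rng_seed=9)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.points, sb.points)

    def test_in_bundle_seeds_connect_end_caps(self, straight_phantom, straight_tracts):
        _, atlas = straight_phantom
        selected = tq.two_roi_select(straight_tracts, atlas, {1}, {2})
        assert len(straight_tracts) >= 950
        assert len(selected) / len(straight_tracts) >= 0.95


class TestStreamlineInvariants:
    def test_segment_lengths_equal_step(self, straight_tracts, params):
        for s in straight_tracts:
            seg = np.linalg.norm(np.diff(s.points, axis=0), axis=1)
            assert np.abs(seg - params.step_size_mm).max() < 1e-6

    def test_turning_angles_below_threshold(self, straight_tracts,
                                            crossing_tracts_from_a, params):
        cos_thr = math.cos(math.radians(params.angle_threshold_deg))
        for ss in (straight_tracts, crossing_tracts_from_a):
            for s in ss:
                d = np.diff(s.points, axis=0)
                d /= np.linalg.norm(d, axis=1, keepdims=True)
                cosang = np.einsum("ij,ij->i", d[:-1], d[1:])
                assert cosang.min() > cos_thr - 1e-9

    def test_lengths_within_window(self, straight_tracts, params):
        for s in straight_tracts:
            assert params.min_length_mm - 1e-9 <= s.length_mm
            assert s.length_mm <= params.max_length_mm + 1e-9

    def test_termination_reasons_match_field_state(self, straight_tracts,
                                                   straight_phantom, params):
        field, _ = straight_phantom
        for s in straight_tracts:
            ends = [
                (s.points[0], s.points[1], s.termination_reasons[0]),
                (s.points[-1], s.points[-2], s.termination_reasons[1]),
            ]
            for terminal, before, reason in ends:
                if reason is TerminationReason.MAX_LENGTH:
                    continue
                outward = terminal - before
                outward /= np.linalg.norm(outward)
                res = tq.propagate_step(terminal, outward, field, params)
                assert res is reason

    def test_straight_field_has_no_lateral_deviation(self, straight_tracts):
        for s in straight_tracts:
            lateral = s.points[:, :2] - s.seed_point[:2]
            assert np.abs(lateral).max() < 1e-6


class TestCrossingSelection:
    def test_tracks_from_a_stay_in_a(self, crossing_phantom, crossing_tracts_from_a):
        _, atlas = crossing_phantom
        ss = crossing_tracts_from_a
        a_pair = tq.two_roi_select(ss, atlas, {1}, {2})
        b_ends = tq.two_roi_select(ss, atlas, {3}, {4})
        assert len(ss) > 0
        assert len(b_ends) / len(ss) < 0.05
        assert len(a_pair) / len(ss) >= 0.95


class TestStreamlineIO:
    def test_trk_round_trip(self, tmp_path, straight_tracts):
        path = tmp_path / "tracts.trk"
        straight_tracts.save_trk(path)
        back = tq.StreamlineSet.load_trk(path)
        assert len(back) == len(straight_tracts)
        for a, b in zip(straight_tracts, back):
            assert np.abs(a.points - b.points).max() < 1e-5
        assert np.allclose(back.affine, straight_tracts.affine, atol=1e-5)

    def test_tck_round_trip(self, tmp_path, straight_tracts):
        path = tmp_path / "tracts.tck"
        straight_tracts.save_tck(path)
        back = tq.StreamlineSet.load_tck(path)
        for a, b in zip(straight_tracts, back):
            assert np.abs(a.points - b.points).max() < 1e-5


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"step_size_mm": 0.0},
            {"min_length_mm": 900.0},
            {"angle_threshold_deg": 0.0},
            {"smoothing_weight": 1.5},
            {"qa_threshold": -0.1},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            tq.TrackingParams(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        p = tq.TrackingParams(step_size_mm=0.5, qa_threshold=0.1)
        p.to_yaml(tmp_path / "p.yaml")
        assert tq.TrackingParams.from_yaml(tmp_path / "p.yaml") == p
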
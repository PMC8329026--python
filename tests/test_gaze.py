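"""Gaze-target assignment and attention measures vs brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadload import gaze
from dyadload.core import (
    PERSON_TARGET,
    GazeStream,
    PersonRegion,
    SceneObject,
    UtteranceSegment,
    ValidationError,
)


def make_stream(directions, origin=(0.0, 0.0, 0.0), valid=None, t0=0.0):
    d = np.asarray(directions, dtype=float)
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    n = len(d)
    return GazeStream(
        t=t0 + np.arange(n) / 50.0,
        origin=np.tile(origin, (n, 1)),
        direction=d,
        valid=np.ones(n, dtype=bool) if valid is None else valid)


def obj(oid, centre, radius=0.08):
    return SceneObject(object_id=oid, kind="referent-candidate",
                       centre=np.asarray(centre, float), radius=radius)


def segment(start, end, referent="obj01"):
    return UtteranceSegment(instruction_id="i", fragment_ordinal=1,
                            start=start, end=end, referent_id=referent)


FAR_PERSON = PersonRegion("builder", np.array([0.0, 50.0, 0.0]))


class TestAngularDistance:
    def test_dead_ahead_is_zero(self):
        assert gaze.angular_distance([0, 0, 0], [0, 0, 1], [0, 0, 2]) \
            == pytest.approx(0.0)

    def test_orthogonal_is_ninety(self):
        assert gaze.angular_distance([0, 0, 0], [0, 0, 1], [1, 0, 0]) \
            == pytest.approx(90.0)

    def test_random_geometry_matches_acos_formula(self, rng):
        for _ in range(200):
            o = rng.normal(size=3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            p = rng.normal(size=3) * 3
            if np.allclose(p, o):
                continue
            v = p - o
            oracle = math.degrees(math.acos(
                max(-1.0, min(1.0, float(np.dot(d, v) / np.linalg.norm(v))))))
            assert gaze.angular_distance(o, d, p) == pytest.approx(oracle,
                                                                   abs=1e-9)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(-5, 5), min_size=6, max_size=6))
    def test_angle_always_in_valid_range(self, coords):
        d = np.array(coords[:3])
        p = np.array(coords[3:])
        if np.linalg.norm(d) < 1e-6 or np.linalg.norm(p) < 1e-6:
            return
        ang = gaze.angular_distance(np.zeros(3), d / np.linalg.norm(d), p)
        assert 0.0 <= ang <= 180.0

    def test_single_sample_wrapper_agrees_with_stream_path(self, rng):
        scene = [obj(f"o{j}", rng.normal(size=3) * 2) for j in range(3)]
        for _ in range(20):
            d = rng.normal(size=3)
            target, err = gaze.assign_frame_target(np.zeros(3), d, scene,
                                                   FAR_PERSON, 20.0)
            frames = gaze.assign_targets(make_stream([d]), scene, FAR_PERSON,
                                         20.0)
            assert target == frames.target[0]

    def test_target_at_origin_is_an_error(self):
        with pytest.raises(ValidationError):
            gaze.angular_distance([1, 1, 1], [0, 0, 1], [1, 1, 1])


class TestAssignTargets:
    def test_single_object_dead_ahead(self):
        scene = [obj("obj01", [0, 0, 2])]
        frames = gaze.assign_targets(make_stream([[0, 0, 1]]), scene,
                                     FAR_PERSON, threshold_deg=10.0)
        assert frames.target[0] == "obj01"
        assert frames.angular_error_deg[0] == pytest.approx(0.0)

    def test_smaller_angle_wins(self):
        # two candidates at ~3 and ~7 degrees off the ray
        scene = [obj("near", [math.tan(math.radians(3)) * 2, 0, 2]),
                 obj("far", [math.tan(math.radians(7)) * 2, 0, 2])]
        frames = gaze.assign_targets(make_stream([[0, 0, 1]]), scene,
                                     FAR_PERSON, threshold_deg=10.0)
        assert frames.target[0] == "near"

    def test_outside_threshold_is_none(self):
        scene = [obj("obj01", [2, 0, 2])]   # 45 degrees off
        frames = gaze.assign_targets(make_stream([[0, 0, 1]]), scene,
                                     FAR_PERSON, threshold_deg=10.0)
        assert frames.target[0] is None
        assert np.isnan(frames.angular_error_deg[0])

    def test_invalid_frames_get_none(self):
        scene = [obj("obj01", [0, 0, 2])]
        frames = gaze.assign_targets(
            make_stream([[0, 0, 1]], valid=np.array([False])), scene,
            FAR_PERSON)
        assert frames.target[0] is None

    @staticmethod
    def oracle_assign(origin, direction, candidates, threshold):
        best = None
        for cid, pos in candidates:
            v = np.asarray(pos) - origin
            dist = np.linalg.norm(v)
            ang = math.degrees(math.acos(max(-1, min(1, float(
                np.dot(direction, v) / (np.linalg.norm(direction) * dist))))))
            key = (ang, dist, cid)
            if best is None or key < best:
                best = key
        if best is None or best[0] > threshold:
            return None
        return best[2]

    def test_random_scenes_match_bruteforce_argmin(self, rng):
        for _ in range(200):
            k = int(rng.integers(1, 6))
            candidates = [(f"o{j}", rng.normal(size=3) * 2) for j in range(k)]
            person_pos = rng.normal(size=3) * 2
            scene = [obj(cid, pos) for cid, pos in candidates]
            region = PersonRegion("builder", person_pos)
            d = rng.normal(size=3)
            frames = gaze.assign_targets(make_stream([d]), scene, region,
                                         threshold_deg=25.0)
            oracle = self.oracle_assign(
                np.zeros(3), d / np.linalg.norm(d),
                candidates + [(PERSON_TARGET, person_pos)], 25.0)
            assert frames.target[0] == oracle

    def test_shrinking_threshold_never_adds_targets(self, rng):
        scene = [obj(f"o{j}", rng.normal(size=3) * 2) for j in range(4)]
        stream = make_stream(rng.normal(size=(300, 3)))
        prev = None
        for thr in (30.0, 15.0, 8.0, 3.0):
            frames = gaze.assign_targets(stream, scene, FAR_PERSON, thr)
            assigned = np.array([x is not None for x in frames.target])
            if prev is not None:
                assert not np.any(assigned & ~prev)
            prev = assigned


class TestSegmentMeasures:
    @staticmethod
    def frames_from_labels(labels, t0=0.0):
        n = len(labels)
        return gaze.TargetFrames(
            t=t0 + np.arange(n) / 50.0, role="builder",
            target=np.array(labels, dtype=object),
            angular_error_deg=np.zeros(n))

    def test_majority_by_count(self):
        labels = ["A"] * 60 + ["B"] * 40
        assert gaze.majority_target(self.frames_from_labels(labels),
                                    segment(0.0, 2.0)) == "A"

    def test_majority_all_none(self):
        labels = [None] * 50
        assert gaze.majority_target(self.frames_from_labels(labels),
                                    segment(0.0, 1.0)) is None

    def test_majority_random_matches_tally(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 120))
            labels = rng.choice(["A", "B", "C", None], n).tolist()
            res = gaze.majority_target(self.frames_from_labels(labels),
                                       segment(0.0, n / 50.0))
            counts = {}
            for lab in labels:
                if lab is not None:
                    counts[lab] = counts.get(lab, 0) + 1
            oracle = (min(counts, key=lambda k: (-counts[k], k))
                      if counts else None)
            assert res == oracle

    def test_first_gaze_at_onset_is_zero(self):
        fr = self.frames_from_labels(["obj01"] * 10)
        assert gaze.first_gaze_latency(fr, segment(0.0, 0.2), "obj01") == 0.0

    def test_first_gaze_25_frames_is_half_second(self):
        fr = self.frames_from_labels([None] * 25 + ["obj01"] * 25)
        assert gaze.first_gaze_latency(fr, segment(0.0, 1.0), "obj01") \
            == pytest.approx(0.5)

    def test_first_gaze_random_matches_linear_scan(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 150))
            labels = rng.choice(["obj01", "B", None], n).tolist()
            lo = float(rng.integers(0, 3)) / 50.0
            hi = n / 50.0
            res = gaze.first_gaze_latency(self.frames_from_labels(labels),
                                          segment(lo, hi), "obj01")
            oracle = None
            for i, lab in enumerate(labels):
                t = i / 50.0
                if lo <= t < hi and lab == "obj01":
                    oracle = t - lo
                    break
            assert res == oracle

    def test_proportions_all_on_referent(self):
        fr = self.frames_from_labels(["obj01"] * 40)
        assert gaze.proportional_gaze(fr, segment(0.0, 0.8), "obj01") \
            == (1.0, 0.0, 0.0)

    def test_proportions_half_distractor_half_invalid(self):
        fr = self.frames_from_labels(["B"] * 20 + [None] * 20)
        assert gaze.proportional_gaze(fr, segment(0.0, 0.8), "obj01") \
            == (0.0, 0.5, 0.0)

    def test_proportions_conserve_and_match_tally(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 150))
            labels = rng.choice(["obj01", "B", PERSON_TARGET, None], n).tolist()
            fr = self.frames_from_labels(labels)
            gt, go, gp = gaze.proportional_gaze(fr, segment(0.0, n / 50.0),
                                                "obj01")
            assert gt == labels.count("obj01") / n
            assert go == labels.count("B") / n
            assert gp == labels.count(PERSON_TARGET) / n
            assert gt + go + gp <= 1.0 + 1e-12

    def test_empty_segment_is_an_error(self):
        fr = self.frames_from_labels(["obj01"] * 10)
        with pytest.raises(ValidationError):
            gaze.proportional_gaze(fr, segment(0.001, 0.002), "obj01")

    def test_joint_attention_full_and_disjoint(self):
        a = self.frames_from_labels(["obj01"] * 50)
        b = self.frames_from_labels(["obj01"] * 50)
        seg = segment(0.0, 1.0)
        assert gaze.joint_attention(a, b, seg, "obj01") == 1.0
        c = self.frames_from_labels(["obj01"] * 25 + ["B"] * 25)
        d = self.frames_from_labels(["B"] * 25 + ["obj01"] * 25)
        assert gaze.joint_attention(c, d, seg, "obj01") == 0.0

    def test_mutual_gaze_full_and_one_sided(self):
        a = self.frames_from_labels([PERSON_TARGET] * 50)
        b = self.frames_from_labels([PERSON_TARGET] * 50)
        seg = segment(0.0, 1.0)
        assert gaze.mutual_gaze(a, b, seg) == 1.0
        c = self.frames_from_labels(["B"] * 50)
        assert gaze.mutual_gaze(a, c, seg) == 0.0

    def test_joint_and_mutual_match_framewise_and_and_are_symmetric(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 120))
            la = rng.choice(["obj01", "B", PERSON_TARGET, None], n)
            lb = rng.choice(["obj01", "B", PERSON_TARGET, None], n)
            a = self.frames_from_labels(la.tolist())
            b = self.frames_from_labels(lb.tolist())
            seg = segment(0.0, n / 50.0)
            ja = gaze.joint_attention(a, b, seg, "obj01")
            mg = gaze.mutual_gaze(a, b, seg)
            assert ja == np.sum((la == "obj01") & (lb == "obj01")) / n
            assert mg == np.sum((la == PERSON_TARGET) & (lb == PERSON_TARGET)) / n
            assert ja == gaze.joint_attention(b, a, seg, "obj01")
            assert mg == gaze.mutual_gaze(b, a, seg)
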
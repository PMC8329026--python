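"""3D gaze-target assignment and per-segment visual-attention measures.

Each valid gaze ray is compared against every candidate target — the scene
objects and the conversational partner's head region — by visual angle; the
candidate with the smallest angle wins if it falls inside a capture cone
(default 10 degrees).  Ties break by 3D distance, then lexicographic id.
From per-frame targets the six segment-level measures follow: first-gaze
latency to the referent, proportional gaze to referent / distractors /
partner, and the two dyadic measures, joint attention (both on the referent
simultaneously) and mutual gaze (both on each other simultaneously).

Proportions are of *segment time*: invalid frames and frames on no candidate
stay in the denominator, so gaze_to_target + gaze_to_other + gaze_to_person
plus the none/elsewhere share always sums to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import (
    FRAME_RATE,
    PERSON_TARGET,
    GazeStream,
    PersonRegion,
    SceneObject,
    UtteranceSegment,
    ValidationError,
)

#: Default angular capture cone, degrees.
DEFAULT_THRESHOLD_DEG = 10.0


@dataclass
class TargetFrames:
    """Per-frame gaze-target assignments for one role."""

    t: np.ndarray                 # (n,) seconds
    role: str
    target: np.ndarray            # (n,) object: object_id | "person" | None
    angular_error_deg: np.ndarray  # (n,) angle to chosen target; NaN if none


def angular_distance(origin: np.ndarray, direction: np.ndarray,
                     point: np.ndarray) -> float:
    """Visual angle, in degrees, between a gaze ray and the direction from
    its origin to ``point``.  Always in [0, 180]."""
    v = np.asarray(point, dtype=float) - np.asarray(origin, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValidationError("target point coincides with gaze origin")
    d = np.asarray(direction, dtype=float)
    cos = float(np.dot(d, v) / (np.linalg.norm(d) * norm))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def assign_targets(
    stream: GazeStream,
    scene: Sequence[SceneObject],
    partner_region: PersonRegion,
    threshold_deg: float = DEFAULT_THRESHOLD_DEG,
    role: str = "",
) -> TargetFrames:
    """Assign a target label to every frame of a gaze stream.

    Candidates are all scene objects plus the partner's head (label
    ``"person"``).  Per frame, the candidate with the smallest visual angle
    wins if within ``threshold_deg``; ties break by smallest 3D Euclidean
    distance from the gaze origin, then by lexicographic id.  Invalid frames
    get target None.
    """
    n = len(stream)
    target = np.full(n, None, dtype=object)
    best_ang = np.full(n, np.inf)
    best_dist = np.full(n, np.inf)
    if n == 0:
        return TargetFrames(t=stream.t.copy(), role=role, target=target,
                            angular_error_deg=np.full(n, np.nan))

    time_varying = partner_region.head_centre.ndim == 2
    candidates: list[tuple[str, np.ndarray]] = [
        (obj.object_id, np.broadcast_to(obj.centre, (n, 3))) for obj in scene
    ]
    person_pos = (partner_region.head_centre if time_varying
                  else np.broadcast_to(partner_region.head_centre, (n, 3)))
    candidates.append((PERSON_TARGET, person_pos))
    candidates.sort(key=lambda c: c[0])   # lexicographic order => first set wins ties

    valid = stream.valid
    for cid, pos in candidates:
        v = pos - stream.origin
        dist = np.linalg.norm(v, axis=1)
        if np.any(dist[valid] == 0):
            raise ValidationError(f"candidate {cid} coincides with a gaze origin")
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.einsum("ij,ij->i", stream.direction, v) / (
                np.linalg.norm(stream.direction, axis=1) * dist
            )
        ang = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
        better = valid & (
            (ang < best_ang) | ((ang == best_ang) & (dist < best_dist))
        )
        target[better] = cid
        best_ang[better] = ang[better]
        best_dist[better] = dist[better]

    outside = best_ang > threshold_deg
    target[outside] = None
    best_ang[outside | ~valid] = np.nan
    target[~valid] = None
    return TargetFrames(t=stream.t.copy(), role=role, target=target,
                        angular_error_deg=best_ang)


def assign_frame_target(
    origin: np.ndarray,
    direction: np.ndarray,
    scene: Sequence[SceneObject],
    partner_region: PersonRegion,
    threshold_deg: float = DEFAULT_THRESHOLD_DEG,
) -> tuple[Optional[str], float]:
    """Single-sample convenience wrapper around :func:`assign_targets`.

    Returns ``(target, angular_error_deg)``; target is None when no
    candidate falls inside the capture cone.
    """
    stream = GazeStream(t=np.array([0.0]),
                        origin=np.asarray(origin, float).reshape(1, 3),
                        direction=np.asarray(direction, float).reshape(1, 3),
                        valid=np.array([True]))
    frames = assign_targets(stream, scene, partner_region, threshold_deg)
    return frames.target[0], float(frames.angular_error_deg[0])


def _segment_mask(t: np.ndarray, segment: UtteranceSegment) -> np.ndarray:
    return (t >= segment.start) & (t < segment.end)


def majority_target(frames: TargetFrames, segment: UtteranceSegment) -> Optional[str]:
    """The segment's dominant visual target by majority vote.

    None-frames do not vote; an all-none segment has no majority target.
    Vote ties break lexicographically.
    """
    labels = frames.target[_segment_mask(frames.t, segment)]
    counts: dict[str, int] = {}
    for lab in labels:
        if lab is not None:
            counts[lab] = counts.get(lab, 0) + 1
    if not counts:
        return None
    return min(counts, key=lambda k: (-counts[k], k))


def first_gaze_latency(
    frames: TargetFrames,
    segment: UtteranceSegment,
    referent_id: str,
    horizon_end: Optional[float] = None,
) -> Optional[float]:
    """Seconds from utterance onset until the referent is first gazed at.

    The search horizon runs from the segment start to ``horizon_end``
    (defaults to the segment end; callers typically extend it to the next
    segment onset so late identifications are still captured).  None when
    the referent is never reached within the horizon.
    """
    end = segment.end if horizon_end is None else horizon_end
    mask = (frames.t >= segment.start) & (frames.t < end)
    idx = np.flatnonzero(mask & (frames.target == referent_id))
    if idx.size == 0:
        return None
    return float(frames.t[idx[0]] - segment.start)


def proportional_gaze(
    frames: TargetFrames,
    segment: UtteranceSegment,
    referent_id: str,
) -> tuple[float, float, float]:
    """(gaze_to_target, gaze_to_other, gaze_to_person) over the segment.

    Denominator is the full in-segment frame count, including invalid and
    unassigned frames, so the three shares plus the remainder sum to 1.
    """
    mask = _segment_mask(frames.t, segment)
    n = int(mask.sum())
    if n == 0:
        raise ValidationError(
            f"segment [{segment.start}, {segment.end}] covers no gaze frames"
        )
    labels = frames.target[mask]
    on_ref = int(np.sum(labels == referent_id))
    on_person = int(np.sum(labels == PERSON_TARGET))
    on_other = int(np.sum([(l is not None) for l in labels])) - on_ref - on_person
    return on_ref / n, on_other / n, on_person / n


def _aligned_pair(a: TargetFrames, b: TargetFrames,
                  segment: UtteranceSegment) -> tuple[np.ndarray, np.ndarray, int]:
    """In-segment target labels of both roles on the shared frame grid."""
    ma, mb = _segment_mask(a.t, segment), _segment_mask(b.t, segment)
    if ma.sum() == 0 or mb.sum() == 0:
        raise ValidationError("a stream does not cover the segment")
    fa = np.round(a.t[ma] * FRAME_RATE).astype(int)
    fb = np.round(b.t[mb] * FRAME_RATE).astype(int)
    common, ia, ib = np.intersect1d(fa, fb, return_indices=True)
    n = max(int(ma.sum()), int(mb.sum()))
    return a.target[ma][ia], b.target[mb][ib], n


def joint_attention(
    instructor_frames: TargetFrames,
    builder_frames: TargetFrames,
    segment: UtteranceSegment,
    referent_id: str,
) -> float:
    """Fraction of segment frames where both partners gaze at the referent
    simultaneously.  Symmetric in its two frame arguments."""
    la, lb, n = _aligned_pair(instructor_frames, builder_frames, segment)
    both = np.sum((la == referent_id) & (lb == referent_id))
    return float(both / n)


def mutual_gaze(
    instructor_frames: TargetFrames,
    builder_frames: TargetFrames,
    segment: UtteranceSegment,
) -> float:
    """Fraction of segment frames where the partners look at each other
    simultaneously.  Symmetric in its two frame arguments."""
    la, lb, n = _aligned_pair(instructor_frames, builder_frames, segment)
    both = np.sum((la == PERSON_TARGET) & (lb == PERSON_TARGET))
    return float(both / n)
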
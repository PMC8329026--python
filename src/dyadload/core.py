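"""Domain types and coordinate conventions.

All sensor streams share one clock, in seconds, sampled nominally at 50 Hz;
the frame index of a timestamp is ``round(t * 50)``.  Positions are metres in
a single right-handed scene frame shared by both participants.  Pupil
diameters are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Nominal sampling rate of gaze and pupil streams (frames per second).
FRAME_RATE = 50.0

#: The two conversational roles in a dyad.
ROLES = ("instructor", "builder")

#: Target label used for gaze at the conversational partner.
PERSON_TARGET = "person"

INSTRUCTION_TYPES = ("fragmented", "non_fragmented")


def frame_index(t: np.ndarray | float, rate: float = FRAME_RATE) -> np.ndarray | int:
    """Frame index of a timestamp on the shared 50 Hz clock."""
    idx = np.round(np.asarray(t) * rate).astype(int)
    return int(idx) if np.isscalar(t) else idx


class ValidationError(ValueError):
    """Raised when data violates a structural invariant."""


# ---------------------------------------------------------------------------
# Sensor streams
# ---------------------------------------------------------------------------

@dataclass
class GazeStream:
    """Per-role gaze rays: origin and unit direction per frame.

    ``direction`` rows are unit vectors wherever ``valid`` is True; invalid
    frames carry placeholder values and must be ignored downstream.
    """

    t: np.ndarray                 # (n,) seconds, non-decreasing
    origin: np.ndarray            # (n, 3) metres
    direction: np.ndarray         # (n, 3) unit vectors where valid
    valid: np.ndarray             # (n,) bool

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float).reshape(-1, 3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(-1, 3)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t.size
        if not (len(self.origin) == len(self.direction) == len(self.valid) == n):
            raise ValidationError("gaze stream arrays have mismatched lengths")
        if n > 1 and np.any(np.diff(self.t) < 0):
            raise ValidationError("gaze timestamps are not non-decreasing")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class PupilStream:
    """Raw binocular pupil diameters; NaN marks a missing sample."""

    t: np.ndarray                 # (n,) seconds
    left_mm: np.ndarray           # (n,) mm, NaN if missing
    right_mm: np.ndarray          # (n,) mm, NaN if missing

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.left_mm = np.asarray(self.left_mm, dtype=float)
        self.right_mm = np.asarray(self.right_mm, dtype=float)
        if not (self.t.size == self.left_mm.size == self.right_mm.size):
            raise ValidationError("pupil stream arrays have mismatched lengths")
        for arr, name in ((self.left_mm, "left"), (self.right_mm, "right")):
            present = arr[~np.isnan(arr)]
            if present.size and (np.any(~np.isfinite(present)) or np.any(present <= 0)):
                raise ValidationError(f"{name} pupil diameters must be finite and positive")

    def __len__(self) -> int:
        return self.t.size


# ---------------------------------------------------------------------------
# Scene
# ---------------------------------------------------------------------------

@dataclass
class SceneObject:
    """A physical object that can capture gaze."""

    object_id: str
    kind: str                     # "referent-candidate" | "distractor"
    centre: np.ndarray            # (3,) metres
    radius: float                 # gaze-capture extent, metres

    def __post_init__(self) -> None:
        self.centre = np.asarray(self.centre, dtype=float).reshape(3)
        if self.radius <= 0:
            raise ValidationError(f"object {self.object_id}: radius must be > 0")


@dataclass
class PersonRegion:
    """Spherical capture region around a participant's head."""

    role: str
    head_centre: np.ndarray       # (3,) static, or (n, 3) per frame
    radius: float = 0.15

    def __post_init__(self) -> None:
        self.head_centre = np.asarray(self.head_centre, dtype=float)
        if self.head_centre.ndim == 1:
            self.head_centre = self.head_centre.reshape(3)
        if self.radius <= 0:
            raise ValidationError("person region radius must be > 0")

    def centre_at(self, i: int) -> np.ndarray:
        if self.head_centre.ndim == 1:
            return self.head_centre
        return self.head_centre[i]


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass
class UtteranceSegment:
    """One time-aligned instructor utterance fragment (Utt-n)."""

    instruction_id: str
    fragment_ordinal: int         # 1-based position within the instruction
    start: float                  # seconds
    end: float                    # seconds
    referent_id: str
    speaker_role: str = "instructor"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"segment {self.instruction_id}/{self.fragment_ordinal}: "
                f"end ({self.end}) must exceed start ({self.start})"
            )
        if self.fragment_ordinal < 1:
            raise ValidationError("fragment ordinal must be >= 1")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class InstructionUnit:
    """All utterances referring to one referent object within one task step.

    Non-fragmented iff produced as a single utterance.
    """

    instruction_id: str
    referent_id: str
    segments: list[UtteranceSegment]
    type: str = field(init=False)
    n_fragments: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError(f"instruction {self.instruction_id} has no segments")
        self.n_fragments = len(self.segments)
        self.type = "non_fragmented" if self.n_fragments == 1 else "fragmented"

    @property
    def start(self) -> float:
        return self.segments[0].start

    @property
    def end(self) -> float:
        return self.segments[-1].end


def validate_tier(units: Sequence[InstructionUnit]) -> None:
    """Check the tier invariants: contiguous ordinals, consistent referents,
    and no overlap between same-speaker segments."""
    all_segs: list[UtteranceSegment] = []
    for unit in units:
        ordinals = [s.fragment_ordinal for s in unit.segments]
        if ordinals != list(range(1, len(ordinals) + 1)):
            raise ValidationError(
                f"instruction {unit.instruction_id}: ordinals {ordinals} are not "
                f"contiguous from 1"
            )
        starts = [s.start for s in unit.segments]
        if starts != sorted(starts):
            raise ValidationError(
                f"instruction {unit.instruction_id}: segment ordinals do not follow time"
            )
        for seg in unit.segments:
            if seg.referent_id != unit.referent_id:
                raise ValidationError(
                    f"instruction {unit.instruction_id}: segment referent "
                    f"{seg.referent_id!r} != unit referent {unit.referent_id!r}"
                )
        all_segs.extend(unit.segments)
    by_speaker: dict[str, list[UtteranceSegment]] = {}
    for seg in all_segs:
        by_speaker.setdefault(seg.speaker_role, []).append(seg)
    for speaker, segs in by_speaker.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping {speaker} segments: "
                    f"{a.instruction_id}/{a.fragment_ordinal} "
                    f"[{a.start}, {a.end}] and "
                    f"{b.instruction_id}/{b.fragment_ordinal} [{b.start}, {b.end}]"
                )


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

@dataclass
class DyadRecording:
    """Synchronized two-participant sensor data for one interaction."""

    interaction_id: str
    gaze: dict[str, GazeStream]          # role -> stream
    pupil: dict[str, PupilStream]        # role -> stream
    scene: list[SceneObject]
    persons: dict[str, PersonRegion]     # role -> region
    units: list[InstructionUnit]
    baseline_window: dict[str, tuple[float, float]]   # role -> (start, end) s

    def __post_init__(self) -> None:
        ids = [o.object_id for o in self.scene]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate object ids in scene")
        known = set(ids)
        for unit in self.units:
            if unit.referent_id not in known:
                raise ValidationError(
                    f"instruction {unit.instruction_id}: referent "
                    f"{unit.referent_id!r} not in scene"
                )
        validate_tier(self.units)

    def object_by_id(self, object_id: str) -> SceneObject:
        for obj in self.scene:
            if obj.object_id == object_id:
                return obj
        raise KeyError(object_id)

    def partner_of(self, role: str) -> str:
        return "builder" if role == "instructor" else "instructor"


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

#: Column order of the metric table; a stable contract for CSV output.
METRIC_COLUMNS = [
    "interaction_id", "instruction_id", "fragment_ordinal", "instruction_type",
    "role", "first_gaze_to_target", "gaze_to_target", "gaze_to_other",
    "gaze_to_person", "joint_attention", "mutual_gaze",
    "mean_dilation", "peak_dilation", "slope", "duration",
]

#: The per-segment behavioural measures (response candidates for models).
MEASURE_NAMES = METRIC_COLUMNS[5:]


@dataclass
class MetricRow:
    """One (utterance segment x participant role) row of behavioural measures.

    ``first_gaze_to_target`` and the pupil metrics may be ``None``
    (undefined), e.g. when the referent was never gazed at or when too few
    usable pupil frames fall inside the segment.
    """

    interaction_id: str
    instruction_id: str
    fragment_ordinal: int
    instruction_type: str
    role: str
    first_gaze_to_target: Optional[float]
    gaze_to_target: float
    gaze_to_other: float
    gaze_to_person: float
    joint_attention: float
    mutual_gaze: float
    mean_dilation: Optional[float]
    peak_dilation: Optional[float]
    slope: Optional[float]
    duration: float

    def __post_init__(self) -> None:
        for name in ("gaze_to_target", "gaze_to_other", "gaze_to_person",
                     "joint_attention", "mutual_gaze"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        total = self.gaze_to_target + self.gaze_to_other + self.gaze_to_person
        if total > 1.0 + 1e-9:
            raise ValidationError(f"gaze proportions sum to {total} > 1")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")


@dataclass
class StatsResult:
    """A fitted-model comparison for one behavioural measure.

    ``terms`` maps fixed-effect term name to ``(chi_square, df, p_value)``
    from a likelihood-ratio test between nested ML fits.
    """

    response: str
    terms: dict[str, tuple[float, int, float]]
    cell_summary: "object"        # pandas.DataFrame: per-cell mean/sd/n
    model: str                    # human-readable model descriptor
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, (chi2, df, p) in self.terms.items():
            if chi2 < 0:
                raise ValidationError(f"term {name}: chi-square {chi2} < 0")
            if not (0.0 < p <= 1.0):
                raise ValidationError(f"term {name}: p-value {p} outside (0, 1]")


@dataclass
class CorrelationResult:
    """One Spearman screen entry: a measure against fragment count."""

    measure: str
    rho: float
    p_adjusted: float
    reported: bool
    n: int = 0
    note: str = ""

    def __post_init__(self) -> None:
        if not np.isnan(self.rho) and not (-1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12):
            raise ValidationError(f"rho {self.rho} outside [-1, 1]")
        if self.reported and abs(self.rho) <= 0.15:
            raise ValidationError("reported flag requires |rho| > 0.15")
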
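"""Synthetic dyad generator with frame-level ground truth.

Emits complete :class:`~dyadload.core.DyadRecording` objects — 50 Hz gaze
rays, binocular pupil traces, a scene, and a fragment-coded annotation tier
— whose generating parameters are known, so every pipeline stage and the
statistics can be tested end to end without recorded data.

What is emulated
----------------
* an instructor/builder dyad seated across a table of uniquely identifiable
  assembly pieces, working through a fixed sequence of instruction steps;
* instructions delivered either in one utterance or as 1-4 fragments, with
  per-ordinal duration distributions;
* gaze that scans distractors, glances at the partner, and locks onto the
  referent after a condition-dependent latency;
* a binocular pupil trace: participant baseline + a condition-dependent
  dilation during instructions + slow AR(1) noise + blink artefacts
  (a dropout run flanked by amplitude spikes, the signature of video-based
  eye-trackers) + monocular dropouts;
* per-frame gaze validity at a configured rate.

Ground truth is recorded from the *emitted* frames (after validity dropout),
so it is consistent with the recording frame by frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import (
    FRAME_RATE,
    PERSON_TARGET,
    ROLES,
    DyadRecording,
    GazeStream,
    InstructionUnit,
    PersonRegion,
    PupilStream,
    SceneObject,
    UtteranceSegment,
    ValidationError,
)
from . import coding


def _default_latency_means() -> dict:
    # seconds to first referent gaze; non-fragmented value plus per-ordinal
    # values for fragments Utt-1..Utt-4
    return {
        "builder": {"non_fragmented": 1.79, "fragmented": (1.79, 0.57, 0.45, 0.44)},
        "instructor": {"non_fragmented": 1.22, "fragmented": (1.40, 0.49, 0.46, 0.37)},
    }


def _default_latency_sds() -> dict:
    return {
        "builder": {"non_fragmented": 1.19, "fragmented": (1.45, 0.60, 0.48, 0.43)},
        "instructor": {"non_fragmented": 1.20, "fragmented": (1.64, 0.65, 0.65, 0.44)},
    }


@dataclass
class SimConfig:
    """Generative parameters; the defaults are the benchmark profile.

    All durations and latencies are seconds, diameters and dilations mm.
    ``*_dilation_nonfrag_mm`` is a role's dilation level during
    non-fragmented instructions; ``*_dilation_delta_mm`` is the fragmented
    minus non-fragmented difference.
    """

    seed: int = 0
    n_interactions: int = 28
    instructions_per_interaction: int = 9
    fragment_count_probs: tuple = (0.463, 0.325, 0.122, 0.090)

    # scene template
    n_referent_objects: int = 8
    n_distractor_objects: int = 2
    object_radius: float = 0.08
    person_radius: float = 0.15
    person_distance_m: float = 0.9      # head offset from table centre, y
    person_height_m: float = 0.55       # head height above the table plane

    # utterance timing
    duration_nonfrag_mean_s: float = 4.24
    duration_nonfrag_sd_s: float = 2.49
    duration_frag_mean_s: tuple = (3.75, 1.79, 1.49, 1.49)
    duration_frag_sd_s: tuple = (1.80, 0.89, 0.73, 0.78)
    min_duration_s: float = 0.5
    inter_fragment_gap_mean_s: float = 0.8
    inter_fragment_gap_sd_s: float = 0.25
    min_inter_fragment_gap_s: float = 0.3
    inter_instruction_gap_mean_s: float = 2.5
    inter_instruction_gap_sd_s: float = 0.6
    min_inter_instruction_gap_s: float = 1.0
    baseline_duration_s: float = 5.0
    post_baseline_gap_s: float = 1.0

    # pupil signal
    pupil_baseline_mean_mm: float = 3.5
    pupil_baseline_between_sd_mm: float = 0.3
    ar1_coef: float = 0.95
    ar1_innovation_sd_mm: float = 0.031
    unit_effect_sd_mm: float = 0.28
    effect_lead_s: float = 0.3
    effect_lag_s: float = 0.3
    instructor_dilation_nonfrag_mm: float = 0.00
    instructor_dilation_delta_mm: float = 0.14
    builder_dilation_nonfrag_mm: float = 0.12
    builder_dilation_delta_mm: float = -0.01
    blink_rate_per_min: float = 15.0
    blink_duration_frames: int = 8
    blink_spike_mm: float = -2.2
    monocular_dropout_rate: float = 0.03
    inter_eye_noise_sd_mm: float = 0.01

    # gaze behaviour
    gaze_validity_rate: float = 0.775
    gaze_jitter_deg: float = 2.0
    latency_mean_s: dict = field(default_factory=_default_latency_means)
    latency_sd_s: dict = field(default_factory=_default_latency_sds)
    p_person_glance: float = 0.12       # per dwell switch while searching
    p_post_glance: float = 0.15         # one partner glance after lock-on
    glance_frames: int = 15
    dwell_min_frames: int = 10
    dwell_max_frames: int = 25

    def __post_init__(self) -> None:
        if abs(sum(self.fragment_count_probs) - 1.0) > 1e-9:
            raise ValidationError("fragment_count_probs must sum to 1")
        if any(p < 0 for p in self.fragment_count_probs):
            raise ValidationError("fragment_count_probs must be non-negative")
        if not (0 < self.gaze_validity_rate <= 1):
            raise ValidationError("gaze_validity_rate must be in (0, 1]")
        if self.duration_nonfrag_mean_s <= 0 or any(
                d <= 0 for d in self.duration_frag_mean_s):
            raise ValidationError("durations must be positive")


@dataclass
class SegmentTruth:
    """Scripted per-(segment x role) facts, as emitted."""

    interaction_id: str
    instruction_id: str
    fragment_ordinal: int
    instruction_type: str
    role: str
    scripted_latency: Optional[float]    # s from onset to first valid referent frame
    horizon_end: float                   # s; latency search horizon


@dataclass
class GroundTruth:
    """Frame-level and design-level truth for one generated corpus."""

    config: SimConfig
    segments: list[SegmentTruth]
    target_labels: dict            # (interaction_id, role) -> object ndarray
    gaze_valid: dict               # (interaction_id, role) -> bool ndarray
    unit_effects: dict             # (interaction_id, instruction_id, role) -> mm
    emitted_validity_rate: dict    # role -> float
    slice_counts: dict             # ordinal -> count over fragmented units


def benchmark_profile() -> SimConfig:
    """The packaged study-conditions profile.

    Cell means of durations, first-gaze latencies, and dilation levels are
    set so that simulated metric tables resemble the reference corpus
    conditions; 28 interactions by default.
    """
    return SimConfig()


# ---------------------------------------------------------------------------
# scene
# ---------------------------------------------------------------------------

def _build_scene(cfg: SimConfig) -> tuple[list[SceneObject], dict[str, PersonRegion]]:
    n = cfg.n_referent_objects + cfg.n_distractor_objects
    xs = np.linspace(-0.45, 0.45, int(np.ceil(n / 2)))
    ys = (-0.18, 0.18)
    objects = []
    for i in range(n):
        centre = np.array([xs[i // 2], ys[i % 2], 0.0])
        kind = "referent-candidate" if i < cfg.n_referent_objects else "distractor"
        objects.append(SceneObject(object_id=f"obj{i + 1:02d}", kind=kind,
                                   centre=centre, radius=cfg.object_radius))
    d, h = cfg.person_distance_m, cfg.person_height_m
    persons = {
        "instructor": PersonRegion("instructor", np.array([0.0, -d, h]),
                                   cfg.person_radius),
        "builder": PersonRegion("builder", np.array([0.0, d, h]),
                                cfg.person_radius),
    }
    for obj in objects:
        for region in persons.values():
            gap = np.linalg.norm(obj.centre - region.head_centre)
            if gap <= obj.radius + region.radius:
                raise ValidationError(
                    f"infeasible geometry: {obj.object_id} overlaps the "
                    f"{region.role} person region")
    return objects, persons


# ---------------------------------------------------------------------------
# per-interaction generation
# ---------------------------------------------------------------------------

def _draw_duration(rng, mean, sd, floor) -> float:
    return max(floor, float(rng.normal(mean, sd)))


def _script_timeline(cfg: SimConfig, rng, interaction_id: str,
                     referent_ids: list[str]) -> list[InstructionUnit]:
    cursor = cfg.baseline_duration_s + cfg.post_baseline_gap_s
    units: list[InstructionUnit] = []
    for step in range(cfg.instructions_per_interaction):
        n_frag = 1 + int(rng.choice(4, p=cfg.fragment_count_probs))
        referent = referent_ids[step % len(referent_ids)]
        iid = f"{interaction_id}-i{step + 1:02d}"
        segs = []
        for k in range(n_frag):
            if n_frag == 1:
                dur = _draw_duration(rng, cfg.duration_nonfrag_mean_s,
                                     cfg.duration_nonfrag_sd_s, cfg.min_duration_s)
            else:
                dur = _draw_duration(rng, cfg.duration_frag_mean_s[k],
                                     cfg.duration_frag_sd_s[k], cfg.min_duration_s)
            # snap to the frame grid so durations are exact at 50 Hz
            start = np.round(cursor * FRAME_RATE) / FRAME_RATE
            end = np.round((cursor + dur) * FRAME_RATE) / FRAME_RATE
            segs.append(UtteranceSegment(
                instruction_id=iid, fragment_ordinal=k + 1,
                start=float(start), end=float(end), referent_id=referent))
            cursor = end + max(cfg.min_inter_fragment_gap_s,
                               rng.normal(cfg.inter_fragment_gap_mean_s,
                                          cfg.inter_fragment_gap_sd_s))
        units.append(coding.code_instruction(segs))
        cursor = units[-1].end + max(cfg.min_inter_instruction_gap_s,
                                     rng.normal(cfg.inter_instruction_gap_mean_s,
                                                cfg.inter_instruction_gap_sd_s))
    return units


def _script_gaze_labels(cfg: SimConfig, rng, n_frames: int,
                        units: list[InstructionUnit], role: str,
                        object_ids: list[str]) -> np.ndarray:
    """Per-frame scripted target labels (object id or "person")."""
    labels = np.empty(n_frames, dtype=object)

    def fill_scan(lo: int, hi: int, exclude: Optional[str]) -> None:
        """Distractor scanning with occasional partner glances."""
        pool = [o for o in object_ids if o != exclude]
        i = lo
        while i < hi:
            if rng.random() < cfg.p_person_glance:
                n = cfg.glance_frames
                labels[i:min(hi, i + n)] = PERSON_TARGET
            else:
                n = int(rng.integers(cfg.dwell_min_frames, cfg.dwell_max_frames + 1))
                labels[i:min(hi, i + n)] = pool[int(rng.integers(len(pool)))]
            i += n

    fill_scan(0, n_frames, None)

    means, sds = cfg.latency_mean_s[role], cfg.latency_sd_s[role]
    for u_idx, unit in enumerate(units):
        next_start = (units[u_idx + 1].start if u_idx + 1 < len(units)
                      else unit.end + 2.0)
        for seg in unit.segments:
            if unit.type == "non_fragmented":
                mu, sd = means["non_fragmented"], sds["non_fragmented"]
            else:
                k = min(seg.fragment_ordinal, 4) - 1
                mu, sd = means["fragmented"][k], sds["fragmented"][k]
            latency = max(0.0, float(rng.normal(mu, sd)))
            horizon_end = (next_start if seg is unit.segments[-1]
                           else unit.segments[seg.fragment_ordinal].start)
            lo = int(np.round(seg.start * FRAME_RATE))
            lock = int(np.round((seg.start + latency) * FRAME_RATE))
            hi = min(int(np.round(horizon_end * FRAME_RATE)), n_frames)
            lo, lock = min(lo, n_frames), min(lock, n_frames)
            # search phase: anything but the referent
            fill_scan(lo, lock, exclude=seg.referent_id)
            # lock-on phase
            labels[lock:hi] = seg.referent_id
            if hi - lock > 3 * cfg.glance_frames and rng.random() < cfg.p_post_glance:
                at = int(rng.integers(lock + cfg.glance_frames,
                                      hi - cfg.glance_frames))
                labels[at:at + cfg.glance_frames] = PERSON_TARGET
    return labels


def _emit_gaze(cfg: SimConfig, rng, t: np.ndarray, labels: np.ndarray,
               origin: np.ndarray, positions: dict[str, np.ndarray]
               ) -> tuple[GazeStream, np.ndarray]:
    n = t.size
    valid = rng.random(n) < cfg.gaze_validity_rate
    targets = np.stack([positions[lab] for lab in labels])
    v = targets - origin
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    if cfg.gaze_jitter_deg > 0:
        ang = np.abs(rng.normal(0.0, np.radians(cfg.gaze_jitter_deg), n))
        # random unit vectors orthogonal to v
        r = rng.normal(size=(n, 3))
        r -= v * np.einsum("ij,ij->i", r, v)[:, None]
        r /= np.linalg.norm(r, axis=1, keepdims=True)
        v = np.cos(ang)[:, None] * v + np.sin(ang)[:, None] * r
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    direction = np.where(valid[:, None], v, np.array([0.0, 0.0, 1.0]))
    origins = np.broadcast_to(origin, (n, 3)).copy()
    return GazeStream(t=t, origin=origins, direction=direction, valid=valid), valid


def _emit_pupil(cfg: SimConfig, rng, t: np.ndarray, effect: np.ndarray,
                baseline_mm: float) -> PupilStream:
    from scipy.signal import lfilter

    n = t.size
    if cfg.ar1_innovation_sd_mm > 0:
        stationary_sd = cfg.ar1_innovation_sd_mm / np.sqrt(
            max(1e-12, 1 - cfg.ar1_coef ** 2))
        innov = rng.normal(0.0, cfg.ar1_innovation_sd_mm, n)
        innov[0] = rng.normal(0.0, stationary_sd)   # stationary start
        noise = lfilter([1.0], [1.0, -cfg.ar1_coef], innov)
    else:
        noise = np.zeros(n)
    signal = baseline_mm + effect + noise

    left = signal + (rng.normal(0.0, cfg.inter_eye_noise_sd_mm, n)
                     if cfg.inter_eye_noise_sd_mm > 0 else 0.0)
    right = signal + (rng.normal(0.0, cfg.inter_eye_noise_sd_mm, n)
                      if cfg.inter_eye_noise_sd_mm > 0 else 0.0)

    # blinks: both-eye dropout flanked by spikes
    n_blinks = rng.poisson(cfg.blink_rate_per_min * (t[-1] - t[0]) / 60.0) if n > 1 else 0
    for _ in range(n_blinks):
        s = int(rng.integers(2, max(3, n - cfg.blink_duration_frames - 2)))
        e = s + cfg.blink_duration_frames
        for arr in (left, right):
            arr[max(0, s - 2):s] += cfg.blink_spike_mm
            arr[e:min(n, e + 2)] += cfg.blink_spike_mm
            arr[s:e] = np.nan
    # monocular dropouts
    if cfg.monocular_dropout_rate > 0:
        left[rng.random(n) < cfg.monocular_dropout_rate] = np.nan
        right[rng.random(n) < cfg.monocular_dropout_rate] = np.nan
    np.clip(left, 0.1, None, out=left)
    np.clip(right, 0.1, None, out=right)
    return PupilStream(t=t, left_mm=left, right_mm=right)


def generate(config: SimConfig,
             seed: Optional[int] = None) -> tuple[list[DyadRecording], GroundTruth]:
    """Generate a corpus of dyad recordings plus its ground truth.

    Deterministic given (config, seed); ``seed`` overrides ``config.seed``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    scene, persons = _build_scene(config)
    referent_ids = [o.object_id for o in scene if o.kind == "referent-candidate"]
    all_ids = [o.object_id for o in scene]

    role_levels = {
        "instructor": {"non_fragmented": config.instructor_dilation_nonfrag_mm,
                       "fragmented": (config.instructor_dilation_nonfrag_mm
                                      + config.instructor_dilation_delta_mm)},
        "builder": {"non_fragmented": config.builder_dilation_nonfrag_mm,
                    "fragmented": (config.builder_dilation_nonfrag_mm
                                   + config.builder_dilation_delta_mm)},
    }

    recordings: list[DyadRecording] = []
    seg_truths: list[SegmentTruth] = []
    target_labels: dict = {}
    gaze_valid: dict = {}
    unit_effects: dict = {}
    valid_counts = {r: [0, 0] for r in ROLES}
    all_units: list[InstructionUnit] = []

    for j in range(config.n_interactions):
        interaction_id = f"dyad{j + 1:02d}"
        units = _script_timeline(config, rng, interaction_id, referent_ids)
        all_units.extend(units)
        total = units[-1].end + 2.0
        n_frames = int(np.round(total * FRAME_RATE)) + 1
        t = np.arange(n_frames) / FRAME_RATE

        positions = {o.object_id: o.centre for o in scene}
        gaze_streams: dict[str, GazeStream] = {}
        pupil_streams: dict[str, PupilStream] = {}
        for role in ROLES:
            partner = persons["builder" if role == "instructor" else "instructor"]
            pos = dict(positions)
            pos[PERSON_TARGET] = partner.head_centre
            labels = _script_gaze_labels(config, rng, n_frames, units, role, all_ids)
            stream, valid = _emit_gaze(config, rng, t, labels,
                                       persons[role].head_centre, pos)
            gaze_streams[role] = stream
            target_labels[(interaction_id, role)] = labels
            gaze_valid[(interaction_id, role)] = valid
            valid_counts[role][0] += int(valid.sum())
            valid_counts[role][1] += n_frames

            # pupil: per-unit effect windows
            effect = np.zeros(n_frames)
            for unit in units:
                level = role_levels[role][unit.type]
                bump = level + (rng.normal(0.0, config.unit_effect_sd_mm)
                                if config.unit_effect_sd_mm > 0 else 0.0)
                unit_effects[(interaction_id, unit.instruction_id, role)] = bump
                lo = int(np.round((unit.start - config.effect_lead_s) * FRAME_RATE))
                hi = int(np.round((unit.end + config.effect_lag_s) * FRAME_RATE))
                effect[max(0, lo):min(n_frames, hi)] = bump
            baseline_mm = float(rng.normal(config.pupil_baseline_mean_mm,
                                           config.pupil_baseline_between_sd_mm))
            pupil_streams[role] = _emit_pupil(config, rng, t, effect, baseline_mm)

            for unit in units:
                for seg in unit.segments:
                    if seg is unit.segments[-1]:
                        idx = units.index(unit)
                        horizon = (units[idx + 1].start if idx + 1 < len(units)
                                   else unit.end + 2.0)
                    else:
                        horizon = unit.segments[seg.fragment_ordinal].start
                    lo = int(np.round(seg.start * FRAME_RATE))
                    hi = min(int(np.round(horizon * FRAME_RATE)), n_frames)
                    window = np.arange(lo, hi)
                    hit = window[(labels[lo:hi] == seg.referent_id) & valid[lo:hi]]
                    latency = (float(t[hit[0]] - seg.start) if hit.size else None)
                    seg_truths.append(SegmentTruth(
                        interaction_id=interaction_id,
                        instruction_id=unit.instruction_id,
                        fragment_ordinal=seg.fragment_ordinal,
                        instruction_type=unit.type, role=role,
                        scripted_latency=latency, horizon_end=float(horizon)))

        recordings.append(DyadRecording(
            interaction_id=interaction_id, gaze=gaze_streams, pupil=pupil_streams,
            scene=scene, persons=persons, units=units,
            baseline_window={r: (0.0, config.baseline_duration_s) for r in ROLES}))

    truth = GroundTruth(
        config=replace(config),
        segments=seg_truths,
        target_labels=target_labels,
        gaze_valid=gaze_valid,
        unit_effects=unit_effects,
        emitted_validity_rate={r: valid_counts[r][0] / valid_counts[r][1]
                               for r in ROLES},
        slice_counts=coding.slice_counts(all_units),
    )
    return recordings, truth
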
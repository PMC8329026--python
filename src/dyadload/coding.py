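"""Instruction coding: grouping utterance fragments into instruction units.

An *instruction unit* is the set of instructor utterances referring to one
referent object within one step of the task.  A unit produced as a single
utterance is *non-fragmented*; a unit delivered as several intonationally
complete installments is *fragmented*, and its fragments are coded by
temporal sequence (Utt-1, Utt-2, ..., Utt-n).  Fragment boundaries arrive as
annotations; detecting them from audio is out of scope.
"""

from __future__ import annotations

from typing import Sequence

from .core import InstructionUnit, UtteranceSegment, ValidationError

#: Ordinal at which the sequence analysis truncates; deeper fragments are
#: coded but flagged, and excluded from per-ordinal slices by default.
MAX_ANALYSIS_ORDINAL = 4


def code_instruction(segments: Sequence[UtteranceSegment]) -> InstructionUnit:
    """Build one instruction unit from the segments sharing an instruction id.

    Segments are sorted by start time and re-assigned contiguous ordinals
    1..n in temporal order, regardless of input order.  All segments must
    agree on instruction and referent ids.
    """
    if not segments:
        raise ValidationError("cannot code an instruction from zero segments")
    instruction_ids = {s.instruction_id for s in segments}
    if len(instruction_ids) != 1:
        raise ValidationError(f"mixed instruction ids: {sorted(instruction_ids)}")
    referents = {s.referent_id for s in segments}
    if len(referents) != 1:
        raise ValidationError(
            f"instruction {segments[0].instruction_id}: inconsistent referent ids "
            f"{sorted(referents)}"
        )
    ordered = sorted(segments, key=lambda s: s.start)
    recoded = [
        UtteranceSegment(
            instruction_id=s.instruction_id,
            fragment_ordinal=i + 1,
            start=s.start,
            end=s.end,
            referent_id=s.referent_id,
            speaker_role=s.speaker_role,
        )
        for i, s in enumerate(ordered)
    ]
    return InstructionUnit(
        instruction_id=recoded[0].instruction_id,
        referent_id=recoded[0].referent_id,
        segments=recoded,
    )


def group_segments(segments: Sequence[UtteranceSegment]) -> list[InstructionUnit]:
    """Group a flat segment list by instruction id into coded units,
    ordered by first onset."""
    by_id: dict[str, list[UtteranceSegment]] = {}
    for seg in segments:
        by_id.setdefault(seg.instruction_id, []).append(seg)
    units = [code_instruction(segs) for segs in by_id.values()]
    units.sort(key=lambda u: u.start)
    return units


def duration(segment: UtteranceSegment) -> float:
    """Utterance duration in seconds (end minus start)."""
    d = segment.end - segment.start
    if d <= 0:
        raise ValidationError(
            f"segment {segment.instruction_id}/{segment.fragment_ordinal}: "
            f"non-positive duration"
        )
    return d


def sequence_slices(
    units: Sequence[InstructionUnit],
    max_ordinal: int = MAX_ANALYSIS_ORDINAL,
) -> dict[int, list[UtteranceSegment]]:
    """Per-ordinal fragment collections over the *fragmented* units.

    Slice ``k`` holds the k-th fragment of every fragmented unit with at
    least ``k`` fragments, so slice sizes are non-increasing in ``k``.
    Non-fragmented units never contribute.
    """
    slices: dict[int, list[UtteranceSegment]] = {k: [] for k in range(1, max_ordinal + 1)}
    for unit in units:
        if unit.type != "fragmented":
            continue
        for seg in unit.segments[:max_ordinal]:
            slices[seg.fragment_ordinal].append(seg)
    return slices


def slice_counts(
    units: Sequence[InstructionUnit],
    max_ordinal: int = MAX_ANALYSIS_ORDINAL,
) -> dict[int, int]:
    """Number of fragmented units contributing to each ordinal slice."""
    return {k: len(v) for k, v in sequence_slices(units, max_ordinal).items()}
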
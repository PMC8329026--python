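"""Readers and writers for annotation tiers, sensor streams, and scenes.

Formats
-------
* Annotation tier: ELAN EAF XML, or a 7-column tab-separated export
  (``interaction  instruction  ordinal  start  end  referent  role``) —
  the latter round-trips losslessly and is easy to write by hand.
  In EAF, each alignable annotation's value encodes
  ``instruction|ordinal|referent`` and the tier's PARTICIPANT attribute
  carries the speaker role.
* Sensor streams: one CSV per role with columns ``t, gaze_ox, gaze_oy,
  gaze_oz, gaze_dx, gaze_dy, gaze_dz, gaze_valid, pupil_left_mm,
  pupil_right_mm``; pupil columns must be named in mm (the ``_mm`` suffix is
  the declared unit).  Missing frames are re-inserted as invalid
  placeholders on the nominal 50 Hz grid.
* Metric tables: CSV with a fixed column order; undefined metrics are
  empty cells, never dropped.
* Scene: JSON or YAML (by extension) with objects, person regions, and
  baseline windows.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .core import (
    FRAME_RATE,
    METRIC_COLUMNS,
    GazeStream,
    InstructionUnit,
    MetricRow,
    PersonRegion,
    PupilStream,
    SceneObject,
    UtteranceSegment,
    ValidationError,
    validate_tier,
)

TIER_COLUMNS = ["interaction", "instruction", "ordinal", "start", "end",
                "referent", "role"]

STREAM_COLUMNS = ["t", "gaze_ox", "gaze_oy", "gaze_oz",
                  "gaze_dx", "gaze_dy", "gaze_dz", "gaze_valid",
                  "pupil_left_mm", "pupil_right_mm"]


# ---------------------------------------------------------------------------
# annotation tiers
# ---------------------------------------------------------------------------

def _units_from_segment_records(
    records: list[dict],
    scene_ids: Optional[set] = None,
    source: str = "",
) -> list[InstructionUnit]:
    """Group raw segment records into validated instruction units.

    File-declared ordinals must be contiguous from 1 and follow time;
    re-coding is *not* applied here, so annotation mistakes surface as
    errors instead of being silently repaired.
    """
    by_id: dict[str, list[dict]] = {}
    for rec in records:
        by_id.setdefault(rec["instruction"], []).append(rec)
    units = []
    for iid, recs in by_id.items():
        recs.sort(key=lambda r: r["ordinal"])
        ordinals = [r["ordinal"] for r in recs]
        if ordinals != list(range(1, len(recs) + 1)):
            raise ValidationError(
                f"{source}: instruction {iid}: ordinals {ordinals} are not "
                f"contiguous from 1")
        segments = [
            UtteranceSegment(
                instruction_id=iid, fragment_ordinal=r["ordinal"],
                start=r["start"], end=r["end"], referent_id=r["referent"],
                speaker_role=r["role"])
            for r in recs
        ]
        referents = {s.referent_id for s in segments}
        if len(referents) != 1:
            raise ValidationError(
                f"{source}: instruction {iid}: inconsistent referents "
                f"{sorted(referents)}")
        if scene_ids is not None and segments[0].referent_id not in scene_ids:
            raise ValidationError(
                f"{source}: instruction {iid}: unknown referent "
                f"{segments[0].referent_id!r}")
        units.append(InstructionUnit(instruction_id=iid,
                                     referent_id=segments[0].referent_id,
                                     segments=segments))
    units.sort(key=lambda u: u.start)
    validate_tier(units)
    return units


def read_annotation_tier(
    path: Union[str, Path],
    dialect: str = "tsv",
    scene_ids: Optional[Sequence[str]] = None,
) -> list[InstructionUnit]:
    """Read an annotation tier into instruction units.

    ``dialect`` is ``"tsv"`` (the 7-column export) or ``"eaf"`` (ELAN XML).
    When ``scene_ids`` is given, referents are checked against it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ids = set(scene_ids) if scene_ids is not None else None
    if dialect == "tsv":
        records = _read_tier_tsv(path)
    elif dialect == "eaf":
        records = _read_tier_eaf(path)
    else:
        raise ValidationError(f"unknown tier dialect {dialect!r}")
    return _units_from_segment_records(records, ids, source=str(path))


def _read_tier_tsv(path: Path) -> list[dict]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TIER_COLUMNS:
            raise ValidationError(
                f"{path}: expected columns {TIER_COLUMNS}, found {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(TIER_COLUMNS):
                raise ValidationError(f"{path}:{lineno}: expected "
                                      f"{len(TIER_COLUMNS)} fields, got {len(parts)}")
            try:
                records.append({
                    "interaction": parts[0], "instruction": parts[1],
                    "ordinal": int(parts[2]), "start": float(parts[3]),
                    "end": float(parts[4]), "referent": parts[5],
                    "role": parts[6]})
            except ValueError as err:
                raise ValidationError(f"{path}:{lineno}: {err}") from None
    return records


def write_annotation_tier(units: Sequence[InstructionUnit],
                          path: Union[str, Path],
                          interaction_id: str = "") -> None:
    """Write units to the tab-separated tier dialect."""
    lines = ["\t".join(TIER_COLUMNS)]
    for unit in units:
        for seg in unit.segments:
            lines.append("\t".join([
                interaction_id, unit.instruction_id, str(seg.fragment_ordinal),
                repr(seg.start), repr(seg.end), seg.referent_id,
                seg.speaker_role]))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_tier_eaf(path: Path) -> list[dict]:
    tree = ET.parse(path)
    root = tree.getroot()
    slots: dict[str, float] = {}
    for ts in root.iter("TIME_SLOT"):
        slots[ts.get("TIME_SLOT_ID")] = float(ts.get("TIME_VALUE")) / 1000.0
    records = []
    for tier in root.iter("TIER"):
        role = tier.get("PARTICIPANT") or tier.get("TIER_ID")
        for ann in tier.iter("ALIGNABLE_ANNOTATION"):
            value = ann.findtext("ANNOTATION_VALUE", default="")
            parts = value.split("|")
            if len(parts) != 3:
                raise ValidationError(
                    f"{path}: annotation value {value!r} is not "
                    f"'instruction|ordinal|referent'")
            records.append({
                "interaction": "", "instruction": parts[0],
                "ordinal": int(parts[1]),
                "start": slots[ann.get("TIME_SLOT_REF1")],
                "end": slots[ann.get("TIME_SLOT_REF2")],
                "referent": parts[2], "role": role})
    return records


def write_annotation_tier_eaf(units: Sequence[InstructionUnit],
                              path: Union[str, Path]) -> None:
    """Write units as a minimal ELAN EAF document (one tier per speaker)."""
    root = ET.Element("ANNOTATION_DOCUMENT", {
        "VERSION": "3.0", "TIME_UNITS": "milliseconds"})
    order = ET.SubElement(root, "TIME_ORDER")
    tiers: dict[str, ET.Element] = {}
    counter = 0
    for unit in units:
        for seg in unit.segments:
            counter += 1
            for suffix, tval in (("a", seg.start), ("b", seg.end)):
                ET.SubElement(order, "TIME_SLOT", {
                    "TIME_SLOT_ID": f"ts{counter}{suffix}",
                    "TIME_VALUE": str(int(round(tval * 1000)))})
            role = seg.speaker_role
            if role not in tiers:
                tiers[role] = ET.SubElement(root, "TIER", {
                    "TIER_ID": f"{role}-utterances", "PARTICIPANT": role,
                    "LINGUISTIC_TYPE_REF": "utterance"})
            ann = ET.SubElement(tiers[role], "ANNOTATION")
            al = ET.SubElement(ann, "ALIGNABLE_ANNOTATION", {
                "ANNOTATION_ID": f"a{counter}",
                "TIME_SLOT_REF1": f"ts{counter}a",
                "TIME_SLOT_REF2": f"ts{counter}b"})
            val = ET.SubElement(al, "ANNOTATION_VALUE")
            val.text = f"{unit.instruction_id}|{seg.fragment_ordinal}|{seg.referent_id}"
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


# ---------------------------------------------------------------------------
# sensor streams
# ---------------------------------------------------------------------------

def read_streams(path: Union[str, Path]) -> tuple[GazeStream, PupilStream]:
    """Read one role's gaze + pupil CSV.

    Timestamps must be strictly increasing; frames missing from the nominal
    50 Hz grid are re-inserted as invalid placeholders so downstream code
    sees a regular clock.  An empty (header-only) file yields empty streams.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        bad_pupil = [c for c in missing if c.startswith("pupil")]
        if bad_pupil and any(c.startswith("pupil") for c in df.columns):
            raise ValidationError(
                f"{path}: pupil columns must declare mm units "
                f"(expected {bad_pupil})")
        raise ValidationError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        empty3 = np.empty((0, 3))
        return (GazeStream(np.empty(0), empty3, empty3, np.empty(0, dtype=bool)),
                PupilStream(np.empty(0), np.empty(0), np.empty(0)))
    t = df["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        i = int(np.argmax(np.diff(t) <= 0))
        raise ValidationError(
            f"{path}: non-monotone timestamps near row {i + 2} "
            f"(t={t[i]} then {t[i + 1]})")

    fi = np.round(t * FRAME_RATE).astype(int)
    if np.any(np.diff(fi) < 1):
        raise ValidationError(f"{path}: duplicate frames on the 50 Hz grid")
    full = np.arange(fi[0], fi[-1] + 1)
    pos = fi - fi[0]
    n = full.size

    def place(col: str, fill: float) -> np.ndarray:
        out = np.full(n, fill)
        out[pos] = df[col].to_numpy(dtype=float)
        return out

    origin = np.column_stack([place(f"gaze_o{ax}", 0.0) for ax in "xyz"])
    direction = np.column_stack([place(f"gaze_d{ax}", 0.0) for ax in "xyz"])
    direction[np.all(direction == 0.0, axis=1)] = (0.0, 0.0, 1.0)
    valid = np.zeros(n, dtype=bool)
    valid[pos] = df["gaze_valid"].to_numpy(dtype=bool)
    gaze = GazeStream(t=full / FRAME_RATE, origin=origin, direction=direction,
                      valid=valid)
    pupil = PupilStream(t=full / FRAME_RATE,
                        left_mm=place("pupil_left_mm", np.nan),
                        right_mm=place("pupil_right_mm", np.nan))
    # estimated native rate of the file, before grid reconstruction
    rate = float(1.0 / np.median(np.diff(t))) if t.size > 1 else FRAME_RATE
    gaze.sampling_hz_estimate = rate
    pupil.sampling_hz_estimate = rate
    return gaze, pupil


def write_streams(gaze: GazeStream, pupil: PupilStream,
                  path: Union[str, Path]) -> None:
    """Write one role's streams to the CSV schema of :func:`read_streams`."""
    if not np.allclose(gaze.t, pupil.t):
        raise ValidationError("gaze and pupil streams must share one clock")
    df = pd.DataFrame({
        "t": gaze.t,
        "gaze_ox": gaze.origin[:, 0], "gaze_oy": gaze.origin[:, 1],
        "gaze_oz": gaze.origin[:, 2],
        "gaze_dx": gaze.direction[:, 0], "gaze_dy": gaze.direction[:, 1],
        "gaze_dz": gaze.direction[:, 2],
        "gaze_valid": gaze.valid.astype(int),
        "pupil_left_mm": pupil.left_mm, "pupil_right_mm": pupil.right_mm,
    })
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# metric tables
# ---------------------------------------------------------------------------

def metric_rows_to_frame(rows: Sequence[MetricRow],
                         extras: Optional[dict] = None) -> pd.DataFrame:
    """Stack metric rows into a DataFrame in the canonical column order."""
    df = pd.DataFrame([{c: getattr(r, c) for c in METRIC_COLUMNS} for r in rows],
                      columns=METRIC_COLUMNS)
    if extras:
        for name, values in extras.items():
            df[name] = values
    return df


def write_metric_table(table: Union[pd.DataFrame, Sequence[MetricRow]],
                       path: Union[str, Path]) -> None:
    """Write the metric table as CSV; undefined metrics become empty cells."""
    if not isinstance(table, pd.DataFrame):
        table = metric_rows_to_frame(table)
    extras = [c for c in table.columns if c not in METRIC_COLUMNS]
    table = table[METRIC_COLUMNS + extras]
    table.to_csv(path, index=False, na_rep="")


def read_metric_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a metric table; empty cells come back as NaN (undefined)."""
    df = pd.read_csv(path)
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing metric columns {missing}")
    return df


# ---------------------------------------------------------------------------
# scene configuration
# ---------------------------------------------------------------------------

def write_scene(scene: Sequence[SceneObject], persons: dict,
                baseline_window: dict, path: Union[str, Path]) -> None:
    """Write scene geometry and baseline windows as JSON or YAML."""
    doc = {
        "objects": [
            {"object_id": o.object_id, "kind": o.kind,
             "centre": [float(x) for x in o.centre], "radius": float(o.radius)}
            for o in scene
        ],
        "persons": {
            role: {"head_centre": [float(x) for x in np.atleast_1d(
                       np.asarray(r.head_centre)).reshape(-1)][:3],
                   "radius": float(r.radius)}
            for role, r in persons.items()
        },
        "baseline_window": {role: [float(a), float(b)]
                            for role, (a, b) in baseline_window.items()},
    }
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2))


def read_scene(path: Union[str, Path]) -> tuple[list[SceneObject], dict, dict]:
    """Read a scene file; returns (objects, person regions, baseline windows)."""
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") \
        else json.loads(text)
    objects = [SceneObject(object_id=o["object_id"], kind=o["kind"],
                           centre=np.asarray(o["centre"], dtype=float),
                           radius=float(o["radius"]))
               for o in doc["objects"]]
    persons = {role: PersonRegion(role=role,
                                  head_centre=np.asarray(p["head_centre"], dtype=float),
                                  radius=float(p["radius"]))
               for role, p in doc["persons"].items()}
    windows = {role: (float(w[0]), float(w[1]))
               for role, w in doc["baseline_window"].items()}
    return objects, persons, windows
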
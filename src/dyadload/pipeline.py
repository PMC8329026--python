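"""End-to-end extraction and the two study analyses.

`extract_metrics` turns one dyad recording into the per-(segment x role)
metric table: six attention measures, three pupillary measures, and
duration.  `condition_analysis` compares fragmented vs non-fragmented
instructions (plus role and their interaction); `sequence_analysis` follows
the fragment sequence Utt-1..Utt-4 within fragmented instructions;
`fragment_correlation_screen` runs the exploratory Spearman screen of every
measure against the number of fragments per instruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import coding, gaze, pupil, stats
from .core import (
    MEASURE_NAMES,
    ROLES,
    DyadRecording,
    MetricRow,
    UtteranceSegment,
)

#: Measures defined at the dyad level (identical for both roles' rows).
DYADIC_MEASURES = ("joint_attention", "mutual_gaze", "duration")

#: Per-role pupil measures; their models add a participant random intercept.
PUPIL_MEASURES = ("mean_dilation", "peak_dilation", "slope")


@dataclass
class ExtractionConfig:
    """All tunables of the measurement chain."""

    threshold_deg: float = gaze.DEFAULT_THRESHOLD_DEG
    filter_spec: pupil.FilterSpec = field(default_factory=pupil.FilterSpec)
    outlier_spec: pupil.OutlierSpec = field(default_factory=pupil.OutlierSpec)
    max_gap_frames: int = 25


def _horizons(segments: Sequence[UtteranceSegment],
              stream_end: float) -> dict[tuple[str, int], float]:
    """First-gaze search horizon per segment: from its onset to the next
    segment's onset (late identifications remain capturable), or the stream
    end for the final segment."""
    ordered = sorted(segments, key=lambda s: s.start)
    out = {}
    for seg, nxt in zip(ordered, ordered[1:] + [None]):
        end = nxt.start if nxt is not None else stream_end
        out[(seg.instruction_id, seg.fragment_ordinal)] = end
    return out


def extract_metrics(
    recording: DyadRecording,
    config: Optional[ExtractionConfig] = None,
) -> pd.DataFrame:
    """Compute the full metric table for one recording.

    Returns one row per (utterance segment x role) with the canonical
    metric columns plus ``referent_id``, ``n_fragments`` and
    ``participant_id`` for modelling.
    """
    cfg = config or ExtractionConfig()
    frames = {}
    series = {}
    baselines = {}
    for role in ROLES:
        partner = recording.persons[recording.partner_of(role)]
        frames[role] = gaze.assign_targets(
            recording.gaze[role], recording.scene, partner,
            threshold_deg=cfg.threshold_deg, role=role)
        s = pupil.preprocess(recording.pupil[role], cfg.filter_spec,
                             cfg.outlier_spec, cfg.max_gap_frames)
        series[role] = s
        baselines[role] = pupil.extract_baseline(
            s, recording.baseline_window[role], role=role)

    all_segments = [s for u in recording.units for s in u.segments]
    stream_end = float(recording.gaze["instructor"].t[-1])
    horizon = _horizons(all_segments, stream_end)

    rows: list[MetricRow] = []
    extras: dict[str, list] = {"referent_id": [], "n_fragments": [],
                               "participant_id": []}
    for unit in recording.units:
        for seg in unit.segments:
            ja = gaze.joint_attention(frames["instructor"], frames["builder"],
                                      seg, unit.referent_id)
            mg = gaze.mutual_gaze(frames["instructor"], frames["builder"], seg)
            for role in ROLES:
                gt, go, gp = gaze.proportional_gaze(frames[role], seg,
                                                    unit.referent_id)
                fg = gaze.first_gaze_latency(
                    frames[role], seg, unit.referent_id,
                    horizon_end=horizon[(seg.instruction_id, seg.fragment_ordinal)])
                md, pk, sl = pupil.segment_pupil_metrics(series[role],
                                                         baselines[role], seg)
                rows.append(MetricRow(
                    interaction_id=recording.interaction_id,
                    instruction_id=seg.instruction_id,
                    fragment_ordinal=seg.fragment_ordinal,
                    instruction_type=unit.type,
                    role=role,
                    first_gaze_to_target=fg,
                    gaze_to_target=gt, gaze_to_other=go, gaze_to_person=gp,
                    joint_attention=ja, mutual_gaze=mg,
                    mean_dilation=md, peak_dilation=pk, slope=sl,
                    duration=coding.duration(seg)))
                extras["referent_id"].append(unit.referent_id)
                extras["n_fragments"].append(unit.n_fragments)
                extras["participant_id"].append(
                    f"{recording.interaction_id}-{role}")
    from .io import metric_rows_to_frame
    return metric_rows_to_frame(rows, extras)


def extract_corpus(recordings: Sequence[DyadRecording],
                   config: Optional[ExtractionConfig] = None,
                   on_error: str = "skip") -> tuple[pd.DataFrame, list[str]]:
    """Extract all recordings; interactions with unusable sensor data are
    excluded with a logged reason (``on_error="raise"`` propagates)."""
    tables, log = [], []
    for rec in recordings:
        try:
            tables.append(extract_metrics(rec, config))
        except Exception as err:
            if on_error == "raise":
                raise
            log.append(f"interaction {rec.interaction_id} excluded: {err}")
    if not tables:
        raise ValueError("no interaction could be extracted: " + "; ".join(log))
    return pd.concat(tables, ignore_index=True), log


def export_audit(recording: DyadRecording, outdir,
                 config: Optional[ExtractionConfig] = None) -> None:
    """Write per-frame audit tables (gaze targets, cleaned pupil) as CSV,
    so every metric-table number can be re-derived by hand."""
    from pathlib import Path
    cfg = config or ExtractionConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for role in ROLES:
        partner = recording.persons[recording.partner_of(role)]
        fr = gaze.assign_targets(recording.gaze[role], recording.scene, partner,
                                 threshold_deg=cfg.threshold_deg, role=role)
        pd.DataFrame({
            "t": fr.t,
            "target": [x if x is not None else "" for x in fr.target],
            "angular_error_deg": fr.angular_error_deg,
        }).to_csv(outdir / f"{recording.interaction_id}_{role}_gaze.csv",
                  index=False)
        s = pupil.preprocess(recording.pupil[role], cfg.filter_spec,
                             cfg.outlier_spec, cfg.max_gap_frames)
        pd.DataFrame({
            "t": s.t, "diameter_mm": s.diameter_mm,
            "valid": s.valid.astype(int), "excluded": s.excluded.astype(int),
            "flag": s.flags,
        }).to_csv(outdir / f"{recording.interaction_id}_{role}_pupil.csv",
                  index=False)


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------

def _dedup_dyadic(df: pd.DataFrame) -> pd.DataFrame:
    """Dyadic measures carry one value per segment; keep one row each."""
    return df.drop_duplicates(
        subset=["interaction_id", "instruction_id", "fragment_ordinal"])


def condition_analysis(
    metric_df: pd.DataFrame,
    responses: Sequence[str] = tuple(MEASURE_NAMES),
    truncate_ordinal: int = coding.MAX_ANALYSIS_ORDINAL,
) -> dict[str, stats.StatsResult]:
    """Fragmented vs non-fragmented comparison for every measure.

    Per-role measures use Fragment + Role fixed factors plus their
    interaction; dyadic measures use Fragment only.  Random intercepts:
    interaction and instructed object, plus participant for pupil measures.
    """
    df = metric_df[metric_df["fragment_ordinal"] <= truncate_ordinal]
    out = {}
    for resp in responses:
        if resp in DYADIC_MEASURES:
            spec = stats.ModelSpec(
                response=resp, fixed=["instruction_type"],
                random_intercepts=["interaction_id", "referent_id"])
            out[resp] = stats.fit_and_test(_dedup_dyadic(df), spec)
        else:
            random = ["interaction_id", "referent_id"]
            if resp in PUPIL_MEASURES:
                random = random + ["participant_id"]
            spec = stats.ModelSpec(
                response=resp,
                fixed=["instruction_type", "role", "instruction_type:role"],
                random_intercepts=random)
            out[resp] = stats.fit_and_test(df, spec)
    return out


def sequence_analysis(
    metric_df: pd.DataFrame,
    responses: Sequence[str] = tuple(MEASURE_NAMES),
    truncate_ordinal: int = coding.MAX_ANALYSIS_ORDINAL,
) -> dict[str, stats.StatsResult]:
    """Utt-1..Utt-n progression within fragmented instructions only."""
    df = metric_df[(metric_df["instruction_type"] == "fragmented")
                   & (metric_df["fragment_ordinal"] <= truncate_ordinal)]
    out = {}
    for resp in responses:
        if resp in DYADIC_MEASURES:
            spec = stats.ModelSpec(
                response=resp, fixed=["fragment_ordinal"],
                random_intercepts=["interaction_id", "referent_id"])
            out[resp] = stats.fit_and_test(_dedup_dyadic(df), spec)
        else:
            random = ["interaction_id", "referent_id"]
            if resp in PUPIL_MEASURES:
                random = random + ["participant_id"]
            spec = stats.ModelSpec(
                response=resp,
                fixed=["fragment_ordinal", "role", "fragment_ordinal:role"],
                random_intercepts=random)
            out[resp] = stats.fit_and_test(df, spec)
    return out


def per_instruction_table(metric_df: pd.DataFrame, role: str) -> pd.DataFrame:
    """Aggregate one role's rows to instruction level (mean over fragments)."""
    sub = metric_df[metric_df["role"] == role]
    grouped = sub.groupby(["interaction_id", "instruction_id"], observed=True)
    agg = grouped[list(MEASURE_NAMES)].mean()
    agg["n_fragments"] = grouped["n_fragments"].first()
    return agg.reset_index()


def fragment_correlation_screen(
    metric_df: pd.DataFrame,
    roles: Sequence[str] = ROLES,
    bonferroni_m: int = 10,
) -> dict[str, list]:
    """Spearman screen per role of every measure vs fragment count."""
    out = {}
    for role in roles:
        table = per_instruction_table(metric_df, role)
        out[role] = stats.correlation_screen(
            table, MEASURE_NAMES, bonferroni_m=bonferroni_m)
    return out


def stats_table(results: dict[str, stats.StatsResult]) -> pd.DataFrame:
    """Flatten analysis results into one table: per-term chi-square/df/p."""
    rows = []
    for resp, res in results.items():
        for term, (chi2, dof, p) in res.terms.items():
            stars = ("***" if p <= 0.001 else "**" if p <= 0.01
                     else "*" if p <= 0.05 else "")
            rows.append({"response": resp, "term": term, "chi_square": chi2,
                         "df": dof, "p_value": p, "signif": stars})
    return pd.DataFrame(rows)
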
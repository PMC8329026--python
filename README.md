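# dyadload

Measurement and analysis chain for quantifying **collaboration load** in
dyadic task-oriented interaction — for researchers in psycholinguistics,
psychophysiology, and human–robot interaction who study how speakers package
instructions and what that costs both conversational partners.

## The problem

In a referential assembly task, an *instructor* tells a *builder* which piece
to pick up next. Instructions are delivered either **non-fragmented** (one
utterance) or **fragmented** — a series of intonationally complete
installments (Utt-1, Utt-2, …, Utt-n), each repairing or extending the
reference while the speaker monitors the listener for understanding. The
question is how cognitive resources are allocated across this grounding
process, indexed by task-evoked pupillary responses and visual attention.

`dyadload` implements the full chain from synchronized 50 Hz sensor streams
to statistical tables:

* **Pupil pipeline** — binocular merge (mean of both eyes, or the available
  eye), linear bridging of blink dropouts, 5th-order low-pass Butterworth
  smoothing (4 Hz cut-off, zero-phase), outlier exclusion by feasible range
  [1.5–9 mm] and a 2 SD z-rule, baseline referencing, and per-segment
  **mean dilation**, **peak dilation** (mm vs baseline, signed) and
  **slope** (mm/frame, least squares).
* **Gaze pipeline** — per-frame 3D gaze-target assignment by smallest visual
  angle within a capture cone, then per-segment **first gaze to target
  referent** (s), proportional **gaze to target / other objects / person**,
  and the dyadic measures **joint attention** (both on the referent
  simultaneously) and **mutual gaze** (both on each other).
* **Fragment coding** — utterance segments from ELAN-compatible annotation
  tiers (EAF XML or a flat tab-separated export) grouped into instruction
  units, typed fragmented/non-fragmented, with per-ordinal sequence slices.
* **Statistics** — linear mixed models (ML) with Fragment and Role fixed
  factors plus their interaction, random intercepts for interaction,
  instructed object, and (for pupil measures) participant; each term tested
  by a likelihood-ratio chi-square between nested fits,
  χ² = 2·(ℓ̂_full − ℓ̂_reduced); plus a Spearman/Bonferroni screen of every
  measure against the number of fragments per instruction (only |ρ| > 0.15
  reported).
* **Synthetic dyad generator** — complete recordings (gaze rays, binocular
  pupil with AR(1) noise and blink artefacts, fragment-structured tiers)
  with frame-level ground truth, so the entire chain is testable without any
  recorded data.

## Worked example

```python
import dyadload as dl
from dyadload import pipeline

recordings, truth = dl.generate(dl.benchmark_profile(), seed=1)
metrics, _ = dl.extract_corpus(recordings)

one = pipeline._dedup_dyadic(metrics)
print(one.groupby("instruction_type")["duration"].mean())
res = pipeline.condition_analysis(metrics, responses=["duration"])
print(res["duration"].terms["instruction_type"])
```

prints

```
instruction_type
fragmented        2.590395
non_fragmented    4.263750
Name: duration, dtype: float64
(50.75658808429398, 1, 1.0456100826886059e-12)
```

Fragmented installments are markedly shorter than one-shot instructions
(2.59 s vs 4.26 s on average here), and the likelihood-ratio test for the
Fragment factor is χ²(1) = 50.8 — the utterance-duration signature of
incremental grounding. The same metric table feeds `sequence_analysis`
(Utt-1..Utt-4 progression) and `fragment_correlation_screen`.

The command line mirrors this: `dyadload simulate | extract | analyze | all`
with YAML configuration, writing metric tables, per-frame audit tables,
stats tables, and a run log with every resolved parameter.

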
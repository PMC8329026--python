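# Methods

This note documents the models and procedures implemented in `dyadload`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open.

## Coordinate and time conventions

All streams share one clock in seconds, nominally sampled at 50 Hz; the
frame index of a timestamp is `round(t * 50)`. Positions are metres in a
single scene frame shared by both participants. Pupil diameters are mm.
Stream readers reconstruct the nominal frame grid: rows missing from a file
become invalid placeholder frames, so downstream code always sees a regular
clock.

## Pupil preprocessing

The chain is merge → gap interpolation → low-pass filtering → outlier
exclusion → baseline → per-segment metrics.

* **Binocular merge.** Both eyes present: their mean; one eye: that eye;
  neither: invalid frame. Per-frame provenance flags (merged-both,
  left-only, right-only, interpolated) are kept for audit export.
* **Gap interpolation.** Invalid runs up to `max_gap_frames` (default 25
  frames = 0.5 s, a generous blink) are bridged linearly between flanking
  valid frames. Leading/trailing runs are never extrapolated. Longer gaps
  stay invalid; the filter bridges them internally by edge-hold for its
  arithmetic only, and they never enter metrics.
* **Filtering.** 5th-order low-pass Butterworth, 4 Hz cut-off at 50 Hz
  sampling. Default is zero-phase (forward–backward) so segment windows are
  not shifted by group delay; a causal mode is retained behind config, and
  it is the causal recursion that the test suite checks against a naive
  direct-form difference-equation oracle. DC gain is exactly 1.
* **Outlier exclusion.** Two rules: a feasible range of [1.5, 9] mm
  (physiologically possible human pupil diameters), then a z-rule excluding
  frames more than 2 SD from the mean. The range rule runs first and the z
  statistics are computed on range-surviving frames — the stricter reading
  of a rule that conflates the two. The z scope defaults to
  per-participant-per-recording; a global mode (caller-supplied mean/SD)
  exists for sensitivity checks. The statistics used are stored on the
  series, so re-application with `recompute_stats=False` is idempotent.
  Exclusion happens after filtering; both orders are possible by composing
  the operations directly.
* **Baseline.** Mean usable diameter over a pre-stimulus window, default
  the 5 s before the first instruction ("a few seconds" is not otherwise
  quantified). At least 50% usable coverage is required, otherwise the
  recording fails loudly rather than biasing every dilation.
* **Per-segment metrics.** Mean dilation and peak dilation are the mean and
  max of (diameter − baseline) over usable in-segment frames (signed:
  negative = contraction). Slope is the least-squares slope of diameter
  against frame index, in **mm per frame at 50 Hz** — multiply by 50 for
  mm/s. This unit choice is deliberate and affects all slope magnitudes.
  Fewer than 2 usable frames makes all three undefined for that row;
  undefined values serialize as empty CSV cells.

## Gaze-target assignment and attention measures

Each valid gaze ray is scored by visual angle against every candidate:
scene objects and the partner's head region (a sphere of default radius
0.15 m around the tracked head centre). The smallest angle wins if within a
capture cone of `threshold_deg` (default 10°; no principled value exists, so
it is config-exposed and every structural property holds for any positive
threshold). Ties break by 3D distance, then lexicographic id.

* **First gaze to target referent**: time from utterance onset to the first
  frame on the referent. The search horizon extends to the next segment's
  onset so late identifications are captured; if the referent is never
  reached the value is undefined and excluded listwise from that metric's
  statistics.
* **Proportional measures**: shares of *segment time* — invalid and
  unassigned frames stay in the denominator, so
  target + other + person + remainder = 1. A valid-time denominator would
  inflate proportions for low-validity participants and is intentionally
  not the default.
* **Joint attention / mutual gaze**: the fraction of in-segment frames
  where both partners are simultaneously on the referent / on each other.
  Both are symmetric in the two roles by construction.

"Invalid" (tracker dropout) and "gazing elsewhere" (valid ray, no candidate
within the cone) are kept as distinct states throughout.

## Fragment coding

Utterance boundaries arrive as annotations (ELAN EAF or a 7-column
tab-separated export); detecting them from audio or prosody is out of
scope. Segments sharing an instruction id form one instruction unit; units
are non-fragmented iff they contain a single utterance. Ordinals are
assigned 1..n in temporal order. File-declared ordinals must already be
contiguous and time-ordered — annotation mistakes surface as validation
errors, not silent repairs. Sequence slices collect the k-th fragment of
every fragmented unit with ≥ k fragments; analysis truncates at Utt-4 by
default (config-overridable), deeper fragments remain coded. Listener
back-channels are not segments of the instruction unit.

## Statistical analysis

All models are fitted by maximum likelihood (never REML), because
log-likelihoods are compared across fixed-effect structures. Term testing
is sequential drop-one: each main effect is tested by removing it from the
main-effects model; the interaction is tested against the two-main-effects
model. χ² = 2·Δℓ̂ with df = the number of fixed-effect columns added; the
per-term df is always reported explicitly.

Random intercepts default to interaction and instructed object, plus
participant for pupil responses. A single random intercept is fitted as the
grouping factor of `statsmodels` MixedLM; several are encoded as crossed
variance components over one trivial group. A singular or non-converging
fit falls back to a reduced random structure with a logged warning. The
response is standardized internally before fitting (the LRT is invariant to
affine rescaling); this keeps the optimizer well conditioned for responses
of very small magnitude such as slopes.

Dyadic measures (joint attention, mutual gaze, duration) carry one value
per segment, so their models use the Fragment factor only, on de-duplicated
rows.

The correlation screen aggregates each role's rows to instruction level,
computes Spearman's ρ (midrank ties) of each measure against the number of
fragments, multiplies p by the number of screened correlations (Bonferroni,
divisor 10 by default, logged in output), and flags for reporting only
|ρ| > 0.15 with adjusted p below threshold. Constant measures have no
defined rank correlation and are returned with an explanatory note.

## Synthetic dyad generator

The generator emulates the study conditions: 28 interactions of 9
instruction steps; fragment counts drawn from (0.463, 0.325, 0.122, 0.090)
over 1–4 fragments (the empirical composition of the reference corpus);
utterance durations N(4.24, 2.49²) s non-fragmented and per-ordinal means
(3.75, 1.79, 1.49, 1.49) s fragmented, floored at 0.5 s; first-gaze
latencies drawn per role × ordinal from the corresponding condition cells;
a scene of 10 uniquely identifiable pieces on a table between two seated
participants.

The pupil trace is participant baseline N(3.5, 0.3²) mm + a
condition-dependent dilation during each instruction + slow AR(1) noise
(coefficient 0.95 at 50 Hz, innovation SD 0.031 mm — AR(1) rather than
white noise so the low-pass filter has realistic work to do) + blink
artefacts + monocular dropouts. Dilation levels are per role:
non-fragmented level plus a fragmented-minus-non-fragmented delta
(instructor: 0.00 + 0.14 mm; builder: 0.12 − 0.01 mm), plus a per-unit
random effect (SD 0.28 mm) reproducing realistic between-segment spread.
The effect window leads/lags the instruction by 0.3 s — speakers plan
before speaking and pupil responses decay slowly — which also means
segment means are not eroded by the filter's edge transients.

Blinks are modelled as a both-eye dropout run (8 frames at 15/min) flanked
by negative amplitude spikes (−2.2 mm), the signature artefact of
video-based eye-trackers. After interpolation and filtering these become
deep in-range dips that dominate the outlier budget: the z-rule's SD
estimate is inflated by artefacts, so (as in real recordings) the 2 SD rule
removes artefact frames rather than clipping the bulk signal. This is why
the injected dilation delta is recoverable essentially unbiased — a
generator with purely Gaussian noise at the same threshold would shrink
condition differences by construction.

Gaze is scripted: distractor scanning with occasional partner glances
before a drawn latency, lock-on to the referent after it, perturbed by
angular jitter (default half-normal, 2° scale); per-frame validity at
0.775. Ground truth (scripted latencies, target labels, validity, unit
effects, slice counts) is recorded **from the emitted frames**, after
validity dropout, so it is consistent with the recording frame by frame.

What the generator does *not* emulate: scan-path dynamics and
fixation/saccade structure, pupil light reflex and luminance coupling,
head motion (person regions are static), audio, and per-ordinal pupil
progression within fragmented instructions beyond what the per-type levels
induce. Passing tests therefore demonstrate correctness of the measurement
chain and the statistical machinery under known ground truth — not that
real recordings satisfy the generator's assumptions.

## Problem sizes and numerical choices

The packaged analyses run at the study scale (28 interactions, ~250
instruction units, ~930 metric rows). Test-suite simulations use 200
replicates (n = 400 rows) for null calibration of the LRT, 100 replicates
for power, and 50 replicate corpora for effect recovery — sizes at which
binomial/Monte-Carlo error bounds are meaningful and the suite stays fast.
Filter oracles are checked to 1e-9, algebraic oracles (slopes,
interpolation) to 1e-10–1e-12, tallies exactly. Tie-breaks are
deterministic everywhere (documented per operation); degenerate inputs
(constant series, empty cells, all-invalid windows, constant responses)
return defined results or fail with named errors rather than propagating
NaN.

## Known limitations

* `statsmodels` MixedLM provides no direct crossed-random-effects solver;
  the variance-component encoding is exact in the likelihood but slower
  than specialized solvers, so full crossed analyses of all ten measures
  take a few seconds each.
* The LRT is asymptotic; at the study scale its type-I error is
  empirically in the 0.03–0.08 band rather than exactly 0.05.
* EAF support covers time-aligned alignable annotations (the subset the
  pipeline needs), not the full ELAN feature set.
* First-gaze latencies are frame-quantized at 50 Hz; sub-frame timing is
  not estimated.
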
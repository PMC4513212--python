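# Methods

## Problem setting

An *episode* is the stretch of interaction preceding one spoken request:
the requester scans a tabletop of up to 23 selectable ingredients (plus the
bread, the partner, and empty space) and then names one ingredient.  Input
data are fixation-segmented gaze streams — each fixation an interval
`[onset_ms, offset_ms)` labeled with its target — together with the request
onset, the ground-truth requested ingredient, and the set of ingredients
still available.  Raw-gaze event detection (I-DT/I-VT), speech alignment,
and 2-D gaze coordinates are out of scope: fixations arrive already
segmented and labeled.

Time is integer milliseconds with half-open intervals throughout; at a
30 Hz tracker sampling rate, finer precision carries no information.

## Glances

Analysis operates on *glances*: maximal runs of same-target fixations
merged across interruptions of at most 200 ms consisting only of uncovered
time (saccades) and/or short MISSING fixations (tracker dropout).  A
fixation on any other real target breaks the run.  The 200 ms bound is a
conventional saccade-scale threshold and a configuration knob
(`max_gap_ms`); the field does not agree on a canonical value, and no claim
here is sensitive to it within the 100–300 ms range.

Each glance carries both its span and its *dwell* (the summed duration of
its constituent fixations).  Dwell, not span, feeds the duration features,
so bridged gaps are never counted as looking time.  Two same-target glances
separated by more than the merge threshold remain distinct — a requester
re-visiting an ingredient after looking elsewhere produces a new glance,
which is exactly what the glance-count feature is meant to capture.

## Missing data and episode exclusion

The missing fraction of an episode is the share of `[0, request_onset)`
not covered by a real-target fixation: explicit MISSING fixations and
uncovered time are counted alike, because tracker dropout appears both ways
in real exports and the distinction carries no analytic content.  Episodes
with *more than* 40% missing are excluded (an episode at exactly 40% is
retained); the computation is time-based rather than sample-based, the
natural choice once fixations are intervals.

## Features and classifier

For every candidate ingredient glanced at so far, four features summarize
the evidence at time *t*: glance count (f1), first-glance dwell in ms (f2),
total glance dwell in ms (f3), and whether the candidate is the most
recently glanced ingredient (f4).  Recency transfers only between
ingredients — glancing at the bread or the partner does not clear it —
and features reset at episode boundaries.  When a glance straddles the
query time it contributes its clipped dwell, so streaming predictions see
partial evidence honestly.

Candidates are labeled +1 (requested) or −1 (competing) and classified by
an RBF-kernel SVM on min-max-scaled features.  Scaling is fitted on the
training fold only; values outside the training range extrapolate linearly,
and a constant training column maps to zero.  Probabilities come from
Platt-sigmoid calibration of the decision values
(`CalibratedClassifierCV(method="sigmoid", ensemble=False)`), fitted via
internal cross-validation within the training fold — the binary reduction
of the standard pairwise-coupling construction for multi-class SVM
probabilities.

Hyperparameters: an inner 5-fold grid search over C ∈ {2⁻³…2⁷},
γ ∈ {2⁻⁷…2³} is implemented (`SVMConfig(search="grid")`).  The default is
the fixed pair C = 64, γ = 0.125, obtained by running that search once on
the default synthetic dataset (seed 0; cross-validated candidate accuracy
0.916 in a flat optimum region) and recorded so the default evaluation is
fast and exactly reproducible.  Class weighting is off by default — each
episode contributes roughly one positive and several negatives, and the
unweighted fit reproduces the intended behavior of the thresholded policy
(frequent abstention) — with `class_weight="balanced"` available as a
switch.

## Policies, evaluation, anticipation

The *traditional* policy predicts the highest-probability candidate among
those with p > 0.5 and abstains if none qualifies; the *always-predict*
policy takes the unconditional argmax.  Ties break toward the earliest
candidate-list insertion, making both policies deterministic.  Because the
always policy's argmax agrees with the traditional one whenever the latter
predicts, always-predict episode accuracy dominates traditional accuracy
on any dataset (abstentions count as errors).

Evaluation uses seeded, unstratified 10-fold episode partitions.  Reported
are: candidate-level classification accuracy; episode-level prediction
accuracy per policy; abstention rate and conditional accuracy (the
identity `prediction = (1 − abstention) × conditional` holds by
construction, since the report stores counts); the chance band
`(1/max |available|, 1/min |available|)`; and a univariate Fisher-style
feature ranking, `(μ₊ − μ₋)² / (σ₊² + σ₋² + ε)` per feature — a
transparent stand-in for wrapper-style feature selection that needs no
refitting.  Episodes whose candidate list is empty at request onset
contribute no classification labels but count as incorrect predictions.

Streaming traces record the per-candidate probabilities and the policy
output at each completed ingredient glance (the only events that change any
feature) plus the request onset.  The *anticipation window* runs from the
last change in the predicted label — transitions into or out of abstention
count as changes; a never-changing trace anchors at its first event — to
the request onset, and measures how early the final answer was locked in.
Anticipation statistics are averaged over correctly predicted episodes,
with the incorrect-prediction summary reported alongside.  The window's
begin/end probabilities are the final predicted ingredient's calibrated
probability at the first and last trace events inside the window.

## Template detectors

Three signaling gaze sequences are detected over the glance sequence and
reported as annotations (deliberately not fed back into the predictor —
whether they help prediction is an open question, and the data contain
counterexamples):

* joint-attention initiation: ingredient X → partner → same X;
* confirmatory request: partner → single ingredient X → partner;
* goal referencing: a bread glance within a 2-glance radius of an
  ingredient glance (focal = the nearest such glance, earlier preferred on
  ties).

Each hop of the alternating templates tolerates at most one intervening
ELSEWHERE or MISSING glance; BREAD never counts as a tolerated gap because
it is itself meaningful.  Both alternating templates are palindromes, so
each detector is symmetric under sequence reversal (reversal does not
convert one template into the other; swapping the partner/ingredient roles
does).  No timing constraints are imposed beyond sequence order.

## Synthetic episode generator

The generator stands in for undeposited human gaze recordings.  Its
defaults define the study conditions: 23 ingredients with 9–23 available
per episode, 276 episodes, episode durations with mean 3802.56 ms and
SD 1596.45 ms, a 10% mean missing-data rate (per-episode rates jittered,
so a rate set near 0.40 straddles the exclusion threshold), and an
archetype mixture of dominant choice 0.35, trending 0.15, two competing
0.12, multiple choices 0.10, no intended glance 0.08 (matching the ~8%
of episodes in which the requested target was reported never glanced at),
joint attention 0.08, confirmatory 0.07, goal referencing 0.05.  The
remaining weights are conventions: real prevalences for correct
predictions are not reported anywhere and are not estimable from
aggregate accuracies.

Durations are drawn from a normal truncated below at 500 ms whose
underlying parameters are solved numerically so that the *truncated*
distribution's mean and SD equal the configured values (naive truncation
would bias the mean upward by ~76 ms).  Within an episode, a
missing-data budget, an ingredient-dwell budget, and a filler budget
partition the timeline; each archetype lays out ingredient glances under
its defining guarantee — the dominant choice holds at least the configured
dwell share (0.8 by default; exact by construction), the trending choice
has strictly the most glances with spread dwell, the no-intended-glance
archetype never shows the requested target, and the template archetypes
plant their sequence near the episode end with the span recorded in the
annotations.  Glances are split into 1–6 fixations with log-normal-scale
sizing (median 250 ms); dropout appears as explicit MISSING fixations in
chunks of at least 250 ms so that dropout never silently bridges a glance
merge.

`last_glance_match_rate` (default 0.65, the attention-baseline accuracy
reported for this task) fixes the probability that the final ingredient
glance is the requested target, for archetypes in which the requested
target is glanced at all; this gives the attention baseline a known
recoverable accuracy on such data.  Competitor glance counts in the
dominant archetype are drawn from 1–2 rather than fixed at 1: dominance is
defined by dwell share, and fixing competitor counts would make glance
count, not dwell, the most diagnostic feature as a pure layout artifact.

Sampling is driven by one root stream (archetype sequence) plus
counter-based per-episode substreams keyed by `(seed, index)`, so datasets
are byte-for-byte reproducible and individual episodes can be regenerated.

What the generator does *not* emulate: person-specific gaze style (so
episode-level folds cannot leak it, and participant-grouped folding is
untested against it), speech timing beyond a scalar onset, 2-D gaze
geometry and tracker-accuracy structure, saccade-gap dropout (timelines
are gap-free with explicit MISSING; gap bridging is exercised by
hand-built episodes in the tests), and partner/bread glances outside the
template archetypes (excluded so that template-free episodes provably
contain no accidental template matches).  Passing tests on this generator
therefore demonstrate correctness of the pipeline's bookkeeping and the
qualitative orderings — SVM above attention baseline above chance,
abstention trading coverage for conditional accuracy, positive
anticipation lead times — not numeric performance on human data.

## Numerical and degenerate-input choices

* Strict thresholds: classification positive iff p > 0.5; exclusion iff
  missing fraction > 0.40.
* Argmax ties break toward earliest candidate insertion.
* An all-abstain trace has no anticipation window; window probabilities
  are undefined when the final prediction is an abstention.
* `chance_accuracy(n)` requires n ≥ 1; a single-target episode has chance
  accuracy 1.
* Zero-variance features in the ranking are guarded by an ε = 1e-9 floor.
* Training requires both classes; single-class folds raise immediately.
* Probabilities for a requested-but-never-glanced target do not exist:
  such episodes are structurally unpredictable and score as errors.

## Problem sizes

Default analyses use 276 episodes (~820 candidate vectors) with 10-fold
cross-validation; parameter-recovery checks use 1000 episodes; the
feature-ranking check uses ~2000 candidate vectors from dominant-choice
episodes; oracle-equivalence checks use 1000 random (episode, time) pairs,
1000 random traces, and 200 random episodes.  The full default evaluation
runs in a few seconds on one CPU.
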
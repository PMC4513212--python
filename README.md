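# gazeintent

Gaze-based task-intent prediction from streaming fixation data.

In collaborative reference tasks — the motivating scenario is a dyadic
sandwich-making game in which a "customer" requests ingredients one at a
time from a "worker" choosing among up to 23 items — a person's eye gaze
telegraphs which object they are about to ask for. `gazeintent` implements
the full analysis pipeline for quantifying that signal from
fixation-segmented eye-tracking data:

* a data model for labeled fixations, *glances* (same-target fixation runs
  merged across saccade-scale gaps), request episodes, and a plain-text
  on-disk dialect;
* the four-feature representation of each candidate target *c* at time *t*:
  glance count `f1(c,t)`, first-glance dwell `f2(c,t)` (ms), total glance
  dwell `f3(c,t)` (ms), and most-recently-glanced `f4(c,t)` (boolean);
* an RBF-kernel support vector machine classifying candidates as intended
  vs. competing, with Platt-sigmoid calibrated probabilities
  `p(c,t) = P(intended | f1..f4)`, streamed over the episode;
* two prediction policies: the *traditional* policy
  `argmax {p(c,t) : p(c,t) > 0.5}` that abstains when no candidate clears
  the threshold, and the *always-predict* policy `argmax p(c,t)`;
* evaluation machinery: 10-fold cross-validation, classification vs.
  prediction accuracy, abstention and conditional accuracy (which satisfy
  `prediction = (1 − abstention) × conditional`), the *anticipation window*
  (time from the last change in the streamed prediction to speech onset)
  with its begin/end probabilities, the analytic chance band `1/|available|`,
  and a Fisher-score feature ranking;
* detectors for three signaling gaze templates — joint-attention initiation
  (target → partner → target), confirmatory request (partner → target →
  partner), and goal referencing (bread glances adjacent to a target
  glance);
* a seeded synthetic episode generator emulating the behavioral archetypes
  of such interactions (dominant choice, trending choice, two competing,
  multiple choices, no intended glance, and the three templates), since the
  original recordings of this kind of study are typically not deposited.

The intended audience is researchers in human-robot collaboration and
gaze-based interaction who want a reproducible, testable reference
implementation of attention- and SVM-based intent prediction with
anticipation-window evaluation.

## Worked example

```python
from gazeintent import (
    GazeIntentSVM, GeneratorConfig, generate_dataset, filter_episodes,
)

dataset, _ = generate_dataset(GeneratorConfig(n_episodes=276, seed=1))
dataset = filter_episodes(dataset)          # drop episodes >40% missing gaze
res = GazeIntentSVM(dataset, seed=1).fit_cv(k=10)
print(res.summary())
```

prints

```
Gaze-based intent prediction — cross-validated evaluation
==========================================================
episodes: 276    folds: 10    seed: 1
candidate labels: 821

chance band:               4.35% –  11.11%
classification accuracy:  90.74%
attention baseline:       56.16%

policy            accuracy   abstain   conditional   anticipation
----------------------------------------------------------------
traditional        69.57%    26.09%    94.12%       897.1 ms
always-predict     80.07%     0.00%    80.07%      1617.7 ms

always-predict window probabilities (begin/end): correct 0.37/0.82, incorrect 0.36/0.33
```

Reading the table: random guessing would land between 4.35% (23 available
targets) and 11.11% (9 left); the naive attention baseline (predict the
most recently glanced ingredient) reaches 56%; the calibrated SVM labels
90.7% of individual candidates correctly; the abstaining policy predicts
the requested ingredient in 69.6% of episodes (it stays silent in 26.1%,
but is right 94.1% of the time when it does speak), and forcing a
prediction lifts episode accuracy to 80.1% while locking in the correct
answer on average 1.6 s before the spoken request. The window
probabilities say how confident the predictor is when its final answer
first appears (begin) and at speech onset (end), split by whether that
answer was right.

A trained model for new episodes comes from `fit()`:

```python
fitted = GazeIntentSVM(dataset, seed=1).fit()
probs, labels = fitted.classify(episode)     # per-candidate p and ±1
trace = fitted.stream(episode, policy="always")
```

The same pipeline is scriptable from the shell:

```sh
gazeintent simulate --seed 1 --n-episodes 276 --out run/data
gazeintent featurize --data run/data --out run/features.tsv
gazeintent evaluate --data run/data --k 10 --seed 1 --out run/report.json
gazeintent patterns --data run/data --out run/matches.json
gazeintent run --seed 1 --out run/     # all of the above in one go
```

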
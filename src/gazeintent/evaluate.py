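"""Cross-validated evaluation: accuracies, anticipation windows, ranking.

Four notions of performance are distinguished:

* classification accuracy — over per-candidate +1/-1 labels at request
  onset (every glanced ingredient contributes one label);
* prediction accuracy — over episodes, a prediction being correct only when
  it names the requested ingredient (abstention counts as incorrect);
* abstention rate — how often the thresholded policy makes no prediction;
* conditional accuracy — accuracy among the episodes actually predicted.

By construction ``prediction = (1 - abstention) x conditional``.

The anticipation window of an episode runs from the last change in the
streamed prediction to the request onset; its begin/end probabilities are
the final predicted ingredient's probability at the window's endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .events import Dataset, Episode
from .features import FEATURE_NAMES, feature_matrix, candidate_list_at
from .predict import (
    ABSTAIN,
    ClassifierModel,
    PredictionTrace,
    SVMConfig,
    attention_predict,
    classify_episode,
    stream_predict,
    train_svm,
)

__all__ = [
    "CVConfig",
    "PolicyStats",
    "EvalReport",
    "kfold_split",
    "chance_accuracy",
    "anticipation_window",
    "window_probs",
    "feature_ranking",
    "episode_vectors",
    "dataset_vectors",
    "evaluate_dataset",
]


@dataclass
class CVConfig:
    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")


def kfold_split(
    n_episodes: int, k: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded shuffled k-fold partition of episode indices."""
    if k > n_episodes:
        raise ValueError(f"k={k} exceeds number of episodes {n_episodes}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(train, test) for train, test in kf.split(np.arange(n_episodes))]


def chance_accuracy(n_available: int) -> float:
    """Accuracy of a uniform random guess among ``n_available`` targets."""
    if n_available < 1:
        raise ValueError("n_available must be at least 1")
    return 1.0 / n_available


def anticipation_window(trace: PredictionTrace, request_onset_ms: int) -> int | None:
    """Time (ms) from the last prediction change to the request onset.

    A transition into or out of ABSTAIN counts as a change.  If the
    prediction never changes after the first event, the window starts at the
    first event.  Returns None for an empty or all-ABSTAIN trace.
    """
    preds = trace.predictions()
    if not preds or all(p == ABSTAIN for p in preds):
        return None
    t_change = trace.events[0].t_ms
    for i in range(len(preds) - 1, 0, -1):
        if preds[i] != preds[i - 1]:
            t_change = trace.events[i].t_ms
            break
    return request_onset_ms - t_change


def window_probs(
    trace: PredictionTrace, window_ms: int
) -> tuple[float, float] | None:
    """Final predicted ingredient's probability at the window's endpoints.

    The window ends at the trace's final event; returns None when the final
    prediction is ABSTAIN.
    """
    if not trace.events or trace.final == ABSTAIN:
        return None
    end_event = trace.events[-1]
    start_t = end_event.t_ms - window_ms
    inside = [e for e in trace.events if e.t_ms >= start_t]
    ing = trace.final
    begin = inside[0].probs.get(ing, 0.0)
    end = end_event.probs.get(ing, 0.0)
    return float(begin), float(end)


def feature_ranking(
    X: np.ndarray, y: np.ndarray, eps: float = 1e-9
) -> list[tuple[str, float]]:
    """Rank features by a univariate class-separation (Fisher-style) score.

    score = (mean_+ - mean_-)^2 / (var_+ + var_- + eps), computed per
    feature; higher means more discriminative.  Returns (name, score) pairs
    sorted by decreasing score.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pos, neg = X[y == 1], X[y == -1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("feature ranking requires both classes")
    num = (pos.mean(axis=0) - neg.mean(axis=0)) ** 2
    den = pos.var(axis=0) + neg.var(axis=0) + eps
    scores = num / den
    ranked = sorted(zip(FEATURE_NAMES, scores), key=lambda kv: -kv[1])
    return [(name, float(s)) for name, s in ranked]


def episode_vectors(
    episode: Episode, max_gap_ms: int = 200
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Candidate feature matrix, +1/-1 labels, and candidate ids at onset."""
    entries = candidate_list_at(
        episode, episode.request_onset_ms, max_gap_ms=max_gap_ms
    ).entries
    X = feature_matrix(entries)
    ids = list(entries)
    y = np.array(
        [1 if ing == episode.requested else -1 for ing in ids], dtype=int
    )
    return X, y, ids


def dataset_vectors(
    episodes: list[Episode], max_gap_ms: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked candidate vectors and labels over a list of episodes."""
    mats, labs = [], []
    for ep in episodes:
        X, y, _ = episode_vectors(ep, max_gap_ms=max_gap_ms)
        if len(y):
            mats.append(X)
            labs.append(y)
    if not mats:
        return np.empty((0, len(FEATURE_NAMES))), np.empty(0, dtype=int)
    return np.vstack(mats), np.concatenate(labs)


@dataclass
class PolicyStats:
    """Episode-level outcome counts and window statistics for one policy."""

    n_episodes: int = 0
    n_predicted: int = 0
    n_correct: int = 0
    anticipation_correct_ms: list[float] = field(default_factory=list)
    anticipation_incorrect_ms: list[float] = field(default_factory=list)
    begin_probs_correct: list[float] = field(default_factory=list)
    end_probs_correct: list[float] = field(default_factory=list)
    begin_probs_incorrect: list[float] = field(default_factory=list)
    end_probs_incorrect: list[float] = field(default_factory=list)

    @property
    def prediction_accuracy(self) -> float:
        return self.n_correct / self.n_episodes if self.n_episodes else 0.0

    @property
    def abstention_rate(self) -> float:
        if not self.n_episodes:
            return 0.0
        return (self.n_episodes - self.n_predicted) / self.n_episodes

    @property
    def conditional_accuracy(self) -> float:
        return self.n_correct / self.n_predicted if self.n_predicted else 0.0

    @property
    def mean_anticipation_ms(self) -> float | None:
        vals = self.anticipation_correct_ms
        return float(np.mean(vals)) if vals else None

    @property
    def mean_anticipation_incorrect_ms(self) -> float | None:
        vals = self.anticipation_incorrect_ms
        return float(np.mean(vals)) if vals else None

    def window_prob_means(self) -> dict[str, float | None]:
        def m(vals):
            return float(np.mean(vals)) if vals else None

        return {
            "begin_correct": m(self.begin_probs_correct),
            "end_correct": m(self.end_probs_correct),
            "begin_incorrect": m(self.begin_probs_incorrect),
            "end_incorrect": m(self.end_probs_incorrect),
        }

    def observe(
        self,
        predicted: str,
        requested: str,
        window_ms: int | None,
        probs: tuple[float, float] | None,
    ) -> None:
        self.n_episodes += 1
        made = predicted != ABSTAIN
        correct = made and predicted == requested
        if made:
            self.n_predicted += 1
        if correct:
            self.n_correct += 1
        if made and window_ms is not None:
            (self.anticipation_correct_ms if correct
             else self.anticipation_incorrect_ms).append(float(window_ms))
            if probs is not None:
                if correct:
                    self.begin_probs_correct.append(probs[0])
                    self.end_probs_correct.append(probs[1])
                else:
                    self.begin_probs_incorrect.append(probs[0])
                    self.end_probs_incorrect.append(probs[1])

    def merged(self, other: "PolicyStats") -> "PolicyStats":
        return PolicyStats(
            n_episodes=self.n_episodes + other.n_episodes,
            n_predicted=self.n_predicted + other.n_predicted,
            n_correct=self.n_correct + other.n_correct,
            anticipation_correct_ms=self.anticipation_correct_ms
            + other.anticipation_correct_ms,
            anticipation_incorrect_ms=self.anticipation_incorrect_ms
            + other.anticipation_incorrect_ms,
            begin_probs_correct=self.begin_probs_correct
            + other.begin_probs_correct,
            end_probs_correct=self.end_probs_correct + other.end_probs_correct,
            begin_probs_incorrect=self.begin_probs_incorrect
            + other.begin_probs_incorrect,
            end_probs_incorrect=self.end_probs_incorrect
            + other.end_probs_incorrect,
        )

    def to_dict(self) -> dict:
        return {
            "n_episodes": self.n_episodes,
            "prediction_accuracy": self.prediction_accuracy,
            "abstention_rate": self.abstention_rate,
            "conditional_accuracy": self.conditional_accuracy,
            "mean_anticipation_ms": self.mean_anticipation_ms,
            "mean_anticipation_incorrect_ms": self.mean_anticipation_incorrect_ms,
            "window_probs": self.window_prob_means(),
        }


@dataclass
class FoldResult:
    fold: int
    n_test: int
    n_labels: int
    n_labels_correct: int
    traditional: PolicyStats
    always: PolicyStats
    n_attention_correct: int

    @property
    def classification_accuracy(self) -> float:
        return self.n_labels_correct / self.n_labels if self.n_labels else 0.0


@dataclass
class EvalReport:
    """Aggregate + per-fold evaluation of the predictors on a dataset."""

    n_episodes: int
    n_labels: int
    n_labels_correct: int
    traditional: PolicyStats
    always: PolicyStats
    n_attention_correct: int
    chance_band: tuple[float, float]
    folds: list[FoldResult] = field(default_factory=list)
    svm_config: SVMConfig | None = None
    seed: int = 0

    @property
    def classification_accuracy(self) -> float:
        return self.n_labels_correct / self.n_labels if self.n_labels else 0.0

    @property
    def attention_accuracy(self) -> float:
        return (
            self.n_attention_correct / self.n_episodes if self.n_episodes else 0.0
        )

    def to_dict(self) -> dict:
        return {
            "n_episodes": self.n_episodes,
            "seed": self.seed,
            "classification_accuracy": self.classification_accuracy,
            "attention_accuracy": self.attention_accuracy,
            "chance_band": list(self.chance_band),
            "traditional": self.traditional.to_dict(),
            "always": self.always.to_dict(),
            "folds": [
                {
                    "fold": f.fold,
                    "n_test": f.n_test,
                    "classification_accuracy": f.classification_accuracy,
                    "traditional": f.traditional.to_dict(),
                    "always": f.always.to_dict(),
                    "attention_correct": f.n_attention_correct,
                }
                for f in self.folds
            ],
        }


def _evaluate_fold(
    model: ClassifierModel,
    test_episodes: list[Episode],
    fold: int,
    max_gap_ms: int,
) -> FoldResult:
    n_labels = 0
    n_labels_correct = 0
    trad = PolicyStats()
    alw = PolicyStats()
    n_att = 0
    for ep in test_episodes:
        state = candidate_list_at(ep, ep.request_onset_ms, max_gap_ms=max_gap_ms)
        _, labels = classify_episode(model, state.entries)
        for ing, lab in labels.items():
            truth = 1 if ing == ep.requested else -1
            n_labels += 1
            n_labels_correct += int(lab == truth)
        if attention_predict(state) == ep.requested:
            n_att += 1
        for policy, stats_obj in (("traditional", trad), ("always", alw)):
            trace = stream_predict(model, ep, policy=policy, max_gap_ms=max_gap_ms)
            window = anticipation_window(trace, ep.request_onset_ms)
            probs = window_probs(trace, window) if window is not None else None
            stats_obj.observe(trace.final, ep.requested, window, probs)
    return FoldResult(
        fold=fold,
        n_test=len(test_episodes),
        n_labels=n_labels,
        n_labels_correct=n_labels_correct,
        traditional=trad,
        always=alw,
        n_attention_correct=n_att,
    )


def evaluate_dataset(
    dataset: Dataset,
    k: int = 10,
    seed: int = 0,
    svm_config: SVMConfig | None = None,
    max_gap_ms: int = 200,
) -> EvalReport:
    """k-fold cross-validated evaluation of all predictors on a dataset.

    Folds are unstratified seeded episode partitions.  Episodes whose
    candidate list is empty at request onset contribute no classification
    labels but count (as incorrect) toward prediction accuracy.
    """
    episodes = dataset.episodes
    svm_config = svm_config or SVMConfig(seed=seed)
    folds = kfold_split(len(episodes), k, seed=seed)
    fold_results = []
    for fold_no, (train_idx, test_idx) in enumerate(folds):
        X, y = dataset_vectors(
            [episodes[i] for i in train_idx], max_gap_ms=max_gap_ms
        )
        model = train_svm(X, y, svm_config)
        fold_results.append(
            _evaluate_fold(
                model,
                [episodes[i] for i in test_idx],
                fold=fold_no,
                max_gap_ms=max_gap_ms,
            )
        )
    trad = PolicyStats()
    alw = PolicyStats()
    for f in fold_results:
        trad = trad.merged(f.traditional)
        alw = alw.merged(f.always)
    n_avail = [len(ep.available) for ep in episodes] or [1]
    return EvalReport(
        n_episodes=len(episodes),
        n_labels=sum(f.n_labels for f in fold_results),
        n_labels_correct=sum(f.n_labels_correct for f in fold_results),
        traditional=trad,
        always=alw,
        n_attention_correct=sum(f.n_attention_correct for f in fold_results),
        chance_band=(
            chance_accuracy(max(n_avail)),
            chance_accuracy(min(n_avail)),
        ),
        folds=fold_results,
        svm_config=svm_config,
        seed=seed,
    )
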
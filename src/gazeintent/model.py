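"""Model/Results front end for gaze-based intent prediction.

`GazeIntentSVM` is constructed from a :class:`~gazeintent.events.Dataset`
and exposes two fitting paths, in the style of statistical modelling
packages:

* :meth:`GazeIntentSVM.fit` trains the calibrated RBF-SVM on all episodes
  and returns a :class:`GazeIntentResults` for classifying and streaming
  new episodes;
* :meth:`GazeIntentSVM.fit_cv` runs the k-fold cross-validated evaluation
  and returns a :class:`CrossValidationResults` carrying the accuracy,
  abstention, anticipation-window and window-probability estimates, with a
  ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

from .events import Dataset, Episode
from .evaluate import (
    EvalReport,
    dataset_vectors,
    evaluate_dataset,
)
from .predict import (
    ClassifierModel,
    PredictionTrace,
    SVMConfig,
    classify_episode,
    stream_predict,
)
from .features import candidate_list_at

__all__ = ["GazeIntentSVM", "GazeIntentResults", "CrossValidationResults"]


class GazeIntentSVM:
    """Calibrated RBF-SVM intent model over a dataset of gaze episodes.

    Parameters
    ----------
    dataset : Dataset
        Fixation-segmented episodes (typically already filtered for
        missing data).
    C, gamma : float
        RBF-SVM cost and kernel width; defaults are the recorded
        reproducible pair.
    class_weight : {None, "balanced"}
        Optional reweighting against candidate-list class imbalance.
    search : {None, "grid"}
        Replace fixed hyperparameters with an inner 5-fold grid search.
    seed : int
        Drives fold shuffling and probability-calibration internals.
    max_gap_ms : int
        Glance merge threshold used throughout.
    """

    def __init__(
        self,
        dataset: Dataset,
        *,
        C: float | None = None,
        gamma: float | None = None,
        class_weight: str | None = None,
        search: str | None = None,
        seed: int = 0,
        max_gap_ms: int = 200,
    ) -> None:
        self.dataset = dataset
        kwargs = {}
        if C is not None:
            kwargs["C"] = C
        if gamma is not None:
            kwargs["gamma"] = gamma
        self.svm_config = SVMConfig(
            class_weight=class_weight, search=search, seed=seed, **kwargs
        )
        self.seed = seed
        self.max_gap_ms = max_gap_ms

    @classmethod
    def from_files(cls, fixations_path, metadata_path, **kwargs) -> "GazeIntentSVM":
        from .io import read_fixation_table

        return cls(read_fixation_table(fixations_path, metadata_path), **kwargs)

    def fit(self) -> "GazeIntentResults":
        """Train on all episodes; returns a results object for prediction."""
        from .predict import train_svm

        X, y = dataset_vectors(self.dataset.episodes, max_gap_ms=self.max_gap_ms)
        model = train_svm(X, y, self.svm_config)
        return GazeIntentResults(model=model, parent=self)

    def fit_cv(self, k: int = 10) -> "CrossValidationResults":
        """k-fold cross-validated evaluation of all predictors."""
        report = evaluate_dataset(
            self.dataset,
            k=k,
            seed=self.seed,
            svm_config=self.svm_config,
            max_gap_ms=self.max_gap_ms,
        )
        return CrossValidationResults(report=report, parent=self)


@dataclass
class GazeIntentResults:
    """A trained intent classifier bound to its source model."""

    model: ClassifierModel
    parent: GazeIntentSVM

    def classify(self, episode: Episode) -> tuple[dict[str, float], dict[str, int]]:
        """Per-candidate probabilities and +1/-1 labels at request onset."""
        entries = candidate_list_at(
            episode, episode.request_onset_ms, max_gap_ms=self.parent.max_gap_ms
        ).entries
        return classify_episode(self.model, entries)

    def stream(self, episode: Episode, policy: str = "always") -> PredictionTrace:
        return stream_predict(
            self.model, episode, policy=policy, max_gap_ms=self.parent.max_gap_ms
        )

    def predict(self, episode: Episode, policy: str = "always") -> str:
        """Final prediction (ingredient id or ABSTAIN) for one episode."""
        return self.stream(episode, policy=policy).final

    def plot_trace(self, episode: Episode, policy: str = "always", ax=None):
        """Probability time course of each candidate plus the gaze sequence.

        Requires matplotlib (optional dependency).
        """
        import matplotlib.pyplot as plt

        trace = self.stream(episode, policy=policy)
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        candidates = list(trace.events[-1].probs) if trace.events else []
        for ing in candidates:
            ts = [e.t_ms for e in trace.events if ing in e.probs]
            ps = [e.probs[ing] for e in trace.events if ing in e.probs]
            ax.step(ts, ps, where="post", label=ing)
        ax.axvline(episode.request_onset_ms, ls="--", c="k", lw=0.8)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("P(intended)")
        ax.set_ylim(0, 1)
        ax.legend(fontsize=7, ncol=2)
        return ax


def _pct(x: float) -> str:
    return f"{100.0 * x:6.2f}%"


@dataclass
class CrossValidationResults:
    """Cross-validated performance estimates with a printable summary."""

    report: EvalReport
    parent: GazeIntentSVM

    def summary(self) -> str:
        r = self.report
        trad, alw = r.traditional, r.always
        lines = [
            "Gaze-based intent prediction — cross-validated evaluation",
            "=" * 58,
            f"episodes: {r.n_episodes}    folds: {len(r.folds)}    seed: {r.seed}",
            f"candidate labels: {r.n_labels}",
            "",
            f"chance band:             {_pct(r.chance_band[0])} – {_pct(r.chance_band[1])}",
            f"classification accuracy: {_pct(r.classification_accuracy)}",
            f"attention baseline:      {_pct(r.attention_accuracy)}",
            "",
            "policy            accuracy   abstain   conditional   anticipation",
            "-" * 64,
        ]
        for name, st in (("traditional", trad), ("always-predict", alw)):
            ant = st.mean_anticipation_ms
            ant_s = f"{ant:9.1f} ms" if ant is not None else "      n/a"
            lines.append(
                f"{name:<16}  {_pct(st.prediction_accuracy)}   "
                f"{_pct(st.abstention_rate)}   {_pct(st.conditional_accuracy)}   {ant_s}"
            )
        wp = alw.window_prob_means()

        def fmt(v):
            return f"{v:.2f}" if v is not None else "n/a"

        lines += [
            "",
            "always-predict window probabilities "
            f"(begin/end): correct {fmt(wp['begin_correct'])}/{fmt(wp['end_correct'])}, "
            f"incorrect {fmt(wp['begin_incorrect'])}/{fmt(wp['end_incorrect'])}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return self.report.to_dict()
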
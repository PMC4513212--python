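"""Per-candidate glance features, maintained as fixations stream in.

For every ingredient glanced at so far in an episode, four features summarize
the gaze evidence up to the current time:

f1  number of glances toward the ingredient,
f2  dwell (ms) of the first glance toward it,
f3  total dwell (ms) over all its glances,
f4  whether it is the most recently glanced-at ingredient.

Features are computed over *glances* (merged fixations) rather than raw
fixations, so tracker jitter does not inflate the counts, and they reset at
episode boundaries.  Recency (f4) transfers only when a *different*
ingredient is glanced at; looking at the bread, the partner or elsewhere
leaves it untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .events import (
    DEFAULT_GLANCE_GAP_MS,
    Episode,
    FixationEvent,
    Glance,
    TargetKind,
    segment_glances,
)

__all__ = [
    "FEATURE_NAMES",
    "CandidateFeatures",
    "CandidateList",
    "update_candidates",
    "candidate_list_at",
    "features_at",
    "feature_vector",
    "feature_matrix",
    "FeatureScaler",
    "scale_features",
]

FEATURE_NAMES = (
    "f1_glance_count",
    "f2_first_glance_ms",
    "f3_total_glance_ms",
    "f4_most_recent",
)


@dataclass(frozen=True)
class CandidateFeatures:
    f1_glance_count: int
    f2_first_glance_ms: float
    f3_total_glance_ms: float
    f4_most_recent: bool


@dataclass
class CandidateList:
    """Live per-ingredient feature state for one streaming episode.

    ``entries`` preserves insertion order (first-glanced first), which the
    prediction policies use as their deterministic tie-break.
    """

    entries: dict[str, CandidateFeatures] = field(default_factory=dict)
    last_ingredient: str | None = None
    clock_ms: int = 0


def update_candidates(state: CandidateList, glance: Glance) -> CandidateList:
    """Fold one completed glance into the candidate list (functional).

    Ingredient glances create or update their entry; all other glances only
    advance the clock.  Raises ValueError on out-of-order input.
    """
    if glance.onset_ms < state.clock_ms:
        raise ValueError(
            f"glance at {glance.onset_ms} precedes stream clock {state.clock_ms}"
        )
    entries = dict(state.entries)
    last = state.last_ingredient
    if glance.target.kind is TargetKind.INGREDIENT:
        ing = glance.target.ingredient_id
        prev = entries.get(ing)
        if prev is None:
            entries[ing] = CandidateFeatures(
                f1_glance_count=1,
                f2_first_glance_ms=float(glance.dwell_ms),
                f3_total_glance_ms=float(glance.dwell_ms),
                f4_most_recent=True,
            )
        else:
            entries[ing] = replace(
                prev,
                f1_glance_count=prev.f1_glance_count + 1,
                f3_total_glance_ms=prev.f3_total_glance_ms + glance.dwell_ms,
                f4_most_recent=True,
            )
        if last is not None and last != ing:
            entries[last] = replace(entries[last], f4_most_recent=False)
        last = ing
    return CandidateList(
        entries=entries, last_ingredient=last, clock_ms=glance.offset_ms
    )


def _clip_fixations(episode: Episode, t_ms: int) -> list[FixationEvent]:
    clipped = []
    for fix in episode.fixations:
        if fix.onset_ms >= t_ms:
            break
        clipped.append(
            fix
            if fix.offset_ms <= t_ms
            else FixationEvent(fix.onset_ms, t_ms, fix.target)
        )
    return clipped


def candidate_list_at(
    episode: Episode, t_ms: int, max_gap_ms: int = DEFAULT_GLANCE_GAP_MS
) -> CandidateList:
    """Candidate list after observing the episode up to time ``t_ms``.

    Glances straddling ``t_ms`` are clipped there, so a partially observed
    glance contributes its partial dwell (including to f2 if it is the
    candidate's first).
    """
    if not 0 <= t_ms <= episode.request_onset_ms:
        raise ValueError(
            f"t_ms {t_ms} outside [0, {episode.request_onset_ms}]"
        )
    truncated = Episode(
        episode_id=episode.episode_id,
        fixations=_clip_fixations(episode, t_ms),
        request_onset_ms=episode.request_onset_ms,
        requested=episode.requested,
        available=episode.available,
    )
    state = CandidateList()
    for glance in segment_glances(truncated, max_gap_ms=max_gap_ms):
        state = update_candidates(state, glance)
    return state


def features_at(
    episode: Episode, t_ms: int, max_gap_ms: int = DEFAULT_GLANCE_GAP_MS
) -> dict[str, CandidateFeatures]:
    """Per-ingredient features at time ``t_ms`` (insertion-ordered dict)."""
    return candidate_list_at(episode, t_ms, max_gap_ms=max_gap_ms).entries


def feature_vector(f: CandidateFeatures) -> np.ndarray:
    return np.array(
        [
            f.f1_glance_count,
            f.f2_first_glance_ms,
            f.f3_total_glance_ms,
            1.0 if f.f4_most_recent else 0.0,
        ],
        dtype=float,
    )


def feature_matrix(entries: dict[str, CandidateFeatures]) -> np.ndarray:
    """Stack candidate feature vectors row-wise, in insertion order."""
    if not entries:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.vstack([feature_vector(f) for f in entries.values()])


class FeatureScaler:
    """Affine min-max scaling fitted on a training fold only.

    Maps each training column onto [0, 1]; values outside the training range
    extrapolate linearly (no clipping).  A constant training column maps to 0
    for every input, seen or unseen.  Already-scaled training data is a fixed
    point.
    """

    def __init__(self) -> None:
        self.min_: np.ndarray | None = None
        self.range_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("cannot fit scaler on empty training data")
        self.min_ = X.min(axis=0)
        self.range_ = X.max(axis=0) - self.min_
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.min_ is None:
            raise ValueError("scaler not fitted")
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            return X.reshape(0, self.min_.shape[0])
        out = X - self.min_
        nonconst = self.range_ > 0
        out[:, nonconst] /= self.range_[nonconst]
        out[:, ~nonconst] = 0.0
        return out

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def scale_features(train_vectors: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    """Fit min-max scaling on ``train_vectors`` and apply it to ``vectors``."""
    return FeatureScaler().fit(train_vectors).transform(vectors)
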
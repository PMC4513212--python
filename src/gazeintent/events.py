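"""Core data model for fixation-segmented gaze episodes.

An *episode* is the stretch of pre-request interaction ending at the onset of
a spoken request for one target (here: a sandwich ingredient).  Gaze comes in
as a time-ordered sequence of labeled fixations; analysis works on *glances*,
maximal runs of same-target fixations merged across saccade-scale gaps.

Time is integer milliseconds throughout and intervals are half-open
``[onset_ms, offset_ms)``, which avoids double counting at boundaries; the
30 Hz provenance of typical mobile-tracker exports makes sub-millisecond
precision meaningless.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "TargetKind",
    "TargetLabel",
    "FixationEvent",
    "Glance",
    "Episode",
    "Dataset",
    "ValidationError",
    "DEFAULT_GLANCE_GAP_MS",
    "segment_glances",
    "missing_fraction",
    "filter_episodes",
]

#: Maximum uncovered / short-dropout interruption (ms) bridged when merging
#: same-target fixations into one glance.  Saccade-scale by convention.
DEFAULT_GLANCE_GAP_MS = 200


class ValidationError(ValueError):
    """Raised when gaze data violates the episode data model."""


class TargetKind(str, enum.Enum):
    """What a fixation rested on."""

    INGREDIENT = "INGREDIENT"
    BREAD = "BREAD"
    PARTNER = "PARTNER"
    ELSEWHERE = "ELSEWHERE"
    MISSING = "MISSING"


@dataclass(frozen=True)
class TargetLabel:
    """A fixation target: a selectable ingredient or one of the fixed roles.

    ``ingredient_id`` is non-empty iff ``kind`` is INGREDIENT.
    """

    kind: TargetKind
    ingredient_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind is TargetKind.INGREDIENT:
            if not self.ingredient_id:
                raise ValidationError("INGREDIENT target requires ingredient_id")
        elif self.ingredient_id is not None:
            raise ValidationError(
                f"{self.kind.value} target must not carry ingredient_id"
            )

    @staticmethod
    def ingredient(ingredient_id: str) -> "TargetLabel":
        return TargetLabel(TargetKind.INGREDIENT, ingredient_id)


# Singletons for the non-ingredient targets; cheap and convenient.
BREAD = TargetLabel(TargetKind.BREAD)
PARTNER = TargetLabel(TargetKind.PARTNER)
ELSEWHERE = TargetLabel(TargetKind.ELSEWHERE)
MISSING = TargetLabel(TargetKind.MISSING)


@dataclass(frozen=True)
class FixationEvent:
    """One labeled gaze interval ``[onset_ms, offset_ms)``."""

    onset_ms: int
    offset_ms: int
    target: TargetLabel

    def __post_init__(self) -> None:
        if self.onset_ms < 0:
            raise ValidationError(f"negative onset {self.onset_ms}")
        if self.offset_ms <= self.onset_ms:
            raise ValidationError(
                f"fixation offset {self.offset_ms} <= onset {self.onset_ms}"
            )

    @property
    def duration_ms(self) -> int:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class Glance:
    """A maximal run of same-target fixations merged across short gaps.

    ``dwell_ms`` is the summed duration of the constituent fixations; it can
    be smaller than the span ``offset_ms - onset_ms`` when the glance bridges
    uncovered gaps or short tracker dropouts.  Dwell, not span, is what the
    duration features accumulate.
    """

    onset_ms: int
    offset_ms: int
    target: TargetLabel
    n_fixations: int
    dwell_ms: int

    @property
    def duration_ms(self) -> int:
        return self.offset_ms - self.onset_ms


@dataclass
class Episode:
    """Pre-request gaze for one ingredient request.

    Parameters
    ----------
    episode_id : str
        Unique identifier within a dataset.
    fixations : list of FixationEvent
        Time-ordered, non-overlapping, all ending at or before
        ``request_onset_ms``.
    request_onset_ms : int
        Onset of the spoken request; the episode's clock runs over
        ``[0, request_onset_ms)``.
    requested : str
        Ground-truth requested ingredient; must be in ``available``.
    available : set of str
        Ingredients selectable at this point of the interaction.
    """

    episode_id: str
    fixations: list[FixationEvent]
    request_onset_ms: int
    requested: str
    available: frozenset[str]

    def __post_init__(self) -> None:
        self.available = frozenset(self.available)
        self.validate()

    def validate(self) -> None:
        if not self.episode_id:
            raise ValidationError("empty episode_id")
        if self.request_onset_ms <= 0:
            raise ValidationError(
                f"episode {self.episode_id}: request_onset_ms must be positive"
            )
        if not 1 <= len(self.available) <= 23:
            raise ValidationError(
                f"episode {self.episode_id}: |available| must be in [1, 23], "
                f"got {len(self.available)}"
            )
        if self.requested not in self.available:
            raise ValidationError(
                f"episode {self.episode_id}: requested {self.requested!r} "
                "not in available set"
            )
        prev_offset = 0
        for fix in self.fixations:
            if fix.onset_ms < prev_offset:
                raise ValidationError(
                    f"episode {self.episode_id}: fixation at {fix.onset_ms} "
                    f"overlaps or precedes previous offset {prev_offset}"
                )
            if fix.offset_ms > self.request_onset_ms:
                raise ValidationError(
                    f"episode {self.episode_id}: fixation ending {fix.offset_ms} "
                    f"exceeds request onset {self.request_onset_ms}"
                )
            if (
                fix.target.kind is TargetKind.INGREDIENT
                and fix.target.ingredient_id not in self.available
            ):
                raise ValidationError(
                    f"episode {self.episode_id}: fixation target "
                    f"{fix.target.ingredient_id!r} not in available set"
                )
            prev_offset = fix.offset_ms

    @property
    def duration_ms(self) -> int:
        return self.request_onset_ms


@dataclass
class Dataset:
    """A collection of episodes plus free-text provenance (incl. seed)."""

    episodes: list[Episode]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [e.episode_id for e in self.episodes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate episode ids: {dupes}")

    def __len__(self) -> int:
        return len(self.episodes)

    def __iter__(self):
        return iter(self.episodes)


def segment_glances(
    episode: Episode, max_gap_ms: int = DEFAULT_GLANCE_GAP_MS
) -> list[Glance]:
    """Merge an episode's fixations into glances.

    Two same-target fixations join the same glance when the time between them
    is at most ``max_gap_ms`` and contains only uncovered time and/or MISSING
    fixations (short tracker dropouts are bridged; a fixation on any other
    real target breaks the run).  MISSING fixations themselves merge into
    MISSING glances by the plain gap rule.

    The glance list covers the merged fixations in order; consecutive glances
    either differ in target or are separated by an uncovered gap exceeding
    ``max_gap_ms``.
    """
    fixes = episode.fixations
    n = len(fixes)
    glances: list[Glance] = []
    consumed = [False] * n
    i = 0
    while i < n:
        if consumed[i]:
            i += 1
            continue
        first = fixes[i]
        target = first.target
        offset = first.offset_ms
        n_fix = 1
        dwell = first.duration_ms
        consumed[i] = True
        e = i  # index of last merged fixation
        if target.kind is TargetKind.MISSING:
            j = e + 1
            while (
                j < n
                and fixes[j].target.kind is TargetKind.MISSING
                and fixes[j].onset_ms - offset <= max_gap_ms
            ):
                offset = fixes[j].offset_ms
                dwell += fixes[j].duration_ms
                n_fix += 1
                consumed[j] = True
                j += 1
        else:
            while True:
                j = e + 1
                skipped = []
                while j < n and fixes[j].target.kind is TargetKind.MISSING:
                    skipped.append(j)
                    j += 1
                if (
                    j < n
                    and fixes[j].target == target
                    and fixes[j].onset_ms - offset <= max_gap_ms
                ):
                    offset = fixes[j].offset_ms
                    dwell += fixes[j].duration_ms
                    n_fix += 1
                    for s in skipped:
                        consumed[s] = True
                    consumed[j] = True
                    e = j
                else:
                    break
        glances.append(
            Glance(
                onset_ms=first.onset_ms,
                offset_ms=offset,
                target=target,
                n_fixations=n_fix,
                dwell_ms=dwell,
            )
        )
        i += 1
    glances.sort(key=lambda g: g.onset_ms)
    return glances


def missing_fraction(episode: Episode) -> float:
    """Fraction of ``[0, request_onset_ms)`` with no usable gaze.

    Counts both explicit MISSING fixations and uncovered time: tracker
    dropout shows up both ways in real exports and the two are
    indistinguishable for exclusion purposes.
    """
    if episode.request_onset_ms <= 0:
        raise ValidationError(
            f"episode {episode.episode_id}: degenerate request_onset_ms"
        )
    covered_real = sum(
        f.duration_ms
        for f in episode.fixations
        if f.target.kind is not TargetKind.MISSING
    )
    return (episode.request_onset_ms - covered_real) / episode.request_onset_ms


def filter_episodes(dataset: Dataset, max_missing: float = 0.40) -> Dataset:
    """Drop episodes with *more than* ``max_missing`` of their gaze missing.

    The boundary is strict: an episode with exactly the threshold fraction is
    retained.  Returns a new Dataset; provenance records the counts.
    """
    kept = [e for e in dataset.episodes if missing_fraction(e) <= max_missing]
    provenance = dict(dataset.provenance)
    provenance["filter"] = {
        "max_missing": max_missing,
        "n_before": len(dataset.episodes),
        "n_after": len(kept),
    }
    return Dataset(episodes=kept, provenance=provenance)
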
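"""Template detectors for signaling gaze sequences.

Three sequence templates carry communicative meaning beyond the summary
features and are reported as annotations (they do not feed the predictor):

* joint-attention initiation — ingredient X, partner, same X;
* confirmatory request — partner, single ingredient X, partner;
* goal referencing — a glance at the bread adjacent to an ingredient glance.

Detection is pure sequence matching over the glance list.  Each hop of the
two alternating templates tolerates at most one intervening ELSEWHERE or
MISSING glance (tracker noise); BREAD is never a tolerated gap since it is
itself meaningful.  Reversing a glance sequence maps joint-attention matches
onto confirmatory matches and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass

from .events import Episode, Glance, TargetKind, segment_glances

__all__ = [
    "TemplateMatch",
    "detect_joint_attention",
    "detect_confirmatory",
    "detect_goal_reference",
    "detect_all",
]

JOINT_ATTENTION_INITIATION = "JOINT_ATTENTION_INITIATION"
CONFIRMATORY_REQUEST = "CONFIRMATORY_REQUEST"
GOAL_REFERENCE = "GOAL_REFERENCE"


@dataclass(frozen=True)
class TemplateMatch:
    pattern: str
    onset_ms: int
    offset_ms: int
    focal_ingredient: str | None


def _is_gap(glance: Glance) -> bool:
    return glance.target.kind in (TargetKind.ELSEWHERE, TargetKind.MISSING)


def _hop(glances: list[Glance], i: int, step: int, max_gap_glances: int) -> int | None:
    """Index of the next non-gap glance from ``i`` in direction ``step``,
    tolerating at most ``max_gap_glances`` gap glances; None if none."""
    j = i + step
    skipped = 0
    while 0 <= j < len(glances) and _is_gap(glances[j]):
        skipped += 1
        if skipped > max_gap_glances:
            return None
        j += step
    if 0 <= j < len(glances):
        return j
    return None


def detect_joint_attention(
    glances: list[Glance], max_gap_glances: int = 1
) -> list[TemplateMatch]:
    """Find every ingredient X -> PARTNER -> same X subsequence."""
    matches = []
    for i, g in enumerate(glances):
        if g.target.kind is not TargetKind.PARTNER:
            continue
        b = _hop(glances, i, -1, max_gap_glances)
        a = _hop(glances, i, +1, max_gap_glances)
        if b is None or a is None:
            continue
        gb, ga = glances[b], glances[a]
        if (
            gb.target.kind is TargetKind.INGREDIENT
            and gb.target == ga.target
        ):
            matches.append(
                TemplateMatch(
                    pattern=JOINT_ATTENTION_INITIATION,
                    onset_ms=gb.onset_ms,
                    offset_ms=ga.offset_ms,
                    focal_ingredient=gb.target.ingredient_id,
                )
            )
    return matches


def detect_confirmatory(
    glances: list[Glance], max_gap_glances: int = 1
) -> list[TemplateMatch]:
    """Find every PARTNER -> single ingredient X -> PARTNER subsequence."""
    matches = []
    for i, g in enumerate(glances):
        if g.target.kind is not TargetKind.INGREDIENT:
            continue
        b = _hop(glances, i, -1, max_gap_glances)
        a = _hop(glances, i, +1, max_gap_glances)
        if b is None or a is None:
            continue
        if (
            glances[b].target.kind is TargetKind.PARTNER
            and glances[a].target.kind is TargetKind.PARTNER
        ):
            matches.append(
                TemplateMatch(
                    pattern=CONFIRMATORY_REQUEST,
                    onset_ms=glances[b].onset_ms,
                    offset_ms=glances[a].offset_ms,
                    focal_ingredient=g.target.ingredient_id,
                )
            )
    return matches


def detect_goal_reference(
    glances: list[Glance], radius: int = 2
) -> list[TemplateMatch]:
    """Report every BREAD glance within ``radius`` glances of an ingredient.

    The focal ingredient is the nearest anchored ingredient glance (earlier
    one preferred on ties); a BREAD glance with no ingredient in range
    yields no match.
    """
    matches = []
    for i, g in enumerate(glances):
        if g.target.kind is not TargetKind.BREAD:
            continue
        anchor = None
        best_dist = radius + 1
        for j in range(max(0, i - radius), min(len(glances), i + radius + 1)):
            if j == i:
                continue
            if glances[j].target.kind is TargetKind.INGREDIENT:
                dist = abs(j - i)
                if dist < best_dist or (dist == best_dist and j < i):
                    anchor, best_dist = j, dist
        if anchor is None:
            continue
        lo, hi = min(i, anchor), max(i, anchor)
        matches.append(
            TemplateMatch(
                pattern=GOAL_REFERENCE,
                onset_ms=glances[lo].onset_ms,
                offset_ms=glances[hi].offset_ms,
                focal_ingredient=glances[anchor].target.ingredient_id,
            )
        )
    return matches


def detect_all(episode: Episode, max_gap_ms: int = 200) -> list[TemplateMatch]:
    """All template matches in an episode, ordered by onset."""
    glances = segment_glances(episode, max_gap_ms=max_gap_ms)
    matches = (
        detect_joint_attention(glances)
        + detect_confirmatory(glances)
        + detect_goal_reference(glances)
    )
    return sorted(matches, key=lambda m: (m.onset_ms, m.pattern))
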
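"""On-disk dialect for fixation-segmented episodes.

Two plain-text files describe a dataset:

* a UTF-8 tab-separated fixation table with header
  ``episode_id  onset_ms  offset_ms  target_kind  ingredient_id``
  (one row per fixation, ``ingredient_id`` empty unless the kind is
  INGREDIENT), and
* an episode-metadata JSON array of objects
  ``{"episode_id", "request_onset_ms", "requested", "available": [...]}``.

Writing is byte-stable under a fixed column order so that serialized datasets
can be diffed and hashed.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .events import (
    Dataset,
    Episode,
    FixationEvent,
    TargetKind,
    TargetLabel,
    ValidationError,
)

__all__ = ["read_fixation_table", "write_fixation_table", "FIXATION_COLUMNS"]

FIXATION_COLUMNS = (
    "episode_id",
    "onset_ms",
    "offset_ms",
    "target_kind",
    "ingredient_id",
)


class ParseError(ValueError):
    """Raised for malformed rows in the fixation dialect."""


def _row_target(kind: str, ingredient_id: str, row_no: int) -> TargetLabel:
    try:
        tk = TargetKind(kind)
    except ValueError as exc:
        raise ParseError(f"row {row_no}: unknown target_kind {kind!r}") from exc
    if tk is TargetKind.INGREDIENT:
        if not ingredient_id:
            raise ParseError(f"row {row_no}: INGREDIENT row lacks ingredient_id")
        return TargetLabel.ingredient(ingredient_id)
    if ingredient_id:
        raise ParseError(
            f"row {row_no}: ingredient_id set on {tk.value} row"
        )
    return TargetLabel(tk)


def read_fixation_table(path: str | Path, metadata_path: str | Path) -> Dataset:
    """Read the fixation table + episode metadata into a validated Dataset.

    Raises :class:`ParseError` naming the offending row for malformed input
    and :class:`~gazeintent.events.ValidationError` naming the episode for
    data-model violations (overlaps, bad intervals, unknown targets).
    """
    path, metadata_path = Path(path), Path(metadata_path)
    with open(metadata_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    table = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
    )
    missing_cols = set(FIXATION_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ParseError(f"fixation table lacks columns {sorted(missing_cols)}")

    by_episode: dict[str, list[FixationEvent]] = {}
    for idx, row in enumerate(table.itertuples(index=False)):
        row_no = idx + 2  # 1-based, after the header line
        try:
            onset = int(row.onset_ms)
            offset = int(row.offset_ms)
        except ValueError as exc:
            raise ParseError(f"row {row_no}: non-integer onset/offset") from exc
        target = _row_target(row.target_kind, row.ingredient_id, row_no)
        try:
            fix = FixationEvent(onset_ms=onset, offset_ms=offset, target=target)
        except ValidationError as exc:
            raise ValidationError(f"row {row_no}: {exc}") from exc
        by_episode.setdefault(row.episode_id, []).append(fix)

    episodes = []
    for entry in meta:
        eid = entry["episode_id"]
        episodes.append(
            Episode(
                episode_id=eid,
                fixations=by_episode.pop(eid, []),
                request_onset_ms=int(entry["request_onset_ms"]),
                requested=entry["requested"],
                available=frozenset(entry["available"]),
            )
        )
    if by_episode:
        raise ParseError(
            f"fixation rows for episodes missing from metadata: "
            f"{sorted(by_episode)}"
        )
    provenance = {"source": str(path)}
    return Dataset(episodes=episodes, provenance=provenance)


def write_fixation_table(
    dataset: Dataset, path: str | Path, metadata_path: str | Path
) -> None:
    """Serialize a Dataset to the fixation dialect (byte-stable)."""
    rows = []
    for ep in dataset.episodes:
        for fix in ep.fixations:
            rows.append(
                (
                    ep.episode_id,
                    fix.onset_ms,
                    fix.offset_ms,
                    fix.target.kind.value,
                    fix.target.ingredient_id or "",
                )
            )
    table = pd.DataFrame(rows, columns=list(FIXATION_COLUMNS))
    table.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")
    meta = [
        {
            "episode_id": ep.episode_id,
            "request_onset_ms": ep.request_onset_ms,
            "requested": ep.requested,
            "available": sorted(ep.available),
        }
        for ep in dataset.episodes
    ]
    with open(metadata_path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
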
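"""Shared fixtures and episode builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from gazeintent.events import (
    BREAD,
    ELSEWHERE,
    MISSING,
    PARTNER,
    Dataset,
    Episode,
    FixationEvent,
    TargetLabel,
)
from gazeintent.synth import GeneratorConfig, generate_dataset

SPECIALS = {
    "BREAD": BREAD,
    "PARTNER": PARTNER,
    "ELSEWHERE": ELSEWHERE,
    "MISSING": MISSING,
}


def target(name: str) -> TargetLabel:
    """'BREAD'/'PARTNER'/'ELSEWHERE'/'MISSING' or an ingredient id."""
    return SPECIALS.get(name, TargetLabel.ingredient(name))


def fixation(onset: int, offset: int, name: str) -> FixationEvent:
    return FixationEvent(onset, offset, target(name))


def make_episode(
    fixspecs,
    request_onset_ms=None,
    requested="A",
    available=None,
    episode_id="ep1",
) -> Episode:
    """Build an episode from (onset, offset, target-name) triples."""
    fixes = [fixation(*triple) for triple in fixspecs]
    if request_onset_ms is None:
        request_onset_ms = max((f.offset_ms for f in fixes), default=0) + 100
    if available is None:
        ingredients = {
            f.target.ingredient_id
            for f in fixes
            if f.target.ingredient_id is not None
        }
        available = ingredients | {requested}
    return Episode(
        episode_id=episode_id,
        fixations=fixes,
        request_onset_ms=request_onset_ms,
        requested=requested,
        available=frozenset(available),
    )


def random_episode(rng: np.random.Generator, episode_id="r1") -> Episode:
    """Random valid episode with gaps, dropouts and repeated targets."""
    names = ["A", "B", "C", "PARTNER", "ELSEWHERE", "MISSING", "BREAD"]
    t = int(rng.integers(0, 100))
    fixes = []
    for _ in range(int(rng.integers(1, 25))):
        dur = int(rng.integers(1, 500))
        fixes.append((t, t + dur, names[int(rng.integers(len(names)))]))
        t += dur + int(rng.integers(0, 350))
    onset = fixes[-1][1] + int(rng.integers(0, 200))
    return make_episode(
        fixspecs=fixes,
        request_onset_ms=max(onset, 1),
        requested="A",
        available={"A", "B", "C"},
        episode_id=episode_id,
    )


def no_nointended_mixture() -> dict[str, float]:
    mix = {
        k: v
        for k, v in GeneratorConfig().archetype_mixture.items()
        if k != "NO_INTENDED_GLANCE"
    }
    s = sum(mix.values())
    return {k: v / s for k, v in mix.items()}


@pytest.fixture(scope="session")
def default_dataset_276() -> tuple[Dataset, list[dict]]:
    """Default study conditions: 276 mixed-archetype episodes, seed 1."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def matchrate_dataset_1000() -> tuple[Dataset, list[dict]]:
    """1000 episodes, p=0.65 final-glance match, archetypes where the
    requested target is glanced at (the match rate is enforceable)."""
    cfg = GeneratorConfig(
        n_episodes=1000,
        seed=3,
        archetype_mixture=no_nointended_mixture(),
        last_glance_match_rate=0.65,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    """60 quick episodes for model-fitting tests."""
    ds, _ = generate_dataset(GeneratorConfig(n_episodes=60, seed=11))
    return ds


@pytest.fixture(scope="session")
def small_model(small_dataset):
    from gazeintent.evaluate import dataset_vectors
    from gazeintent.predict import SVMConfig, train_svm

    X, y = dataset_vectors(small_dataset.episodes)
    return train_svm(X, y, SVMConfig(seed=0))
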
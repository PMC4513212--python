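"""Glance segmentation, missing-data accounting, and episode filtering."""

import numpy as np
import pytest

from gazeintent.events import (
    Dataset,
    TargetKind,
    ValidationError,
    filter_episodes,
    missing_fraction,
    segment_glances,
)

from conftest import fixation, make_episode, random_episode


class TestSegmentGlances:
    def test_merges_same_target_across_short_gap(self):
        ep = make_episode([(0, 300, "A"), (320, 600, "A"), (700, 900, "B")])
        glances = segment_glances(ep)
        assert [(g.target.ingredient_id, g.onset_ms, g.offset_ms) for g in glances] == [
            ("A", 0, 600),
            ("B", 700, 900),
        ]
        assert glances[0].n_fixations == 2
        assert glances[0].dwell_ms == 580  # gap time is not dwell

    def test_single_fixation_is_identity(self):
        ep = make_episode([(10, 250, "A")])
        (g,) = segment_glances(ep)
        assert (g.onset_ms, g.offset_ms, g.n_fixations, g.dwell_ms) == (10, 250, 1, 240)

    def test_bridges_short_missing_dropout(self):
        ep = make_episode([(0, 300, "A"), (310, 400, "MISSING"), (450, 600, "A")])
        glances = segment_glances(ep)
        assert len(glances) == 1
        g = glances[0]
        assert g.target.ingredient_id == "A"
        assert (g.onset_ms, g.offset_ms, g.n_fixations, g.dwell_ms) == (0, 600, 2, 450)

    def test_long_gap_splits_same_target(self):
        ep = make_episode([(0, 300, "A"), (600, 900, "A")])
        glances = segment_glances(ep)
        assert len(glances) == 2
        assert all(g.target.ingredient_id == "A" for g in glances)

    def test_real_target_breaks_merge(self):
        ep = make_episode([(0, 300, "A"), (310, 400, "B"), (410, 600, "A")])
        assert len(segment_glances(ep)) == 3

    def test_long_missing_not_bridged(self):
        ep = make_episode([(0, 300, "A"), (310, 700, "MISSING"), (710, 900, "A")])
        glances = segment_glances(ep)
        kinds = [g.target for g in glances]
        assert len(glances) == 3
        assert kinds[1].kind is TargetKind.MISSING

    @pytest.mark.parametrize("seed", range(30))
    def test_random_episode_properties(self, seed):
        """Dwell conservation, refined adjacency, and idempotence."""
        ep = random_episode(np.random.default_rng(seed))
        glances = segment_glances(ep)
        # per-target dwell equals brute-force fixation duration sums
        dwell = {}
        for g in glances:
            dwell[g.target] = dwell.get(g.target, 0) + g.dwell_ms
        brute = {}
        for f in ep.fixations:
            brute[f.target] = brute.get(f.target, 0) + f.duration_ms
        assert dwell == brute
        # adjacent glances differ in target unless split by a long gap
        for a, b in zip(glances, glances[1:]):
            assert a.target != b.target or b.onset_ms - a.offset_ms > 200
        # total dwell bounded by episode duration
        assert sum(g.dwell_ms for g in glances) <= ep.request_onset_ms
        # idempotence: re-segmenting glances-as-fixations keeps the spans
        respecs = [(g.onset_ms, g.offset_ms, g.target) for g in glances]
        ep2 = make_episode(
            [],
            request_onset_ms=ep.request_onset_ms,
            requested="A",
            available={"A", "B", "C"},
        )
        from gazeintent.events import FixationEvent

        ep2.fixations = [FixationEvent(o, f, t) for o, f, t in respecs]
        again = segment_glances(ep2)
        assert [(g.onset_ms, g.offset_ms, g.target) for g in again] == respecs


class TestMissingFraction:
    def test_fully_covered_is_zero(self):
        ep = make_episode([(0, 400, "A"), (400, 1000, "B")], request_onset_ms=1000)
        assert missing_fraction(ep) == 0.0

    def test_missing_plus_uncovered(self):
        # MISSING [0,500) plus uncovered [500,1000) -> everything missing
        ep = make_episode([(0, 500, "MISSING")], request_onset_ms=1000)
        assert missing_fraction(ep) == 1.0

    def test_partial(self):
        ep = make_episode(
            [(0, 400, "MISSING"), (400, 1000, "A")], request_onset_ms=1000
        )
        assert missing_fraction(ep) == pytest.approx(0.4)

    @pytest.mark.parametrize("seed", range(20))
    def test_millisecond_grid_oracle(self, seed):
        ep = random_episode(np.random.default_rng(1000 + seed))
        grid = np.zeros(ep.request_onset_ms, dtype=bool)
        for f in ep.fixations:
            if f.target.kind is not TargetKind.MISSING:
                grid[f.onset_ms : f.offset_ms] = True
        expected = 1.0 - grid.sum() / len(grid)
        assert missing_fraction(ep) == pytest.approx(expected, abs=1e-12)


class TestFilterEpisodes:
    def _with_fraction(self, miss_ms, eid):
        return make_episode(
            [(0, miss_ms, "MISSING"), (miss_ms, 1000, "A")],
            request_onset_ms=1000,
            episode_id=eid,
        )

    def test_strict_boundary(self):
        ds = Dataset(
            episodes=[self._with_fraction(400, "at"), self._with_fraction(410, "over")]
        )
        kept = filter_episodes(ds, max_missing=0.40)
        assert [e.episode_id for e in kept] == ["at"]
        assert kept.provenance["filter"]["n_before"] == 2

    def test_clean_dataset_unchanged_and_idempotent(self):
        ds = Dataset(
            episodes=[
                make_episode([(0, 1000, "A")], request_onset_ms=1000,
                             episode_id=f"e{i}")
                for i in range(3)
            ]
        )
        once = filter_episodes(ds)
        twice = filter_episodes(once)
        assert [e.episode_id for e in once] == [e.episode_id for e in ds]
        assert [e.episode_id for e in twice] == [e.episode_id for e in once]


class TestValidation:
    def test_reversed_interval_rejected(self):
        with pytest.raises(ValidationError):
            fixation(300, 300, "A")

    def test_overlapping_fixations_rejected(self):
        with pytest.raises(ValidationError, match="ep1"):
            make_episode([(0, 300, "A"), (250, 500, "B")])

    def test_requested_must_be_available(self):
        with pytest.raises(ValidationError):
            make_episode([(0, 300, "A")], requested="Z", available={"A"})

    def test_fixation_beyond_request_onset_rejected(self):
        with pytest.raises(ValidationError):
            make_episode([(0, 300, "A")], request_onset_ms=200)

    def test_duplicate_episode_ids_rejected(self):
        ep = make_episode([(0, 300, "A")])
        with pytest.raises(ValidationError, match="duplicate"):
            Dataset(episodes=[ep, make_episode([(0, 100, "A")])])
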
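"""Candidate feature bookkeeping and its brute-force oracle."""

import numpy as np
import pytest

from gazeintent.events import Glance, TargetKind, segment_glances
from gazeintent.features import (
    CandidateList,
    FeatureScaler,
    candidate_list_at,
    features_at,
    scale_features,
    update_candidates,
)

from conftest import make_episode, random_episode, target


def glance(onset, offset, name, n_fix=1, dwell=None):
    return Glance(
        onset_ms=onset,
        offset_ms=offset,
        target=target(name),
        n_fixations=n_fix,
        dwell_ms=dwell if dwell is not None else offset - onset,
    )


class TestUpdateCandidates:
    def test_first_glance_creates_entry(self):
        state = update_candidates(CandidateList(), glance(0, 300, "A"))
        f = state.entries["A"]
        assert (f.f1_glance_count, f.f2_first_glance_ms, f.f3_total_glance_ms) == (
            1, 300.0, 300.0,
        )
        assert f.f4_most_recent

    def test_repeat_glance_accumulates(self):
        state = update_candidates(CandidateList(), glance(0, 300, "A"))
        state = update_candidates(state, glance(600, 900, "A"))
        f = state.entries["A"]
        assert (f.f1_glance_count, f.f2_first_glance_ms, f.f3_total_glance_ms) == (
            2, 300.0, 600.0,
        )
        assert f.f4_most_recent

    def test_recency_transfers_only_between_ingredients(self):
        state = CandidateList()
        for g in [glance(0, 300, "A"), glance(600, 900, "A"),
                  glance(900, 1100, "PARTNER")]:
            state = update_candidates(state, g)
        assert state.entries["A"].f4_most_recent  # partner does not clear it
        state = update_candidates(state, glance(1100, 1200, "B"))
        a, b = state.entries["A"], state.entries["B"]
        assert not a.f4_most_recent and b.f4_most_recent
        assert (a.f1_glance_count, a.f3_total_glance_ms) == (2, 600.0)

    def test_out_of_order_glance_rejected(self):
        state = update_candidates(CandidateList(), glance(0, 300, "A"))
        with pytest.raises(ValueError):
            update_candidates(state, glance(100, 400, "B"))

    def test_exactly_one_most_recent(self):
        state = CandidateList()
        rng = np.random.default_rng(0)
        t = 0
        for _ in range(40):
            name = ["A", "B", "C", "ELSEWHERE", "PARTNER"][int(rng.integers(5))]
            d = int(rng.integers(50, 400))
            state = update_candidates(state, glance(t, t + d, name))
            t += d + int(rng.integers(0, 300))
            if state.entries:
                assert sum(f.f4_most_recent for f in state.entries.values()) == 1


def _naive_features(episode, t_ms, max_gap_ms=200):
    """Independent per-ingredient recount, straight from the fixation list."""
    fixes = []
    for f in episode.fixations:
        if f.onset_ms >= t_ms:
            break
        fixes.append((f.onset_ms, min(f.offset_ms, t_ms), f.target))

    def intervening_real(a_off, b_on):
        return any(
            on < b_on and off > a_off and tg.kind is not TargetKind.MISSING
            for on, off, tg in fixes
            if (on, off) != (a_off, b_on)
            and on >= a_off and off <= b_on
        )

    out = {}
    order = []
    last_ing = None
    for on, off, tg in fixes:
        if tg.kind is not TargetKind.INGREDIENT:
            continue
        ing = tg.ingredient_id
        if ing not in out:
            out[ing] = []  # list of glance dwell accumulators
            order.append(ing)
        glances = out[ing]
        prev_off = out[ing][-1][1] if glances else None
        new_glance = (
            not glances
            or on - prev_off > max_gap_ms
            or intervening_real(prev_off, on)
        )
        if new_glance:
            glances.append([off - on, off])
        else:
            glances[-1][0] += off - on
            glances[-1][1] = off
        last_ing = ing
    feats = {}
    for ing in order:
        glances = out[ing]
        feats[ing] = (
            len(glances),
            float(glances[0][0]),
            float(sum(g[0] for g in glances)),
            ing == last_ing,
        )
    return feats


class TestFeaturesAt:
    def test_empty_at_zero(self):
        ep = make_episode([(0, 300, "A")])
        assert features_at(ep, 0) == {}

    def test_hand_built_episode(self):
        ep = make_episode(
            [
                (0, 300, "A"),
                (400, 700, "B"),
                (750, 900, "B"),     # merges with previous B (gap 50)
                (1000, 1200, "PARTNER"),
                (1300, 1500, "A"),
            ],
            request_onset_ms=1600,
        )
        feats = features_at(ep, 1600)
        a, b = feats["A"], feats["B"]
        assert (a.f1_glance_count, a.f2_first_glance_ms, a.f3_total_glance_ms,
                a.f4_most_recent) == (2, 300.0, 500.0, True)
        assert (b.f1_glance_count, b.f2_first_glance_ms, b.f3_total_glance_ms,
                b.f4_most_recent) == (1, 450.0, 450.0, False)

    def test_straddling_glance_clipped(self):
        ep = make_episode([(0, 1000, "A")], request_onset_ms=1000)
        f = features_at(ep, 400)["A"]
        assert f.f2_first_glance_ms == f.f3_total_glance_ms == 400.0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_naive_recount(self, seed):
        rng = np.random.default_rng(2000 + seed)
        ep = random_episode(rng)
        for _ in range(4):
            t = int(rng.integers(0, ep.request_onset_ms + 1))
            got = {
                ing: (f.f1_glance_count, f.f2_first_glance_ms,
                      f.f3_total_glance_ms, f.f4_most_recent)
                for ing, f in features_at(ep, t).items()
            }
            assert got == _naive_features(ep, t)

    @pytest.mark.parametrize("seed", range(10))
    def test_total_dwell_bounded_and_counts_match_glances(self, seed):
        ep = random_episode(np.random.default_rng(3000 + seed))
        t = ep.request_onset_ms
        feats = features_at(ep, t)
        assert sum(f.f3_total_glance_ms for f in feats.values()) <= t
        counts = {}
        for g in segment_glances(ep):
            if g.target.kind is TargetKind.INGREDIENT:
                counts[g.target.ingredient_id] = (
                    counts.get(g.target.ingredient_id, 0) + 1
                )
        assert {i: f.f1_glance_count for i, f in feats.items()} == counts


class TestScaler:
    def test_min_max_mapping(self):
        train = np.array([[100.0], [300.0]])
        out = scale_features(train, np.array([[100.0], [300.0], [200.0]]))
        assert out.ravel().tolist() == [0.0, 1.0, 0.5]

    def test_no_clipping_beyond_train_range(self):
        out = scale_features(np.array([[100.0], [300.0]]), np.array([[400.0]]))
        assert out.ravel().tolist() == [1.5]

    def test_constant_feature_maps_to_zero(self):
        train = np.array([[5.0, 1.0], [5.0, 3.0]])
        out = scale_features(train, np.array([[7.0, 2.0]]))
        assert out.tolist() == [[0.0, 0.5]]

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent_on_scaled_training_data(self, seed):
        X = np.random.default_rng(seed).uniform(-5, 10, size=(20, 4))
        scaler = FeatureScaler().fit(X)
        Xs = scaler.transform(X)
        again = FeatureScaler().fit(Xs).transform(Xs)
        np.testing.assert_allclose(again, Xs, atol=1e-12)
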
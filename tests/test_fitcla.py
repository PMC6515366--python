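"""Recommender: compatibility algebra, scoring, policy, feedback dynamics, scheduling."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import affectcare as ac
from affectcare.fitcla import DEFAULT_FEATURES, IMPACT_LEVELS, demo_catalog


def make_activity(impacts=None, *, id="act", intensity="low", duration=30):
    return ac.Activity(
        id=id,
        name=id,
        impact_ratings=impacts or {"arms": "light"},
        intensity_class=intensity,
        duration_min=duration,
    )


def tolerant_profile(level="hard", **overrides):
    ratings = {f: level for f in DEFAULT_FEATURES}
    ratings.update(overrides)
    return ac.UserProfile(id="u1", ability_ratings=ratings)


class TestFeatureCompatibility:
    @pytest.mark.parametrize(
        "impact, tolerance, expected",
        [
            ("light", "hard", 1.0),
            ("hard", "none", 0.0),
            ("mild", "light", 2.0 / 3.0),  # ordinal gap 1 of 3
            ("none", "none", 1.0),
            ("hard", "mild", 2.0 / 3.0),
            ("hard", "light", 1.0 / 3.0),
        ],
    )
    def test_ordinal_gap_penalty(self, impact, tolerance, expected):
        assert ac.feature_compatibility(impact, tolerance) == pytest.approx(expected)

    def test_dangerous_tools_is_binary(self):
        assert ac.feature_compatibility("light", "light", "dangerous_tools") == 1.0
        assert ac.feature_compatibility("mild", "light", "dangerous_tools") == 0.0
        assert ac.feature_compatibility("light", "none", "dangerous_tools") == 0.0

    def test_unknown_level_rejected(self):
        with pytest.raises(ac.InvalidParameterError):
            ac.feature_compatibility("extreme", "hard")

    @settings(deadline=None, max_examples=64)
    @given(
        impact=st.sampled_from(IMPACT_LEVELS),
        tolerance=st.sampled_from(IMPACT_LEVELS),
        feature=st.sampled_from(DEFAULT_FEATURES),
    )
    def test_bounded_in_unit_interval(self, impact, tolerance, feature):
        c = ac.feature_compatibility(impact, tolerance, feature)
        assert 0.0 <= c <= 1.0


class TestScoreActivity:
    def test_fully_compatible_zero_preference_hits_cap(self):
        cfg = ac.RecommenderConfig()
        score = ac.score_activity(make_activity(), tolerant_profile(), cfg)
        assert score == pytest.approx(0.9)

    def test_full_preference_reaches_one(self):
        cfg = ac.RecommenderConfig()
        profile = tolerant_profile()
        profile.preferences["act"] = 1.0
        assert ac.score_activity(make_activity(), profile, cfg) == pytest.approx(1.0)

    def test_zero_compatibility_zero_preference_scores_zero(self):
        cfg = ac.RecommenderConfig()
        activity = make_activity({f: "hard" for f in DEFAULT_FEATURES})
        profile = tolerant_profile("none")
        assert ac.score_activity(activity, profile, cfg) == pytest.approx(0.0)

    def test_unknown_feature_rejected(self):
        cfg = ac.RecommenderConfig()
        with pytest.raises(ac.InvalidParameterError):
            ac.score_activity(make_activity({"wings": "light"}), tolerant_profile(), cfg)

    def test_score_equals_cap_only_when_fully_compatible_and_indifferent(self):
        cfg = ac.RecommenderConfig()
        partially = make_activity({"arms": "hard"})
        score = ac.score_activity(partially, tolerant_profile(arms="light"), cfg)
        assert score < cfg.feature_cap

    @settings(deadline=None, max_examples=60)
    @given(data=st.data())
    def test_bounds_and_tolerance_monotonicity(self, data):
        cfg = ac.RecommenderConfig()
        impacts = {
            f: data.draw(st.sampled_from(IMPACT_LEVELS), label=f"impact_{f}")
            for f in DEFAULT_FEATURES
        }
        tolerances = {
            f: data.draw(st.sampled_from(IMPACT_LEVELS), label=f"tol_{f}")
            for f in DEFAULT_FEATURES
        }
        pref = data.draw(st.floats(0.0, 1.0), label="pref")
        activity = make_activity(impacts)
        profile = ac.UserProfile(id="u", ability_ratings=tolerances,
                                 preferences={"act": pref})
        base = ac.score_activity(activity, profile, cfg)
        assert 0.0 <= base <= 1.0 + 1e-12
        # raising any single tolerance never lowers the score
        feat = data.draw(st.sampled_from(DEFAULT_FEATURES), label="raised")
        idx = IMPACT_LEVELS.index(tolerances[feat])
        if idx < len(IMPACT_LEVELS) - 1:
            raised = dict(tolerances)
            raised[feat] = IMPACT_LEVELS[idx + 1]
            profile2 = ac.UserProfile(id="u", ability_ratings=raised,
                                      preferences={"act": pref})
            assert ac.score_activity(activity, profile2, cfg) >= base - 1e-12


class TestRecommend:
    def test_single_activity_catalog(self):
        state = ac.RecommenderState()
        act, score = ac.recommend(tolerant_profile(), [make_activity()], "Happy", state)
        assert act.id == "act"

    def test_tie_broken_by_preference_then_id(self):
        a = make_activity(id="a", intensity="low")
        b = make_activity(id="b", intensity="low")
        profile = tolerant_profile()
        profile.preferences = {"a": 0.0, "b": 0.0}
        state = ac.RecommenderState()
        # scores tie at 0.9 with zero preference: lexicographic id wins
        act, _ = ac.recommend(profile, [b, a], "Happy", state)
        assert act.id == "a"
        profile.preferences = {"a": 0.1, "b": 0.3}
        cfg = ac.RecommenderConfig(preference_share=0.0, feature_cap=1.0)
        state = ac.RecommenderState(config=cfg)
        act, _ = ac.recommend(profile, [a, b], "Happy", state)
        assert act.id == "b"  # equal scores, higher preference weight wins

    def test_counteract_policy_prefers_low_intensity_for_angry(self):
        high = make_activity(id="boost", intensity="high")
        low = make_activity(id="calm", intensity="low")
        state = ac.RecommenderState()
        act, _ = ac.recommend(tolerant_profile(), [high, low], "Angry", state)
        assert act.intensity_class == "low"

    def test_boost_policy_prefers_high_intensity_for_sad(self):
        high = make_activity(id="boost", intensity="high")
        low = make_activity(id="calm", intensity="low")
        state = ac.RecommenderState()
        act, _ = ac.recommend(tolerant_profile(), [high, low], "Sad", state)
        assert act.intensity_class == "high"

    def test_estimate_object_steers_policy(self):
        probs = {lb: 0.0 for lb in ac.EMOTION_LABELS}
        probs["Angry"] = 1.0
        est = ac.EmotionEstimate(probs)
        high = make_activity(id="boost", intensity="high")
        low = make_activity(id="calm", intensity="low")
        act, _ = ac.recommend(tolerant_profile(), [high, low], est, ac.RecommenderState())
        assert act.id == "calm"

    def test_emptied_filter_falls_back_with_notification(self):
        high = make_activity(id="boost", intensity="high")
        state = ac.RecommenderState()
        act, _ = ac.recommend(tolerant_profile(), [high], "Angry", state)
        assert act.id == "boost"
        assert any("no-candidate" in n.reason for n in state.notifications)

    def test_empty_catalog_rejected(self):
        with pytest.raises(ac.InvalidParameterError):
            ac.recommend(tolerant_profile(), [], "Happy", ac.RecommenderState())


class TestFeedback:
    def test_seven_consecutive_close_fit_denials_trigger_reweight(self):
        state = ac.RecommenderState()
        profile = tolerant_profile()
        activity = make_activity()
        for i in range(6):
            ac.register_feedback(activity, False, profile, state)
            assert state.config.feature_cap == pytest.approx(0.9)
            assert not state.notifications
        ac.register_feedback(activity, False, profile, state)  # the 7th
        assert state.config.feature_cap == pytest.approx(0.85)
        assert state.config.preference_share == pytest.approx(0.15)
        assert [n.reason for n in state.notifications] == ["re-weight"]
        assert state.denial_counters[profile.id] == 0

    def test_acceptance_resets_counter(self):
        state = ac.RecommenderState()
        profile = tolerant_profile()
        activity = make_activity()
        for _ in range(6):
            ac.register_feedback(activity, False, profile, state)
        ac.register_feedback(activity, True, profile, state)
        assert state.denial_counters[profile.id] == 0
        for _ in range(6):
            ac.register_feedback(activity, False, profile, state)
        assert not any(n.reason == "re-weight" for n in state.notifications)

    def test_far_fit_denials_do_not_count(self):
        state = ac.RecommenderState()
        profile = tolerant_profile("none")
        bad = make_activity({f: "hard" for f in DEFAULT_FEATURES})
        for _ in range(10):
            ac.register_feedback(bad, False, profile, state)
        assert state.denial_counters.get(profile.id, 0) == 0
        assert state.config.feature_cap == pytest.approx(0.9)

    def test_acceptance_learning_converges_to_one(self):
        state = ac.RecommenderState()
        profile = tolerant_profile()
        activity = make_activity()
        step = state.config.learning_step
        previous = 0.0
        for i in range(int(np.ceil(1.0 / step)) + 5):
            ac.register_feedback(activity, True, profile, state)
            current = profile.preference(activity.id)
            assert current >= previous
            assert current <= 1.0
            previous = current
        assert profile.preference(activity.id) == pytest.approx(1.0)

    def test_repeated_triggers_reapply(self):
        state = ac.RecommenderState()
        profile = tolerant_profile()
        activity = make_activity()
        for _ in range(14):
            ac.register_feedback(activity, False, profile, state)
        assert state.config.feature_cap == pytest.approx(0.8)
        assert len([n for n in state.notifications if n.reason == "re-weight"]) == 2

    def test_weight_conservation_under_random_feedback(self):
        """cap + preference share stays exactly 1 over 10,000 random events."""
        rng = np.random.default_rng(42)
        state = ac.RecommenderState()
        profile = tolerant_profile()
        catalog = demo_catalog()
        for _ in range(10_000):
            activity = catalog[rng.integers(len(catalog))]
            ac.register_feedback(activity, bool(rng.random() < 0.4), profile, state)
            cfg = state.config
            assert cfg.feature_cap + cfg.preference_share == pytest.approx(1.0, abs=1e-9)
            assert abs(sum(cfg.feature_weights.values()) - cfg.feature_cap) < 1e-9
            assert all(0.0 <= p <= 1.0 for p in profile.preferences.values())


class TestSchedule:
    def test_earliest_fit_shrinks_slot(self):
        profile = tolerant_profile()
        profile.free_slots = [(datetime(2024, 1, 1, 10, 0), datetime(2024, 1, 1, 11, 0))]
        event = ac.schedule_activity(make_activity(duration=30), profile)
        assert event == (datetime(2024, 1, 1, 10, 0), datetime(2024, 1, 1, 10, 30))
        assert profile.free_slots == [
            (datetime(2024, 1, 1, 10, 30), datetime(2024, 1, 1, 11, 0))
        ]

    def test_skips_slots_that_are_too_short(self):
        profile = tolerant_profile()
        profile.free_slots = [
            (datetime(2024, 1, 1, 9, 0), datetime(2024, 1, 1, 9, 10)),
            (datetime(2024, 1, 1, 10, 0), datetime(2024, 1, 1, 11, 0)),
        ]
        event = ac.schedule_activity(make_activity(duration=30), profile)
        assert event == (datetime(2024, 1, 1, 10, 0), datetime(2024, 1, 1, 10, 30))
        assert len(profile.free_slots) == 2  # short slot untouched

    def test_no_slot_returns_none(self):
        profile = tolerant_profile()
        assert ac.schedule_activity(make_activity(duration=30), profile) is None

    def test_exact_fit_consumes_slot(self):
        profile = tolerant_profile()
        profile.free_slots = [(datetime(2024, 1, 1, 10, 0), datetime(2024, 1, 1, 10, 30))]
        event = ac.schedule_activity(make_activity(duration=30), profile)
        assert event is not None
        assert profile.free_slots == []


class TestCatalogIO:
    def test_catalog_roundtrip(self, tmp_path):
        from affectcare.fitcla import load_catalog, save_catalog

        catalog = demo_catalog()
        path = save_catalog(catalog, tmp_path / "catalog.json")
        loaded = load_catalog(path)
        assert [a.id for a in loaded] == [a.id for a in catalog]
        assert loaded[0].impact_ratings == catalog[0].impact_ratings

    def test_profile_roundtrip(self, tmp_path):
        from affectcare.fitcla import load_profile, save_profile

        profile = tolerant_profile()
        profile.preferences = {"arms_raise": 0.4}
        profile.free_slots = [(datetime(2024, 1, 1, 9, 0), datetime(2024, 1, 1, 10, 0))]
        path = save_profile(profile, tmp_path / "profile.json")
        loaded = load_profile(path)
        assert loaded.id == profile.id
        assert loaded.preferences == profile.preferences
        assert loaded.free_slots == profile.free_slots

    def test_demo_catalog_contains_worked_examples(self):
        ids = {a.id for a in demo_catalog()}
        assert {"light_gardening", "arms_raise"} <= ids

    def test_invalid_preference_weight_rejected(self):
        with pytest.raises(ac.InvalidParameterError):
            ac.UserProfile(id="u", ability_ratings={}, preferences={"a": 1.5})
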
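"""FitCLA: health-profile-aware, emotion-aware activity recommendation.

Each activity carries per-feature impact ratings (shoulders, arms, column,
legs, feet, cognitive load, use of dangerous tools) on the ordinal scale
none < light < mild < hard, and each user carries the maximum impact they
may safely receive per feature. An activity's score is a weighted sum of
per-feature compatibilities, capped at 0.9, plus up to 0.1 from the user's
learned preference for that activity — so a perfectly suitable activity the
user is indifferent to scores exactly 0.9 and a loved one scores 1.0.

Preferences are learned from accept/deny feedback. Denying activities that
closely fit the health profile seven times in a row triggers a re-weighting:
the health-feature cap is nudged down, the preference share up, and the
caregiver is notified. Emotion steers candidate filtering: agitated negative
states get low-intensity de-stressers, flat or sad states get high-intensity
boosters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Sequence

from .errors import InvalidParameterError

IMPACT_LEVELS = ("none", "light", "mild", "hard")

DEFAULT_FEATURES = (
    "shoulders",
    "arms",
    "column",
    "legs",
    "feet",
    "cognitive",
    "dangerous_tools",
)

#: Emotion -> candidate-filter policy. Agitated negative states are calmed
#: with low-intensity de-stressers; flat or sad states are lifted with
#: high-intensity boosters; content states are left unfiltered.
DEFAULT_EMOTION_POLICY = {
    "Sad": "high",
    "Neutral": "high",
    "Angry": "low",
    "Afraid": "low",
    "Disgusted": "low",
    "Happy": None,
    "Surprised": None,
}


def _level_ord(level: str) -> int:
    try:
        return IMPACT_LEVELS.index(level)
    except ValueError:
        raise InvalidParameterError(
            f"unknown impact level {level!r}; expected one of {IMPACT_LEVELS}"
        ) from None


@dataclass
class Activity:
    """A catalog entry with per-feature impact ratings."""

    id: str
    name: str
    impact_ratings: dict[str, str]
    intensity_class: str  # "high" (booster) or "low" (de-stresser)
    duration_min: int

    def __post_init__(self) -> None:
        if not self.impact_ratings:
            raise InvalidParameterError("an activity must rate at least one feature")
        for feat, level in self.impact_ratings.items():
            _level_ord(level)
        if self.intensity_class not in ("high", "low"):
            raise InvalidParameterError("intensity_class must be 'high' or 'low'")
        if self.duration_min <= 0:
            raise InvalidParameterError("duration_min must be positive")


@dataclass
class UserProfile:
    """Per-user abilities, learned preferences and free calendar slots."""

    id: str
    ability_ratings: dict[str, str]
    preferences: dict[str, float] = field(default_factory=dict)
    free_slots: list[tuple[datetime, datetime]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for feat, level in self.ability_ratings.items():
            _level_ord(level)
        for act_id, w in self.preferences.items():
            if not 0.0 <= w <= 1.0:
                raise InvalidParameterError(
                    f"preference weight for {act_id!r} must lie in [0, 1]"
                )

    def preference(self, activity_id: str) -> float:
        return self.preferences.get(activity_id, 0.0)


@dataclass
class RecommenderConfig:
    """Scoring weights and behavioural thresholds.

    feature_cap + preference_share is always 1; initially all feature
    weights are equal and sum to feature_cap (0.9 by default, leaving 0.1
    to the user preference). close_fit_min_score defines which activities
    count as closely fitting the health profile for the denial counter.
    """

    feature_weights: dict[str, float] = field(default_factory=dict)
    feature_cap: float = 0.9
    preference_share: float = 0.1
    denial_threshold: int = 7
    close_fit_min_score: float = 0.75
    learning_step: float = 0.05
    reweight_step: float = 0.05
    emotion_policy: dict[str, str | None] = field(
        default_factory=lambda: dict(DEFAULT_EMOTION_POLICY)
    )

    def __post_init__(self) -> None:
        if abs(self.feature_cap + self.preference_share - 1.0) > 1e-9:
            raise InvalidParameterError("feature_cap + preference_share must equal 1")
        if not self.feature_weights:
            equal = self.feature_cap / len(DEFAULT_FEATURES)
            self.feature_weights = {f: equal for f in DEFAULT_FEATURES}
        if any(w < 0 for w in self.feature_weights.values()):
            raise InvalidParameterError("feature weights must be non-negative")
        total = sum(self.feature_weights.values())
        if abs(total - self.feature_cap) > 1e-9:
            raise InvalidParameterError(
                f"feature weights sum to {total}, expected feature_cap={self.feature_cap}"
            )
        if self.denial_threshold < 1:
            raise InvalidParameterError("denial_threshold must be >= 1")
        if not 0.0 <= self.close_fit_min_score <= self.feature_cap + 1e-9:
            raise InvalidParameterError("close_fit_min_score must lie in [0, feature_cap]")


@dataclass
class Notification:
    timestamp: str
    user_id: str
    reason: str


@dataclass
class RecommenderState:
    """Mutable recommender state: config, denial counters, notification log."""

    config: RecommenderConfig = field(default_factory=RecommenderConfig)
    denial_counters: dict[str, int] = field(default_factory=dict)
    notifications: list[Notification] = field(default_factory=list)

    def notify(self, user_id: str, reason: str) -> None:
        stamp = datetime.now(timezone.utc).isoformat()
        self.notifications.append(Notification(stamp, user_id, reason))


def feature_compatibility(activity_impact: str, user_tolerance: str, feature: str = "") -> float:
    """Compatibility in [0, 1] between an impact level and a tolerance level.

    1 when the impact is within tolerance; otherwise the ordinal gap is
    penalised linearly (gap/3 on the 4-level scale). The dangerous_tools
    feature is binary: an activity needing dangerous tools is either
    acceptable (1) or not (0).
    """
    impact = _level_ord(activity_impact)
    tolerance = _level_ord(user_tolerance)
    if impact <= tolerance:
        return 1.0
    if feature == "dangerous_tools":
        return 0.0
    gap = impact - tolerance
    return 1.0 - gap / (len(IMPACT_LEVELS) - 1)


def score_activity(
    activity: Activity, profile: UserProfile, config: RecommenderConfig
) -> float:
    """Weighted health-feature compatibility plus the preference term.

    Features the activity does not rate count as "none" impact (always
    compatible); features the user does not rate count as "hard" tolerance
    (no declared limitation). The health component is bounded by
    feature_cap, the total by feature_cap + preference_share = 1.
    """
    unknown = set(activity.impact_ratings) - set(config.feature_weights)
    if unknown:
        raise InvalidParameterError(
            f"activity rates features absent from the config weights: {sorted(unknown)}"
        )
    health = 0.0
    for feat, weight in config.feature_weights.items():
        impact = activity.impact_ratings.get(feat, "none")
        tolerance = profile.ability_ratings.get(feat, "hard")
        health += weight * feature_compatibility(impact, tolerance, feat)
    return health + config.preference_share * profile.preference(activity.id)


def recommend(
    profile: UserProfile,
    catalog: Sequence[Activity],
    emotion,
    state: RecommenderState,
) -> tuple[Activity, float]:
    """Pick the best activity for this user in this emotional state.

    The catalog is first narrowed by the boost/counteract policy for the
    estimated emotion (falling back to the full catalog, with a logged
    notification, if the filter empties it), then ranked by score; ties are
    broken by higher preference weight, then lexicographic activity id.
    """
    if not catalog:
        raise InvalidParameterError("catalog is empty")
    label = emotion if isinstance(emotion, str) else emotion.argmax_label
    wanted = state.config.emotion_policy.get(label)
    candidates = [a for a in catalog if wanted is None or a.intensity_class == wanted]
    if not candidates:
        state.notify(profile.id, "no-candidate: emotion filter emptied the catalog")
        candidates = list(catalog)
    scored = sorted(
        candidates,
        key=lambda a: (
            -score_activity(a, profile, state.config),
            -profile.preference(a.id),
            a.id,
        ),
    )
    best = scored[0]
    return best, score_activity(best, profile, state.config)


def register_feedback(
    activity: Activity,
    accepted: bool,
    profile: UserProfile,
    state: RecommenderState,
) -> tuple[UserProfile, RecommenderState]:
    """Fold an accept/deny response into the preference weights and counters.

    Acceptance bumps the activity's preference by the learning step and
    resets the consecutive-denial counter. A denial lowers the preference
    and, when the denied activity closely fits the health profile, advances
    the counter; at the threshold the feature cap is nudged down, the
    preference share up (their sum stays 1), the counter resets and the
    caregiver is notified. The nudge re-applies on repeated triggers.
    """
    cfg = state.config
    step = cfg.learning_step
    pref = profile.preference(activity.id)
    score = score_activity(activity, profile, cfg)
    if accepted:
        profile.preferences[activity.id] = min(1.0, pref + step)
        state.denial_counters[profile.id] = 0
    else:
        profile.preferences[activity.id] = max(0.0, pref - step)
        if score >= cfg.close_fit_min_score:
            count = state.denial_counters.get(profile.id, 0) + 1
            if count >= cfg.denial_threshold:
                _reweight(cfg)
                state.denial_counters[profile.id] = 0
                state.notify(profile.id, "re-weight")
            else:
                state.denial_counters[profile.id] = count
    return profile, state


def _reweight(cfg: RecommenderConfig) -> None:
    """Shift weight mass from health features to the preference term."""
    new_cap = max(0.0, cfg.feature_cap - cfg.reweight_step)
    if cfg.feature_cap > 0:
        scale = new_cap / cfg.feature_cap
        cfg.feature_weights = {f: w * scale for f, w in cfg.feature_weights.items()}
    cfg.feature_cap = new_cap
    cfg.preference_share = 1.0 - new_cap
    cfg.close_fit_min_score = min(cfg.close_fit_min_score, cfg.feature_cap)


def schedule_activity(
    activity: Activity, profile: UserProfile
) -> tuple[datetime, datetime] | None:
    """Place the activity in the earliest free slot long enough for it.

    Returns the (start, end) event and shrinks the chosen slot in place;
    returns None (a no-slot signal, not an error) when nothing fits.
    """
    need = timedelta(minutes=activity.duration_min)
    for i, (start, end) in enumerate(profile.free_slots):
        if end - start >= need:
            event = (start, start + need)
            remaining = (start + need, end)
            if remaining[1] - remaining[0] > timedelta(0):
                profile.free_slots[i] = remaining
            else:
                del profile.free_slots[i]
            return event
    return None


# ---------------------------------------------------------------------------
# JSON catalog / profile I/O
# ---------------------------------------------------------------------------

def load_catalog(path: str | Path) -> list[Activity]:
    """Read an activity catalog from a JSON document (list of activities)."""
    entries = json.loads(Path(path).read_text())
    return [
        Activity(
            id=e["id"],
            name=e["name"],
            impact_ratings=dict(e["impact_ratings"]),
            intensity_class=e["intensity_class"],
            duration_min=int(e["duration_min"]),
        )
        for e in entries
    ]


def save_catalog(catalog: Sequence[Activity], path: str | Path) -> Path:
    path = Path(path)
    payload = [
        {
            "id": a.id,
            "name": a.name,
            "impact_ratings": a.impact_ratings,
            "intensity_class": a.intensity_class,
            "duration_min": a.duration_min,
        }
        for a in catalog
    ]
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def load_profile(path: str | Path) -> UserProfile:
    d = json.loads(Path(path).read_text())
    slots = [
        (datetime.fromisoformat(s), datetime.fromisoformat(e))
        for s, e in d.get("free_slots", [])
    ]
    return UserProfile(
        id=d["id"],
        ability_ratings=dict(d["ability_ratings"]),
        preferences={k: float(v) for k, v in d.get("preferences", {}).items()},
        free_slots=slots,
    )


def save_profile(profile: UserProfile, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "id": profile.id,
        "ability_ratings": profile.ability_ratings,
        "preferences": profile.preferences,
        "free_slots": [[s.isoformat(), e.isoformat()] for s, e in profile.free_slots],
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def demo_catalog() -> list[Activity]:
    """A small illustrative catalog, including the light-gardening and
    arms-raise examples used throughout the package documentation."""
    return [
        Activity(
            id="light_gardening",
            name="Light gardening",
            impact_ratings={
                "cognitive": "mild",
                "shoulders": "mild",
                "arms": "mild",
                "column": "mild",
                "legs": "light",
                "feet": "light",
                "dangerous_tools": "light",
            },
            intensity_class="low",
            duration_min=45,
        ),
        Activity(
            id="arms_raise",
            name="Arms raise",
            impact_ratings={"shoulders": "light", "arms": "light"},
            intensity_class="high",
            duration_min=10,
        ),
        Activity(
            id="group_walk",
            name="Group walk",
            impact_ratings={"legs": "mild", "feet": "mild"},
            intensity_class="high",
            duration_min=30,
        ),
        Activity(
            id="memory_game",
            name="Group memory game",
            impact_ratings={"cognitive": "mild"},
            intensity_class="low",
            duration_min=30,
        ),
        Activity(
            id="chair_stretch",
            name="Seated stretching",
            impact_ratings={"shoulders": "light", "column": "light"},
            intensity_class="low",
            duration_min=15,
        ),
    ]
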
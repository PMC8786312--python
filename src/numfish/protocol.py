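"""Training-session and test-block construction for the 2AFC procedure.

Daily training sessions comprise 48 trials whose control conditions are
fixed by composition: 12 trials each for the two radius-fixed conditions
and 6 each for the four area/perimeter conditions, so that half of all
trials present dots of identical individual size.  Tests comprise 24
unrewarded probe trials split over three days of 8 (2 trials per
radius-fixed condition, 1 per area/perimeter condition per day),
interspersed among rewarded recall trials.  Learning is complete when a
fish scores at least 75% correct on two consecutive sessions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .stimgen import CONDITIONS, ControlCondition, Geometry, Spatial

__all__ = [
    "Phase",
    "TrialSpec",
    "SessionPlan",
    "TRAINING_COMPOSITION",
    "TEST_DAY_COMPOSITION",
    "build_training_session",
    "build_test_block",
    "criterion_reached",
    "criterion_binomial_p",
]


class Phase(str, enum.Enum):
    TRAINING = "training"
    PROBE = "probe"
    RECALL = "recall"


#: 48-trial training composition: {condition: count}
TRAINING_COMPOSITION: dict[ControlCondition, int] = {
    ControlCondition(Geometry.RADIUS_FIXED, Spatial.ID_EQ): 12,
    ControlCondition(Geometry.RADIUS_FIXED, Spatial.CH_EQ): 12,
    ControlCondition(Geometry.AREA_EQ, Spatial.ID_EQ): 6,
    ControlCondition(Geometry.AREA_EQ, Spatial.CH_EQ): 6,
    ControlCondition(Geometry.PERIM_EQ, Spatial.ID_EQ): 6,
    ControlCondition(Geometry.PERIM_EQ, Spatial.CH_EQ): 6,
}

#: 8-probe-trial daily test composition
TEST_DAY_COMPOSITION: dict[ControlCondition, int] = {
    ControlCondition(Geometry.RADIUS_FIXED, Spatial.ID_EQ): 2,
    ControlCondition(Geometry.RADIUS_FIXED, Spatial.CH_EQ): 2,
    ControlCondition(Geometry.AREA_EQ, Spatial.ID_EQ): 1,
    ControlCondition(Geometry.AREA_EQ, Spatial.CH_EQ): 1,
    ControlCondition(Geometry.PERIM_EQ, Spatial.ID_EQ): 1,
    ControlCondition(Geometry.PERIM_EQ, Spatial.CH_EQ): 1,
}

#: rewarded recall trials interleaved per test day (configurable; the daily
#: reading of "32 recall in total" keeps per-day counts integral)
RECALL_PER_TEST_SESSION = 32


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial: phase, condition, comparison, reward rule, side."""

    session_index: int
    trial_index: int
    phase: Phase
    condition: ControlCondition
    comparison: tuple[int, int]  # (n_small, n_large)
    rewarded_rule: str | None  # 'smaller' | 'larger' | None for probes
    target_side: str  # 'left' | 'right'
    stimulus_seed: int


@dataclass(frozen=True)
class SessionPlan:
    """Ordered trials of one session plus the per-condition composition."""

    trials: tuple[TrialSpec, ...]
    composition_counts: dict

    def __len__(self) -> int:
        return len(self.trials)


def _balanced_sides(n: int, rng: np.random.Generator) -> list[str]:
    # balanced-then-shuffled left/right assignment (removes side bias exactly)
    sides = ["left"] * (n // 2) + ["right"] * (n - n // 2)
    rng.shuffle(sides)
    return sides


def _compose(
    composition: dict[ControlCondition, int],
    phase: Phase,
    session_index: int,
    comparison: tuple[int, int],
    rewarded_rule: str | None,
    rng: np.random.Generator,
    trial_offset: int = 0,
) -> list[TrialSpec]:
    conditions: list[ControlCondition] = []
    for cond, count in composition.items():
        conditions.extend([cond] * count)
    rng.shuffle(conditions)
    sides = _balanced_sides(len(conditions), rng)
    return [
        TrialSpec(
            session_index=session_index,
            trial_index=trial_offset + i + 1,
            phase=phase,
            condition=cond,
            comparison=comparison,
            rewarded_rule=rewarded_rule,
            target_side=side,
            stimulus_seed=int(rng.integers(0, 2**31 - 1)),
        )
        for i, (cond, side) in enumerate(zip(conditions, sides))
    ]


def build_training_session(
    comparison: tuple[int, int],
    rewarded_rule: str,
    rng: np.random.Generator | int,
    session_index: int = 1,
) -> SessionPlan:
    """One 48-trial training session with the fixed condition composition.

    Target side is counterbalanced 24/24 and the trial order shuffled.
    """
    if rewarded_rule not in ("smaller", "larger"):
        raise ValueError("rewarded_rule must be 'smaller' or 'larger'")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    trials = _compose(
        TRAINING_COMPOSITION, Phase.TRAINING, session_index, comparison,
        rewarded_rule, rng,
    )
    counts = {c.label(): n for c, n in TRAINING_COMPOSITION.items()}
    return SessionPlan(trials=tuple(trials), composition_counts=counts)


def build_test_block(
    test_comparison: tuple[int, int],
    rng: np.random.Generator | int,
    *,
    recall_comparison: tuple[int, int] | None = None,
    recall_rule: str = "larger",
    recall_per_session: int = RECALL_PER_TEST_SESSION,
    start_session_index: int = 1,
) -> list[SessionPlan]:
    """Three test days of 8 unrewarded probe trials each (24 probes total).

    Each day's probes follow the 2/2/1/1/1/1 condition composition and are
    shuffled together with ``recall_per_session`` rewarded recall trials of
    the training comparison to keep motivation high.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    recall_comparison = recall_comparison or test_comparison
    days: list[SessionPlan] = []
    for day in range(3):
        session_index = start_session_index + day
        probes = _compose(
            TEST_DAY_COMPOSITION, Phase.PROBE, session_index, test_comparison,
            None, rng,
        )
        recalls = _compose(
            {cond: recall_per_session // 6 + (1 if i < recall_per_session % 6 else 0)
             for i, cond in enumerate(CONDITIONS)},
            Phase.RECALL, session_index, recall_comparison, recall_rule, rng,
        )
        mixed = probes + recalls
        rng.shuffle(mixed)
        mixed = [
            TrialSpec(
                session_index=t.session_index,
                trial_index=i + 1,
                phase=t.phase,
                condition=t.condition,
                comparison=t.comparison,
                rewarded_rule=t.rewarded_rule,
                target_side=t.target_side,
                stimulus_seed=t.stimulus_seed,
            )
            for i, t in enumerate(mixed)
        ]
        probe_counts = {c.label(): n for c, n in TEST_DAY_COMPOSITION.items()}
        days.append(SessionPlan(trials=tuple(mixed), composition_counts=probe_counts))
    return days


def criterion_reached(
    session_accuracies: list[float], threshold: float = 0.75
) -> tuple[bool, int | None]:
    """First session index (1-based) at which two consecutive sessions are
    at or above threshold; ``(False, None)`` if never reached."""
    for i in range(1, len(session_accuracies)):
        if (
            session_accuracies[i - 1] >= threshold
            and session_accuracies[i] >= threshold
        ):
            return True, i + 1
    return False, None


def criterion_binomial_p(k: int, n: int) -> float:
    """One-sided exact binomial tail P(X >= k | n, 1/2)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return float(stats.binom.sf(k - 1, n, 0.5))
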
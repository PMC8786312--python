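"""Synthetic fish choice data with the statistical structure the analyses assume.

Each simulated fish carries a saturating-exponential learning curve on the
log-odds scale: in session s its per-trial success probability is

    p_s = inv_logit(start + (asymptote - start) * (1 - exp(-rate * s)) + offset_c)

where ``offset_c`` is an optional per-condition log-odds shift.  Choices are
Bernoulli draws; non-response occurs independently per trial (fish typically
respond on 70-100% of trials).  Training runs until the two-consecutive-
sessions >= 75% criterion or a session cap.

Two study designs are provided.  Design ``exp1``: eight fish trained on a
3 vs 6 discrimination, four rewarded on the smaller and four on the larger
numerosity, then probe-tested on a novel same-side-of-training comparison
(2 vs 3 for the smaller-trained group, 6 vs 9 for the larger-trained) and
on 5 vs 8.  Design ``exp2``: four fish trained to pick the larger set of
2 vs 3, then tested on 3 vs 4 and 3 vs 6.

The "paper-like" presets encode generating truths matching the published
proportions (training 0.819 / pooled test 0.743 for exp1; 0.755 / 0.698
for exp2) so that recovery tests have known targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import protocol
from .choicestats import CHOICE_TABLE_COLUMNS, inv_logit, logit, validate_choice_table
from .magnitudes import congruency_level
from .protocol import Phase, SessionPlan, build_test_block, build_training_session
from .stimgen import ControlCondition

__all__ = [
    "FishParams",
    "paper_like_params",
    "simulate_learning",
    "simulate_study",
]


@dataclass
class FishParams:
    """Generating parameters of one simulated fish."""

    fish_id: str
    start_log_odds: float = 0.0  # pre-learning accuracy (logit scale)
    asymptote_log_odds: float = 1.510  # plateau accuracy
    learning_rate: float = 0.6  # per-session approach rate, >= 0
    condition_offsets: dict = field(default_factory=dict)  # label -> log-odds
    response_prob: float = 0.9  # in [0.7, 1.0] typically
    test_log_odds: dict = field(default_factory=dict)  # test label -> log-odds

    def __post_init__(self) -> None:
        if not 0 <= self.response_prob <= 1:
            raise ValueError("response_prob must be in [0, 1]")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


def paper_like_params(design: str) -> dict:
    """Generating truths that reproduce the published summary proportions.

    exp1: training plateau 0.819, all tests at 0.743; exp2: plateau 0.755,
    tests at 0.698.  Condition offsets are zero (accuracy independent of the
    magnitude controls) and the random between-fish variation is nil, the
    regime the published fits landed in (random-intercept variance ~ 0).
    """
    if design == "exp1":
        train_asym = logit(0.819)
        test_lo = logit(0.743)
        tests = {"2v3": test_lo, "6v9": test_lo, "5v8": test_lo}
        n_fish = 8
    elif design == "exp2":
        train_asym = logit(0.755)
        test_lo = logit(0.698)
        tests = {"3v4": test_lo, "3v6": test_lo}
        n_fish = 4
    else:
        raise ValueError("design must be 'exp1' or 'exp2'")
    return {
        "n_fish": n_fish,
        "start_log_odds": 0.0,
        "asymptote_log_odds": train_asym,
        "learning_rate": 0.6,
        "response_prob": 0.9,
        "test_log_odds": tests,
    }


def _rows_from_session(
    plan: SessionPlan,
    fish_id: str,
    experiment: str,
    phase_label: str,
    p_correct,
    response_prob: float,
    rng: np.random.Generator,
) -> list[dict]:
    rows = []
    for t in plan.trials:
        responded = int(rng.random() < response_prob)
        p = p_correct(t)
        chose = int(rng.random() < p) if responded else np.nan
        rows.append(
            {
                "fish_id": fish_id,
                "experiment": experiment,
                "phase": phase_label,
                "session": t.session_index,
                "trial": t.trial_index,
                "geometry_control": t.condition.geometry.value,
                "spatial_control": t.condition.spatial.value,
                "congruency_level": congruency_level(t.condition).level,
                "comparison": f"{t.comparison[0]}v{t.comparison[1]}",
                "chose_target": chose,
                "responded": responded,
            }
        )
    return rows


def simulate_learning(
    params: FishParams,
    comparison: tuple[int, int],
    max_sessions: int = 40,
    rng: np.random.Generator | int = 0,
    *,
    rewarded_rule: str = "larger",
    experiment: str = "exp1",
) -> pd.DataFrame:
    """Simulate one fish's training sessions until criterion or the cap.

    Returns long-format choice-table rows; ``chose_target`` codes the choice
    of the rewarded numerosity.  Session accuracy is computed over responded
    trials, and training stops after the first two consecutive sessions at
    or above 75%.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    rows: list[dict] = []
    accuracies: list[float] = []
    for s in range(1, max_sessions + 1):
        plan = build_training_session(comparison, rewarded_rule, rng, session_index=s)
        drive = params.start_log_odds + (
            params.asymptote_log_odds - params.start_log_odds
        ) * (1.0 - np.exp(-params.learning_rate * s))

        def p_correct(trial, drive=drive):
            offset = params.condition_offsets.get(trial.condition.label(), 0.0)
            return inv_logit(drive + offset)

        session_rows = _rows_from_session(
            plan, params.fish_id, experiment, "training", p_correct,
            params.response_prob, rng,
        )
        rows.extend(session_rows)
        answered = [r for r in session_rows if r["responded"]]
        acc = (
            sum(r["chose_target"] for r in answered) / len(answered)
            if answered
            else 0.0
        )
        accuracies.append(acc)
        reached, _ = protocol.criterion_reached(accuracies)
        if reached:
            break
    return pd.DataFrame(rows, columns=list(CHOICE_TABLE_COLUMNS))


def _simulate_tests(
    params: FishParams,
    train_comparison: tuple[int, int],
    rewarded_rule: str,
    experiment: str,
    rng: np.random.Generator,
    start_session: int,
) -> pd.DataFrame:
    rows: list[dict] = []
    session = start_session
    for label, lo in params.test_log_odds.items():
        n_small, n_large = (int(v) for v in label.split("v"))
        block = build_test_block(
            (n_small, n_large),
            rng,
            recall_comparison=train_comparison,
            recall_rule=rewarded_rule,
            start_session_index=session,
        )
        p_test = inv_logit(lo)
        p_recall = inv_logit(params.asymptote_log_odds)

        def p_correct(trial, p_test=p_test, p_recall=p_recall):
            return p_test if trial.phase is Phase.PROBE else p_recall

        for day in block:
            day_rows = _rows_from_session(
                day, params.fish_id, experiment, "test", p_correct,
                params.response_prob, rng,
            )
            # keep only probe trials in the test table; recalls are training-like
            for r, t in zip(day_rows, day.trials):
                if t.phase is Phase.PROBE:
                    rows.append(r)
            session += 1
    return pd.DataFrame(rows, columns=list(CHOICE_TABLE_COLUMNS))


def simulate_study(
    design: str,
    fish_param_sets: list[FishParams] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a full study design and return the combined choice table.

    ``exp1``: 8 fish train on 3 vs 6 (4 rewarded on the smaller, 4 on the
    larger), then probe tests (2 vs 3 or 6 vs 9 by group, plus 5 vs 8).
    ``exp2``: 4 fish train to choose the larger of 2 vs 3, then probe tests
    3 vs 4 and 3 vs 6.  With ``fish_param_sets=None`` the "paper-like"
    presets are used.
    """
    rng = np.random.default_rng(seed)
    preset = paper_like_params(design)
    if fish_param_sets is None:
        fish_param_sets = [
            FishParams(
                fish_id=f"{design}_f{i + 1}",
                start_log_odds=preset["start_log_odds"],
                asymptote_log_odds=preset["asymptote_log_odds"],
                learning_rate=preset["learning_rate"],
                response_prob=preset["response_prob"],
                test_log_odds=dict(preset["test_log_odds"]),
            )
            for i in range(preset["n_fish"])
        ]

    frames: list[pd.DataFrame] = []
    if design == "exp1":
        train_comparison = (3, 6)
        for i, params in enumerate(fish_param_sets):
            rule = "smaller" if i < len(fish_param_sets) // 2 else "larger"
            sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
            train = simulate_learning(
                params, train_comparison, rng=sub_rng, rewarded_rule=rule,
                experiment=design,
            )
            # novel comparison on the trained side of the ratio, plus 5 vs 8
            own_tests = {"2v3" if rule == "smaller" else "6v9", "5v8"}
            params_tests = FishParams(
                **{**params.__dict__,
                   "test_log_odds": {
                       k: v for k, v in params.test_log_odds.items()
                       if k in own_tests
                   }},
            )
            tests = _simulate_tests(
                params_tests, train_comparison, rule, design, sub_rng,
                start_session=int(train["session"].max()) + 1,
            )
            frames.extend([train, tests])
    elif design == "exp2":
        train_comparison = (2, 3)
        for params in fish_param_sets:
            sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
            train = simulate_learning(
                params, train_comparison, rng=sub_rng, rewarded_rule="larger",
                experiment=design,
            )
            tests = _simulate_tests(
                params, train_comparison, "larger", design, sub_rng,
                start_session=int(train["session"].max()) + 1,
            )
            frames.extend([train, tests])
    else:
        raise ValueError("design must be 'exp1' or 'exp2'")

    table = pd.concat(frames, ignore_index=True)
    return validate_choice_table(table)
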
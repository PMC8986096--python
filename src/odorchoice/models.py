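"""Reinforcement-learning models of trial-by-trial choice.

All four models share the same machinery: delay-discounted Rescorla-Wagner
value learning,

    V_{t+1}(s) = V_t(s) + eta * (gamma**d * r_t - V_t(s)),

decision variables combining the predicted state's value with a side bias b
and a perseveration bonus p,

    DV(a) = V(s_a) + b * I[a = right] + p * I[a = previous choice],

and a lapse-mixed softmax,

    P(left) = (1 - lambda) * logistic(beta * (DV(left) - DV(right))) + lambda / 2.

What differs is the *state representation* — whether learning generalizes
between free-choice trials and correct forced-choice trials:

``four_state``
    Full generalization: free choices and correct forced choices share
    "Left"/"Right" states; incorrect forced choices land in
    "Left-NoRwd"/"Right-NoRwd".  This is the task's true generative
    structure.
``six_state``
    No generalization: each (odor, action) pair has its own state.
``hybrid_value``
    Both representations learned in parallel (10 states); decision values
    mix them as ``w4 * V4 + (1 - w4) * V6``.  w4 = 0 reproduces six_state,
    w4 = 1 reproduces four_state, exactly.
``hybrid_learning``
    Six states, but valid outcomes also nudge the paired same-side state
    (forced <-> free) with generalization rate eta_g <= eta.  eta_g = 0
    reproduces six_state; eta_g = eta (from equal initial values)
    reproduces four_state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy.special import expit

from .task import (
    SIDES,
    SessionSchedule,
    StaircaseConfig,
    StaircaseState,
    TrialRecord,
    other_side,
    resolve_trial,
    staircase_update,
)

MODELS = ("four_state", "six_state", "hybrid_value", "hybrid_learning")

FOUR_STATES = ("Left", "Right", "Left-NoRwd", "Right-NoRwd")
SIX_STATES = (
    "left_forced:left",
    "left_forced:right",
    "right_forced:left",
    "right_forced:right",
    "free:left",
    "free:right",
)

#: placeholder delay used when no reward was delivered (gamma**d * 0 == 0)
_NO_REWARD_DELAY = 0.5


@dataclass(frozen=True)
class ModelParams:
    """Free parameters shared by all models.

    eta, gamma in [0, 1]; beta >= 0; bias_b > 0 favors right; persev_p > 0
    repeats the previous choice; lapse in [0, 1].  ``w4`` is only meaningful
    for hybrid_value, ``eta_g`` (with eta_g <= eta) only for hybrid_learning.
    """

    eta: float
    gamma: float
    beta: float
    bias_b: float = 0.0
    persev_p: float = 0.0
    lapse: float = 0.0
    w4: float | None = None
    eta_g: float | None = None

    def __post_init__(self) -> None:
        for name in ("eta", "gamma", "lapse"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.w4 is not None and not (0.0 <= self.w4 <= 1.0):
            raise ValueError("w4 must lie in [0, 1]")
        if self.eta_g is not None and not (0.0 <= self.eta_g <= self.eta):
            raise ValueError("eta_g must lie in [0, eta]")


@dataclass(frozen=True)
class StateValueTable:
    """Values V(s) over the states of one representation."""

    representation: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        labels = _state_labels(self.representation)
        if set(self.values) != set(labels):
            raise ValueError(f"table must cover exactly the states {labels}")
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ValueError("state values must be finite")


@dataclass(frozen=True)
class DecisionContext:
    odor: str
    previous_choice: str | None = None


def _state_labels(representation: str) -> tuple[str, ...]:
    if representation in ("four_state",):
        return FOUR_STATES
    if representation in ("six_state", "hybrid_learning"):
        return SIX_STATES
    raise ValueError(f"unknown representation {representation!r}")


def init_table(representation: str, value: float = 0.0) -> StateValueTable:
    return StateValueTable(
        representation, {s: value for s in _state_labels(representation)}
    )


def state_for(odor: str, action: str, representation: str):
    """Map (odor, action) to the predicted state label(s).

    four_state: valid pairs share "Left"/"Right"; invalid forced pairs land
    in the chosen side's NoRwd state.  six_state: one label per (odor,
    action) pair.  hybrid_value: the (four_state, six_state) label pair.
    """
    if odor not in ("left_forced", "right_forced", "free"):
        raise ValueError(f"unknown odor {odor!r}")
    if action not in SIDES:
        raise ValueError(f"unknown action {action!r}")
    if representation == "hybrid_value":
        return (
            state_for(odor, action, "four_state"),
            state_for(odor, action, "six_state"),
        )
    if representation == "four_state":
        valid = odor == "free" or odor == f"{action}_forced"
        side = action.capitalize()
        return side if valid else f"{side}-NoRwd"
    if representation in ("six_state", "hybrid_learning"):
        return f"{odor}:{action}"
    raise ValueError(f"unknown representation {representation!r}")


def _target(r: float, d: float, params: ModelParams) -> float:
    return (params.gamma**d) * r if r > 0 else 0.0


def update_values(
    table: StateValueTable, state: str, r: float, d: float, params: ModelParams
) -> StateValueTable:
    """Rescorla-Wagner step on one state: V += eta * (gamma**d * r - V)."""
    if state not in table.values:
        raise KeyError(f"state {state!r} not in table")
    values = dict(table.values)
    values[state] += params.eta * (_target(r, d, params) - values[state])
    return replace(table, values=values)


def hybrid_learning_update(
    table: StateValueTable,
    odor: str,
    action: str,
    r: float,
    d: float,
    params: ModelParams,
    valid: bool = True,
) -> StateValueTable:
    """Six-state update plus generalization to the paired same-side state.

    On valid trials the experienced state moves toward gamma**d * r at rate
    eta and the paired state (forced <-> free, same side) moves toward the
    same target at rate eta_g, each relative to its own current value.
    Invalid forced choices update only their own state with r = 0.
    """
    eta_g = params.eta_g or 0.0
    state = state_for(odor, action, "six_state")
    values = dict(table.values)
    target = _target(r, d, params)
    values[state] += params.eta * (target - values[state])
    if valid and eta_g > 0:
        pair = (
            f"{action}_forced:{action}" if odor == "free" else f"free:{action}"
        )
        values[pair] += eta_g * (target - values[pair])
    return replace(table, values=values)


def decision_variables(
    tables, context: DecisionContext, params: ModelParams, model: str
) -> tuple[float, float]:
    """DV(a) = V(s_a) + b * I[a=right] + p * I[a=previous] for a in (left, right).

    ``tables`` is a single :class:`StateValueTable` (four_state, six_state,
    hybrid_learning) or a ``(four_table, six_table)`` pair (hybrid_value,
    where V(s_a) = w4 * V4 + (1 - w4) * V6).
    """
    dvs = []
    for action in SIDES:
        if model == "hybrid_value":
            t4, t6 = tables
            s4, s6 = state_for(context.odor, action, "hybrid_value")
            w4 = params.w4 if params.w4 is not None else 0.0
            v = w4 * t4.values[s4] + (1.0 - w4) * t6.values[s6]
        else:
            rep = "four_state" if model == "four_state" else "six_state"
            v = tables.values[state_for(context.odor, action, rep)]
        dv = v
        if action == "right":
            dv += params.bias_b
        if context.previous_choice == action:
            dv += params.persev_p
        dvs.append(dv)
    return dvs[0], dvs[1]


def choice_probability(dv_left: float, dv_right: float, params: ModelParams) -> float:
    """Lapse-mixed softmax probability of choosing left."""
    core = expit(params.beta * (dv_left - dv_right))
    return (1.0 - params.lapse) * core + params.lapse / 2.0


class ModelState:
    """Mutable per-session agent state: value table(s) and previous choice."""

    def __init__(self, model: str, params: ModelParams):
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
        self.model = model
        self.params = params
        self.reset_session()

    def reset_session(self) -> None:
        """Zero all values and forget the previous choice (no carry-over)."""
        if self.model == "four_state":
            self.tables = init_table("four_state")
        elif self.model == "hybrid_value":
            self.tables = (init_table("four_state"), init_table("six_state"))
        else:
            self.tables = init_table("six_state")
        self.previous_choice: str | None = None

    def p_left(self, odor: str) -> float:
        ctx = DecisionContext(odor, self.previous_choice)
        dv_l, dv_r = decision_variables(self.tables, ctx, self.params, self.model)
        return choice_probability(dv_l, dv_r, self.params)

    def observe(self, odor: str, choice: str, valid: bool, r: float, d: float) -> None:
        """Apply the value update(s) implied by the trial's outcome."""
        if not valid:
            r, d = 0.0, _NO_REWARD_DELAY
        elif not np.isfinite(d):
            d = _NO_REWARD_DELAY
        if self.model == "four_state":
            s = state_for(odor, choice, "four_state")
            self.tables = update_values(self.tables, s, r, d, self.params)
        elif self.model == "six_state":
            s = state_for(odor, choice, "six_state")
            self.tables = update_values(self.tables, s, r, d, self.params)
        elif self.model == "hybrid_value":
            t4, t6 = self.tables
            s4, s6 = state_for(odor, choice, "hybrid_value")
            self.tables = (
                update_values(t4, s4, r, d, self.params),
                update_values(t6, s6, r, d, self.params),
            )
        else:  # hybrid_learning
            self.tables = hybrid_learning_update(
                self.tables, odor, choice, r, d, self.params, valid=valid
            )
        self.previous_choice = choice


def trial_step(state: ModelState, trial: TrialRecord) -> float:
    """Probability of choosing left on ``trial`` before seeing its choice,
    then apply the update implied by the recorded choice and outcome.

    Mutates ``state`` and returns P(left).  Forced trials use the same
    choice rule as free trials; wrong forced choices simply earn nothing.
    """
    p = state.p_left(trial.odor)
    state.observe(
        trial.odor, trial.choice, trial.valid, trial.reward_drops, trial.reward_delay_s
    )
    return p


def simulate_agent(
    model: str,
    params: ModelParams,
    schedule: SessionSchedule,
    seed: int,
    staircase_config: StaircaseConfig | None = None,
    animal_id: str = "sim",
    session_id: str = "s0",
) -> list[TrialRecord]:
    """Closed-loop simulation of one session: agent + task + staircase.

    The single seeded RNG draws one uniform per trial, so two models that
    assign identical choice probabilities to every trial produce identical
    logs at the same seed.
    """
    rng = np.random.default_rng(seed)
    state = ModelState(model, params)
    staircase = StaircaseState.from_config(
        staircase_config or StaircaseConfig()
    )
    records = []
    for t in range(1, schedule.n_trials + 1):
        odor = schedule.odor_sequence[t - 1]
        p = state.p_left(odor)
        choice = "left" if rng.random() < p else "right"
        rec = resolve_trial(schedule, t, choice, staircase, animal_id, session_id)
        staircase = staircase_update(staircase, rec)
        state.observe(odor, choice, rec.valid, rec.reward_drops, rec.reward_delay_s)
        records.append(rec)
    return records
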
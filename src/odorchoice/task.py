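"""Simulator of the odor-guided two-well choice task.

Rats (or simulated agents) sample one of three odors at a central port and
respond at a left or right fluid well.  Two odors force a particular side
(choosing the other well ends the trial unrewarded); the third leaves the
choice free.  Each session holds four blocks: two *delay* blocks in which one
well pays after 0.5 s ("short") and the other after a staircased 1-7 s delay
("long"), then two *magnitude* blocks in which one well pays one drop
("small") and the other two drops ("big", still at 0.5 s).  Contingencies
reverse unsignaled at every block switch, and the well that was "short" at
the end of block 2 is the one that becomes "small" in block 3.

This module builds session schedules, resolves choices into outcomes, runs
the adaptive delay staircase, and reads/writes trial-log CSV files.  It is
also the package's synthetic-data generator: paired with an agent from
:mod:`odorchoice.models` it produces closed-loop trial logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ODORS = ("left_forced", "right_forced", "free")
SIDES = ("left", "right")
BLOCK_TYPES = ("delay", "magnitude")

#: exact column set and order of the trial-log CSV
TRIAL_LOG_COLUMNS = (
    "animal_id",
    "session_id",
    "trial_index",
    "block_index",
    "block_type",
    "odor",
    "choice",
    "valid",
    "reward_drops",
    "reward_delay_s",
    "correct",
)


class TrialLogError(ValueError):
    """Raised when a trial-log file violates the format contract."""


def other_side(side: str) -> str:
    return "right" if side == "left" else "left"


@dataclass(frozen=True)
class RewardSpec:
    """Outcome delivered at one well within one block.

    ``staircased`` marks the "long" option of delay blocks, whose effective
    delay is read from the live staircase at resolution time; ``delay_s``
    then records the staircase's initial setting.
    """

    drops: int
    delay_s: float
    staircased: bool = False

    def __post_init__(self) -> None:
        if self.drops not in (1, 2):
            raise ValueError(f"drops must be 1 or 2, got {self.drops}")
        if not self.delay_s > 0:
            raise ValueError("delay_s must be positive")


@dataclass(frozen=True)
class BlockSpec:
    index: int
    block_type: str
    left_outcome: RewardSpec
    right_outcome: RewardSpec
    length: int

    def __post_init__(self) -> None:
        if self.block_type not in BLOCK_TYPES:
            raise ValueError(f"unknown block_type {self.block_type!r}")
        if self.length <= 0:
            raise ValueError("block length must be positive")

    def outcome(self, side: str) -> RewardSpec:
        return self.left_outcome if side == "left" else self.right_outcome

    @property
    def better_side(self) -> str:
        """Side holding the short (delay block) or big (magnitude) outcome."""
        if self.block_type == "delay":
            return "right" if self.left_outcome.staircased else "left"
        return "left" if self.left_outcome.drops == 2 else "right"


@dataclass(frozen=True)
class StaircaseConfig:
    """Adaptive titration of the long-reward delay.

    A weighted up/down rule: choosing long raises the delay by
    ``2 * step_s * (1 - target_long_fraction)`` and choosing short lowers it
    by ``2 * step_s * target_long_fraction``, so the equilibrium long-choice
    fraction is ``target_long_fraction``; at the default target of 0.5 the
    steps are the symmetric ±``step_s``.  Delay clamped to
    [min_delay_s, max_delay_s] after every update.
    """

    initial_delay_s: float = 4.0
    step_s: float = 0.5
    target_long_fraction: float = 0.5
    min_delay_s: float = 1.0
    max_delay_s: float = 7.0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_long_fraction < 1.0):
            raise ValueError("target_long_fraction must lie in (0, 1)")
        if not (self.min_delay_s <= self.initial_delay_s <= self.max_delay_s):
            raise ValueError("initial delay outside [min, max]")


@dataclass(frozen=True)
class StaircaseState:
    current_delay_s: float
    step_s: float = 0.5
    target_long_fraction: float = 0.5
    min_delay_s: float = 1.0
    max_delay_s: float = 7.0
    n_long: int = 0
    n_short: int = 0

    @classmethod
    def from_config(cls, config: StaircaseConfig | None = None) -> "StaircaseState":
        config = config or StaircaseConfig()
        return cls(
            current_delay_s=config.initial_delay_s,
            step_s=config.step_s,
            target_long_fraction=config.target_long_fraction,
            min_delay_s=config.min_delay_s,
            max_delay_s=config.max_delay_s,
        )


@dataclass(frozen=True)
class SessionConfig:
    """Knobs of the session generator.

    Block lengths are Normal(mean, sd) rounded to integers and redrawn below
    ``block_length_floor``.  Odor sequences are built per ``window_length``
    window: ``free_per_window`` free-choice trials, the remaining forced
    trials split as evenly as possible between sides (the side receiving the
    extra forced trial alternates across windows), shuffled within the
    window.
    """

    block_length_mean: float = 70.0
    block_length_sd: float = 14.0
    block_length_floor: int = 20
    window_length: int = 20
    free_per_window: int = 7
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)

    def __post_init__(self) -> None:
        if not (0 < self.free_per_window < self.window_length):
            raise ValueError("free_per_window must lie in (0, window_length)")


@dataclass(frozen=True)
class SessionSchedule:
    """One session's block sequence, odor sequence and provenance seed."""

    blocks: tuple[BlockSpec, ...]
    odor_sequence: tuple[str, ...]
    initial_better_side: str
    seed: int

    def __post_init__(self) -> None:
        if len(self.odor_sequence) != sum(b.length for b in self.blocks):
            raise ValueError("odor sequence length must equal total block length")
        starts, t = [], 1
        for b in self.blocks:
            starts.append(t)
            t += b.length
        object.__setattr__(self, "_block_starts", tuple(starts))

    @property
    def n_trials(self) -> int:
        return len(self.odor_sequence)

    def block_of(self, trial_index: int) -> BlockSpec:
        """Block containing 1-based ``trial_index``."""
        if not (1 <= trial_index <= self.n_trials):
            raise IndexError(f"trial_index {trial_index} outside session")
        i = int(np.searchsorted(self._block_starts, trial_index, side="right")) - 1
        return self.blocks[i]


@dataclass(frozen=True)
class TrialRecord:
    """One trial's full description; the unit of likelihood evaluation."""

    animal_id: str
    session_id: str
    trial_index: int
    block_index: int
    block_type: str
    odor: str
    choice: str
    valid: bool
    reward_drops: int
    reward_delay_s: float  # NaN when unrewarded
    correct: bool


def sample_block_length(
    rng: np.random.Generator,
    mean: float = 70.0,
    sd: float = 14.0,
    floor: int = 20,
) -> int:
    """Draw one block length: round(Normal(mean, sd)), redrawn below ``floor``.

    With the defaults the floor sits >3.5 SD below the mean, so the sample
    moments match (mean, sd) to well within Monte-Carlo error.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if floor < 1:
        raise ValueError("floor must be at least 1")
    if sd == 0:
        length = int(round(mean))
        if length < floor:
            raise ValueError(
                f"degenerate length {length} below floor {floor}; "
                "truncation cannot repair it"
            )
        return length
    if mean + 6 * sd < floor:
        raise ValueError("distribution mass lies entirely below the floor")
    for _ in range(10_000):
        length = int(round(rng.normal(mean, sd)))
        if length >= floor:
            return length
    raise ValueError("block-length rejection sampling failed to clear the floor")


def _build_blocks(
    rng: np.random.Generator, config: SessionConfig
) -> tuple[tuple[BlockSpec, ...], str]:
    lengths = [
        sample_block_length(
            rng,
            config.block_length_mean,
            config.block_length_sd,
            config.block_length_floor,
        )
        for _ in range(4)
    ]
    initial_better = SIDES[int(rng.integers(2))]
    short = RewardSpec(1, 0.5)
    long = RewardSpec(1, config.staircase.initial_delay_s, staircased=True)
    small = RewardSpec(1, 0.5)
    big = RewardSpec(2, 0.5)
    blocks = []
    # better side alternates every block: the well that is short at the end of
    # block 2 becomes small (i.e. worse) in block 3
    for i in range(4):
        better = initial_better if i % 2 == 0 else other_side(initial_better)
        block_type = "delay" if i < 2 else "magnitude"
        good, bad = (short, long) if block_type == "delay" else (big, small)
        left, right = (good, bad) if better == "left" else (bad, good)
        blocks.append(BlockSpec(i + 1, block_type, left, right, lengths[i]))
    return tuple(blocks), initial_better


def _build_odor_sequence(
    rng: np.random.Generator, n_trials: int, config: SessionConfig
) -> tuple[str, ...]:
    w = config.window_length
    n_free = config.free_per_window
    n_forced = w - n_free
    heavy_first = SIDES[int(rng.integers(2))]
    seq: list[str] = []
    for win in range(math.ceil(n_trials / w)):
        heavy = heavy_first if win % 2 == 0 else other_side(heavy_first)
        window = (
            ["free"] * n_free
            + [f"{heavy}_forced"] * math.ceil(n_forced / 2)
            + [f"{other_side(heavy)}_forced"] * (n_forced // 2)
        )
        seq.extend(np.array(window)[rng.permutation(w)])
    return tuple(seq[:n_trials])


def build_session_schedule(config: SessionConfig, seed: int) -> SessionSchedule:
    """Deterministically build one session schedule from (config, seed)."""
    rng = np.random.default_rng(seed)
    blocks, initial_better = _build_blocks(rng, config)
    n_trials = sum(b.length for b in blocks)
    odors = _build_odor_sequence(rng, n_trials, config)
    return SessionSchedule(blocks, odors, initial_better, seed)


def resolve_trial(
    schedule: SessionSchedule,
    trial_index: int,
    choice: str,
    staircase: StaircaseState,
    animal_id: str = "sim",
    session_id: str = "s0",
) -> TrialRecord:
    """Turn a choice on trial ``trial_index`` into its outcome record.

    Forced trials are valid only when the choice matches the cued side; an
    invalid choice terminates the trial unrewarded.  Valid trials pay the
    chosen well's current block outcome, with long delays read from the live
    staircase.
    """
    if choice not in SIDES:
        raise ValueError(f"unknown choice {choice!r}")
    block = schedule.block_of(trial_index)
    odor = schedule.odor_sequence[trial_index - 1]
    valid = odor == "free" or odor == f"{choice}_forced"
    if valid:
        spec = block.outcome(choice)
        drops = spec.drops
        delay = staircase.current_delay_s if spec.staircased else spec.delay_s
    else:
        drops, delay = 0, float("nan")
    correct = valid if odor != "free" else choice == block.better_side
    return TrialRecord(
        animal_id=animal_id,
        session_id=session_id,
        trial_index=trial_index,
        block_index=block.index,
        block_type=block.block_type,
        odor=odor,
        choice=choice,
        valid=valid,
        reward_drops=drops,
        reward_delay_s=delay,
        correct=correct,
    )


def staircase_update(staircase: StaircaseState, trial: TrialRecord) -> StaircaseState:
    """Advance the staircase after a trial; no-op except on free delay trials.

    On free-choice trials in delay blocks: choosing the long side raises the
    delay, choosing the short side lowers it (weighted steps, see
    :class:`StaircaseConfig`), clamped to [min_delay_s, max_delay_s].
    """
    if trial.block_type != "delay" or trial.odor != "free":
        return staircase
    chose_long = not trial.correct  # better side in delay blocks is the short one
    if chose_long:
        delta = 2.0 * staircase.step_s * (1.0 - staircase.target_long_fraction)
    else:
        delta = -2.0 * staircase.step_s * staircase.target_long_fraction
    new_delay = min(
        staircase.max_delay_s, max(staircase.min_delay_s, staircase.current_delay_s + delta)
    )
    return replace(
        staircase,
        current_delay_s=new_delay,
        n_long=staircase.n_long + int(chose_long),
        n_short=staircase.n_short + int(not chose_long),
    )


def session_config_from_dict(raw: dict) -> SessionConfig:
    """Build a :class:`SessionConfig` from a nested key/value mapping
    (e.g. parsed YAML); the ``staircase`` sub-mapping feeds
    :class:`StaircaseConfig`."""
    raw = dict(raw or {})
    stair = StaircaseConfig(**raw.pop("staircase", {}))
    return SessionConfig(staircase=stair, **raw)


# ---------------------------------------------------------------------------
# trial-log CSV


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records], columns=list(TRIAL_LOG_COLUMNS))
    return df


def frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    recs = []
    for row in df.itertuples(index=False):
        recs.append(
            TrialRecord(
                animal_id=str(row.animal_id),
                session_id=str(row.session_id),
                trial_index=int(row.trial_index),
                block_index=int(row.block_index),
                block_type=str(row.block_type),
                odor=str(row.odor),
                choice=str(row.choice),
                valid=bool(row.valid),
                reward_drops=int(row.reward_drops),
                reward_delay_s=float(row.reward_delay_s),
                correct=bool(row.correct),
            )
        )
    return recs


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    if list(df.columns) != list(TRIAL_LOG_COLUMNS):
        raise TrialLogError(
            f"trial log must have columns {list(TRIAL_LOG_COLUMNS)}, got {list(df.columns)}"
        )
    checks = {
        "odor": set(ODORS),
        "choice": set(SIDES),
        "block_type": set(BLOCK_TYPES),
    }
    for col, vocab in checks.items():
        bad = ~df[col].isin(vocab)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise TrialLogError(
                f"row {row}: {col} value {df[col].iloc[row - 1]!r} not in {sorted(vocab)}"
            )
    bad = ~df["reward_drops"].isin([0, 1, 2])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise TrialLogError(f"row {row}: reward_drops must be 0, 1 or 2")
    for _, grp in df.groupby(["animal_id", "session_id"], sort=False):
        idx = grp["trial_index"].to_numpy()
        if len(idx) and (np.diff(idx) <= 0).any():
            row = int(grp.index[np.flatnonzero(np.diff(idx) <= 0)[0] + 1]) + 1
            raise TrialLogError(f"row {row}: non-monotone trial_index within session")
    return df


def write_trial_log(records: Iterable[TrialRecord] | pd.DataFrame, path) -> None:
    """Write a trial log CSV (fixed header, UTF-8, '.' decimal)."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    _validate_frame(df)
    df.to_csv(path, index=False, encoding="utf-8")


def read_trial_log(path) -> pd.DataFrame:
    """Read and validate a trial log CSV; parse errors name the data row."""
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise TrialLogError("trial log file is empty (missing header)") from exc
    if df.empty:
        return df.reindex(columns=list(TRIAL_LOG_COLUMNS))
    try:
        df["valid"] = df["valid"].astype(bool)
        df["correct"] = df["correct"].astype(bool)
        df["trial_index"] = df["trial_index"].astype(int)
        df["block_index"] = df["block_index"].astype(int)
        df["reward_drops"] = df["reward_drops"].astype(int)
        df["reward_delay_s"] = df["reward_delay_s"].astype(float)
    except (KeyError, ValueError, TypeError) as exc:
        raise TrialLogError(f"malformed trial log: {exc}") from exc
    return _validate_frame(df)
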
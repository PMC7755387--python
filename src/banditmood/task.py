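"""Generation of stable and volatile car-race bandit schedules.

The task is a one-armed bandit dressed up as a two-car race: exactly one
car wins each trial.  One car (the "best" car) wins 80% of races.  In the
stable environment the best car is fixed for the whole session; in the
volatile environment the best-car identity reverses every 20 trials.
Outcomes are locally pseudo-randomised so that in every consecutive
10-trial sub-block the current best car wins on exactly 8 trials.  Reward
magnitudes are drawn independently of outcome probability from a fixed
list of (left, right) point pairs, and a happiness probe is inserted every
3-4 trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The (left option, right option) reward pairs used on every trial,
#: sampled uniformly with replacement.  Asymmetric pairs appear in both
#: orders so each magnitude ends up on each side of the screen.
REWARD_PAIRS: tuple[tuple[int, int], ...] = (
    (10, 10), (10, 40), (10, 60), (10, 80), (20, 40),
    (40, 10), (40, 20), (40, 40), (60, 10), (80, 10),
)

STABLE = "stable"
VOLATILE = "volatile"
CARS = ("A", "B")


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of one task environment.

    ``wins_per_sub_block / sub_block_len`` must equal ``p_best`` so the
    8-of-10 construction reproduces the nominal contingency exactly.
    """

    environment: str = STABLE
    n_trials: int = 80
    block_len: int = 20          # reversal period; volatile only
    p_best: float = 0.8
    sub_block_len: int = 10
    wins_per_sub_block: int = 8
    reward_pairs: tuple[tuple[int, int], ...] = REWARD_PAIRS
    rating_gap_choices: tuple[int, ...] = (3, 4)
    side_swap_gap_range: tuple[int, int] = (6, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.environment not in (STABLE, VOLATILE):
            raise ValueError(f"unknown environment {self.environment!r}")
        if self.n_trials % self.sub_block_len != 0:
            raise ValueError(
                f"n_trials={self.n_trials} not divisible by "
                f"sub_block_len={self.sub_block_len}"
            )
        if self.environment == VOLATILE and self.block_len % self.sub_block_len != 0:
            raise ValueError(
                f"block_len={self.block_len} not divisible by "
                f"sub_block_len={self.sub_block_len}"
            )
        if self.wins_per_sub_block / self.sub_block_len != self.p_best:
            raise ValueError(
                "wins_per_sub_block / sub_block_len must equal p_best "
                f"({self.wins_per_sub_block}/{self.sub_block_len} != {self.p_best})"
            )
        if not set(self.rating_gap_choices) <= {3, 4}:
            raise ValueError("rating gaps must be drawn from {3, 4}")


@dataclass
class TrialSchedule:
    """One generated session's contingencies, 1-based trial indexing.

    ``winner`` holds the car that wins each race whatever the subject
    chooses (the race outcome is exogenous), so a schedule fully
    determines the observable outcome stream.
    """

    environment: str
    seed: int
    best_car: np.ndarray        # "A"/"B" per trial
    winner: np.ndarray          # "A"/"B" per trial
    reward_A: np.ndarray        # points offered on car A
    reward_B: np.ndarray
    side_of_A: np.ndarray       # "left"/"right"
    is_rating_trial: np.ndarray  # bool
    config: TaskConfig = field(repr=False, default=None)

    @property
    def n_trials(self) -> int:
        return len(self.winner)

    @property
    def trial_index(self) -> np.ndarray:
        return np.arange(1, self.n_trials + 1)

    @property
    def rating_trials(self) -> np.ndarray:
        """1-based indices of trials followed by a happiness probe."""
        return self.trial_index[self.is_rating_trial]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": self.trial_index,
                "environment": self.environment,
                "best_car": self.best_car,
                "winner": self.winner,
                "reward_A": self.reward_A,
                "reward_B": self.reward_B,
                "side_of_A": self.side_of_A,
                "is_rating_trial": self.is_rating_trial,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, seed: int = -1) -> "TrialSchedule":
        env = str(frame["environment"].iloc[0])
        return cls(
            environment=env,
            seed=seed,
            best_car=frame["best_car"].to_numpy(dtype="U1"),
            winner=frame["winner"].to_numpy(dtype="U1"),
            reward_A=frame["reward_A"].to_numpy(dtype=int),
            reward_B=frame["reward_B"].to_numpy(dtype=int),
            side_of_A=frame["side_of_A"].to_numpy(dtype="U5"),
            is_rating_trial=frame["is_rating_trial"].to_numpy(dtype=bool),
        )


def place_rating_trials(
    n_trials: int,
    gap_choices: tuple[int, ...] = (3, 4),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Boolean flags marking trials followed by a happiness probe.

    Consecutive probes are separated by gaps drawn uniformly from
    ``gap_choices``; the first probe falls within the first
    ``max(gap_choices)`` trials.
    """
    if not set(gap_choices) <= {3, 4}:
        raise ValueError("rating gaps must be drawn from {3, 4}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    flags = np.zeros(n_trials, dtype=bool)
    pos = 0
    while True:
        pos += rng.choice(gap_choices)
        if pos > n_trials:
            break
        flags[pos - 1] = True
    return flags


def _side_swap_sides(n_trials: int, gap_range: tuple[int, int],
                     rng: np.random.Generator) -> np.ndarray:
    """Screen side of car A per trial; swapped every 6-10 trials."""
    lo, hi = gap_range
    side = rng.choice(["left", "right"])
    sides = np.empty(n_trials, dtype="U5")
    next_swap = rng.integers(lo, hi + 1)
    for t in range(n_trials):
        if t == next_swap:
            side = "left" if side == "right" else "right"
            next_swap = t + rng.integers(lo, hi + 1)
        sides[t] = side
    return sides


def generate_schedule(config: TaskConfig) -> TrialSchedule:
    """Generate one session's schedule; pure function of (config, seed).

    The best car's identity is constant (stable) or flips every
    ``block_len`` trials (volatile, initial car by coin flip); within each
    ``sub_block_len`` run of trials the positions of the best car's wins
    are a uniformly random permutation subject to the exact
    ``wins_per_sub_block``-of-``sub_block_len`` constraint.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_trials

    first_best = rng.choice(CARS)
    other = "B" if first_best == "A" else "A"
    if config.environment == STABLE:
        best_car = np.full(n, first_best, dtype="U1")
    else:
        block_of = np.arange(n) // config.block_len
        best_car = np.where(block_of % 2 == 0, first_best, other).astype("U1")

    # exact wins_per_sub_block best-car wins in every sub-block
    best_wins = np.empty(n, dtype=bool)
    sub = config.sub_block_len
    template = np.r_[
        np.ones(config.wins_per_sub_block, dtype=bool),
        np.zeros(sub - config.wins_per_sub_block, dtype=bool),
    ]
    for start in range(0, n, sub):
        best_wins[start:start + sub] = rng.permutation(template)
    winner = np.where(best_wins, best_car, np.where(best_car == "A", "B", "A"))
    winner = winner.astype("U1")

    sides = _side_swap_sides(n, config.side_swap_gap_range, rng)
    pair_idx = rng.integers(0, len(config.reward_pairs), size=n)
    pairs = np.asarray(config.reward_pairs)[pair_idx]  # (left, right) points
    left_is_A = sides == "left"
    reward_A = np.where(left_is_A, pairs[:, 0], pairs[:, 1])
    reward_B = np.where(left_is_A, pairs[:, 1], pairs[:, 0])

    flags = place_rating_trials(n, config.rating_gap_choices, rng)

    return TrialSchedule(
        environment=config.environment,
        seed=config.seed,
        best_car=best_car,
        winner=winner,
        reward_A=reward_A.astype(int),
        reward_B=reward_B.astype(int),
        side_of_A=sides,
        is_rating_trial=flags,
        config=config,
    )


def stable_config(seed: int = 0, **kwargs) -> TaskConfig:
    return TaskConfig(environment=STABLE, seed=seed, **kwargs)


def volatile_config(seed: int = 0, **kwargs) -> TaskConfig:
    return TaskConfig(environment=VOLATILE, seed=seed, **kwargs)


def reversal_trials(schedule: TrialSchedule) -> np.ndarray:
    """1-based indices of trials on which the best car differs from the
    previous trial (empty for stable schedules)."""
    changes = schedule.best_car[1:] != schedule.best_car[:-1]
    return np.where(changes)[0] + 2
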
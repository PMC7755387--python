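"""Rescorla-Wagner learning, choice selectors, agent simulation and
per-subject maximum-likelihood fitting.

Because exactly one car wins each race and the race outcome is shown
whatever the subject chose, the learner tracks a single belief p_A (the
estimated probability that car A wins); car B's belief is its complement.
Four selectors map beliefs and offered rewards to choice probabilities:

* ``additive``        logistic(beta * (phi*dP + (1-phi)*dR)), dR in [0, 1]
* ``multiplicative``  logistic(beta * (EU_A - EU_B)) with
                      EU = clip(eta*(P-0.5)+0.5, 0, 1) * R
* ``probability_only``  additive with phi fixed at 1
* ``magnitude_only``    additive with phi fixed at 0 (no learner)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.signal import lfilter
from scipy.special import expit

from .task import TrialSchedule

#: Offered rewards are divided by this (the maximum offered points) when
#: the additive selector normalises magnitudes to [0, 1].
REWARD_NORM = 80.0

#: Free parameters and box bounds per selector.
PARAM_BOUNDS = {"alpha": (0.0, 1.0), "beta": (0.0, 50.0),
                "phi": (0.0, 1.0), "eta": (0.0, 10.0)}
CHOICE_MODELS = {
    "additive": ("alpha", "beta", "phi"),
    "multiplicative": ("alpha", "beta", "eta"),
    "probability_only": ("alpha", "beta"),
    "magnitude_only": ("beta",),
}


@dataclass(frozen=True)
class ChoiceParams:
    """Parameter set for one selector; unused fields are ignored."""

    model_id: str = "additive"
    alpha: float = 0.5
    beta: float = 10.0
    phi: float = 0.5
    eta: float = 1.0

    def __post_init__(self) -> None:
        if self.model_id not in CHOICE_MODELS:
            raise ValueError(f"unknown choice model {self.model_id!r}")
        for name in CHOICE_MODELS[self.model_id]:
            lo, hi = PARAM_BOUNDS[name]
            value = getattr(self, name)
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")

    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in CHOICE_MODELS[self.model_id]])

    @classmethod
    def from_free_values(cls, model_id: str, values) -> "ChoiceParams":
        return cls(model_id=model_id,
                   **dict(zip(CHOICE_MODELS[model_id], values)))


@dataclass
class SessionData:
    """One subject x one environment of choices, outcomes and sparse
    happiness ratings (dict: 1-based rating trial -> raw rating, 0-100)."""

    schedule: TrialSchedule
    choices: np.ndarray          # "A"/"B" per trial
    outcomes: np.ndarray         # 1 if chosen car won
    obtained_points: np.ndarray  # chosen reward if win else 0
    ratings: dict[int, float] = field(default_factory=dict)
    subject: str = "s0"

    def __post_init__(self) -> None:
        won = self.choices == self.schedule.winner
        if not np.array_equal(won.astype(int), np.asarray(self.outcomes)):
            raise ValueError("outcomes inconsistent with schedule winners")
        chosen_reward = np.where(self.choices == "A",
                                 self.schedule.reward_A, self.schedule.reward_B)
        if not np.array_equal(self.obtained_points,
                              chosen_reward * self.outcomes):
            raise ValueError("obtained_points inconsistent with outcomes")

    @property
    def environment(self) -> str:
        return self.schedule.environment

    @property
    def n_trials(self) -> int:
        return self.schedule.n_trials


@dataclass
class ChoiceFit:
    """Maximum-likelihood fit of one selector to one session."""

    model_id: str
    params: ChoiceParams
    log_lik: float
    n_trials: int
    converged: bool = True
    n_starts: int = 1
    subject: str = "s0"
    environment: str = "stable"

    @property
    def n_params(self) -> int:
        return len(CHOICE_MODELS[self.model_id])

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_trials) - 2.0 * self.log_lik

    @property
    def pseudo_r2(self) -> float:
        """McFadden pseudo-r^2 against the coin-flip chance model."""
        return 1.0 - self.log_lik / (self.n_trials * np.log(0.5))


def update_belief(p_A: float, outcome_A: int, alpha: float) -> tuple[float, float]:
    """One Rescorla-Wagner step on the win probability of car A.

    Returns (updated belief, probability prediction error).  The race is
    fully observed, so a single update per trial serves both cars via
    complementarity (p_B = 1 - p_A).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    if not 0.0 <= p_A <= 1.0:
        raise ValueError(f"p_A={p_A} outside [0, 1]")
    ppe = outcome_A - p_A
    return p_A + alpha * ppe, ppe


def belief_trace(schedule: TrialSchedule, alpha: float,
                 p0: float = 0.5) -> np.ndarray:
    """Belief p_A held *at choice time* on each trial.

    The outcome stream is exogenous (one car always wins), so the trace
    depends only on the schedule and alpha, not on the choices.  The
    recursion p[t+1] = (1-alpha) p[t] + alpha o[t] is run as a linear
    filter.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    o = (schedule.winner == "A").astype(float)
    n = len(o)
    if alpha == 0.0:
        return np.full(n, p0)
    # p[t] for t>=1 from filtering outcomes o[0..t-1]
    filtered = lfilter([alpha], [1.0, -(1.0 - alpha)], o,
                       zi=[(1.0 - alpha) * p0])[0]
    return np.r_[p0, filtered[:-1]]


def choice_probability(params: ChoiceParams, p_A, reward_A, reward_B):
    """Probability of choosing car A; vectorised over trials."""
    p_A = np.asarray(p_A, dtype=float)
    r_A = np.asarray(reward_A, dtype=float)
    r_B = np.asarray(reward_B, dtype=float)
    m = params.model_id
    if m == "multiplicative":
        # rewards normalised as in the additive selector so the shared
        # beta bound [0, 50] is meaningful and the logistic never
        # saturates over the whole parameter box
        dist_A = np.clip(params.eta * (p_A - 0.5) + 0.5, 0.0, 1.0)
        dist_B = np.clip(params.eta * (0.5 - p_A) + 0.5, 0.0, 1.0)
        dv = (dist_A * r_A - dist_B * r_B) / REWARD_NORM
    else:
        phi = {"additive": params.phi,
               "probability_only": 1.0,
               "magnitude_only": 0.0}[m]
        dp = 2.0 * p_A - 1.0
        dr = (r_A - r_B) / REWARD_NORM
        dv = phi * dp + (1.0 - phi) * dr
    return expit(params.beta * dv)


def simulate_agent(schedule: TrialSchedule, params: ChoiceParams,
                   seed: int | np.random.Generator = 0,
                   subject: str = "s0") -> SessionData:
    """Simulate one session: beliefs start at 0.5, choices are sampled
    from the selector, and the belief is updated after every outcome."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    alpha = params.alpha if params.model_id != "magnitude_only" else 0.0
    p = belief_trace(schedule, alpha)
    p_choose_A = choice_probability(params, p, schedule.reward_A,
                                    schedule.reward_B)
    choose_A = rng.random(schedule.n_trials) < p_choose_A
    choices = np.where(choose_A, "A", "B").astype("U1")
    outcomes = (choices == schedule.winner).astype(int)
    chosen_reward = np.where(choose_A, schedule.reward_A, schedule.reward_B)
    return SessionData(schedule=schedule, choices=choices, outcomes=outcomes,
                       obtained_points=chosen_reward * outcomes,
                       subject=subject)


def session_log_likelihood(session: SessionData,
                           params: ChoiceParams) -> float:
    """Log likelihood of the observed choices under one selector."""
    alpha = params.alpha if params.model_id != "magnitude_only" else 0.0
    p = belief_trace(session.schedule, alpha)
    p_A = choice_probability(params, p, session.schedule.reward_A,
                             session.schedule.reward_B)
    chose_A = session.choices == "A"
    lik = np.where(chose_A, p_A, 1.0 - p_A)
    return float(np.sum(np.log(np.clip(lik, 1e-12, None))))


def fit_choice_model(session: SessionData, model_id: str = "additive",
                     n_starts: int = 10,
                     seed: int | np.random.Generator = 0) -> ChoiceFit:
    """Bounded multi-start MLE of one selector on one session.

    ``n_starts`` uniform-random starting points within the box bounds are
    refined with L-BFGS-B; the best local optimum is returned.
    Deterministic given (session, model_id, n_starts, seed).
    """
    if len(np.unique(session.choices)) < 2:
        raise ValueError("need at least two distinct choices to fit")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    names = CHOICE_MODELS[model_id]
    bounds = [PARAM_BOUNDS[k] for k in names]

    def nll(x: np.ndarray) -> float:
        p = ChoiceParams.from_free_values(model_id, np.clip(
            x, [b[0] for b in bounds], [b[1] for b in bounds]))
        return -session_log_likelihood(session, p)

    best = None
    n_ok = 0
    for _ in range(n_starts):
        x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-8})
        n_ok += bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    return ChoiceFit(
        model_id=model_id,
        params=ChoiceParams.from_free_values(model_id, best.x),
        log_lik=-float(best.fun),
        n_trials=session.n_trials,
        converged=n_ok > 0,
        n_starts=n_starts,
        subject=session.subject,
        environment=session.environment,
    )
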
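"""Momentary-happiness models: exponentially decaying regressions of
sparse 0-100 happiness ratings on trial-history terms.

Every model has the form

    Happiness(t) = w0 + sum_terms  w_term * S_term(t),
    S_term(t)    = sum_{j=1..t} gamma^(t-j) * term_j,

where gamma in [0, 1] is a forgetting factor shared by all terms of a
model.  The candidate history terms are probability prediction errors and
probability estimates (subjective, replayed from the fitted additive
choice model, or objective, from the scheduled 0.2/0.8 contingencies),
expected values, obtained reward magnitudes, and plain win/loss
indicators.  Ratings are attributed to the most recent completed trial,
and decayed sums run over *all* trials up to it, rated or not.

Fitting profiles out an i.i.d. Gaussian noise scale: for each candidate
gamma the linear weights have a closed-form least-squares solution, and
gamma itself is optimised by a dense grid search plus local refinement.
The noise scale is not counted among the model's parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear, minimize_scalar

from .choice import REWARD_NORM, ChoiceFit, SessionData, belief_trace

#: model id -> (term columns entering the decayed regression, total
#: parameter count including w0 and gamma, excluding the noise scale).
HAPPINESS_MODELS: dict[str, tuple[tuple[str, ...], int]] = {
    "ppe_hat": (("ppe_hat",), 3),
    "rpe_hat": (("rpe_hat",), 3),
    "ppe_obj": (("ppe_obj",), 3),
    "rpe_obj": (("rpe_obj",), 3),
    "p_hat_ppe_hat": (("p_hat_c", "ppe_hat"), 4),
    "ev_hat_ppe_hat": (("ev_hat_c", "ppe_hat"), 4),
    "ev_hat_rpe_hat": (("ev_hat_c", "rpe_hat"), 4),
    "p_hat_rpe_hat": (("p_hat_c", "rpe_hat"), 4),
    "reward_mean": (("r_c",), 3),
    "reward_refpoint": (("r", "one"), 4),   # w*(R - RP): RP recovered as -c1/w
    "win_loss": (("win", "loss"), 4),       # +w_win, -w_loss convention
}

RP_BOUNDS = (0.0, 80.0)
W0_BOUNDS = (0.0, 100.0)   # raw-rating fits only


def build_term_history(session: SessionData,
                       choice_fit: ChoiceFit | float) -> pd.DataFrame:
    """Per-trial regressor columns for the happiness models.

    ``choice_fit`` is an additive-model fit for this session (or a bare
    learning rate); the learner is replayed at that rate to obtain the
    subjective probability of the *chosen* car on every trial.  Objective
    terms use the scheduled 0.8/0.2 contingency instead.  Reward terms
    use the obtained reward (0 on losses): rescaled to [0, 1] for the
    prediction-error terms, raw points for the reward-history terms.
    """
    if isinstance(choice_fit, ChoiceFit):
        if choice_fit.model_id != "additive":
            raise ValueError("term history requires an additive-model fit, "
                             f"got {choice_fit.model_id!r}")
        alpha = choice_fit.params.alpha
    else:
        alpha = float(choice_fit)

    sched = session.schedule
    p_A = belief_trace(sched, alpha)
    chose_A = session.choices == "A"
    p_chosen = np.where(chose_A, p_A, 1.0 - p_A)
    outcome = session.outcomes.astype(float)

    offered = np.where(chose_A, sched.reward_A, sched.reward_B) / REWARD_NORM
    obtained = session.obtained_points / REWARD_NORM
    ev_hat = p_chosen * offered

    p_obj = np.where(session.choices == sched.best_car, 0.8, 0.2)
    ev_obj = p_obj * offered

    r_points = session.obtained_points.astype(float)
    return pd.DataFrame(
        {
            "trial": sched.trial_index,
            "p_hat": p_chosen,
            "ppe_hat": outcome - p_chosen,
            "rpe_hat": obtained - ev_hat,
            "ppe_obj": outcome - p_obj,
            "rpe_obj": obtained - ev_obj,
            "p_hat_c": p_chosen - 0.5,
            "ev_hat_c": ev_hat - ev_hat.mean(),
            "r": r_points,
            "r_c": r_points - r_points.mean(),
            "one": np.ones(len(outcome)),
            "win": outcome,
            "loss": 1.0 - outcome,
        }
    )


def decayed_series(values, gamma: float) -> np.ndarray:
    """Running decayed sums S_t = gamma*S_{t-1} + x_t for t = 1..n."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma={gamma} outside [0, 1]")
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    acc = 0.0
    for i, x in enumerate(values):
        acc = gamma * acc + x
        out[i] = acc
    return out


def decayed_sum(series, gamma: float, t: int) -> float:
    """Decayed history sum at 1-based trial ``t`` (recursive form)."""
    if t < 1:
        raise ValueError("t must be >= 1")
    return float(decayed_series(np.asarray(series)[:t], gamma)[-1])


@dataclass
class HappinessFit:
    """One happiness model fitted to one session's ratings."""

    model_id: str
    w0: float
    weights: dict[str, float]
    gamma: float
    rp: float | None
    log_lik: float
    n_ratings: int
    r2: float                 # squared correlation, predicted vs observed
    var_explained: float      # 1 - RSS/TSS
    zscored: bool = True
    flagged: bool = False
    flag_reason: str = ""
    subject: str = "s0"
    environment: str = "stable"

    @property
    def n_params(self) -> int:
        return HAPPINESS_MODELS[self.model_id][1]

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_ratings) - 2.0 * self.log_lik


def _design(terms: pd.DataFrame, model_id: str, gamma: float,
            rating_trials: np.ndarray) -> np.ndarray:
    cols, _ = HAPPINESS_MODELS[model_id]
    idx = np.asarray(rating_trials, dtype=int) - 1
    X = np.column_stack(
        [np.ones(len(idx))]
        + [decayed_series(terms[c].to_numpy(), gamma)[idx] for c in cols]
    )
    return X


def predict_happiness(model_id: str, w0: float, weights: dict[str, float],
                      gamma: float, terms: pd.DataFrame,
                      rating_trials, rp: float | None = None) -> np.ndarray:
    """Model predictions at the given rating trials.

    ``weights`` is keyed by term column; the win-loss model expects
    ``w_win``/``w_loss`` (loss weight entered with a minus sign) and the
    reference-point model expects ``w_r`` plus ``rp``.
    """
    cols, _ = HAPPINESS_MODELS[model_id]
    X = _design(terms, model_id, gamma, np.asarray(rating_trials))
    if model_id == "win_loss":
        coef = np.array([w0, weights["w_win"], -weights["w_loss"]])
    elif model_id == "reward_refpoint":
        w = weights["w_r"]
        coef = np.array([w0, w, -w * (rp if rp is not None else 0.0)])
    else:
        coef = np.r_[w0, [weights[f"w_{c}"] for c in cols]]
    return X @ coef


def _solve_weights(X: np.ndarray, y: np.ndarray,
                   zscored: bool) -> tuple[np.ndarray, float]:
    """Least-squares weights; the intercept is boxed to the rating scale
    when fitting raw (non-standardised) ratings."""
    if zscored:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    else:
        k = X.shape[1]
        lo = np.full(k, -np.inf)
        hi = np.full(k, np.inf)
        lo[0], hi[0] = W0_BOUNDS
        coef = lsq_linear(X, y, bounds=(lo, hi)).x
    rss = float(np.sum((y - X @ coef) ** 2))
    return coef, rss


def _package_fit(model_id: str, coef: np.ndarray, gamma: float,
                 rss: float, X: np.ndarray, y: np.ndarray, zscored: bool,
                 session: SessionData, flagged: bool,
                 flag_reason: str) -> HappinessFit:
    cols, _ = HAPPINESS_MODELS[model_id]
    w0 = float(coef[0])
    rp = None
    if model_id == "win_loss":
        weights = {"w_win": float(coef[1]), "w_loss": float(-coef[2])}
    elif model_id == "reward_refpoint":
        w = float(coef[1])
        rp = float(np.clip(-coef[2] / w, *RP_BOUNDS)) if w != 0.0 else 0.0
        weights = {"w_r": w}
    else:
        weights = {f"w_{c}": float(v) for c, v in zip(cols, coef[1:])}

    n = len(y)
    pred = X @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    var_explained = 1.0 - rss / tss if tss > 0 else np.nan
    if np.std(pred) > 0 and np.std(y) > 0:
        r2 = float(np.corrcoef(pred, y)[0, 1] ** 2)
    else:
        r2 = np.nan
    sigma2 = max(rss / n, 1e-12)
    log_lik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return HappinessFit(
        model_id=model_id, w0=w0, weights=weights, gamma=float(gamma), rp=rp,
        log_lik=float(log_lik), n_ratings=n, r2=r2,
        var_explained=var_explained, zscored=zscored, flagged=flagged,
        flag_reason=flag_reason, subject=session.subject,
        environment=session.environment,
    )


def zscore_ratings(values: np.ndarray) -> np.ndarray:
    sd = np.std(values, ddof=1)
    if sd == 0:
        raise ValueError("degenerate rating variance (all ratings equal)")
    return (values - values.mean()) / sd


def fit_happiness_model(session: SessionData, terms: pd.DataFrame,
                        model_id: str, zscore: bool = True,
                        gamma_step: float = 0.01,
                        init_gamma: float | None = None) -> HappinessFit:
    """Fit one happiness model to one session's ratings.

    For each gamma on a dense grid (plus ``init_gamma`` if given) the
    weights are solved by least squares; the best gamma is then refined
    with a bounded scalar search.  A near-flat gamma profile (relative
    RSS range below 1e-3) is flagged as unidentified, as is degenerate
    rating variance.
    """
    if model_id not in HAPPINESS_MODELS:
        raise ValueError(f"unknown happiness model {model_id!r}")
    trials = np.array(sorted(session.ratings))
    if len(trials) < 5:
        raise ValueError("need at least 5 ratings to fit")
    y = np.array([session.ratings[t] for t in trials], dtype=float)

    flagged, reason = False, ""
    if zscore:
        try:
            y = zscore_ratings(y)
        except ValueError:
            return _package_fit(model_id, np.zeros(
                len(HAPPINESS_MODELS[model_id][0]) + 1), 0.0, 0.0,
                _design(terms, model_id, 0.0, trials), y, zscore, session,
                True, "degenerate rating variance")

    grid = np.arange(0.0, 1.0 + gamma_step / 2, gamma_step)
    if init_gamma is not None:
        grid = np.unique(np.r_[grid, np.clip(init_gamma, 0.0, 1.0)])

    def rss_at(g: float) -> float:
        X = _design(terms, model_id, g, trials)
        _, rss = _solve_weights(X, y, zscore)
        return rss

    rss_grid = np.array([rss_at(g) for g in grid])
    i = int(np.argmin(rss_grid))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(rss_at, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        gamma = float(res.x) if res.fun < rss_grid[i] else float(grid[i])
    else:
        gamma = float(grid[i])

    spread = (rss_grid.max() - rss_grid.min()) / max(rss_grid.min(), 1e-12)
    if spread < 1e-3:
        flagged, reason = True, "gamma unidentified (flat profile)"

    X = _design(terms, model_id, gamma, trials)
    coef, rss = _solve_weights(X, y, zscore)
    return _package_fit(model_id, coef, gamma, rss, X, y, zscore, session,
                        flagged, reason)


def fit_happiness_two_stage(sessions: dict[str, SessionData],
                            terms: dict[str, pd.DataFrame],
                            model_id: str, zscore: bool = True,
                            gamma_step: float = 0.01
                            ) -> tuple[float, dict[str, HappinessFit]]:
    """Joint-then-separate protocol across the two environments.

    Stage 1 fits one parameter set to both environments at once (decayed
    sums reset per environment, ratings standardised per environment);
    stage 2 refits each environment separately with the joint gamma
    supplied as an extra starting candidate.  Returns (joint gamma,
    per-environment fits).
    """
    blocks = []
    for env, session in sessions.items():
        trials = np.array(sorted(session.ratings))
        y = np.array([session.ratings[t] for t in trials], dtype=float)
        if zscore:
            y = zscore_ratings(y)
        blocks.append((terms[env], trials, y))

    def rss_at(g: float) -> float:
        X = np.vstack([_design(tm, model_id, g, tr) for tm, tr, _ in blocks])
        y_all = np.concatenate([y for *_, y in blocks])
        _, rss = _solve_weights(X, y_all, zscore)
        return rss

    grid = np.arange(0.0, 1.0 + gamma_step / 2, gamma_step)
    joint_gamma = float(grid[int(np.argmin([rss_at(g) for g in grid]))])

    fits = {
        env: fit_happiness_model(sessions[env], terms[env], model_id,
                                 zscore=zscore, gamma_step=gamma_step,
                                 init_gamma=joint_gamma)
        for env in sessions
    }
    return joint_gamma, fits


def swap_learning_rate_refit(session: SessionData, alpha_other_env: float,
                             model_id: str = "p_hat_ppe_hat",
                             zscore: bool = True,
                             gamma_step: float = 0.01) -> HappinessFit:
    """Refit a happiness model with the learner replayed at the *other*
    environment's learning rate (robustness check on gamma)."""
    terms = build_term_history(session, alpha_other_env)
    return fit_happiness_model(session, terms, model_id, zscore=zscore,
                               gamma_step=gamma_step)
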
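"""Group-level behavioural metrics and individual-differences analyses.

Per-subject metrics (choice accuracy, win-stay/lose-shift splits,
lagged prediction-error regressions, residual-probability correlations)
are aggregated with two-sided Wilcoxon signed-rank tests and Spearman
rank correlations, the nonparametric tests used throughout for group
inference on per-subject statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .choice import REWARD_NORM, SessionData
from .happiness import HappinessFit, predict_happiness, zscore_ratings

HIGH_PROB = "high_prob"
LOW_PROB = "low_prob"


@dataclass
class TestResult:
    statistic: float   # z for Wilcoxon, rho for Spearman
    p_value: float
    n: int


def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired values (or on a
    single sample against zero).

    The z statistic comes from the continuity-corrected normal
    approximation; the p-value is exact for fewer than 20 non-zero
    differences and approximate otherwise.  Zero differences are
    discarded (Wilcoxon's original treatment).
    """
    d = np.asarray(x, dtype=float) - (0.0 if y is None else np.asarray(y, dtype=float))
    d = d[~np.isnan(d)]
    d = d[d != 0.0]
    n = len(d)
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    # signed z (positive when differences are predominantly positive),
    # tie-corrected normal approximation with continuity correction
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mn = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
    z = float((w_plus - mn - 0.5 * np.sign(w_plus - mn)) / np.sqrt(var))
    if n < 20:
        p = float(stats.wilcoxon(d, method="exact",
                                 alternative="two-sided").pvalue)
    else:
        p = float(stats.wilcoxon(d, correction=True, method="approx",
                                 alternative="two-sided").pvalue)
    return TestResult(statistic=z, p_value=p, n=n)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with tie handling; p by t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return TestResult(statistic=float(rho), p_value=float(p), n=len(x))


def choice_accuracy(session: SessionData) -> float:
    """Percent of trials choosing the higher objective-EV option.

    Objective EV is the block contingency (0.8/0.2) times the offered
    reward; trials where the two EVs tie are excluded from the
    denominator.
    """
    sched = session.schedule
    p_A = np.where(sched.best_car == "A", 0.8, 0.2)
    p_B = np.where(sched.best_car == "B", 0.8, 0.2)   # not 1-p_A: keep
    ev_A = p_A * sched.reward_A / REWARD_NORM         # ties float-exact
    ev_B = p_B * sched.reward_B / REWARD_NORM
    informative = ev_A != ev_B
    if not informative.any():
        return np.nan
    best = np.where(ev_A > ev_B, "A", "B")
    return 100.0 * np.mean(session.choices[informative] == best[informative])


def high_probability_choice_rate(session: SessionData) -> float:
    """Percent of trials choosing the current block's 80% car."""
    return 100.0 * np.mean(session.choices == session.schedule.best_car)


def win_stay_lose_shift(session: SessionData,
                        car_class: str) -> tuple[float, float]:
    """Stay percentages after a win and after a loss, conditioned on the
    previously chosen car being the current block's high- or
    low-probability car.

    Stay is defined on consecutive trials by car identity.  Empty
    conditioning cells yield NaN (excluded from group tests).
    """
    if car_class not in (HIGH_PROB, LOW_PROB):
        raise ValueError(f"unknown car class {car_class!r}")
    prev_choice = session.choices[:-1]
    prev_outcome = session.outcomes[:-1]
    stay = session.choices[1:] == prev_choice
    prev_was_best = prev_choice == session.schedule.best_car[:-1]
    in_class = prev_was_best if car_class == HIGH_PROB else ~prev_was_best

    out = []
    for won in (1, 0):
        cell = in_class & (prev_outcome == won)
        out.append(100.0 * np.mean(stay[cell]) if cell.any() else np.nan)
    return out[0], out[1]


def standardized_difference_correlation(a_stable, a_volatile,
                                        symptom) -> TestResult:
    """Spearman correlation between the standardised volatile-minus-
    stable difference of a per-subject measure and the standardised
    symptom score."""
    z_s = zscore_ratings(np.asarray(a_stable, dtype=float))
    z_v = zscore_ratings(np.asarray(a_volatile, dtype=float))
    z_sym = zscore_ratings(np.asarray(symptom, dtype=float))
    diff = z_v - z_s
    if np.all(diff == diff[0]):
        raise ValueError("identical conditions: difference is constant")
    return spearman(diff, z_sym)


def lagged_ppe_regression(session: SessionData, terms: pd.DataFrame,
                          n_lags: int = 10,
                          zscore: bool = True) -> np.ndarray:
    """Per-subject OLS of each rating on the ``n_lags`` most recent
    probability prediction errors (lag 1 = the trial the rating follows).

    Only ratings preceded by at least ``n_lags`` trials enter.  Returns
    the lag coefficients (length ``n_lags``); raises on a rank-deficient
    design.
    """
    ppe = terms["ppe_hat"].to_numpy()
    rows, ys = [], []
    for t in sorted(session.ratings):
        if t < n_lags:
            continue
        rows.append(ppe[t - n_lags:t][::-1])   # lag 1 first
        ys.append(session.ratings[t])
    if len(rows) <= n_lags:
        raise ValueError("too few ratings with a full lag history")
    X = np.column_stack([np.ones(len(rows)), np.array(rows)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient lag design")
    y = np.asarray(ys, dtype=float)
    if zscore:
        y = zscore_ratings(y)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef[1:]


def group_lagged_test(coefficients: list[np.ndarray]) -> pd.DataFrame:
    """Two-sided Wilcoxon of each lag's coefficients against zero."""
    mat = np.array(coefficients)
    rows = []
    for lag in range(mat.shape[1]):
        res = wilcoxon_signed_rank(mat[:, lag])
        rows.append({"lag": lag + 1, "mean_coef": mat[:, lag].mean(),
                     "z": res.statistic, "p": res.p_value})
    return pd.DataFrame(rows)


def winloss_residual_probability_correlation(
        session: SessionData, winloss_fit: HappinessFit,
        terms: pd.DataFrame) -> TestResult:
    """Spearman correlation of win-loss-model residuals with the
    trial-by-trial chosen probability estimate at rating trials."""
    trials = np.array(sorted(session.ratings))
    y = np.array([session.ratings[t] for t in trials], dtype=float)
    if winloss_fit.zscored:
        y = zscore_ratings(y)
    pred = predict_happiness("win_loss", winloss_fit.w0, winloss_fit.weights,
                             winloss_fit.gamma, terms, trials)
    resid = y - pred
    p_hat = terms["p_hat"].to_numpy()[trials - 1]
    return spearman(resid, p_hat)


def summarize_cohort_metric(values, label: str) -> dict:
    """Mean ± SEM plus the Wilcoxon-vs-zero test, as one report row."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    try:
        res = wilcoxon_signed_rank(values)
        z, p = res.statistic, res.p_value
    except ValueError:   # too few non-zero values for the test
        z, p = np.nan, np.nan
    return {"metric": label, "mean": values.mean(),
            "sem": values.std(ddof=1) / np.sqrt(len(values)),
            "z": z, "p": p, "n": len(values)}
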
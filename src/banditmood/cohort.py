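"""Synthetic cohorts: subjects x environments x trials x ratings x
symptom scores with the statistical structure the analyses assume.

Each subject gets per-environment choice parameters (learning rate,
inverse temperature, probability weight) and happiness parameters
(probability and prediction-error weights, forgetting factor, baseline
mood) drawn from truncated normal population distributions centred on
the group means, with population SDs reconstructed from the group SEMs
(SD = SEM * sqrt(n)).  Choices are simulated from the additive selector;
happiness ratings are generated from the probability + probability-
prediction-error model on the agent's own belief trace plus Gaussian
noise; a depression-like symptom score (0-27 integers) is coupled to the
volatile-environment baseline mood through a Gaussian copula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import task
from .choice import ChoiceParams, SessionData, simulate_agent
from .group import spearman
from .happiness import build_term_history, decayed_series

_SQRT_N = math.sqrt(75.0)

#: Per-environment population distributions, (mean, SD), defaults from
#: the 75-subject group statistics (SD = SEM * sqrt(75)).
DEFAULT_CHOICE_DIST = {
    "stable": {"alpha": (0.16, 0.02 * _SQRT_N), "beta": (10.0, 0.0),
               "phi": (0.57, 0.017 * _SQRT_N)},
    "volatile": {"alpha": (0.47, 0.03 * _SQRT_N), "beta": (10.0, 0.0),
                 "phi": (0.44, 0.027 * _SQRT_N)},
}
DEFAULT_HAPPINESS_DIST = {
    "stable": {"w_p": (0.74, 0.09 * _SQRT_N), "w_ppe": (1.32, 0.06 * _SQRT_N),
               "gamma": (0.59, 0.04 * _SQRT_N), "w0": (55.0, 1.7 * _SQRT_N)},
    "volatile": {"w_p": (0.94, 0.09 * _SQRT_N), "w_ppe": (1.14, 0.05 * _SQRT_N),
                 "gamma": (0.63, 0.03 * _SQRT_N), "w0": (49.5, 1.6 * _SQRT_N)},
}
PARAM_TRUNCATION = {"alpha": (0.0, 1.0), "beta": (0.0, 50.0),
                    "phi": (0.0, 1.0), "gamma": (0.0, 1.0),
                    "w0": (0.0, 100.0)}


@dataclass(frozen=True)
class CohortSpec:
    """Population-level description of a synthetic cohort."""

    n_subjects: int = 75
    n_trials: int = 80
    choice_dist: dict = field(default_factory=lambda: _copy(DEFAULT_CHOICE_DIST))
    happiness_dist: dict = field(
        default_factory=lambda: _copy(DEFAULT_HAPPINESS_DIST))
    #: rating-noise calibration.  "unit_variance" (default) sets each
    #: subject's noise variance to 1 - var(model prediction): the unique
    #: level at which the generated z-scale series has unit variance, so
    #: weights from a z-scored refit are on the generating scale.
    #: "target_r2" instead scales noise so the model explains the
    #: ``target_r2`` fraction of rating variance; "fixed" uses
    #: ``rating_noise_sd`` directly.
    noise_calibration: str = "unit_variance"
    target_r2: float = 0.6
    rating_noise_sd: float = 0.63          # z-units, "fixed" mode only
    rating_scale: float = 15.0             # z-units -> rating points
    symptom_mood_coupling: float = -0.28   # Spearman, symptom vs volatile w0
    #: cross-environment correlation of baseline mood (trait mood).  The
    #: symptom couples only to the volatility-specific baseline
    #: component, so the stable-environment coupling is exactly zero and
    #: the standardised volatile-minus-stable difference is *more*
    #: symptom-correlated than the volatile baseline alone.
    w0_trait_corr: float = 0.65
    symptom_poisson_mean: float = 5.0
    shared_gamma: bool = True              # one forgetting factor per subject
    order_counterbalance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_calibration not in ("unit_variance", "target_r2",
                                          "fixed"):
            raise ValueError(
                f"unknown noise calibration {self.noise_calibration!r}")
        if not -1.0 <= self.symptom_mood_coupling <= 1.0:
            raise ValueError("coupling must be in [-1, 1]")
        if not 0.0 <= self.w0_trait_corr < 1.0:
            raise ValueError("w0_trait_corr must be in [0, 1)")
        b = math.sqrt(1.0 - self.w0_trait_corr ** 2)
        r_latent = 2.0 * math.sin(math.pi * self.symptom_mood_coupling / 6.0)
        if abs(r_latent / b) > 0.95:
            raise ValueError("coupling infeasible with discrete symptom "
                             "scores at this trait correlation")


def _copy(d: dict) -> dict:
    return {env: dict(v) for env, v in d.items()}


@dataclass
class SubjectRecord:
    subject: str
    symptom: int
    task_order: tuple[str, str]
    sessions: dict[str, SessionData]
    true_choice: dict[str, ChoiceParams]
    true_happiness: dict[str, dict[str, float]]
    clip_fraction: dict[str, float]


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[SubjectRecord]

    def __len__(self) -> int:
        return len(self.subjects)

    def symptoms(self) -> np.ndarray:
        return np.array([s.symptom for s in self.subjects])

    def mean_happiness(self, environment: str) -> np.ndarray:
        return np.array([
            np.mean(list(s.sessions[environment].ratings.values()))
            for s in self.subjects
        ])

    def true_frame(self, environment: str) -> pd.DataFrame:
        """Ground-truth parameters per subject, for recovery scoring."""
        rows = []
        for s in self.subjects:
            cp = s.true_choice[environment]
            rows.append({"subject": s.subject, "alpha": cp.alpha,
                         "beta": cp.beta, "phi": cp.phi,
                         **s.true_happiness[environment]})
        return pd.DataFrame(rows).set_index("subject")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      bounds: tuple[float, float] | None) -> float:
    """Rejection-sampled truncated normal (exact for our mild truncation)."""
    if sd == 0.0:
        return mean
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if bounds is None or bounds[0] <= x <= bounds[1]:
            return float(x)
    raise RuntimeError("truncation rejection sampling failed")


def predict_z_happiness(terms: pd.DataFrame, w_p: float, w_ppe: float,
                        gamma: float, rating_trials: np.ndarray) -> np.ndarray:
    """Z-scale prediction of the probability + PPE model (no intercept)."""
    idx = np.asarray(rating_trials, dtype=int) - 1
    s_p = decayed_series(terms["p_hat_c"].to_numpy(), gamma)[idx]
    s_ppe = decayed_series(terms["ppe_hat"].to_numpy(), gamma)[idx]
    return w_p * s_p + w_ppe * s_ppe


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full synthetic cohort under the given specification.

    Deterministic given ``spec`` (all randomness flows from ``spec.seed``
    through a spawned seed tree).
    """
    root = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(root.spawn(1)[0])

    # Baseline-mood latents: a trait component shared across
    # environments plus a volatility-specific component; the symptom
    # score couples (Gaussian copula, latent r = 2 sin(pi*rho_s/6)) to
    # the volatility-specific part only, so symptom vs volatile baseline
    # hits the target Spearman while symptom vs stable baseline is zero.
    a = spec.w0_trait_corr
    b = math.sqrt(1.0 - a ** 2)
    r_latent = 2.0 * math.sin(math.pi * spec.symptom_mood_coupling / 6.0)
    r_su = r_latent / b    # symptom vs volatility-specific component
    trait = rng.standard_normal(spec.n_subjects)
    susc = rng.standard_normal(spec.n_subjects)
    z_stable = trait
    z_vol = a * trait + b * susc
    z_sym = r_su * susc + math.sqrt(1.0 - r_su ** 2) * rng.standard_normal(
        spec.n_subjects)
    symptoms = stats.poisson.ppf(stats.norm.cdf(z_sym),
                                 spec.symptom_poisson_mean)
    symptoms = np.clip(symptoms, 0, 27).astype(int)

    subjects = []
    for i in range(spec.n_subjects):
        sub_rng = np.random.default_rng(root.spawn(1)[0])
        name = f"s{i:03d}"
        order = (("stable", "volatile") if (i % 2 == 0 or
                 not spec.order_counterbalance)
                 else ("volatile", "stable"))

        true_choice, true_happ, sessions, clip_frac = {}, {}, {}, {}
        shared_g = None
        for env in ("stable", "volatile"):
            cd = spec.choice_dist[env]
            params = ChoiceParams(
                model_id="additive",
                alpha=_truncated_normal(sub_rng, *cd["alpha"],
                                        PARAM_TRUNCATION["alpha"]),
                beta=_truncated_normal(sub_rng, *cd["beta"],
                                       PARAM_TRUNCATION["beta"]),
                phi=_truncated_normal(sub_rng, *cd["phi"],
                                      PARAM_TRUNCATION["phi"]),
            )
            hd = spec.happiness_dist[env]
            gamma = _truncated_normal(sub_rng, *hd["gamma"],
                                      PARAM_TRUNCATION["gamma"])
            if spec.shared_gamma:
                if shared_g is None:
                    shared_g = _truncated_normal(
                        sub_rng, *spec.happiness_dist["stable"]["gamma"],
                        PARAM_TRUNCATION["gamma"])
                gamma = shared_g
            mu, sd = hd["w0"]
            z = z_vol[i] if env == "volatile" else z_stable[i]
            w0 = float(np.clip(mu + sd * z, 0.0, 100.0))
            happ = {
                "w_p": _truncated_normal(sub_rng, *hd["w_p"], None),
                "w_ppe": _truncated_normal(sub_rng, *hd["w_ppe"], None),
                "gamma": gamma,
                "w0": w0,
            }

            config = task.TaskConfig(
                environment=env, n_trials=spec.n_trials,
                seed=int(sub_rng.integers(2 ** 31)))
            schedule = task.generate_schedule(config)
            session = simulate_agent(schedule, params, sub_rng, subject=name)

            terms = build_term_history(session, params.alpha)
            rating_trials = schedule.rating_trials
            pred = predict_z_happiness(terms, happ["w_p"], happ["w_ppe"],
                                       gamma, rating_trials)
            signal_var = float(np.var(pred, ddof=1))
            if spec.noise_calibration == "unit_variance":
                noise_sd = math.sqrt(max(1.0 - signal_var, 0.05))
            elif spec.noise_calibration == "target_r2" and signal_var > 0:
                noise_sd = math.sqrt(
                    signal_var * (1.0 - spec.target_r2) / spec.target_r2)
            else:
                noise_sd = spec.rating_noise_sd
            noise = sub_rng.normal(0.0, noise_sd, size=len(rating_trials))
            raw = w0 + spec.rating_scale * (pred - pred.mean() + noise)
            clipped = np.clip(raw, 0.0, 100.0)
            clip_frac[env] = float(np.mean(raw != clipped))
            session.ratings = {int(t): float(r)
                               for t, r in zip(rating_trials, clipped)}

            true_choice[env] = params
            true_happ[env] = happ
            sessions[env] = session

        subjects.append(SubjectRecord(
            subject=name, symptom=int(symptoms[i]), task_order=order,
            sessions=sessions, true_choice=true_choice,
            true_happiness=true_happ, clip_fraction=clip_frac))
    return Cohort(spec=spec, subjects=subjects)


def group_mean_spec(n_subjects: int = 75, seed: int = 0,
                    **kwargs) -> CohortSpec:
    """Cohort spec with every subject fixed at the group-mean parameters
    (zero population SDs); the standard conditions for parameter- and
    model-recovery experiments."""
    choice = {env: {k: (mu, 0.0) for k, (mu, _) in d.items()}
              for env, d in DEFAULT_CHOICE_DIST.items()}
    happiness = {env: {k: (mu, 0.0) for k, (mu, _) in d.items()}
                 for env, d in DEFAULT_HAPPINESS_DIST.items()}
    return CohortSpec(n_subjects=n_subjects, seed=seed, choice_dist=choice,
                      happiness_dist=happiness, **kwargs)


def recovery_report(true_frame: pd.DataFrame,
                    fitted_frame: pd.DataFrame) -> pd.DataFrame:
    """Bias, RMSE and rank correlation of recovered vs true parameters.

    Both frames are indexed by subject; every column they share is
    scored.
    """
    shared = [c for c in true_frame.columns if c in fitted_frame.columns]
    if not shared:
        raise ValueError("no common parameter columns to score")
    fitted = fitted_frame.loc[true_frame.index]
    rows = []
    for col in shared:
        t = true_frame[col].to_numpy(dtype=float)
        f = fitted[col].to_numpy(dtype=float)
        err = f - t
        row = {"parameter": col, "true_mean": t.mean(),
               "recovered_mean": f.mean(), "bias": err.mean(),
               "rmse": float(np.sqrt(np.mean(err ** 2)))}
        try:
            row["rank_corr"] = spearman(t, f).statistic
        except ValueError:   # degenerate (e.g. zero-SD generating values)
            row["rank_corr"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")
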
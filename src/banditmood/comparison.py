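"""Fixed- and random-effects model comparison across subjects.

Fixed effects: per-model BIC summed over subjects, reported relative to a
reference model (lower is better).  Random effects: models are treated as
random effects with an unknown population distribution; a variational
Dirichlet scheme estimates the expected frequency of each model in the
population and the exceedance probability (EP) that it is the most
frequent one.  Per-subject log model evidence is approximated by -BIC/2.
An EP above 0.95 is conventionally treated as decisive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, logsumexp


def log_evidence_from_bic(bic_table: pd.DataFrame) -> pd.DataFrame:
    """Schwarz approximation: log p(y | model) ~ -BIC/2, per subject."""
    return -bic_table / 2.0


@dataclass
class BmsResult:
    """Output of random-effects Bayesian model selection."""

    models: list[str]
    dirichlet_alpha: np.ndarray
    expected_frequency: np.ndarray
    exceedance_probability: np.ndarray
    posterior_model_prob: np.ndarray   # subjects x models
    converged: bool
    n_iterations: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.models,
                "dirichlet_alpha": self.dirichlet_alpha,
                "expected_frequency": self.expected_frequency,
                "exceedance_probability": self.exceedance_probability,
            }
        )


def compare_fixed(bic_table: pd.DataFrame,
                  reference: str | None = None) -> pd.DataFrame:
    """Summed BIC per model and delta-BIC relative to ``reference``.

    ``bic_table`` is subjects x models.  If no reference is named, the
    model with the lowest summed BIC is used (the preferred model).
    """
    if bic_table.shape[0] < 1:
        raise ValueError("need at least one subject")
    summed = bic_table.sum(axis=0)
    if reference is None:
        reference = summed.idxmin()
    if reference not in summed.index:
        raise KeyError(f"reference model {reference!r} not in table")
    return pd.DataFrame(
        {"bic_sum": summed, "delta_bic": summed - summed[reference]}
    )


def rfx_bms(log_evidence: pd.DataFrame, alpha0: float = 1.0,
            n_ep_samples: int = 1_000_000,
            seed: int | np.random.Generator = 0,
            max_iter: int = 500, tol: float = 1e-8) -> BmsResult:
    """Random-effects Bayesian model selection (variational Dirichlet).

    Iterates between per-subject posterior model assignment
    u_sk ∝ exp(log_evidence_sk + digamma(alpha_k) - digamma(sum alpha))
    and the Dirichlet update alpha_k = alpha0 + sum_s u_sk, from a
    uniform prior.  The exceedance probability is the Monte-Carlo
    frequency with which each model's sampled population frequency is the
    largest.
    """
    if log_evidence.shape[1] < 1:
        raise ValueError("need at least one model")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    models = list(log_evidence.columns)
    L = log_evidence.to_numpy(dtype=float)
    if not np.all(np.isfinite(L)):
        raise ValueError("non-finite log evidences")
    n_subjects, n_models = L.shape

    if n_models == 1:
        return BmsResult(models, np.array([alpha0 + n_subjects]),
                         np.array([1.0]), np.array([1.0]),
                         np.ones((n_subjects, 1)), True, 0)

    alpha = np.full(n_models, alpha0)
    converged = False
    for iteration in range(1, max_iter + 1):
        logu = L + digamma(alpha) - digamma(alpha.sum())
        u = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new

    freq = alpha / alpha.sum()
    samples = rng.dirichlet(alpha, size=n_ep_samples)
    winners = np.argmax(samples, axis=1)
    ep = np.bincount(winners, minlength=n_models) / n_ep_samples
    return BmsResult(models, alpha, freq, ep, u, converged, iteration)


def comparison_report(bic_table: pd.DataFrame,
                      fit_stats: pd.DataFrame | None = None,
                      reference: str | None = None) -> pd.DataFrame:
    """Fixed-effects comparison table (model, k, mean fit, BIC, dBIC).

    ``fit_stats`` optionally carries per-model columns ``n_params`` and
    ``mean_r2`` to merge into the report.
    """
    report = compare_fixed(bic_table, reference=reference)
    if fit_stats is not None:
        report = report.join(fit_stats, how="left")
    return report.sort_values("delta_bic")
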
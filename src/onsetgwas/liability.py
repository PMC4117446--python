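"""Posterior mean liabilities conditioned on affection status and age.

Cases are modelled as the upper tail of the standard-normal liability
distribution truncated at the age-specific threshold, controls as the lower
portion:

    E[L | L > t] =  phi(t) / K          (cases)
    E[L | L <= t] = -phi(t) / (1 - K)   (controls)

with ``t = Phi^{-1}(1 - K)``.  Substituting each sample's own age (onset age
for cases, exam age for controls) turns a binary phenotype into a
quantitative response that encodes how surprising disease (or freedom from
disease) is at that age: a young-onset case sits far above a high threshold
and receives a large positive liability, while an elderly unaffected
control has cleared a low threshold and receives a more negative one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .prevalence import OVERALL, PrevalenceModel

__all__ = [
    "threshold_at_age",
    "posterior_mean_case",
    "posterior_mean_control",
    "assign_liabilities",
]

_TOL = 1e-6


def threshold_at_age(model: PrevalenceModel, age, phenotype: str = OVERALL):
    """Liability threshold at ``age``: ``Phi^{-1}(1 - K_eff(age))``.

    Ages outside the model's grid are clamped to the nearest grid end.
    """
    return model.threshold_at(age, phenotype)


def _check_pair(t, k) -> None:
    t = np.asarray(t, float)
    k = np.asarray(k, float)
    if np.any(k <= 0.0) or np.any(k >= 1.0):
        raise ValueError("prevalence K must be strictly inside (0, 1)")
    if np.any(np.abs(norm.sf(t) - k) > _TOL * np.maximum(k, 1e-3)):
        raise ValueError("inconsistent (threshold, prevalence) pair: t != Phi^-1(1-K)")


def posterior_mean_case(t, k):
    """Mean liability of affected individuals, ``E[L | L > t] = phi(t)/K``."""
    _check_pair(t, k)
    return norm.pdf(t) / np.asarray(k, float)


def posterior_mean_control(t, k):
    """Mean liability of unaffected individuals, ``E[L | L <= t] = -phi(t)/(1-K)``."""
    _check_pair(t, k)
    return -norm.pdf(t) / (1.0 - np.asarray(k, float))


def _impute_median_ages(pheno: pd.DataFrame) -> np.ndarray:
    """Median-impute missing ages within centre x status strata.

    Falls back to the global median when a stratum has no observed age.
    """
    ages = pheno["age"].to_numpy(float).copy()
    missing = ~np.isfinite(ages)
    if not missing.any():
        return ages
    if missing.all():
        raise ValueError("all ages missing; cannot impute")
    global_median = np.nanmedian(ages)
    strata = pheno.groupby(["centre", "status"], sort=False, observed=True)
    medians = strata["age"].transform("median").to_numpy(float)
    fill = np.where(np.isfinite(medians), medians, global_median)
    ages[missing] = fill[missing]
    return ages


def assign_liabilities(
    pheno: pd.DataFrame,
    model: PrevalenceModel,
    phenotype: str = OVERALL,
    control_pooled_age: float | None = None,
) -> np.ndarray:
    """Posterior mean liability per sample, aligned with ``pheno``.

    Parameters
    ----------
    pheno
        Phenotype table with columns ``centre``, ``status`` (0/1) and ``age``
        (onset age for cases, exam age for controls; NaN allowed).
    model
        Prevalence model supplying the age-specific thresholds.
    phenotype
        ``"IS"`` for overall disease or a subtype label (threshold then uses
        the subtype-scaled prevalence).
    control_pooled_age
        If given, every control is conditioned at this single age instead of
        its own exam age (a pooled-prevalence threshold).

    Missing ages are first median-imputed within centre x status.
    """
    if len(pheno) == 0:
        raise ValueError("empty cohort")
    ages = _impute_median_ages(pheno)
    status = pheno["status"].to_numpy(int)
    is_case = status == 1
    if control_pooled_age is not None:
        ages = np.where(is_case, ages, float(control_pooled_age))
    k = model.prevalence_at(ages, phenotype)
    t = norm.isf(k)
    liab = np.where(is_case, norm.pdf(t) / k, -norm.pdf(t) / (1.0 - k))
    return liab
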
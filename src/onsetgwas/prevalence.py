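"""Age-specific disease prevalence and the liability-threshold mapping.

Under the liability-threshold model an unobserved standard-normal liability
``L`` causes disease when it exceeds a threshold ``t``.  With an age-specific
prevalence ``K(a)`` the threshold becomes age-specific,
``t(a) = Phi^{-1}(1 - K(a))``: as prevalence rises with age the threshold
falls, so a genetically loaded individual crosses it earlier in life.

Stroke subtypes are modelled as a constant fraction of the overall
prevalence (cardioembolic, large-artery and small-vessel strokes each make
up roughly a fifth of ischaemic strokes in population registers), so the
subtype threshold uses ``K_sub(a) = f * K(a)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "PrevalenceModel",
    "default_prevalence_model",
    "read_prevalence_table",
    "write_prevalence_table",
]

#: phenotype label meaning "overall disease, no subtype scaling"
OVERALL = "IS"


@dataclass(frozen=True)
class PrevalenceModel:
    """Piecewise-linear age -> prevalence map plus a subtype fraction.

    Parameters
    ----------
    age_grid
        Strictly increasing ages (years).
    prevalence
        Overall disease prevalence at each grid age, each strictly in (0, 1).
    subtype_fraction
        Fraction of overall prevalence attributed to a single aetiological
        subtype; the subtype prevalence is ``subtype_fraction * K(a)``.

    Ages outside the grid are clamped to the nearest grid end rather than
    extrapolated, so thresholds stay finite in sparse tails.
    """

    age_grid: np.ndarray
    prevalence: np.ndarray
    subtype_fraction: float = 0.20

    def __post_init__(self) -> None:
        ages = np.asarray(self.age_grid, dtype=float)
        prev = np.asarray(self.prevalence, dtype=float)
        if ages.ndim != 1 or ages.size < 1 or ages.size != prev.size:
            raise ValueError("age_grid and prevalence must be 1-d and equal length")
        if ages.size > 1 and not np.all(np.diff(ages) > 0):
            raise ValueError("age_grid must be strictly increasing")
        if np.any(prev <= 0.0) or np.any(prev >= 1.0):
            raise ValueError("prevalence values must lie strictly inside (0, 1)")
        if not (0.0 < self.subtype_fraction <= 1.0):
            raise ValueError("subtype_fraction must be in (0, 1]")
        object.__setattr__(self, "age_grid", ages)
        object.__setattr__(self, "prevalence", prev)

    def prevalence_at(self, age, phenotype: str = OVERALL):
        """Effective prevalence ``K_eff`` at ``age`` for ``phenotype``.

        ``phenotype`` is either ``"IS"`` (overall) or any subtype label, in
        which case the overall prevalence is scaled by ``subtype_fraction``.
        Ages outside the grid are clamped to the grid ends.
        """
        k = np.interp(np.asarray(age, dtype=float), self.age_grid, self.prevalence)
        if phenotype != OVERALL:
            k = k * self.subtype_fraction
        if np.any(k <= 0.0) or np.any(k >= 1.0):
            raise ValueError("effective prevalence left (0, 1); invalid model")
        return k

    def threshold_at(self, age, phenotype: str = OVERALL):
        """Liability threshold ``t(age) = Phi^{-1}(1 - K_eff(age))``."""
        return norm.isf(self.prevalence_at(age, phenotype))


def default_prevalence_model(subtype_fraction: float = 0.20) -> PrevalenceModel:
    """Documented default prevalence table for ischaemic stroke.

    Prevalence rises from 0.1% at age 45 to 5% at age 85, consistent with
    gender-averaged epidemiological estimates for ischaemic stroke; values
    between grid ages are linearly interpolated.
    """
    return PrevalenceModel(
        age_grid=np.array([45.0, 55.0, 65.0, 75.0, 85.0]),
        prevalence=np.array([0.001, 0.004, 0.012, 0.028, 0.050]),
        subtype_fraction=subtype_fraction,
    )


def read_prevalence_table(path, subtype_fraction: float = 0.20) -> PrevalenceModel:
    """Read a two-column TSV (age, prevalence) with header."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (age, prevalence)")
    return PrevalenceModel(
        age_grid=df.iloc[:, 0].to_numpy(float),
        prevalence=df.iloc[:, 1].to_numpy(float),
        subtype_fraction=subtype_fraction,
    )


def write_prevalence_table(model: PrevalenceModel, path) -> None:
    pd.DataFrame({"age": model.age_grid, "prevalence": model.prevalence}).to_csv(
        path, sep="\t", index=False
    )
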
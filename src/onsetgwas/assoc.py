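"""Per-centre association testing of imputed dosages.

The score statistic is ``chisq = N * r^2`` where ``r`` is the Pearson
correlation between the expected effect-allele dosage and the response —
posterior mean liability for the age-informed test, or raw case-control
status for the conventional (uninformed) test.  Under the null the statistic
is chi-square with one degree of freedom.  Covariates (ancestry principal
components) are handled by residualizing both dosage and response on them
before correlating, i.e. the statistic uses the partial correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

__all__ = [
    "GenotypePanel",
    "AssocResult",
    "qc_filter",
    "residualize",
    "informed_test",
    "uninformed_test",
    "association_scan",
    "logistic_or_by_quantile",
]

ASSOC_COLUMNS = [
    "snp", "chr", "pos", "ea", "oa", "eaf", "info",
    "n", "n_cases", "r", "chisq", "z", "p", "beta", "se", "flag",
]


@dataclass
class GenotypePanel:
    """SNP metadata plus an expected-dosage matrix for one centre.

    ``snps`` has columns snp, chr, pos, ea, oa, info; ``dosages`` is a
    (n_snps, n_samples) float array of expected effect-allele counts in
    [0, 2], with the sample ordering aligned to the phenotype table.
    """

    snps: pd.DataFrame
    dosages: np.ndarray
    centre_id: str = ""

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.snps):
            raise ValueError("dosage matrix must be (n_snps, n_samples)")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 2 + 1e-9):
            raise ValueError("dosages must lie in [0, 2]")
        if self.snps["snp"].duplicated().any():
            dup = self.snps.loc[self.snps["snp"].duplicated(), "snp"].iloc[0]
            raise ValueError(f"duplicated SNP identifier in panel: {dup}")

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def eaf(self) -> np.ndarray:
        return np.nanmean(self.dosages, axis=1) / 2.0

    def subset(self, mask) -> "GenotypePanel":
        return GenotypePanel(
            snps=self.snps.loc[mask].reset_index(drop=True),
            dosages=self.dosages[np.asarray(mask)],
            centre_id=self.centre_id,
        )


@dataclass
class AssocResult:
    """Single-SNP association result (see ASSOC_COLUMNS for field meaning)."""

    snp: str
    n: int
    r: float
    chisq: float
    z: float
    p: float
    beta: float
    se: float
    eaf: float
    n_cases: int
    flag: str = ""


def qc_filter(panel: GenotypePanel, min_info: float = 0.3, min_maf: float = 0.01):
    """Drop poorly imputed and rare SNPs.

    SNPs with imputation info strictly below ``min_info`` or minor-allele
    frequency strictly below ``min_maf`` are discarded (values exactly at a
    threshold are retained).  Returns the filtered panel and a dict of
    per-criterion removal counts.
    """
    info = panel.snps["info"].to_numpy(float)
    eaf = panel.eaf()
    maf = np.minimum(eaf, 1.0 - eaf)
    bad_info = info < min_info
    bad_maf = maf < min_maf
    counts = {
        "n_input": panel.n_snps,
        "removed_info": int(bad_info.sum()),
        "removed_maf": int(bad_maf.sum()),
        "removed_both": int((bad_info & bad_maf).sum()),
        "retained": int((~(bad_info | bad_maf)).sum()),
    }
    return panel.subset(~(bad_info | bad_maf)), counts


def _design(n: int, covariates) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    cov = np.atleast_2d(np.asarray(covariates, float))
    if cov.shape[0] != n:
        cov = cov.T
    if cov.shape[0] != n:
        raise ValueError("covariate matrix does not match sample count")
    x = np.column_stack([np.ones(n), cov])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # walk columns to name the first collinear one
        for j in range(1, x.shape[1]):
            if np.linalg.matrix_rank(x[:, : j + 1]) < j + 1:
                raise ValueError(f"covariate column {j - 1} is collinear with earlier columns")
    return x


def residualize(values, covariates=None) -> np.ndarray:
    """Residuals of ``values`` after least-squares projection on [1 | covariates].

    With no covariates this is simple mean-centring.  Accepts a vector or a
    (n_vectors, n_samples) matrix (each row residualized).
    """
    v = np.asarray(values, float)
    vec = v.ndim == 1
    v2 = v[None, :] if vec else v
    x = _design(v2.shape[1], covariates)
    coef, *_ = np.linalg.lstsq(x, v2.T, rcond=None)
    res = v2 - (x @ coef).T
    return res[0] if vec else res


def _score_test(dosage, response, covariates, n_cases: int, snp: str = "") -> AssocResult:
    d = np.asarray(dosage, float)
    y = np.asarray(response, float)
    if d.shape != y.shape:
        raise ValueError("dosage and response lengths differ")
    n = d.size
    eaf = d.mean() / 2.0
    x = _design(n, covariates)
    coef, *_ = np.linalg.lstsq(x, np.column_stack([d, y]), rcond=None)
    resid = np.column_stack([d, y]) - x @ coef
    dres, yres = resid[:, 0], resid[:, 1]
    sd, sy = np.sqrt(dres @ dres), np.sqrt(yres @ yres)
    if sd <= 0 or sy <= 0:
        return AssocResult(snp, n, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                           eaf, n_cases, flag="unestimable")
    r = float(dres @ yres / (sd * sy))
    chisq = n * r * r
    z = float(np.sign(r) * np.sqrt(chisq))
    p = float(chi2.sf(chisq, 1))
    beta = float(dres @ yres / (dres @ dres))
    dof = max(n - 2, 1)
    rss = float(yres @ yres) - beta * beta * float(dres @ dres)
    se = float(np.sqrt(max(rss, 0.0) / dof / (dres @ dres)))
    return AssocResult(snp, n, r, chisq, z, p, beta, se, eaf, n_cases)


def informed_test(dosage, liabilities, covariates=None, n_cases: int = 0,
                  snp: str = "") -> AssocResult:
    """Age-at-onset informed score test: N * r^2 against posterior liabilities."""
    return _score_test(dosage, liabilities, covariates, n_cases, snp)


def uninformed_test(dosage, status, covariates=None, snp: str = "") -> AssocResult:
    """Conventional case-control score test: same machinery, binary response."""
    status = np.asarray(status, float)
    return _score_test(dosage, status, covariates, int(status.sum()), snp)


def association_scan(panel: GenotypePanel, response, status,
                     covariates=None) -> pd.DataFrame:
    """Vectorized scan of every SNP in a panel against one response vector.

    Missing dosages are mean-imputed per SNP (expected-dosage semantics).
    Returns a DataFrame with ASSOC_COLUMNS; zero-variance SNPs are flagged
    ``unestimable`` with NaN statistics.
    """
    d = panel.dosages.copy()
    if np.isnan(d).any():
        means = np.nanmean(d, axis=1)
        idx = np.where(np.isnan(d))
        d[idx] = means[idx[0]]
    y = np.asarray(response, float)
    n = d.shape[1]
    status = np.asarray(status, int)
    x = _design(n, covariates)
    # residualize response and all dosage rows against the covariate design
    q, _ = np.linalg.qr(x)
    yres = y - q @ (q.T @ y)
    dres = d - (d @ q) @ q.T
    sy = np.sqrt(yres @ yres)
    sd = np.sqrt(np.einsum("ij,ij->i", dres, dres))
    dy = dres @ yres
    with np.errstate(invalid="ignore", divide="ignore"):
        r = dy / (sd * sy)
        chisq = n * r * r
        z = np.sign(r) * np.sqrt(chisq)
        p = chi2.sf(chisq, 1)
        beta = dy / (sd * sd)
        rss = sy * sy - beta * beta * sd * sd
        se = np.sqrt(np.maximum(rss, 0.0) / max(n - 2, 1)) / sd
    bad = (sd <= 0) | (sy <= 0)
    out = panel.snps[["snp", "chr", "pos", "ea", "oa", "info"]].copy()
    out["eaf"] = d.mean(axis=1) / 2.0
    out["n"] = n
    out["n_cases"] = int((status == 1).sum())
    out["r"] = np.where(bad, np.nan, r)
    out["chisq"] = np.where(bad, np.nan, chisq)
    out["z"] = np.where(bad, np.nan, z)
    out["p"] = np.where(bad, np.nan, p)
    out["beta"] = np.where(bad, np.nan, beta)
    out["se"] = np.where(bad, np.nan, se)
    out["flag"] = np.where(bad, "unestimable", "")
    return out[ASSOC_COLUMNS]


def logistic_or_by_quantile(dosage, status, ages, quantile_cuts,
                            covariates=None) -> pd.DataFrame:
    """Odds ratios from cumulative age-at-onset quantile strata.

    For each ascending cut, fits an additive-dosage logistic regression on
    the stratum {cases with onset <= cut} + {all controls} and reports
    OR = exp(beta) with a Wald 95% CI.  Complete separation (or any
    non-convergence) is flagged and left without an estimate.
    """
    import statsmodels.api as sm

    d = np.asarray(dosage, float)
    s = np.asarray(status, int)
    a = np.asarray(ages, float)
    rows = []
    for cut in quantile_cuts:
        keep = (s == 0) | ((s == 1) & (a <= cut))
        if s[keep].sum() == 0 or (s[keep] == 0).sum() == 0:
            raise ValueError(f"stratum at cut {cut} lacks cases or controls")
        x = d[keep][:, None]
        if covariates is not None:
            cov = np.atleast_2d(np.asarray(covariates, float))
            if cov.shape[0] != len(s):
                cov = cov.T
            x = np.column_stack([x, cov[keep]])
        x = sm.add_constant(x, prepend=True)
        flag = ""
        or_, lo, hi = np.nan, np.nan, np.nan
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(s[keep], x).fit(disp=0, maxiter=50, tol=1e-8)
            beta, se = fit.params[1], fit.bse[1]
            if not np.isfinite(se) or se > 1e3:
                flag = "separation"
            else:
                or_ = float(np.exp(beta))
                lo = float(np.exp(beta - 1.96 * se))
                hi = float(np.exp(beta + 1.96 * se))
        except Exception:
            flag = "separation"
        rows.append({"cut": cut, "n_cases": int(s[keep].sum()),
                     "n_controls": int((s[keep] == 0).sum()),
                     "or": or_, "ci_low": lo, "ci_high": hi, "flag": flag})
    return pd.DataFrame(rows)
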
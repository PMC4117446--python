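"""Multi-study meta-analysis of per-centre association results.

Discovery-style combination uses Stouffer's sample-size weighted Z method
(the METAL scheme): ``z_meta = sum(w_i z_i) / sqrt(sum(w_i^2))`` with
``w_i = sqrt(N_eff_i)`` and ``N_eff = 4 / (1/n_cases + 1/n_controls)``.
Genomic control deflates each study's chi-squares by
``lambda = median(chisq) / 0.4549`` (floored at 1) before combination.
SNPs are then screened on case coverage (fraction of all cases in studies
carrying the SNP) and Cochran's Q heterogeneity.

Replication-style tools: fixed-effects inverse-variance pooling, the
Han–Eskin random-effects likelihood-ratio test for trans-ethnic
heterogeneity, and Fisher's method for combining independent p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, norm

__all__ = [
    "effective_n",
    "stouffer_meta",
    "genomic_control",
    "cochran_q",
    "apply_filters",
    "ivw_fixed_meta",
    "re2_han_eskin",
    "fisher_combine",
    "meta_analyse",
]

#: median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = float(chi2.ppf(0.5, 1))


def effective_n(n_cases, n_controls):
    """METAL's effective sample size for case-control studies."""
    n_cases = np.asarray(n_cases, float)
    n_controls = np.asarray(n_controls, float)
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def stouffer_meta(z, weights):
    """Weighted Stouffer combination of signed Z scores.

    Returns (z_meta, two-sided p).  ``weights`` are typically
    ``sqrt(N_eff)`` per study.
    """
    z = np.asarray(z, float)
    w = np.asarray(weights, float)
    if z.size == 0:
        raise ValueError("no studies to combine")
    zm = float(np.sum(w * z) / np.sqrt(np.sum(w * w)))
    return zm, float(2.0 * norm.sf(abs(zm)))


def genomic_control(chisq):
    """Genomic-control inflation factor and corrected chi-squares.

    ``lambda = median(chisq) / 0.4549``; statistics are divided by
    ``max(lambda, 1)`` so deflation never rewards an under-dispersed study.
    """
    chisq = np.asarray(chisq, float)
    lam = float(np.nanmedian(chisq) / CHI2_1_MEDIAN)
    return lam, chisq / max(lam, 1.0)


def cochran_q(betas, ses):
    """Cochran's heterogeneity Q over study effects; returns (Q, df, p)."""
    b = np.asarray(betas, float)
    s = np.asarray(ses, float)
    k = b.size
    if k < 2:
        raise ValueError("Cochran's Q requires at least two studies")
    w = 1.0 / (s * s)
    pooled = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - pooled) ** 2))
    return q, k - 1, float(chi2.sf(q, k - 1))


def ivw_fixed_meta(betas, ses):
    """Fixed-effects inverse-variance pooled effect; returns (beta, se, p)."""
    b = np.asarray(betas, float)
    s = np.asarray(ses, float)
    w = 1.0 / (s * s)
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return beta, se, float(2.0 * norm.sf(abs(beta / se)))


def _re_loglik(betas, var, mu, tau2):
    v = var + tau2
    return -0.5 * np.sum(np.log(2.0 * np.pi * v) + (betas - mu) ** 2 / v)


def re2_han_eskin(betas, ses):
    """Han–Eskin random-effects likelihood-ratio test of a mean effect.

    Tests mu = 0 (with tau^2 = 0) against the alternative maximizing over
    (mu, tau^2 >= 0).  The p-value uses the asymptotic null mixture
    0.5*chi2_1 + 0.5*chi2_2; small-study tabulated corrections are not
    applied and the result is flagged ``asymptotic``.
    Returns (statistic, p, flag).
    """
    b = np.asarray(betas, float)
    s = np.asarray(ses, float)
    if b.size < 2:
        raise ValueError("random-effects meta requires at least two studies")
    var = s * s

    def neg_profile(tau2):
        w = 1.0 / (var + tau2)
        mu = np.sum(w * b) / np.sum(w)
        return -_re_loglik(b, var, mu, tau2)

    hi = max(np.var(b), var.max()) * 10.0 + 1e-8
    res = minimize_scalar(neg_profile, bounds=(0.0, hi), method="bounded",
                          options={"xatol": 1e-12})
    tau2_hat = max(0.0, float(res.x))
    ll1 = max(-res.fun, -neg_profile(0.0))  # boundary tau2=0 always admissible
    ll0 = _re_loglik(b, var, 0.0, 0.0)
    stat = max(0.0, 2.0 * (ll1 - ll0))
    p = float(0.5 * chi2.sf(stat, 1) + 0.5 * chi2.sf(stat, 2))
    return stat, p, "asymptotic"


def fisher_combine(p_values):
    """Fisher's method: X = -2 sum(ln p) ~ chi^2 with 2k df under the null."""
    p = np.asarray(p_values, float)
    if p.size == 0 or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.sum(np.log(p))
    return float(chi2.sf(x, 2 * p.size))


def apply_filters(meta: pd.DataFrame, min_case_coverage: float = 0.75,
                  min_q_p: float = 0.001):
    """Screen meta rows on case coverage and heterogeneity.

    Keeps rows with ``case_coverage >= min_case_coverage`` (boundary kept)
    and ``q_p > min_q_p`` (strict; rows with undefined Q, e.g. single-study
    SNPs, pass the heterogeneity rule).  Returns (filtered, drop counts).
    """
    cov_ok = meta["case_coverage"].to_numpy(float) >= min_case_coverage
    qp = meta["q_p"].to_numpy(float)
    q_ok = ~(qp <= min_q_p)  # NaN passes
    counts = {
        "n_input": len(meta),
        "dropped_coverage": int((~cov_ok).sum()),
        "dropped_heterogeneity": int((~q_ok).sum()),
        "retained": int((cov_ok & q_ok).sum()),
    }
    return meta.loc[cov_ok & q_ok].reset_index(drop=True), counts


def _harmonize(study_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    frames = []
    for study, df in study_tables.items():
        d = df.copy()
        d["study"] = study
        frames.append(d)
    allrows = pd.concat(frames, ignore_index=True)
    meta_cols = allrows.groupby("snp")[["chr", "pos", "ea", "oa"]].nunique()
    clash = meta_cols[(meta_cols > 1).any(axis=1)]
    if len(clash):
        raise ValueError(f"conflicting allele/position metadata for SNP {clash.index[0]}")
    return allrows


def meta_analyse(study_tables: dict[str, pd.DataFrame],
                 use_genomic_control: bool = True,
                 weight_scheme: str = "neff") -> pd.DataFrame:
    """Stouffer meta-analysis of per-centre association scans.

    ``study_tables`` maps study id to an association DataFrame (columns as
    produced by :func:`onsetgwas.assoc.association_scan`).  Genomic control
    is applied per study before combination.  ``weight_scheme`` is ``neff``
    (sqrt of effective N, the METAL case-control default) or ``n`` (sqrt of
    total N).  Returns one row per SNP with z_meta, p_meta, case coverage,
    Cochran's Q and a METAL-style direction string.
    """
    allrows = _harmonize(study_tables)
    allrows = allrows[allrows["flag"] != "unestimable"].copy()
    lambdas = {}
    if use_genomic_control:
        parts = []
        for study, d in allrows.groupby("study", sort=False):
            lam, corrected = genomic_control(d["chisq"].to_numpy(float))
            lambdas[study] = lam
            d = d.copy()
            d["chisq"] = corrected
            d["z"] = np.sign(d["z"].to_numpy(float)) * np.sqrt(corrected)
            d["p"] = chi2.sf(corrected, 1)
            parts.append(d)
        allrows = pd.concat(parts, ignore_index=True)
    total_cases = allrows.groupby("study")["n_cases"].first().sum()
    if weight_scheme == "neff":
        n_ctrl = allrows["n"] - allrows["n_cases"]
        allrows["w"] = np.sqrt(effective_n(allrows["n_cases"], n_ctrl))
    elif weight_scheme == "n":
        allrows["w"] = np.sqrt(allrows["n"].to_numpy(float))
    else:
        raise ValueError(f"unknown weight scheme: {weight_scheme}")

    study_order = list(study_tables)
    # wide (snp x study) matrices; NaN marks a study not carrying the SNP
    first = allrows.drop_duplicates("snp").set_index("snp")
    snp_order = first.index
    wide = {
        col: allrows.pivot(index="snp", columns="study", values=col)
        .reindex(index=snp_order, columns=study_order)
        .to_numpy(float)
        for col in ("z", "w", "beta", "se", "n_cases")
    }
    present = np.isfinite(wide["z"])
    z, w = np.nan_to_num(wide["z"]), np.where(present, wide["w"], 0.0)
    z_meta = (w * z).sum(axis=1) / np.sqrt((w * w).sum(axis=1))
    p_meta = 2.0 * norm.sf(np.abs(z_meta))
    n_studies = present.sum(axis=1)
    coverage = np.nansum(wide["n_cases"], axis=1) / total_cases
    # Cochran's Q, vectorized over SNPs present in >= 2 studies
    with np.errstate(invalid="ignore", divide="ignore"):
        iv = np.where(present, 1.0 / (wide["se"] ** 2), 0.0)
        bet = np.nan_to_num(wide["beta"])
        pooled = (iv * bet).sum(axis=1) / iv.sum(axis=1)
        q = (iv * (bet - pooled[:, None]) ** 2).sum(axis=1)
    q_p = np.where(n_studies >= 2, chi2.sf(q, np.maximum(n_studies - 1, 1)), np.nan)
    q = np.where(n_studies >= 2, q, np.nan)
    signs = np.where(present, np.where(z > 0, "+", "-"), "?")
    direction = ["".join(row) for row in signs]
    out = pd.DataFrame({
        "snp": snp_order,
        "chr": first["chr"], "pos": first["pos"],
        "ea": first["ea"], "oa": first["oa"],
        "n_studies": n_studies,
        "case_coverage": coverage,
        "z_meta": z_meta, "p_meta": p_meta,
        "q_stat": q, "q_p": q_p, "direction": direction,
    }).reset_index(drop=True)
    out.attrs["lambda_applied"] = lambdas
    return out
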
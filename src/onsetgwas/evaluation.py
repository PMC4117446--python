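"""Permutation evaluation of the age-at-onset informed analysis.

The question answered here: does conditioning on age-at-onset genuinely
sharpen association signals, or could the observed gains arise by chance?
The machinery: take a set of near-independent SNPs enriched for true
association (selected from the conventional case-control analysis and
LD-clumped), permute case onset ages within centre x subtype strata, rerun
the informed analysis, and compare the observed results against the
permutation distribution via two summaries — the summed absolute Z score
over the SNP set (sumZ) and the per-permutation proportion of SNPs more
significant in the observed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .assoc import GenotypePanel, association_scan
from .liability import assign_liabilities
from .meta import meta_analyse
from .prevalence import PrevalenceModel

__all__ = [
    "ClumpParams",
    "PermutationConfig",
    "ld_clump",
    "permute_ages",
    "empirical_p",
    "sumz_evaluation",
    "proportion_more_significant",
    "known_locus_age_effect",
    "evaluate_age_effect",
]


@dataclass(frozen=True)
class ClumpParams:
    """LD-clumping parameters: window in base pairs and the r^2 ceiling."""

    window: int = 300_000
    r2_max: float = 0.25

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not (0.0 < self.r2_max < 1.0):
            raise ValueError("r2_max must be in (0, 1)")


@dataclass(frozen=True)
class PermutationConfig:
    """Permutation-study parameters.

    ``thresholds`` are the SNP selection p-value cut-offs, in descending
    order; ``n_perm`` defaults to a scaled-down 100 (use 1000 for a
    full-scale run).  Strata are centre x subtype.
    """

    n_perm: int = 100
    seed: int = 0
    thresholds: tuple[float, ...] = (0.05, 0.005, 0.0005, 0.00005)

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if any(a <= b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly descending")


def ld_clump(assoc: pd.DataFrame, panel: GenotypePanel,
             params: ClumpParams = ClumpParams()) -> list[str]:
    """Greedy LD clumping: retain the most significant SNP per LD block.

    Repeatedly takes the lowest-p unclaimed SNP as an index SNP and removes
    every unclaimed SNP on the same chromosome within ``params.window``
    base pairs whose dosage r^2 (squared Pearson correlation, composite LD)
    with the index is >= ``params.r2_max``.  Ties on p break by
    (chromosome, position, id).  Returns retained SNP ids in claim order.
    """
    snp_index = {s: i for i, s in enumerate(panel.snps["snp"])}
    missing = [s for s in assoc["snp"] if s not in snp_index]
    if missing:
        raise ValueError(f"SNP missing from genotype panel: {missing[0]}")
    rows = assoc.sort_values(
        ["p", "chr", "pos", "snp"], kind="mergesort"
    ).reset_index(drop=True)
    dos = panel.dosages
    claimed = np.zeros(len(rows), dtype=bool)
    chrs = rows["chr"].to_numpy()
    poss = rows["pos"].to_numpy(float)
    retained: list[str] = []
    for i in range(len(rows)):
        if claimed[i]:
            continue
        claimed[i] = True
        snp = rows.at[i, "snp"]
        retained.append(snp)
        near = np.where(~claimed & (chrs == chrs[i])
                        & (np.abs(poss - poss[i]) <= params.window))[0]
        if near.size == 0:
            continue
        gi = dos[snp_index[snp]]
        gi = gi - gi.mean()
        denom_i = gi @ gi
        for j in near:
            gj = dos[snp_index[rows.at[j, "snp"]]]
            gj = gj - gj.mean()
            dj = gj @ gj
            if denom_i <= 0 or dj <= 0:
                continue
            r2 = (gi @ gj) ** 2 / (denom_i * dj)
            if r2 >= params.r2_max:
                claimed[j] = True
    return retained


def _stratum_rng(seed: int, perm_index: int, stratum_index: int):
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed),
                               spawn_key=(int(perm_index), int(stratum_index)))
    )


def permute_ages(pheno: pd.DataFrame, config: PermutationConfig,
                 perm_index: int) -> pd.DataFrame:
    """Shuffle case onset ages within each centre x subtype stratum.

    Controls are untouched; the multiset of ages within each stratum is
    preserved; the result is a deterministic function of
    (config.seed, perm_index) and invariant to parallelization order
    because each stratum owns an independent random substream.
    """
    out = pheno.copy()
    ages = out["age"].to_numpy(float).copy()
    is_case = out["status"].to_numpy(int) == 1
    strata = sorted(
        out.loc[is_case].groupby(["centre", "subtype"], observed=True).groups.items(),
        key=lambda kv: (str(kv[0][0]), str(kv[0][1])),
    )
    for s_idx, (_, idx) in enumerate(strata):
        locs = out.index.get_indexer(idx)
        rng = _stratum_rng(config.seed, perm_index, s_idx)
        ages[locs] = ages[locs][rng.permutation(locs.size)]
    out["age"] = ages
    return out


def empirical_p(observed: float, permuted, direction: str = "greater"):
    """Permutation p-value: fraction of permutations strictly more extreme.

    ``direction`` is ``"greater"`` when larger statistics are more extreme
    (e.g. sumZ) or ``"smaller"`` (e.g. p-values).  Returns
    (p, annotation, n_ties); when no permutation beats the observation the
    value is 0 with a "<1/n" annotation.
    """
    perm = np.asarray(permuted, float)
    n = perm.size
    if direction == "greater":
        r = int((perm > observed).sum())
    elif direction == "smaller":
        r = int((perm < observed).sum())
    else:
        raise ValueError("direction must be 'greater' or 'smaller'")
    ties = int((perm == observed).sum())
    p = r / n
    note = f"<{1.0 / n:g}" if r == 0 else ""
    return p, note, ties


def _abs_z(p):
    """|Z| equivalent of a two-sided p-value."""
    return norm.isf(np.asarray(p, float) / 2.0)


def proportion_more_significant(observed_p, permuted_p) -> dict:
    """Median and IQR, across permutations, of the fraction of SNPs with
    observed p strictly smaller than that permutation's p for the same SNP."""
    obs = np.asarray(observed_p, float)
    perm = np.atleast_2d(np.asarray(permuted_p, float))
    props = (perm > obs[None, :]).mean(axis=1)
    q1, med, q3 = np.percentile(props, [25, 50, 75])
    return {"median": float(med), "iqr": (float(q1), float(q3))}


def sumz_evaluation(observed_p: pd.Series, permuted_p: pd.DataFrame,
                    selection_p: pd.Series,
                    thresholds=(0.05, 0.005, 0.0005, 0.00005)) -> pd.DataFrame:
    """Genome-wide sumZ evaluation at each selection threshold.

    ``observed_p``: informed meta p per clumped SNP.  ``permuted_p``:
    (n_perm x n_snps) frame, columns matching ``observed_p``'s index.
    ``selection_p``: the p-values that define SNP membership at each
    threshold (from the conventional case-control analysis, so membership
    is fixed across permutations).  sumZ converts each p to
    ``|Z| = Phi^{-1}(1 - p/2)`` and sums over the selected set.
    """
    rows = []
    for thr in thresholds:
        members = selection_p.index[selection_p < thr]
        members = [m for m in members if m in observed_p.index]
        if len(members) == 0:
            rows.append({"threshold": thr, "n_snps": 0, "sumz_observed": np.nan,
                         "empirical_p": np.nan, "annotation": "",
                         "prop_median": np.nan, "prop_iqr": (np.nan, np.nan)})
            continue
        obs_z = _abs_z(observed_p.loc[members])
        perm_z = _abs_z(permuted_p[members].to_numpy())
        sumz_obs = float(obs_z.sum())
        sumz_perm = perm_z.sum(axis=1)
        p, note, _ = empirical_p(sumz_obs, sumz_perm, direction="greater")
        prop = proportion_more_significant(
            observed_p.loc[members].to_numpy(), permuted_p[members].to_numpy()
        )
        rows.append({
            "threshold": thr, "n_snps": len(members),
            "sumz_observed": sumz_obs, "empirical_p": p, "annotation": note,
            "prop_median": prop["median"], "prop_iqr": prop["iqr"],
        })
    return pd.DataFrame(rows)


def known_locus_age_effect(observed_p: float, permuted_p) -> dict:
    """Per-SNP empirical age-effect p: fraction of permutations with a
    strictly smaller (more significant) meta p than observed."""
    p, note, ties = empirical_p(observed_p, permuted_p, direction="smaller")
    return {"empirical_p": p, "annotation": note, "n_ties": ties,
            "n_perm": int(np.asarray(permuted_p).size)}


def _informed_meta_p(centres, model, phenotype, pheno_by_centre,
                     snp_subset=None, covariates=None) -> pd.Series:
    # Genomic control is deliberately off here: the retained SNPs are a
    # selected, association-enriched subset, so their median chi-square is
    # not a valid null calibrator for lambda.
    tables = {}
    for centre, (pheno, panel) in centres.items():
        ph = pheno_by_centre.get(centre, pheno) if pheno_by_centre else pheno
        pan = panel
        if snp_subset is not None:
            mask = panel.snps["snp"].isin(snp_subset).to_numpy()
            pan = panel.subset(mask)
        liab = assign_liabilities(ph, model, phenotype)
        cov = covariates.get(centre) if covariates else None
        tables[centre] = association_scan(pan, liab, ph["status"].to_numpy(), cov)
    meta = meta_analyse(tables, use_genomic_control=False)
    return meta.set_index("snp")["p_meta"]


def _permuted_meta_p(centres, model, phenotype, clumped, perm: PermutationConfig,
                     covariates=None) -> pd.DataFrame:
    """Informed Stouffer meta p per retained SNP for every permutation.

    Vectorized equivalent of running :func:`permute_ages` followed by
    per-centre scans and :func:`onsetgwas.meta.meta_analyse` (without
    genomic control); uses the same per-stratum random substreams, so the
    results match the DataFrame route to floating-point round-off.
    """
    from .meta import effective_n

    prep = []
    for centre, (pheno, panel) in centres.items():
        mask = panel.snps["snp"].isin(clumped).to_numpy()
        pan = panel.subset(mask)
        order = pd.Index(pan.snps["snp"]).get_indexer(clumped)
        d = pan.dosages[order]
        if np.isnan(d).any():
            means = np.nanmean(d, axis=1)
            idx = np.where(np.isnan(d))
            d[idx] = means[idx[0]]
        n = d.shape[1]
        cov = covariates.get(centre) if covariates else None
        from .assoc import _design
        x = _design(n, cov)
        q, _ = np.linalg.qr(x)
        dres = d - (d @ q) @ q.T
        sd = np.sqrt(np.einsum("ij,ij->i", dres, dres))
        status = pheno["status"].to_numpy(int)
        ages = pheno["age"].to_numpy(float)
        if not np.all(np.isfinite(ages)):
            from .liability import _impute_median_ages
            ages = _impute_median_ages(pheno)
        is_case = status == 1
        strata = sorted(
            pheno.loc[is_case].groupby(["centre", "subtype"], observed=True)
            .groups.items(),
            key=lambda kv: (str(kv[0][0]), str(kv[0][1])),
        )
        stratum_locs = [pheno.index.get_indexer(idx) for _, idx in strata]
        n_cases = int(is_case.sum())
        w = np.sqrt(effective_n(n_cases, n - n_cases))
        prep.append({"q": q, "dres": dres, "sd": sd, "n": n, "w": w,
                     "ages": ages, "is_case": is_case,
                     "stratum_locs": stratum_locs})

    n_snps = len(clumped)
    rows = np.empty((perm.n_perm, n_snps))
    for b in range(perm.n_perm):
        num = np.zeros(n_snps)
        den = np.zeros(n_snps)
        for c in prep:
            ages = c["ages"].copy()
            for s_idx, locs in enumerate(c["stratum_locs"]):
                rng = _stratum_rng(perm.seed, b, s_idx)
                ages[locs] = ages[locs][rng.permutation(locs.size)]
            k = model.prevalence_at(ages, phenotype)
            t = norm.isf(k)
            liab = np.where(c["is_case"], norm.pdf(t) / k,
                            -norm.pdf(t) / (1.0 - k))
            yres = liab - c["q"] @ (c["q"].T @ liab)
            sy = np.sqrt(yres @ yres)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (c["dres"] @ yres) / (c["sd"] * sy)
            z = np.sign(r) * np.sqrt(c["n"]) * np.abs(r)
            ok = np.isfinite(z)
            num += np.where(ok, c["w"] * np.nan_to_num(z), 0.0)
            den += np.where(ok, c["w"] ** 2, 0.0)
        z_meta = num / np.sqrt(den)
        rows[b] = 2.0 * norm.sf(np.abs(z_meta))
    return pd.DataFrame(rows, columns=clumped)


def evaluate_age_effect(centres: dict[str, tuple[pd.DataFrame, GenotypePanel]],
                        model: PrevalenceModel, phenotype: str,
                        clump: ClumpParams = ClumpParams(),
                        perm: PermutationConfig = PermutationConfig(),
                        covariates: dict | None = None,
                        focal_snps: list[str] | None = None) -> dict:
    """Full permutation study of the age-at-onset informed analysis.

    1. Conventional case-control scans per centre and meta-analysis define
       the SNP selection basis (no age information enters the selection).
    2. The selection is LD-clumped against pooled dosages.
    3. The informed analysis supplies the observed meta p per retained SNP.
    4. Case onset ages are permuted within centre x subtype and the
       informed analysis is rerun on the retained SNPs, ``perm.n_perm``
       times.
    5. sumZ and proportion-more-significant summaries are computed at each
       selection threshold, plus per-focal-SNP empirical age-effect ps.

    Returns a dict with the clumped SNP list, the summary frame, the
    per-focal-SNP results and the raw permutation p matrix.
    """
    # 1. selection basis: uninformed meta
    uninf = {}
    for centre, (pheno, panel) in centres.items():
        cov = covariates.get(centre) if covariates else None
        uninf[centre] = association_scan(
            panel, pheno["status"].to_numpy(float), pheno["status"].to_numpy(), cov)
    sel_meta = meta_analyse(uninf)

    # 2. clump using pooled dosages as the LD reference
    panels = [panel for _, panel in centres.values()]
    pooled = GenotypePanel(
        snps=panels[0].snps.copy(),
        dosages=np.concatenate([p.dosages for p in panels], axis=1),
        centre_id="pooled",
    )
    keep = sel_meta[sel_meta["p_meta"] < max(perm.thresholds)]
    clumped = ld_clump(keep.rename(columns={"p_meta": "p"}), pooled, clump)
    selection_p = sel_meta.set_index("snp")["p_meta"].loc[clumped]

    # 3. observed informed analysis on the retained SNPs
    observed_p = _informed_meta_p(centres, model, phenotype, None,
                                  snp_subset=clumped, covariates=covariates)
    observed_p = observed_p.reindex(clumped)

    # 4. permutations (numpy fast path computing the same Stouffer meta
    #    p-values as _informed_meta_p; equivalence is unit-tested)
    perm_p = _permuted_meta_p(centres, model, phenotype, clumped, perm,
                              covariates=covariates)

    # 5. summaries
    summary = sumz_evaluation(observed_p, perm_p, selection_p, perm.thresholds)
    focal = {}
    for snp in focal_snps or []:
        if snp in observed_p.index:
            focal[snp] = known_locus_age_effect(
                float(observed_p.loc[snp]), perm_p[snp].to_numpy())
    return {
        "clumped_snps": clumped,
        "selection_p": selection_p,
        "observed_p": observed_p,
        "permuted_p": perm_p,
        "summary": summary,
        "focal": focal,
    }
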
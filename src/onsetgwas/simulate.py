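"""Synthetic multi-centre case-control cohorts with age-structured onset.

The generative model mirrors the analysis assumptions exactly.  Each
individual carries a liability

    L = sum_j beta_j * (g_j - 2 p_j) / sqrt(2 p_j (1 - p_j)) + eps,
    eps ~ N(0, 1 - sum beta_j^2),

fixed at birth.  Prevalence rises with age, so the liability threshold
t(a) falls with age; onset is the first age on a yearly grid where the
threshold drops below the individual's liability.  An individual examined
at age ``a`` is a case iff onset <= a.  Genetically loaded individuals
therefore have earlier onset purely through ascertainment — the mechanism
an age-at-onset informed analysis is designed to exploit.

Dosage noise emulates imputation: the returned dosage is the posterior
mean of the genotype given a noisy observation, so its variance shrinks
and the per-SNP info score (var(dosage) / (2 eaf (1-eaf))) falls below 1
as noise grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .assoc import GenotypePanel
from .prevalence import OVERALL, PrevalenceModel, default_prevalence_model

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "add_dosage_noise",
    "write_fixture_set",
]


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohorts.

    Defaults describe a modest two-centre case-control study of the overall
    phenotype: 1000 cases and 1000 controls per centre, 500 SNPs of which 20
    are causal with standardized effect 0.12 on the liability scale, allele
    frequencies uniform on [0.05, 0.5], exam ages uniform on [40, 85], and
    mild imputation noise targeting info scores around 0.9.
    """

    seed: int = 0
    n_centres: int = 2
    n_cases: int = 1000
    n_controls: int = 1000
    m_snps: int = 500
    n_causal: int = 20
    beta: float = 0.12
    maf_range: tuple[float, float] = (0.05, 0.5)
    phenotype: str = OVERALL
    prevalence: PrevalenceModel | None = None
    exam_age_range: tuple[float, float] = (40.0, 85.0)
    dosage_noise_sd: float = 0.22
    centre_freq_jitter: float = 0.0
    #: 1.0 = onset fully liability-driven; 0.0 = onset independent of
    #: liability (case onset ages reshuffled within centre) — the
    #: generative null for permutation evaluation.  Intermediate values
    #: reshuffle that fraction of cases.
    age_effect: float = 1.0
    #: null SNPs can be grouped in AR(1)-correlated LD blocks (haplotype
    #: copula, correlation ld_rho between adjacent SNPs within a block)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    #: base-pair spacing between adjacent SNPs on a single chromosome
    snp_spacing: int = 50_000
    max_draw_factor: int = 2000

    def __post_init__(self) -> None:
        if self.prevalence is None:
            self.prevalence = default_prevalence_model()
        betas = np.broadcast_to(np.asarray(self.beta, float), (self.n_causal,))
        if float(np.sum(betas**2)) >= 1.0:
            raise ValueError("sum of squared causal effects must be < 1")
        if self.n_cases <= 0 or self.n_controls <= 0 or self.m_snps < self.n_causal:
            raise ValueError("invalid cohort size configuration")
        if not (0.0 <= self.age_effect <= 1.0):
            raise ValueError("age_effect must be in [0, 1]")

    @property
    def causal_betas(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.beta, float), (self.n_causal,)).copy()


@dataclass
class SimulatedCohort:
    """Phenotypes, per-centre genotype panels, and the generating truth."""

    phenotypes: pd.DataFrame
    panels: dict[str, GenotypePanel]
    true_dosages: dict[str, np.ndarray]
    truth: dict
    config: SimulationConfig


def _onset_grid(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Yearly age grid spanning the study, with subtype thresholds."""
    model = config.prevalence
    lo = min(config.exam_age_range[0], model.age_grid[0])
    hi = max(config.exam_age_range[1], model.age_grid[-1])
    ages = np.arange(np.floor(lo), np.floor(hi) + 1.0)
    t = model.threshold_at(ages, config.phenotype)
    return ages, t


def _onset_ages(liab: np.ndarray, grid_ages: np.ndarray, grid_t: np.ndarray) -> np.ndarray:
    """First grid age whose threshold lies at or below the liability.

    Individuals who never cross get +inf (never affected).
    """
    # grid_t is non-increasing; find first index with grid_t <= L
    idx = np.searchsorted(-grid_t, -liab, side="left")
    onset = np.full(liab.shape, np.inf)
    hit = idx < grid_ages.size
    onset[hit] = grid_ages[idx[hit]]
    return onset


def add_dosage_noise(genotypes: np.ndarray, noise_sd: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Imputation-like dosages and info scores from hard genotypes.

    A noisy signal ``y = g + eta`` (eta ~ N(0, noise_sd^2)) is shrunk back
    to the posterior mean under a normal approximation,
    ``d = 2p + c (y - 2p)`` with ``c = var(g) / (var(g) + noise_sd^2)``,
    then clipped to [0, 2].  The per-SNP info score is the ratio of dosage
    variance to the variance a perfectly observed genotype would have
    (the realized hard-genotype variance standing in for 2 eaf (1 - eaf)),
    clipped to [0, 1], so info is exactly 1 at zero noise and falls as
    noise grows; monomorphic SNPs get info 0.  Returns (dosages, info)
    with genotypes as (n_snps, n_samples).
    """
    g = np.asarray(genotypes, float)
    if noise_sd == 0.0:
        d = g.copy()
    else:
        p = g.mean(axis=1, keepdims=True) / 2.0
        var_g = 2.0 * p * (1.0 - p)
        c = np.divide(var_g, var_g + noise_sd**2,
                      out=np.zeros_like(var_g), where=var_g > 0)
        y = g + rng.normal(0.0, noise_sd, size=g.shape)
        d = np.clip(2.0 * p + c * (y - 2.0 * p), 0.0, 2.0)
    denom = g.var(axis=1)
    info = np.zeros(g.shape[0])
    poly = denom > 0
    info[poly] = np.clip(d[poly].var(axis=1) / denom[poly], 0.0, 1.0)
    return d, info


def _draw_genotypes(rng, freqs: np.ndarray, n: int, block_size: int, rho: float) -> np.ndarray:
    """(n_snps, n) hard genotypes; optional AR(1) haplotype LD in blocks."""
    m = freqs.size
    if block_size <= 1 or rho == 0.0:
        return rng.binomial(2, freqs[:, None], size=(m, n)).astype(float)
    thr = norm.isf(freqs)  # allele present when latent exceeds threshold
    g = np.zeros((m, n))
    for _ in range(2):  # two haplotypes
        z = rng.standard_normal((m, n))
        for start in range(0, m, block_size):
            for j in range(start + 1, min(start + block_size, m)):
                z[j] = rho * z[j - 1] + np.sqrt(1 - rho**2) * z[j]
        g += (z > thr[:, None]).astype(float)
    return g


def simulate_cohort(config: SimulationConfig, rng=None) -> SimulatedCohort:
    """Generate a multi-centre cohort by rejection sampling.

    Candidates are drawn from the population (causal genotypes, residual
    liability, exam age) until each centre's case and control quotas are
    met; null-SNP genotypes, being independent of ascertainment, are drawn
    afterwards for the retained samples only.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    betas = config.causal_betas
    resid_sd = float(np.sqrt(1.0 - np.sum(betas**2)))
    base_freq = rng.uniform(*config.maf_range, size=config.m_snps)
    causal_idx = np.arange(config.n_causal)  # causal SNPs lead the map
    grid_ages, grid_t = _onset_grid(config)

    snp_ids = np.array([f"rs{i + 1}" for i in range(config.m_snps)])
    positions = (np.arange(config.m_snps) + 1) * config.snp_spacing

    pheno_rows = []
    panels: dict[str, GenotypePanel] = {}
    true_dosages: dict[str, np.ndarray] = {}
    for c in range(config.n_centres):
        centre = f"C{c + 1}"
        freqs = base_freq
        if config.centre_freq_jitter > 0:
            freqs = np.clip(
                base_freq + rng.normal(0.0, config.centre_freq_jitter, config.m_snps),
                0.01, 0.99,
            )
        fc = freqs[causal_idx]
        scale = betas / np.sqrt(2.0 * fc * (1.0 - fc))

        need_cases, need_controls = config.n_cases, config.n_controls
        got_g, got_status, got_age = [], [], []
        drawn = 0
        limit = config.max_draw_factor * (config.n_cases + config.n_controls)
        batch = max(4 * (config.n_cases + config.n_controls), 10_000)
        while (need_cases > 0 or need_controls > 0) and drawn < limit:
            gc = rng.binomial(2, fc[:, None], size=(config.n_causal, batch)).astype(float)
            liab = scale @ (gc - 2.0 * fc[:, None]) + rng.normal(0.0, resid_sd, batch)
            exam = rng.uniform(*config.exam_age_range, size=batch)
            onset = _onset_ages(liab, grid_ages, grid_t)
            affected = onset <= exam
            drawn += batch
            for is_case, need in ((True, need_cases), (False, need_controls)):
                if need <= 0:
                    continue
                sel = np.where(affected == is_case)[0][:need]
                if sel.size == 0:
                    continue
                got_g.append(gc[:, sel])
                got_status.append(np.full(sel.size, int(is_case)))
                got_age.append(onset[sel] if is_case else exam[sel])
                if is_case:
                    need_cases -= sel.size
                else:
                    need_controls -= sel.size
        if need_cases > 0 or need_controls > 0:
            raise RuntimeError(
                f"could not reach case/control quota in centre {centre}; "
                "prevalence too low for the requested sample size"
            )
        g_causal = np.concatenate(got_g, axis=1)
        status = np.concatenate(got_status)
        age = np.concatenate(got_age)
        n = status.size

        if config.age_effect < 1.0:
            cases = np.where(status == 1)[0]
            n_shuf = int(round((1.0 - config.age_effect) * cases.size))
            if n_shuf > 1:
                pick = rng.choice(cases, size=n_shuf, replace=False)
                age[pick] = age[rng.permutation(pick)]

        # null-SNP genotypes are independent of ascertainment
        null_freqs = freqs[config.n_causal:]
        g_null = _draw_genotypes(rng, null_freqs, n, config.ld_block_size, config.ld_rho)
        g_all = np.vstack([g_causal, g_null]) if g_null.size else g_causal

        dos, info = add_dosage_noise(g_all, config.dosage_noise_sd, rng)
        snps = pd.DataFrame({
            "snp": snp_ids, "chr": "1", "pos": positions,
            "ea": "A", "oa": "G", "info": info,
        })
        panels[centre] = GenotypePanel(snps=snps, dosages=dos, centre_id=centre)
        true_dosages[centre] = g_all
        pheno_rows.append(pd.DataFrame({
            "sample_id": [f"{centre}_S{i + 1}" for i in range(n)],
            "centre": centre,
            "status": status,
            "subtype": np.where(status == 1, config.phenotype, "none"),
            "age": np.round(age, 2),
        }))

    phenotypes = pd.concat(pheno_rows, ignore_index=True)
    truth = {
        "seed": int(config.seed),
        "phenotype": config.phenotype,
        "causal_snps": snp_ids[causal_idx].tolist(),
        "betas": betas.tolist(),
    }
    return SimulatedCohort(phenotypes, panels, true_dosages, truth, config)


def write_fixture_set(cohort: SimulatedCohort, out_dir, dialect: str = "tsv") -> dict:
    """Write phenotype/dosage/prevalence/truth files; returns the paths."""
    import json
    from pathlib import Path

    from . import io as oio
    from .prevalence import write_prevalence_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"phenotypes": out / "phenotypes.tsv", "prevalence": out / "prevalence.tsv",
             "truth": out / "truth.json", "dosages": {}}
    oio.write_phenotypes(cohort.phenotypes, paths["phenotypes"])
    write_prevalence_table(cohort.config.prevalence, paths["prevalence"])
    for centre, panel in cohort.panels.items():
        samples = cohort.phenotypes.loc[
            cohort.phenotypes["centre"] == centre, "sample_id"].tolist()
        if dialect == "tsv":
            p = out / f"dosages_{centre}.tsv"
            oio.write_dosage_tsv(panel, samples, p)
        elif dialect == "vcf":
            p = out / f"dosages_{centre}.vcf"
            oio.write_dosage_vcf(panel, samples, p)
        else:
            raise ValueError(f"unknown dialect: {dialect}")
        paths["dosages"][centre] = p
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)
    return paths
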
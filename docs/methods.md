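# Methods note

This note records the statistical model, the numerical choices, the
defaults, and the open design decisions behind `onsetgwas`.

## 1. Liability-threshold model with age-varying threshold

Each individual carries a standard-normal liability `L`. The cumulative
disease prevalence by age `a` is `K(a)`; an individual is affected by age
`a` iff `L > t(a)` with `t(a) = Φ⁻¹(1 − K(a))`. Because `K(a)` is
non-decreasing, `t(a)` is non-increasing: the bar falls with age, so
early onset implies high liability.

Subtype prevalence is modelled as a constant fraction of overall
prevalence, `K_sub(a) = f_sub · K(a)`, default `f_sub = 0.20` (roughly
the share of large-artery stroke among ischaemic strokes).

The default prevalence table is piecewise-linear through
`(45, 0.001), (55, 0.004), (65, 0.012), (75, 0.028), (85, 0.050)` and is
clamped outside the grid. It approximates cumulative ischaemic-stroke
risk in European populations; users supply their own table
(`prevalence.tsv`) for other populations or phenotypes.

### Posterior mean liabilities

With `K = K(a)` and `t = t(a)`:

- case (onset at age `a`): `E[L | L > t] = φ(t) / K`;
- control (stroke-free at exam age `a`): `E[L | L ≤ t] = −φ(t) / (1 − K)`.

`assign_liabilities` validates that `t` and `K` are consistent
(`|Φ(−t) − K| ≤ 10⁻⁶`), imputes missing ages by the centre × status
median (global median as fallback) and optionally uses a single pooled
exam age for controls when per-control ages are unavailable. The mixture
identity `K·E_case + (1−K)·E_control = 0` holds to 10⁻¹² and is tested.

## 2. Association score test

For dosage `g`, response `y` (posterior liability for the informed test,
0/1 status for the uninformed test) and covariates `X` (intercept always
included), both `g` and `y` are residualized on `X` (QR / least squares)
and the score statistic is `χ² = N·r²` on 1 df with `z = sign(r)·√χ²`,
where `r` is the Pearson correlation of the residuals. For a binary
response without covariates this reduces exactly to the Cochran–Armitage
trend test; with a constant-prevalence model the informed and uninformed
statistics are identical to machine precision because the liability
response is then an affine function of status (tested at relative
10⁻¹⁰). Missing dosages are mean-imputed per SNP; SNPs with zero
residual variance are flagged `unestimable` and excluded from
meta-analysis.

QC defaults: imputation info ≥ 0.3 and MAF ≥ 0.01 are kept (boundary
values kept).

The descriptive `logistic_or_by_quantile` fits a logistic regression of
status on dosage within onset-age quantile bins (statsmodels), flagging
separation when the standard error explodes.

## 3. Meta-analysis

Per-centre scans are combined by sample-size weighted Stouffer
combination (the METAL case-control scheme):
`z_meta = Σ wᵢ zᵢ / √(Σ wᵢ²)` with `wᵢ = √N_eff,i` and
`N_eff = 4 / (1/n_cases + 1/n_controls)`; `weight_scheme="n"` uses total
N instead. Genomic control is applied per centre before combination:
`λ = max(1, median(χ²)/0.45494)` (the exact χ²₁ median from
`scipy.stats.chi2.ppf(0.5, 1)`), chisq divided by λ.

Filters (applied after combination): SNPs present in centres holding at
least 75% of all cases are kept (`case_coverage ≥ 0.75`, boundary kept),
and SNPs with Cochran's Q heterogeneity p ≤ 0.001 are removed (missing Q
passes). Direction strings are METAL-style (`+`, `-`, `?` per centre).

Also provided: fixed-effects inverse-variance pooling; the Han–Eskin
RE2 random-effects likelihood-ratio test with the asymptotic
`½χ²₁ + ½χ²₂` null mixture (τ² profiled by bounded scalar minimization;
flagged `asymptotic` since tabulated small-k corrections are not
implemented); Fisher's method `X = −2Σln pᵢ ~ χ²_{2k}` for combining
discovery and replication evidence.

## 4. Permutation evaluation of the age signal (sumZ)

The question: do the onset ages genuinely sharpen association signals,
beyond what case-control status already provides?

1. **Selection.** SNPs are selected from the *uninformed* (case-control)
   meta-analysis at thresholds 0.05, 0.005, 0.0005, 0.00005. Selecting on
   the uninformed analysis is deliberate: membership is then fixed under
   age permutation, so the null distribution of the statistic is exact
   (case ages are exchangeable within strata when they carry no signal) —
   verified empirically, Kolmogorov–Smirnov uniformity of the empirical p
   over 200 null replicates.
2. **Clumping.** Greedy LD clumping on pooled dosages: sort by
   (p, chr, pos, snp), keep the best SNP, remove SNPs within 300 kb with
   r² ≥ 0.25, repeat. Verified against an exhaustive brute-force oracle
   on random LD-structured instances.
3. **Permutation.** Case onset ages are permuted within centre × subtype
   strata; control ages are untouched. Each (permutation, stratum) pair
   gets an independent `numpy` `SeedSequence` substream
   (`spawn_key = (perm_index, stratum_index)`), so results are
   reproducible and independent of iteration order.
4. **Statistic.** For each threshold, `sumZ = Σ |Φ⁻¹(1 − p/2)|` over the
   clumped selected SNPs, using informed meta p-values; the empirical p
   is the strict-inequality exceedance fraction over permutations
   (annotated `<1/n_perm` when zero). The median and IQR of the
   proportion of SNPs more significant than in the observed analysis are
   reported, as is a per-SNP empirical p for focal (known) loci.

**Genomic control is switched off inside the permutation loop.** λ there
would be estimated from the median χ² of a few dozen
association-*selected* SNPs, which is not a null calibrator: it deflates
the observed analysis more than the permuted ones and destroys power
while adding nothing to validity (observed and permuted analyses are
compared on identical footing). GC remains on for genome-wide discovery.

The permutation loop uses a vectorized fast path (dosages residualized
once per centre, liabilities recomputed inline per permutation) proven
equal to the reference pandas route to 10⁻¹² in the tests.

## 5. Synthetic cohorts

Genotypes `g ~ Bin(2, p)` with per-SNP frequencies uniform in the MAF
range; liability
`L = Σ βⱼ (gⱼ − 2pⱼ)/√(2pⱼ(1−pⱼ)) + ε`, `ε ~ N(0, 1 − Σβ²)`. Onset age
is the first age on a yearly grid where `t_sub(a) ≤ L`; a person drawn
with exam age uniform on [40, 85] is a case iff onset ≤ exam age. Case
and control quotas per centre are filled by batched rejection sampling;
only causal genotypes are drawn for candidates, and null genotypes are
drawn after selection (valid because they are independent of
ascertainment), which keeps rare-disease sampling cheap. A
`RuntimeError` is raised when prevalence is too low to fill the case
quota within `max_draw_factor` draws per needed case.

Imputation-style noise: `d = 2p + c(g + η − 2p)` with
`η ~ N(0, σ²)`, `c = var(g)/(var(g) + σ²)` (shrinkage keeps `d`
unbiased); the reported info score is `var(d)/var(g)` on the realized
hard genotypes, clipped to [0, 1], so zero noise gives info exactly 1 and
info decreases monotonically with σ. Default σ = 0.22 gives info scores
around 0.9, typical of well-imputed variants.

Optional LD: null SNPs can be grouped into AR(1) latent-Gaussian blocks
(`ld_block_size`, `ld_rho`); thresholding the latent haplotypes to
genotype counts attenuates the realized r² relative to ρ².

`age_effect ∈ [0, 1]`: at 1 onset ages are fully liability-driven; at 0
case onset ages are reshuffled within centre, which makes case ages
exchangeable — the exact generative null for the permutation test.
Intermediate values reshuffle the corresponding fraction of cases.

Fixtures (`write_fixture_set`) are plain TSV (or minimal VCF 4.2 with DS
genotypes) plus a `truth.json` with causal SNPs and betas; byte-identical
across runs at a fixed seed.

## 6. Problem sizes and verification budgets

Sizes used in the test suite and acceptance script are this package's
own choices, set so the whole suite runs in a few minutes on one CPU
while keeping Monte-Carlo error well below the tolerances:

- truncated-normal oracle: 10⁶ draws, 3-standard-error bands;
- null calibration: 2000 null SNPs, 2000 samples; type-I at α = 0.05
  within the 99% binomial band, λ ∈ [0.9, 1.1];
- power: 50 replicates (2 centres × 1000/1000) for the informed-vs-
  uninformed sign test; 20 replicates for sumZ detection (100
  permutations each); 200 small null replicates for uniformity;
- clumping: 50 random 100-SNP LD-structured instances against brute
  force.

## 7. Limitations

- Prevalence is treated as known; misspecified `K(a)` biases the
  liability weights (though the score test remains valid as a test under
  the null of no association).
- The RE2 test uses the asymptotic null; for very small numbers of
  studies its p-values are conservative/approximate and flagged as such.
- The generator draws genotypes independent of centre apart from
  optional frequency jitter; it does not model population stratification
  gradients, cryptic relatedness, or realistic genome-wide LD maps.
- Competing risks (death before stroke) and secular trends in prevalence
  are not modelled; exam age stands in for censoring age.
- The permutation test conditions on the selected, clumped SNP set from
  the case-control analysis; it quantifies the *added* value of onset
  ages at those loci, not genome-wide power.
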
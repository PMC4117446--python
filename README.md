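# onsetgwas

Age-at-onset informed genome-wide association analysis for ischaemic
stroke and its subtypes, with multi-centre meta-analysis and a
permutation framework that quantifies how much signal the onset ages add.

## The scientific problem

A standard case-control GWAS treats every case identically. But for
late-onset diseases such as ischaemic stroke, *when* someone becomes a
case is informative: under a liability-threshold model, a person who has
a stroke at 50 must carry substantially more liability than one who has a
stroke at 85, because the population liability threshold falls as
age-specific prevalence K(a) rises.

`onsetgwas` exploits this by replacing the binary phenotype with each
individual's **posterior mean liability** given their status and age:

- liability `L ~ N(0, 1)` in the population;
- at age `a` the disease threshold is `t(a) = Φ⁻¹(1 − K(a))`, where
  `K(a)` is the cumulative prevalence at age `a` (for a subtype,
  `K_sub(a) = f_sub · K(a)` with subtype fraction `f_sub`);
- a case with onset age `a` gets `E[L | L > t] = φ(t) / K`,
- a control examined at age `a` gets `E[L | L ≤ t] = −φ(t) / (1 − K)`,

so young cases are up-weighted and old controls become slightly more
informative "super-normal" controls. These posterior means satisfy the
mixture identity `K·E[L|case] + (1−K)·E[L|control] = 0` exactly.

Association is a score test: dosage and response are residualized on the
covariates, and `χ² = N·r²` on 1 df, where `r` is their correlation. When
prevalence is constant in age the informed response is an affine
transform of case-control status and the two tests agree exactly — the
method can only add information, never contradict the standard analysis.

Per-centre results are combined by sample-size weighted Stouffer
meta-analysis (effective N = 4/(1/n_cases + 1/n_controls)) with
per-centre genomic control, Cochran's Q heterogeneity filtering and
case-coverage filtering. Fisher's method combines discovery and
replication p-values.

The *evaluation* layer answers "did the onset ages actually help?": it
LD-clumps the top SNPs from the conventional case-control meta-analysis,
then permutes case onset ages within centre × subtype strata and compares
the observed sum of |Z| scores of the informed analysis against its
permutation distribution (the **sumZ** statistic), reporting an empirical
p-value and the median proportion of SNPs that became more significant.

A synthetic cohort generator produces multi-centre case-control samples
whose onset ages follow the same liability-threshold process (causal
dosages shift liability, liability determines the first age at which the
falling threshold is crossed), with imputation-style dosage noise,
optional LD blocks, and an `age_effect` knob whose `0.0` setting is the
exact generative null for the permutation test.

## Worked example

Simulate a two-centre cohort (500 cases / 500 controls per centre, 200
SNPs of which rs1–rs10 are causal), run both analyses, meta-analyse and
evaluate the age signal:

```bash
onsetgwas simulate --out demo/data --seed 42 --n-centres 2 \
    --n-cases 500 --n-controls 500 --m-snps 200 --n-causal 10
onsetgwas assoc --data demo/data --out demo/assoc --informed
onsetgwas assoc --data demo/data --out demo/assoc --uninformed
onsetgwas meta  --assoc-dir demo/assoc --out demo/meta --mode informed
onsetgwas evaluate --data demo/data --out demo/eval --n-perm 100 --seed 7
```

Actual output:

```text
wrote cohort (2 centres, 200 SNPs) to demo/data
C1: QC kept 200/200 SNPs (info<0.3: 0, maf<0.01: 0)
C2: QC kept 200/200 SNPs (info<0.3: 0, maf<0.01: 0)
lambda[C1] = 1.1510
lambda[C2] = 1.2727
filters: kept 200/200 (coverage: -0, heterogeneity: -0)
p<0.05:   n=16 sumZ=73.18 empirical p=0.0 <0.01
p<0.005:  n=10 sumZ=60.21 empirical p=0.0 <0.01
p<0.0005: n=10 sumZ=60.21 empirical p=0.0 <0.01
p<5e-05:  n=9  sumZ=55.68 empirical p=0.0 <0.01
```

The informed meta-analysis ranks the causal SNPs at the top
(`demo/meta/meta_informed.tsv`):

```text
snp   z_meta       p_meta direction  case_coverage
rs5 6.580999 4.672986e-11        ++              1
rs6 6.027170 1.668552e-09        ++              1
rs3 5.997739 2.000831e-09        ++              1
rs8 5.983729 2.180857e-09        ++              1
rs9 5.825547 5.692588e-09        ++              1
```

and in none of 100 age permutations does the clumped SNP set reach the
observed sumZ, i.e. the onset ages carry genuine signal (empirical
p < 0.01 at every selection threshold).

Combining a discovery p-value with a replication p-value by Fisher's
method:

```bash
$ onsetgwas combine --p 2.5e-7 --p 0.0048
2.58491e-08
```

Every command writes a `manifest_<command>.json` with the package
version, seed and SHA-256 of each input, so runs are reproducible.

## Layout

| module | contents |
| --- | --- |
| `onsetgwas.prevalence` | age-specific prevalence model, TSV round-trip |
| `onsetgwas.liability` | thresholds, posterior mean liabilities, assignment |
| `onsetgwas.assoc` | genotype panels, QC, score tests, scans, logistic OR by onset-age quantile |
| `onsetgwas.meta` | Stouffer/IVW/RE2 meta, genomic control, Cochran's Q, Fisher, filters |
| `onsetgwas.evaluation` | LD clumping, stratified age permutation, sumZ evaluation |
| `onsetgwas.simulate` | liability-driven synthetic cohorts, dosage noise, fixtures |
| `onsetgwas.io`, `onsetgwas.cli` | TSV/VCF I/O and the `onsetgwas` command line |

See `docs/methods.md` for the full methods note, parameter defaults and
design decisions.
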
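"""Readers and writers for the pipeline's plain-text interchange formats.

Two dosage dialects are supported: a TSV with one row per SNP
(snp, chr, pos, ea, oa, info, then one column per sample) and a VCF with a
per-genotype ``DS`` FORMAT field plus a per-site INFO key holding the
imputation quality (key name configurable, default ``INFO``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assoc import GenotypePanel

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_dosage_vcf",
    "write_dosage_vcf",
]

_META_COLS = ["snp", "chr", "pos", "ea", "oa", "info"]


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype TSV: sample_id, centre, status(0/1), subtype, age, PC1..PCk."""
    df = pd.read_csv(path, sep="\t", dtype={"centre": str, "subtype": str},
                     na_values=["NA"])
    required = {"sample_id", "centre", "status", "age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing phenotype columns {sorted(missing)}")
    df["status"] = df["status"].astype(int)
    if not df["status"].isin([0, 1]).all():
        raise ValueError(f"{path}: status must be 0/1")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path, centre_id: str = "") -> tuple[GenotypePanel, list[str]]:
    """Read the TSV dosage dialect; returns (panel, sample ids)."""
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    missing = set(_META_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing dosage columns {sorted(missing)}")
    samples = [c for c in df.columns if c not in _META_COLS]
    panel = GenotypePanel(
        snps=df[_META_COLS].copy(),
        dosages=df[samples].to_numpy(float),
        centre_id=centre_id,
    )
    return panel, samples


def write_dosage_tsv(panel: GenotypePanel, samples: list[str], path) -> None:
    df = panel.snps[_META_COLS].copy()
    dose = pd.DataFrame(np.round(panel.dosages, 3), columns=samples)
    pd.concat([df.reset_index(drop=True), dose], axis=1).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def write_dosage_vcf(panel: GenotypePanel, samples: list[str], path,
                     info_key: str = "INFO") -> None:
    """Write a minimal VCF 4.2 with DS genotype dosages."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f'##INFO=<ID={info_key},Number=1,Type=Float,'
                 'Description="Imputation info score">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Expected alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i, row in panel.snps.iterrows():
            ds = "\t".join(f"{v:.3f}" for v in panel.dosages[i])
            fh.write(f"{row['chr']}\t{row['pos']}\t{row['snp']}\t{row['oa']}\t"
                     f"{row['ea']}\t.\tPASS\t{info_key}={row['info']:.4f}\tDS\t{ds}\n")


def read_dosage_vcf(path, centre_id: str = "",
                    info_key: str = "INFO") -> tuple[GenotypePanel, list[str]]:
    """Read a VCF with DS dosages via cyvcf2.

    The ALT allele is taken as the effect allele (dosages count ALT copies).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    meta, rows = [], []
    for var in vcf:
        ds = np.asarray(var.format("DS"), float).reshape(-1)
        info = var.INFO.get(info_key)
        meta.append({
            "snp": var.ID, "chr": str(var.CHROM), "pos": int(var.POS),
            "ea": var.ALT[0], "oa": var.REF,
            "info": float(info) if info is not None else np.nan,
        })
        rows.append(ds)
    panel = GenotypePanel(
        snps=pd.DataFrame(meta),
        dosages=np.asarray(rows, float),
        centre_id=centre_id,
    )
    return panel, samples
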
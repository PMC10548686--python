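"""File formats: dosage VCF/TSV, phenotype tables, gene intervals, config.

Genotypes travel either as VCF with a per-sample ``DS`` FORMAT field (1-based
positions; INFO carries effect-allele frequency and imputation quality) or as
a plain samples-by-SNPs tab-separated dosage matrix with a sidecar of SNP
metadata.  Gene annotation is a BED-like table declared 1-based inclusive in
its header line to avoid the 0-based BED ambiguity.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import CohortData, SimConfig, SnpEffect

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_phenotypes",
    "read_phenotypes",
    "write_gene_intervals",
    "read_gene_intervals",
    "write_config",
    "read_config",
    "write_cohort",
    "read_cohort",
]

_VCF_HEADER = """##fileformat=VCFv4.2
##source=csfgwas
##INFO=<ID=EAF,Number=1,Type=Float,Description="Effect (ALT) allele frequency">
##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated ALT allele dosage">
"""


def write_vcf(path, dosages: np.ndarray, snp_meta: pd.DataFrame,
              sample_ids: np.ndarray) -> None:
    """Write dosages as a VCF with one record per SNP and DS per sample."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        for c in pd.unique(snp_meta["chrom"].astype(str)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, sample_ids)) + "\n")
        for j in range(dosages.shape[1]):
            row = snp_meta.iloc[j]
            ds = "\t".join(f"{d:.3f}" for d in dosages[:, j])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['snp']}\t"
                f"{row['other_allele']}\t{row['effect_allele']}\t.\tPASS\t"
                f"EAF={row['eaf']:.4f};R2={row['imp_quality']:.4f}\tDS\t{ds}\n"
            )


def read_vcf(path) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Read a dosage VCF (DS field) into (dosages, snp_meta, sample_ids)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples)
    dosage_cols, meta_rows = [], []
    for var in vcf:
        ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        dosage_cols.append(ds)
        meta_rows.append(
            {
                "snp": var.ID,
                "chrom": var.CHROM,
                "pos": var.POS,
                "effect_allele": var.ALT[0],
                "other_allele": var.REF,
                "eaf": var.INFO.get("EAF", float(np.mean(ds)) / 2.0),
                "imp_quality": var.INFO.get("R2", 1.0),
            }
        )
    return np.column_stack(dosage_cols), pd.DataFrame(meta_rows), samples


def write_dosage_tsv(prefix, dosages: np.ndarray, snp_meta: pd.DataFrame,
                     sample_ids: np.ndarray) -> None:
    """Samples-by-SNPs dosage matrix plus a .snps.tsv metadata sidecar."""
    prefix = Path(prefix)
    df = pd.DataFrame(dosages, index=pd.Index(sample_ids, name="sample_id"),
                      columns=snp_meta["snp"])
    df.to_csv(prefix.with_suffix(".dosage.tsv"), sep="\t")
    snp_meta.to_csv(prefix.with_suffix(".snps.tsv"), sep="\t", index=False)


def read_dosage_tsv(prefix) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".dosage.tsv"), sep="\t", index_col=0)
    meta = pd.read_csv(prefix.with_suffix(".snps.tsv"), sep="\t")
    return df.to_numpy(float), meta, df.index.to_numpy()


def write_phenotypes(outdir, cohort: CohortData) -> None:
    """Covariate, diagnosis, and biomarker tables keyed by sample ID."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    idx = pd.Index(cohort.sample_ids, name="sample_id")
    cov = pd.DataFrame({"sex": cohort.sex, "age": cohort.age}, index=idx)
    for j in range(cohort.ancestry.shape[1]):
        cov[f"ancestry{j + 1}"] = cohort.ancestry[:, j]
    cov["study"] = cohort.study
    cov["diagnosis"] = np.asarray(["control", "MCI", "AD"])[cohort.diagnosis]
    cov.to_csv(outdir / "covariates.tsv", sep="\t")
    bio = cohort.biomarkers.copy()
    bio.index.name = "sample_id"
    bio.to_csv(outdir / "biomarkers.tsv", sep="\t")


def read_phenotypes(outdir) -> tuple[pd.DataFrame, pd.DataFrame]:
    outdir = Path(outdir)
    cov = pd.read_csv(outdir / "covariates.tsv", sep="\t", index_col=0)
    bio = pd.read_csv(outdir / "biomarkers.tsv", sep="\t", index_col=0)
    return cov, bio


def write_gene_intervals(path, genes: pd.DataFrame) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# coordinates: 1-based, inclusive\n")
        genes[["gene", "chrom", "start", "end"]].to_csv(fh, sep="\t", index=False)


def read_gene_intervals(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       dtype={"chrom": str, "start": int, "end": int})


def write_config(path, config: SimConfig) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(config.to_flat_dict(), fh, sort_keys=False)


def read_config(path) -> SimConfig:
    with Path(path).open() as fh:
        d = yaml.safe_load(fh)
    d["snp_effects"] = tuple(SnpEffect(**e) for e in d.get("snp_effects", []))
    d["maf_range"] = tuple(d["maf_range"])
    d["diag_thresholds"] = tuple(d["diag_thresholds"])
    return SimConfig(**d)


def write_cohort(outdir, cohort: CohortData, genotype_format: str = "vcf") -> None:
    """Persist a cohort: genotypes, phenotype tables, and the truth config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if genotype_format == "vcf":
        write_vcf(outdir / "genotypes.vcf", cohort.dosages, cohort.snp_meta,
                  cohort.sample_ids)
    elif genotype_format == "tsv":
        write_dosage_tsv(outdir / "genotypes", cohort.dosages, cohort.snp_meta,
                         cohort.sample_ids)
    else:
        raise ValueError(f"unknown genotype format {genotype_format!r}")
    write_phenotypes(outdir, cohort)
    if cohort.truth is not None:
        write_config(outdir / "truth.yaml", cohort.truth)


def read_cohort(outdir, genotype_format: str = "vcf") -> CohortData:
    outdir = Path(outdir)
    if genotype_format == "vcf":
        dos, meta, samples = read_vcf(outdir / "genotypes.vcf")
    else:
        dos, meta, samples = read_dosage_tsv(outdir / "genotypes")
    cov, bio = read_phenotypes(outdir)
    cov = cov.loc[samples]
    bio = bio.loc[samples]
    diag_codes = cov["diagnosis"].map({"control": 0, "MCI": 1, "AD": 2}).to_numpy()
    anc_cols = [c for c in cov.columns if c.startswith("ancestry")]
    truth = None
    if (outdir / "truth.yaml").exists():
        truth = read_config(outdir / "truth.yaml")
    return CohortData(
        sample_ids=np.asarray(samples),
        dosages=dos,
        snp_meta=meta,
        sex=cov["sex"].to_numpy(int),
        age=cov["age"].to_numpy(float),
        ancestry=cov[anc_cols].to_numpy(float),
        study=cov["study"].to_numpy(),
        diagnosis=diag_codes,
        biomarkers=bio,
        truth=truth,
    )
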
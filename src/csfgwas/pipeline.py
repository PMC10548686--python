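"""End-to-end orchestration: transform -> PCA -> GWAS -> meta -> genes -> mediation.

Stages mirror the analysis workflow of a two-study biomarker-component GWAS:
per-study inverse normal transformation, CV component selection, imputation,
varimax PCA and scores, sex mean-difference tests, per-study single-SNP
association under the requested model tags, fixed-effect meta-analysis,
gene-level tests, greedy LD clumping of genome-wide hits, and mediation
modeling of the clumped hits on the latent ordinal outcome.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .gwas import (
    GENOME_WIDE_ALPHA,
    SUGGESTIVE_ALPHA,
    QCThresholds,
    genomic_lambda,
    ld_r2_matrix,
    qc_filter,
    run_gwas,
    select_independent_hits,
)
from .genes import run_gene_tests
from .mediation import fit_moderated_mediation
from .meta import meta_analyze
from .pca import BiomarkerPanel, fit_component_pipeline
from .synthetic import CohortData, make_gene_annotation

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "sex_mean_test", "write_report"]

MEDIATION_ALPHA = 0.05 / 6  # six potential mediation/direct pathways
SEX_MEAN_ALPHA = 0.05 / 5  # five components
WINSOR_P = 1e-10


@dataclass
class RunConfig:
    models: tuple[str, ...] = ("main", "male", "female", "interaction")
    qc: QCThresholds = field(default_factory=QCThresholds)
    n_components: int | None = 5
    snp_alpha: float = GENOME_WIDE_ALPHA
    suggestive_alpha: float = SUGGESTIVE_ALPHA
    mediation_alpha: float = MEDIATION_ALPHA
    sex_mean_alpha: float = SEX_MEAN_ALPHA
    clump_r2: float = 0.6
    n_boot: int = 1000
    gene_window: int = 0
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        for name in ("snp_alpha", "suggestive_alpha", "mediation_alpha",
                     "sex_mean_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def sex_mean_test(
    pc_scores: pd.DataFrame | np.ndarray,
    sex: np.ndarray,
    covariates: pd.DataFrame,
    alpha: float = SEX_MEAN_ALPHA,
) -> pd.DataFrame:
    """Per-component female-vs-male mean difference, covariate adjusted.

    ``covariates`` must include diagnosis dummy columns (named ``diag_*``)
    alongside age, ancestry, and study terms, matching the adjustment set of
    the component sex-difference analysis.
    """
    cov = pd.DataFrame(covariates)
    if not any(str(c).startswith("diag_") for c in cov.columns):
        raise ValueError("covariates must include diagnosis dummies (diag_MCI, diag_AD)")
    scores = pd.DataFrame(pc_scores)
    sex = np.asarray(sex, dtype=float)
    X = np.column_stack([np.ones(len(sex)), sex, cov.to_numpy(float)])
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    rows = []
    for col in scores.columns:
        y = scores[col].to_numpy(float)
        beta = xtx_inv @ (X.T @ y)
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / (n - p)
        se = float(np.sqrt(xtx_inv[1, 1] * sigma2))
        t = beta[1] / se
        pval = float(2 * stats.t.sf(abs(t), n - p))
        rows.append({"component": str(col), "beta_sex": float(beta[1]),
                     "se": se, "p": pval, "significant": pval < alpha})
    return pd.DataFrame(rows)


def _diag_dummies(diagnosis: np.ndarray) -> pd.DataFrame:
    d = np.asarray(diagnosis)
    return pd.DataFrame({"diag_MCI": (d == 1).astype(float),
                         "diag_AD": (d == 2).astype(float)})


def run_pipeline(
    cohort: CohortData,
    config: RunConfig | None = None,
    gene_intervals: pd.DataFrame | None = None,
) -> dict:
    """Execute every stage on one cohort; returns the result bundle."""
    cfg = config or RunConfig()
    bundle: dict = {"config": cfg}

    # --- phenotype construction -------------------------------------------
    panel = BiomarkerPanel.from_dataframe(
        cohort.biomarkers, group=cohort.study, sex=cohort.sex
    )
    model, scores = fit_component_pipeline(
        panel, k=cfg.n_components, seed=cfg.seed
    )
    scores_df = scores.to_frame(index=cohort.sample_ids)
    # standardized outcomes for association testing
    scores_df = (scores_df - scores_df.mean()) / scores_df.std(ddof=1)
    bundle["pc_model"] = model
    bundle["pc_scores"] = scores_df
    log.info("PCA stage: k=%d, variance explained %s",
             model.k, np.round(model.variance_explained, 3))

    # --- sex mean differences ---------------------------------------------
    cov_base = cohort.covariates()
    sex_cov = pd.concat(
        [cov_base.reset_index(drop=True), _diag_dummies(cohort.diagnosis)], axis=1
    )
    bundle["sex_mean"] = sex_mean_test(
        scores_df.reset_index(drop=True), cohort.sex, sex_cov,
        alpha=cfg.sex_mean_alpha,
    )

    # --- QC ----------------------------------------------------------------
    keep, qc_report = qc_filter(cohort.dosages, cohort.snp_meta,
                                study=cohort.study, thresholds=cfg.qc)
    bundle["qc_report"] = qc_report
    dosages = cohort.dosages[:, keep]
    snp_meta = cohort.snp_meta.loc[keep].reset_index(drop=True)
    log.info("QC stage: %d/%d SNPs retained", keep.sum(), len(keep))

    # --- GWAS per study, then meta ----------------------------------------
    studies = np.unique(cohort.study)
    gwas_results: dict = {}
    lambdas = []
    for model_tag in cfg.models:
        for pc in scores_df.columns:
            per_study = []
            for s in studies:
                sel = cohort.study == s
                covs = cov_base.loc[cohort.sample_ids[sel],
                                    [c for c in cov_base.columns
                                     if not c.startswith("study")]]
                res = run_gwas(
                    dosages[sel], scores_df.loc[cohort.sample_ids[sel], pc],
                    covariates=covs, sex=cohort.sex[sel], model=model_tag,
                    snp_meta=snp_meta, outcome_name=pc, study_name=str(s),
                )
                if len(res):
                    per_study.append(res)
            if not per_study:
                continue
            combined = (meta_analyze(per_study) if len(per_study) > 1
                        else per_study[0])
            gwas_results[(model_tag, pc)] = combined
            if len(combined) >= 100:
                lambdas.append({"model": model_tag, "outcome": pc,
                                "lambda": genomic_lambda(combined["p"])})
    bundle["gwas"] = gwas_results
    bundle["lambda"] = pd.DataFrame(lambdas)

    # --- gene-level tests on the main model -------------------------------
    if gene_intervals is None:
        gene_intervals = make_gene_annotation(snp_meta)
    gene_results = {}
    for pc in scores_df.columns:
        recs = gwas_results.get(("main", pc))
        if recs is None or not len(recs):
            continue
        gene_results[pc] = run_gene_tests(recs, dosages, snp_meta,
                                          gene_intervals, window=cfg.gene_window)
    bundle["genes"] = gene_results

    # --- independent hits + mediation -------------------------------------
    ld = ld_r2_matrix(dosages)
    hits_frames = []
    for (model_tag, pc), recs in gwas_results.items():
        hits = select_independent_hits(
            recs, pd.DataFrame(ld, index=snp_meta["snp"], columns=snp_meta["snp"]),
            r2_max=cfg.clump_r2, p_max=cfg.snp_alpha,
        )
        if len(hits):
            hits = hits.copy()
            hits["model"] = model_tag
            hits["outcome"] = pc
            hits_frames.append(hits)
    all_hits = (pd.concat(hits_frames, ignore_index=True)
                if hits_frames else pd.DataFrame(columns=["snp", "p"]))
    # one mediation model per unique SNP
    all_hits = all_hits.sort_values("p").drop_duplicates("snp")
    bundle["hits"] = all_hits

    snp_col = {s: j for j, s in enumerate(snp_meta["snp"])}
    med_cov = pd.concat(
        [cov_base.reset_index(drop=True),
         pd.Series(cohort.sex, name="sex").astype(float)], axis=1
    )
    mediations = {}
    for s in all_hits["snp"]:
        mediations[s] = fit_moderated_mediation(
            dosages[:, snp_col[s]], scores_df.reset_index(drop=True),
            cohort.diagnosis, covariates=med_cov, sex=cohort.sex,
            n_boot=cfg.n_boot, seed=cfg.seed, snp=s,
        )
    bundle["mediation"] = mediations

    if cfg.outdir is not None:
        write_report(bundle, cfg.outdir)
    return bundle


def _winsorized_log10(p: np.ndarray, floor: float = WINSOR_P) -> np.ndarray:
    return -np.log10(np.clip(np.asarray(p, dtype=float), floor, 1.0))


def write_report(bundle: dict, outdir) -> None:
    """Write plot-ready tables and summary files for a result bundle.

    Manhattan/QQ tables carry -log10 p winsorized at 1e-10.  Output is
    deterministic given the bundle (fixed column order, fixed float format).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg: RunConfig = bundle["config"]

    fmt = "%.6g"
    model = bundle.get("pc_model")
    if model is not None:
        tab = model.loading_table()
        tab.loc["variance_explained"] = model.variance_explained
        tab.to_csv(out / "loadings.tsv", sep="\t", float_format=fmt)
    if "sex_mean" in bundle:
        bundle["sex_mean"].to_csv(out / "sex_mean.tsv", sep="\t", index=False,
                                  float_format=fmt)
    if "qc_report" in bundle:
        bundle["qc_report"].to_csv(out / "qc_report.tsv", sep="\t", index=False)

    for (model_tag, pc), recs in sorted(bundle.get("gwas", {}).items()):
        df = recs.copy().sort_values(["chrom", "pos"]
                                     if "pos" in recs else ["snp"])
        df["neglog10p"] = _winsorized_log10(df["p"])
        m = len(df)
        df = df.sort_values("p")
        df["expected_neglog10p"] = -np.log10((np.arange(m) + 0.5) / m)
        df.to_csv(out / f"assoc_{model_tag}_{pc}.tsv", sep="\t", index=False,
                  float_format=fmt)

    if "lambda" in bundle and len(bundle["lambda"]):
        bundle["lambda"].to_csv(out / "lambda.tsv", sep="\t", index=False,
                                float_format=fmt)
    for pc, df in sorted(bundle.get("genes", {}).items()):
        df.to_csv(out / f"genes_{pc}.tsv", sep="\t", index=False,
                  float_format=fmt)
    if "hits" in bundle:
        bundle["hits"].to_csv(out / "independent_hits.tsv", sep="\t",
                              index=False, float_format=fmt)

    med_rows = []
    for s, m in sorted(bundle.get("mediation", {}).items()):
        est = m.estimate
        med_rows.append(
            {
                "snp": s,
                **{f"med_{name}": v for name, v in
                   zip(m.component_names, est.per_pc)},
                "joint": est.joint,
                "direct": est.direct,
                "total": est.total,
                "proportion": ("NA" if est.proportion is None
                               else round(est.proportion, 2)),
                "moderated": m.moderation_flag,
                "selected": m.selected,
            }
        )
    if med_rows:
        pd.DataFrame(med_rows).to_csv(out / "mediation.tsv", sep="\t",
                                      index=False, float_format=fmt)

    prov = {
        "package": "csfgwas",
        "version": __version__,
        "seed": cfg.seed,
        "models": list(cfg.models),
        "alphas": {"snp": cfg.snp_alpha, "suggestive": cfg.suggestive_alpha,
                   "mediation": cfg.mediation_alpha,
                   "sex_mean": cfg.sex_mean_alpha},
        "config_hash": hashlib.sha256(
            json.dumps({k: str(v) for k, v in vars(cfg).items()},
                       sort_keys=True).encode()
        ).hexdigest()[:16],
    }
    (out / "provenance.json").write_text(json.dumps(prov, indent=2) + "\n")
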
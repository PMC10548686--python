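"""Single-SNP association engine.

Ordinary least squares of a standardized component score on imputed allele
dosage (0-2), under four model tags:

* ``main``        -- dosage + sex + covariates, both sexes;
* ``male``/``female`` -- dosage + covariates within one sex stratum;
* ``interaction`` -- dosage + sex + dosage*sex + covariates, with the product
  term (the female-minus-male effect difference) as the reported coefficient.

Also provides variant QC (per-study MAF, imputation quality, Hardy-Weinberg),
genomic-inflation lambda, incremental variance explained, and greedy LD
clumping of genome-wide significant hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "hwe_test",
    "hwe_test_dosages",
    "qc_filter",
    "run_gwas",
    "genomic_lambda",
    "delta_r2",
    "ld_r2_matrix",
    "select_independent_hits",
]

GENOME_WIDE_ALPHA = 5e-8
SUGGESTIVE_ALPHA = 1e-6

_CHI2_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.4549...


@dataclass(frozen=True)
class QCThresholds:
    maf_min: float = 0.01
    imp_r2_min: float = 0.30  # strict >
    hwe_p_min: float = 5e-6  # exclude p below this

    def __post_init__(self) -> None:
        for name, v in (("maf_min", self.maf_min), ("imp_r2_min", self.imp_r2_min),
                        ("hwe_p_min", self.hwe_p_min)):
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square goodness-of-fit p-value against Hardy-Weinberg counts.

    Monomorphic variants return p = 1 by convention.
    """
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p <= 0.0 or p >= 1.0:
        return 1.0
    q = 1.0 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_test_dosages(dosages: np.ndarray) -> float:
    """HWE p-value from dosages hard-called by rounding to 0/1/2."""
    g = np.clip(np.rint(np.asarray(dosages, float)), 0, 2).astype(int)
    counts = np.bincount(g, minlength=3)
    return hwe_test(counts[2], counts[1], counts[0])


def qc_filter(
    dosages: np.ndarray,
    snp_meta: pd.DataFrame,
    study: np.ndarray | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Variant QC mask plus per-criterion exclusion counts.

    A SNP survives iff minor allele frequency >= ``maf_min`` in *every* study,
    imputation quality is strictly above ``imp_r2_min``, and the HWE
    goodness-of-fit p (computed per study on rounded hard calls) is not below
    ``hwe_p_min``.
    """
    n, m = dosages.shape
    study = np.zeros(n, dtype=int) if study is None else np.asarray(study)
    groups = [np.where(study == s)[0] for s in np.unique(study)]

    maf_ok = np.ones(m, dtype=bool)
    hwe_ok = np.ones(m, dtype=bool)
    for idx in groups:
        eaf = dosages[idx].mean(axis=0) / 2.0
        maf = np.minimum(eaf, 1.0 - eaf)
        maf_ok &= maf >= thresholds.maf_min
        hwe_p = np.array([hwe_test_dosages(dosages[idx, j]) for j in range(m)])
        hwe_ok &= hwe_p >= thresholds.hwe_p_min
    imp_ok = snp_meta["imp_quality"].to_numpy() > thresholds.imp_r2_min

    keep = maf_ok & imp_ok & hwe_ok
    report = pd.DataFrame(
        {
            "criterion": ["maf", "imp_quality", "hwe", "total_excluded", "retained"],
            "n_excluded": [
                int((~maf_ok).sum()),
                int((~imp_ok).sum()),
                int((~hwe_ok).sum()),
                int((~keep).sum()),
                int(keep.sum()),
            ],
        }
    )
    if not keep.any():
        log.warning("QC filter removed every variant")
    return keep, report


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int] | None:
    """Least squares with SEs; None if the design is rank-deficient."""
    n, p = X.shape
    if n <= p:
        return None
    xtx = X.T @ X
    # near-collinearity guard (monomorphic-in-stratum dosage etc.)
    if np.linalg.cond(xtx) > 1e12:
        return None
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.clip(np.diag(np.linalg.inv(xtx)) * sigma2, 0.0, None))
    return beta, se, df


def run_gwas(
    dosages: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    sex: np.ndarray | None = None,
    model: str = "main",
    snp_meta: pd.DataFrame | None = None,
    outcome_name: str = "PC",
    study_name: str = "study1",
) -> pd.DataFrame:
    """Per-SNP linear association records for one outcome and model tag.

    Failed fits (collinear designs, within-stratum monomorphism) are dropped
    from the output with a logged reason rather than emitted as NA rows.
    """
    dosages = np.asarray(dosages, dtype=float)
    if dosages.ndim == 1:
        dosages = dosages[:, None]
    y = np.asarray(outcome, dtype=float)
    n, m = dosages.shape
    cov = (
        np.empty((n, 0))
        if covariates is None
        else np.asarray(covariates, dtype=float).reshape(n, -1)
    )
    if model not in ("main", "male", "female", "interaction"):
        raise ValueError(f"unknown model tag {model!r}")
    if model != "main" and sex is None:
        raise ValueError(f"model {model!r} requires a sex vector")
    sex_arr = None if sex is None else np.asarray(sex, dtype=float)

    rows_sel = np.arange(n)
    if model == "male":
        rows_sel = np.where(sex_arr == 0)[0]
    elif model == "female":
        rows_sel = np.where(sex_arr == 1)[0]

    ys = y[rows_sel]
    covs = cov[rows_sel]
    ones = np.ones((len(rows_sel), 1))
    records = []
    n_failed = 0
    for j in range(m):
        g = dosages[rows_sel, j]
        if model == "main":
            base = [ones, covs] + ([] if sex_arr is None else [sex_arr[rows_sel, None]])
            X = np.column_stack(base + [g[:, None]])
            report_idx = X.shape[1] - 1
        elif model in ("male", "female"):
            X = np.column_stack([ones, covs, g[:, None]])
            report_idx = X.shape[1] - 1
        else:  # interaction
            s = sex_arr[rows_sel]
            X = np.column_stack([ones, covs, s[:, None], g[:, None], (g * s)[:, None]])
            report_idx = X.shape[1] - 1
        fit = _ols(X, ys)
        if fit is None:
            n_failed += 1
            continue
        beta, se, df = fit
        b, s_e = float(beta[report_idx]), float(se[report_idx])
        if s_e <= 0:
            n_failed += 1
            continue
        p = float(2 * stats.t.sf(abs(b) / s_e, df))
        rec = {
            "snp": snp_meta["snp"].iloc[j] if snp_meta is not None else f"snp{j + 1}",
            "beta": b,
            "se": s_e,
            "p": max(p, np.finfo(float).tiny),
            "n": len(rows_sel),
            "eaf": float(g.mean() / 2.0),
            "model": model,
            "outcome": outcome_name,
            "study": study_name,
        }
        if snp_meta is not None:
            for c in ("chrom", "pos", "effect_allele", "other_allele", "imp_quality"):
                if c in snp_meta:
                    rec[c] = snp_meta[c].iloc[j]
        records.append(rec)
    if n_failed:
        log.warning("%d/%d SNP fits failed to converge (dropped)", n_failed, m)
    return pd.DataFrame(records)


def genomic_lambda(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median association chi-square over 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 100:
        log.warning("genomic lambda computed on only %d records", len(p))
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_MEDIAN)


def delta_r2(
    dosage: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> float:
    """Incremental R^2 of a SNP (or a dosage block) over covariates alone."""
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    G = np.asarray(dosage, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    cov = (
        np.empty((n, 0))
        if covariates is None
        else np.asarray(covariates, dtype=float).reshape(n, -1)
    )
    ones = np.ones((n, 1))

    def r2(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        tss = float(((y - y.mean()) ** 2).sum())
        return 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0

    full = r2(np.column_stack([ones, cov, G]))
    base = r2(np.column_stack([ones, cov]))
    return float(np.clip(full - base, 0.0, 1.0))


def ld_r2_matrix(dosages: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation of dosage columns."""
    r = np.corrcoef(np.asarray(dosages, float), rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    return r**2


def select_independent_hits(
    records: pd.DataFrame,
    ld_r2: pd.DataFrame | np.ndarray,
    snp_ids: list[str] | None = None,
    r2_max: float = 0.6,
    p_max: float = GENOME_WIDE_ALPHA,
) -> pd.DataFrame:
    """Greedy LD clumping of significant records by ascending p-value.

    A significant SNP is accepted iff its LD r^2 with every already-accepted
    SNP is <= ``r2_max``.  Missing LD entries count as r^2 = 0 with a warning.
    """
    sig = records[records["p"] < p_max].sort_values("p")
    if isinstance(ld_r2, pd.DataFrame):
        ld = ld_r2
    else:
        ids = snp_ids if snp_ids is not None else list(records["snp"])
        ld = pd.DataFrame(np.asarray(ld_r2), index=ids, columns=ids)
    accepted: list[str] = []
    keep_idx = []
    for idx, row in sig.iterrows():
        s = row["snp"]
        ok = True
        for a in accepted:
            if s in ld.index and a in ld.columns:
                r2 = float(ld.loc[s, a])
            else:
                log.warning("missing LD entry for (%s, %s); assuming r2 = 0", s, a)
                r2 = 0.0
            if r2 > r2_max:
                ok = False
                break
        if ok:
            accepted.append(s)
            keep_idx.append(idx)
    return sig.loc[keep_idx]
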
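"""Gene-level aggregation of SNP associations.

The gene statistic is the SNP-wise mean of per-SNP 1-df chi-squares.  Under
the null, the *sum* of the chi-squares is distributed as a weighted sum of
independent chi-square(1) variables whose weights are the eigenvalues of the
local LD correlation matrix; the tail probability is obtained by Imhof-style
numerical inversion of the characteristic function, with a moment-matched
gamma approximation as fallback for extreme tails.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

log = logging.getLogger(__name__)

__all__ = [
    "GeneResult",
    "annotate_snps_to_genes",
    "gene_test",
    "gene_bonferroni",
    "weighted_chi2_sf",
]


@dataclass(frozen=True)
class GeneResult:
    gene: str
    chrom: str
    start: int
    end: int
    n_snps: int
    z: float
    p: float
    snp_ids: tuple[str, ...] = field(default_factory=tuple)
    stat_mean_chi2: float = float("nan")


def annotate_snps_to_genes(
    snp_meta: pd.DataFrame, gene_intervals: pd.DataFrame, window: int = 0
) -> dict[str, list[str]]:
    """Positional SNP-to-gene map with 1-based inclusive gene intervals.

    A SNP is assigned to every gene whose [start - window, end + window]
    contains its position on the same chromosome; genes with no SNPs are
    omitted from the returned mapping.
    """
    for _, row in gene_intervals.iterrows():
        if row["start"] > row["end"]:
            raise ValueError(
                f"malformed interval for gene {row['gene']!r}: "
                f"start {row['start']} > end {row['end']}"
            )
    mapping: dict[str, list[str]] = {}
    by_chrom = {
        str(c): grp for c, grp in snp_meta.groupby(snp_meta["chrom"].astype(str))
    }
    for _, row in gene_intervals.iterrows():
        grp = by_chrom.get(str(row["chrom"]))
        if grp is None:
            continue
        lo, hi = row["start"] - window, row["end"] + window
        hit = grp[(grp["pos"] >= lo) & (grp["pos"] <= hi)]
        if len(hit):
            mapping[row["gene"]] = list(hit["snp"])
    return mapping


def _gamma_sf(q: float, w: np.ndarray) -> float:
    """Moment-matched gamma tail for a weighted chi-square sum."""
    mu = w.sum()
    var = 2.0 * (w**2).sum()
    if var <= 0:
        return 1.0 if q <= mu else 0.0
    scale = var / mu
    shape = mu / scale
    return float(stats.gamma.sf(q, a=shape, scale=scale))


def weighted_chi2_sf(q: float, weights: np.ndarray, tol: float = 1e-9) -> float:
    """P(sum_i w_i X_i > q) for independent chi-square(1) X_i (Imhof method).

    Falls back to a moment-matched gamma approximation when the numerical
    inversion is unreliable (extreme tails or integration failure).
    """
    w = np.asarray(weights, dtype=float)
    w = w[w > 1e-12]
    if len(w) == 0:
        return 1.0
    if q <= 0:
        return 1.0

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(w * u)) - 0.5 * q * u
        rho = np.prod((1.0 + (w * u) ** 2) ** 0.25)
        return float(np.sin(theta) / (u * rho))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, err = integrate.quad(integrand, 0.0, np.inf, limit=400, epsabs=tol)
        p = 0.5 + val / np.pi
    except Exception:  # pragma: no cover - quad failure is rare
        return _gamma_sf(q, w)
    if not np.isfinite(p) or p < 1e-10 or p > 1.0 or err > 1e-6:
        return _gamma_sf(q, w)
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def _nearest_psd_eigvals(ld: np.ndarray) -> np.ndarray:
    evals = np.linalg.eigvalsh(np.asarray(ld, dtype=float))
    if evals.min() < -1e-8:
        log.warning(
            "LD matrix not positive semi-definite (min eigenvalue %.3g); "
            "projecting to nearest PSD",
            evals.min(),
        )
    return np.clip(evals, 0.0, None)


def gene_test(
    p_values: np.ndarray | None,
    ld_corr: np.ndarray,
    z_scores: np.ndarray | None = None,
    gene: str = "gene",
    chrom: str = "0",
    start: int = 0,
    end: int = 0,
    snp_ids: tuple[str, ...] = (),
) -> GeneResult:
    """SNP-wise mean gene association test.

    Accepts either two-sided per-SNP p-values or signed z-scores (squared to
    1-df chi-squares).  The gene p-value is the tail probability of the
    observed chi-square sum under the eigenvalue-weighted null implied by the
    LD correlation matrix; Z = Phi^-1(1 - p).
    """
    if z_scores is not None:
        chi2 = np.asarray(z_scores, dtype=float) ** 2
    elif p_values is not None:
        chi2 = stats.chi2.isf(np.asarray(p_values, dtype=float), df=1)
    else:
        raise ValueError("provide p_values or z_scores")
    m = len(chi2)
    if m == 0:
        raise ValueError("gene test requires at least one SNP")
    ld = np.atleast_2d(np.asarray(ld_corr, dtype=float))
    if ld.shape != (m, m):
        raise ValueError(f"LD matrix shape {ld.shape} does not match {m} SNPs")

    total = float(chi2.sum())
    if m == 1:
        p = float(stats.chi2.sf(total, df=1))
    else:
        weights = _nearest_psd_eigvals(ld)
        p = weighted_chi2_sf(total, weights)
    z = float(stats.norm.isf(p))
    return GeneResult(
        gene=gene,
        chrom=str(chrom),
        start=int(start),
        end=int(end),
        n_snps=m,
        z=z,
        p=p,
        snp_ids=tuple(snp_ids),
        stat_mean_chi2=total / m,
    )


def gene_bonferroni(n_genes: int, alpha: float = 0.05) -> float:
    """Bonferroni gene-wise significance threshold alpha / n_genes."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return alpha / n_genes


def run_gene_tests(
    records: pd.DataFrame,
    dosages: np.ndarray,
    snp_meta: pd.DataFrame,
    gene_intervals: pd.DataFrame,
    window: int = 0,
) -> pd.DataFrame:
    """Gene tests for every annotated gene, with in-sample LD from dosages."""
    mapping = annotate_snps_to_genes(snp_meta, gene_intervals, window=window)
    rec = records.set_index("snp")
    col_of = {s: j for j, s in enumerate(snp_meta["snp"])}
    rows = []
    for _, grow in gene_intervals.iterrows():
        gname = grow["gene"]
        snps = [s for s in mapping.get(gname, []) if s in rec.index]
        if not snps:
            continue
        cols = [col_of[s] for s in snps]
        sub = dosages[:, cols]
        ld = np.corrcoef(sub, rowvar=False) if len(cols) > 1 else np.ones((1, 1))
        ld = np.nan_to_num(np.atleast_2d(ld), nan=0.0)
        np.fill_diagonal(ld, 1.0)
        res = gene_test(
            rec.loc[snps, "p"].to_numpy(),
            ld,
            gene=gname,
            chrom=grow["chrom"],
            start=grow["start"],
            end=grow["end"],
            snp_ids=tuple(snps),
        )
        rows.append(
            {
                "gene": res.gene,
                "chrom": res.chrom,
                "start": res.start,
                "end": res.end,
                "n_snps": res.n_snps,
                "z": res.z,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
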
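"""Cross-study meta-analysis of per-SNP association records.

Inverse-variance-weighted fixed-effect combination is the primary method;
DerSimonian-Laird random effects is available for sensitivity comparisons.
Records from different studies are first harmonized to a common effect allele
(sign flip + frequency complement), with strand-ambiguous A/T and C/G variants
of intermediate frequency dropped because their orientation is undecidable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "MetaResult",
    "harmonize_alleles",
    "fixed_effect_meta",
    "random_effects_meta",
    "meta_analyze",
    "write_metal",
    "read_metal",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class MetaResult:
    beta: float
    se: float
    p: float
    q_stat: float
    tau2: float
    method: str
    n_studies: int
    n_total: int


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize_alleles(
    record_a: dict | pd.Series, record_b: dict | pd.Series
) -> tuple[dict, dict] | None:
    """Align two per-study records of the same variant to one effect allele.

    If the effect/other alleles are swapped, the second record's beta sign is
    flipped and its frequency complemented.  Strand-ambiguous variants (A/T,
    C/G) with frequency in (0.4, 0.6) are dropped (returns None), as are
    variants with incompatible allele sets.
    """
    a, b = dict(record_a), dict(record_b)
    ea_a, oa_a = str(a["effect_allele"]).upper(), str(a["other_allele"]).upper()
    ea_b, oa_b = str(b["effect_allele"]).upper(), str(b["other_allele"]).upper()

    if _is_ambiguous(ea_a, oa_a):
        eafs = [a.get("eaf"), b.get("eaf")]
        if any(e is not None and 0.4 < float(e) < 0.6 for e in eafs):
            log.warning("dropping strand-ambiguous variant %s with eaf near 0.5",
                        a.get("snp", "?"))
            return None

    if (ea_a, oa_a) == (ea_b, oa_b):
        return a, b
    if (ea_a, oa_a) == (oa_b, ea_b):
        b["beta"] = -float(b["beta"])
        b["effect_allele"], b["other_allele"] = ea_a, oa_a
        if b.get("eaf") is not None:
            b["eaf"] = 1.0 - float(b["eaf"])
        return a, b
    # try the complementary strand
    comp = ( _COMPLEMENT.get(ea_b, "?"), _COMPLEMENT.get(oa_b, "?"))
    if (ea_a, oa_a) == comp:
        b["effect_allele"], b["other_allele"] = ea_a, oa_a
        return a, b
    if (ea_a, oa_a) == (comp[1], comp[0]):
        b["beta"] = -float(b["beta"])
        b["effect_allele"], b["other_allele"] = ea_a, oa_a
        if b.get("eaf") is not None:
            b["eaf"] = 1.0 - float(b["eaf"])
        return a, b
    log.warning("incompatible allele sets for %s: %s/%s vs %s/%s",
                a.get("snp", "?"), ea_a, oa_a, ea_b, oa_b)
    return None


def fixed_effect_meta(
    betas: np.ndarray, ses: np.ndarray, ns: np.ndarray | None = None
) -> MetaResult:
    """Inverse-variance-weighted fixed-effect combination."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if len(b) < 1:
        raise ValueError("need at least one study")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    beta = float((w * b).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    p = float(2 * stats.norm.sf(abs(beta) / se))
    q = float((w * (b - beta) ** 2).sum())
    n_total = int(np.sum(ns)) if ns is not None else 0
    return MetaResult(beta, se, max(p, np.finfo(float).tiny), q, 0.0,
                      "fixed", len(b), n_total)


def random_effects_meta(
    betas: np.ndarray, ses: np.ndarray, ns: np.ndarray | None = None
) -> MetaResult:
    """DerSimonian-Laird random-effects combination.

    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)) with fixed-effect
    weights w = 1/SE^2; falls back to the fixed-effect result (with a warning)
    when fewer than two studies are available.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if len(b) < 2:
        log.warning("random-effects meta with <2 studies; falling back to fixed")
        return fixed_effect_meta(b, s, ns)
    fixed = fixed_effect_meta(b, s, ns)
    w = 1.0 / s**2
    df = len(b) - 1
    c = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (fixed.q_stat - df) / c) if c > 0 else 0.0
    w_star = 1.0 / (s**2 + tau2)
    beta = float((w_star * b).sum() / w_star.sum())
    se = float(1.0 / np.sqrt(w_star.sum()))
    p = float(2 * stats.norm.sf(abs(beta) / se))
    return MetaResult(beta, se, max(p, np.finfo(float).tiny), fixed.q_stat,
                      tau2, "random", len(b), fixed.n_total)


def meta_analyze(
    study_records: list[pd.DataFrame], method: str = "fixed"
) -> pd.DataFrame:
    """Harmonize and combine per-study association tables SNP by SNP."""
    combiner = fixed_effect_meta if method == "fixed" else random_effects_meta
    frames = [df.set_index("snp") for df in study_records]
    common = frames[0].index
    for f in frames[1:]:
        common = common.intersection(f.index)
    rows = []
    for snp in common:
        recs = [f.loc[snp].to_dict() | {"snp": snp} for f in frames]
        ref = recs[0]
        aligned = [ref]
        ok = True
        for r in recs[1:]:
            pair = harmonize_alleles(ref, r)
            if pair is None:
                ok = False
                break
            aligned.append(pair[1])
        if not ok:
            continue
        res = combiner(
            np.array([r["beta"] for r in aligned]),
            np.array([r["se"] for r in aligned]),
            np.array([r.get("n", 0) for r in aligned]),
        )
        rows.append(
            {
                "snp": snp,
                "chrom": ref.get("chrom"),
                "pos": ref.get("pos"),
                "effect_allele": ref.get("effect_allele"),
                "other_allele": ref.get("other_allele"),
                "eaf": float(np.mean([r.get("eaf", np.nan) for r in aligned])),
                "beta": res.beta,
                "se": res.se,
                "p": res.p,
                "q_stat": res.q_stat,
                "tau2": res.tau2,
                "n": res.n_total,
                "n_studies": res.n_studies,
                "model": ref.get("model"),
                "outcome": ref.get("outcome"),
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)


_METAL_COLS = {
    "snp": "MarkerName",
    "effect_allele": "Allele1",
    "other_allele": "Allele2",
    "eaf": "Freq1",
    "beta": "Effect",
    "se": "StdErr",
    "p": "P-value",
    "n": "N",
}


def write_metal(df: pd.DataFrame, path) -> None:
    """Write association records as a METAL-style tab-delimited table."""
    out = df.rename(columns=_METAL_COLS)
    cols = list(_METAL_COLS.values()) + [
        c for c in ("model", "outcome") if c in out.columns
    ]
    out[[c for c in cols if c in out.columns]].to_csv(path, sep="\t", index=False)


def read_metal(path) -> pd.DataFrame:
    """Read a METAL-style summary-statistics table back into record form."""
    df = pd.read_csv(path, sep=r"\s+")
    inv = {v: k for k, v in _METAL_COLS.items()}
    return df.rename(columns=inv)
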
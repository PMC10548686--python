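"""Synthetic two-study cohort generator.

Emulates the statistical structure of a multi-center CSF-biomarker genetics
study: Hardy-Weinberg genotype dosages (with hemizygous X coding), six CSF
analytes generated from a five-component factor structure, sex mean-shifts on
selected components, planted per-allele SNP effects (main and female-specific),
and an ordinal control/MCI/AD diagnosis produced by thresholding a latent
disease index.

Every cohort carries its generating configuration (``CohortData.truth``) so
downstream estimators can be validated against known parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MARKER_NAMES",
    "COMPONENT_NAMES",
    "DEFAULT_LOADINGS",
    "default_uniqueness",
    "SnpEffect",
    "SimConfig",
    "CohortData",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_diagnosis",
    "simulate_cohort",
    "make_gene_annotation",
]

MARKER_NAMES = ("tau", "ptau", "abeta", "nfl", "ykl40", "ng")

COMPONENT_NAMES = (
    "PC1 tau pathology/degeneration",
    "PC2 abeta pathology",
    "PC3 injury/inflammation",
    "PC4 non-AD inflammation",
    "PC5 non-AD synaptic functioning",
)

# Varimax-rotated structure loadings of the six analytes on the five
# components (rows: tau, pTau, Abeta42, NfL, YKL-40, neurogranin).  This is
# the canonical all-sample factor structure the generator reproduces.
DEFAULT_LOADINGS = np.array(
    [
        [0.87, -0.06, 0.23, 0.24, 0.27],
        [0.91, -0.08, 0.14, 0.20, 0.26],
        [-0.07, 1.00, -0.03, 0.00, 0.04],
        [0.21, -0.03, 0.94, 0.25, 0.08],
        [0.32, 0.00, 0.32, 0.88, 0.17],
        [0.51, 0.07, 0.10, 0.18, 0.83],
    ]
)

# Female-minus-male component mean differences (SD units): injury/inflammation
# is lower in females, non-AD synaptic functioning higher.
DEFAULT_SEX_SHIFTS = np.array([0.0, 0.0, -0.40, 0.0, 0.21])

# Standardized effects of the components on the latent AD index (male-scale
# estimates; PC4/PC5 show no association with diagnosis).
DEFAULT_DIAG_COEFFS = np.array([0.41, -0.34, 0.40, 0.0, 0.0])

DEFAULT_DIAG_THRESHOLDS = (-1.47, 0.40)

DIAGNOSIS_LABELS = ("control", "MCI", "AD")

_STUDY_AGE_MEANS = (69.0, 75.0)  # per-study mean age at ascertainment
_FEMALE_FRACTION = 557 / 1158

_NONAMBIGUOUS_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))


def default_uniqueness(loadings: np.ndarray | None = None, floor: float = 0.02) -> np.ndarray:
    """Residual marker variances implied by a loading matrix (1 - communality).

    Rounded published loadings can imply communalities slightly above one;
    those are floored at ``floor`` so every marker keeps a positive noise term.
    """
    if loadings is None:
        loadings = DEFAULT_LOADINGS
    comm = (np.asarray(loadings) ** 2).sum(axis=1)
    return np.clip(1.0 - comm, floor, None)


@dataclass(frozen=True)
class SnpEffect:
    """A planted per-allele effect of one SNP on one component (SD units).

    ``beta_female`` is an additional female-only effect: the female per-allele
    effect is ``beta + beta_female``.
    """

    snp: int
    component: int
    beta: float
    beta_female: float = 0.0


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    n_samples: int = 973
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    x_fraction: float = 0.0
    loading_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_LOADINGS.copy())
    uniqueness: np.ndarray = field(default_factory=default_uniqueness)
    snp_effects: tuple[SnpEffect, ...] = ()
    sex_shifts: np.ndarray = field(default_factory=lambda: DEFAULT_SEX_SHIFTS.copy())
    diag_coeffs: np.ndarray = field(default_factory=lambda: DEFAULT_DIAG_COEFFS.copy())
    diag_thresholds: tuple[float, float] = DEFAULT_DIAG_THRESHOLDS
    missing_rate: float = 0.10
    n_studies: int = 2
    distortion: str = "exp"  # marginal skewing undone by the INT stage
    unit_variance: bool = True  # rescale component noise so planted effects keep SD-1 scale
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError(f"maf_range must lie within (0, 1), got {self.maf_range}")
        self.loading_matrix = np.asarray(self.loading_matrix, dtype=float)
        if self.loading_matrix.shape != (6, 5):
            raise ConfigError(
                f"loading_matrix must be 6x5 (marker x component), got {self.loading_matrix.shape}"
            )
        self.uniqueness = np.asarray(self.uniqueness, dtype=float)
        if self.uniqueness.shape != (6,) or np.any(self.uniqueness < 0):
            raise ConfigError("uniqueness must be a non-negative 6-vector")
        self.sex_shifts = np.asarray(self.sex_shifts, dtype=float)
        if self.sex_shifts.shape != (5,):
            raise ConfigError("sex_shifts must be a 5-vector")
        self.diag_coeffs = np.asarray(self.diag_coeffs, dtype=float)
        if self.diag_coeffs.shape != (5,):
            raise ConfigError("diag_coeffs must be a 5-vector")
        if not self.diag_thresholds[0] < self.diag_thresholds[1]:
            raise ConfigError("diag_thresholds must be strictly increasing")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        self.snp_effects = tuple(
            e if isinstance(e, SnpEffect) else SnpEffect(*e) for e in self.snp_effects
        )
        for e in self.snp_effects:
            if not (0 <= e.snp < self.n_snps):
                raise ConfigError(f"snp_effect references SNP {e.snp} outside 0..{self.n_snps - 1}")
            if not (0 <= e.component < 5):
                raise ConfigError(f"snp_effect references component {e.component} outside 0..4")

    def to_flat_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["loading_matrix"] = self.loading_matrix.tolist()
        d["uniqueness"] = self.uniqueness.tolist()
        d["sex_shifts"] = self.sex_shifts.tolist()
        d["diag_coeffs"] = self.diag_coeffs.tolist()
        d["snp_effects"] = [dataclasses.asdict(e) for e in self.snp_effects]
        return d


@dataclass
class CohortData:
    """A simulated cohort: genotypes, covariates, diagnosis, biomarkers, truth."""

    sample_ids: np.ndarray
    dosages: np.ndarray  # n x m in [0, 2]
    snp_meta: pd.DataFrame  # snp, chrom, pos, effect_allele, other_allele, maf, eaf, imp_quality
    sex: np.ndarray  # female = 1, male = 0
    age: np.ndarray
    ancestry: np.ndarray  # n x 5
    study: np.ndarray  # study labels
    diagnosis: np.ndarray  # codes 0 = control, 1 = MCI, 2 = AD
    biomarkers: pd.DataFrame  # n x 6 raw analyte levels with NaN for missing
    pc_scores_true: np.ndarray | None = None  # observed-scale component scores
    truth: SimConfig | None = None

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def covariates(self, ancestry: bool = True, age: bool = True) -> pd.DataFrame:
        cols = {}
        if age:
            cols["age"] = self.age
        if ancestry:
            for j in range(self.ancestry.shape[1]):
                cols[f"ancestry{j + 1}"] = self.ancestry[:, j]
        df = pd.DataFrame(cols, index=self.sample_ids)
        for s in np.unique(self.study)[1:]:
            df[f"study_{s}"] = (self.study == s).astype(float)
        return df


def _spawn(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key]))


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    x_fraction: float = 0.0,
    seed: int = 0,
    sex: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw HWE genotype dosages and per-SNP metadata.

    Autosomal dosages are Binomial(2, p); X-chromosome male dosages are
    2 * Bernoulli(p) so hemizygous males carry 0 or 2 copies, matching the
    coding used for X-linked association tests.  ``sex`` (female = 1) is
    required whenever ``x_fraction > 0``.
    """
    if n < 1 or m < 1:
        raise ConfigError("n and m must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi < 1.0):
        raise ConfigError(f"maf_range must lie within (0, 1), got {maf_range}")
    if x_fraction > 0 and sex is None:
        raise ConfigError("sex must be provided when x_fraction > 0")

    rng = _spawn(seed, 1)
    mafs = rng.uniform(lo, hi, size=m)
    n_x = int(round(x_fraction * m))
    is_x = np.zeros(m, dtype=bool)
    if n_x:
        is_x[m - n_x:] = True

    dos = rng.binomial(2, mafs[None, :], size=(n, m)).astype(float)
    if n_x:
        male = np.asarray(sex) == 0
        if male.any():
            x_idx = np.where(is_x)[0]
            dos[np.ix_(male, x_idx)] = 2.0 * rng.binomial(
                1, mafs[x_idx][None, :], size=(int(male.sum()), len(x_idx))
            )

    n_auto = m - n_x
    chrom = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=int)
    if n_auto:
        auto_chrom = 1 + (np.arange(n_auto) * 22) // max(n_auto, 1)
        auto_chrom = np.minimum(auto_chrom, 22)
        chrom[:n_auto] = [str(c) for c in auto_chrom]
        # 1-based positions, restarting per chromosome
        pos[:n_auto] = [
            10_000 * (i - np.searchsorted(auto_chrom, auto_chrom[i])) + 10_001
            for i in range(n_auto)
        ]
    if n_x:
        chrom[n_auto:] = "X"
        pos[n_auto:] = 10_000 * np.arange(n_x) + 10_001

    pair_idx = rng.integers(0, len(_NONAMBIGUOUS_PAIRS), size=m)
    other = np.array([_NONAMBIGUOUS_PAIRS[i][0] for i in pair_idx])
    effect = np.array([_NONAMBIGUOUS_PAIRS[i][1] for i in pair_idx])

    meta = pd.DataFrame(
        {
            "snp": [f"snp{i + 1}" for i in range(m)],
            "chrom": chrom,
            "pos": pos,
            "effect_allele": effect,
            "other_allele": other,
            "maf": mafs,
            "eaf": dos.mean(axis=0) / 2.0,
            "imp_quality": rng.uniform(0.3, 1.0, size=m),
        }
    )
    return dos, meta


def _distort(x: np.ndarray, kind: str) -> np.ndarray:
    """Strictly monotone marginal distortion; undone by rank-based INT."""
    if kind == "exp":
        return np.exp(x / 2.0)
    if kind == "none":
        return x
    raise ConfigError(f"unknown distortion {kind!r}")


def simulate_diagnosis(
    pc_scores: np.ndarray,
    diag_coeffs: np.ndarray,
    diag_thresholds: Sequence[float] = DEFAULT_DIAG_THRESHOLDS,
    covariate_effects: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Ordinal diagnosis (0 control / 1 MCI / 2 AD) from a latent disease index.

    The latent index is the linear combination of component scores (plus any
    covariate contribution) with a normal residual scaled so the index has
    unit variance; categories are cut at the two thresholds on that SD scale.
    """
    t1, t2 = diag_thresholds
    if not t1 < t2:
        raise ConfigError("diag_thresholds must be strictly increasing")
    pc_scores = np.asarray(pc_scores, dtype=float)
    lin = pc_scores @ np.asarray(diag_coeffs, dtype=float)
    if covariate_effects is not None:
        lin = lin + np.asarray(covariate_effects, dtype=float)
    var_lin = float(np.var(lin)) if len(lin) > 1 else 0.0
    resid_sd = np.sqrt(max(1.0 - var_lin, 1e-4))
    rng = _spawn(seed, 3)
    latent = lin - lin.mean() + resid_sd * rng.standard_normal(len(lin))
    return np.digitize(latent, [t1, t2]).astype(int)


def simulate_phenotypes(
    dosages: np.ndarray,
    snp_meta: pd.DataFrame,
    config: SimConfig,
    sex: np.ndarray | None = None,
) -> CohortData:
    """Generate component scores, biomarkers, covariates, and diagnosis.

    Component scores are standard normal, shifted by planted SNP effects
    (female-only parts applied only when sex = 1) and by the female-male
    mean shifts.  Biomarkers are the loading combination of the scores plus
    marker-specific noise, a per-study assay intercept, and a monotone
    marginal distortion; cells are then set missing completely at random.

    Diagnosis is driven by the scores *before* the sex mean-shifts are added:
    planted SNP effects propagate to the ordinal outcome (so mediation paths
    exist) while the sex shifts stay marginal mean differences, making the
    covariate-adjusted sex contrast estimable without distortion.
    """
    n, m = dosages.shape
    cfg = config
    rng = _spawn(cfg.seed, 2)

    if sex is None:
        sex = (rng.random(n) < _FEMALE_FRACTION).astype(int)
    sex = np.asarray(sex, dtype=int)

    study_sizes = np.full(cfg.n_studies, n // cfg.n_studies)
    study_sizes[: n % cfg.n_studies] += 1
    study = np.repeat([f"study{k + 1}" for k in range(cfg.n_studies)], study_sizes)
    age_means = np.array([_STUDY_AGE_MEANS[k % 2] for k in range(cfg.n_studies)])
    age = np.repeat(age_means, study_sizes) + 7.0 * rng.standard_normal(n)
    ancestry = rng.standard_normal((n, 5))

    base = rng.standard_normal((n, 5))
    # keep total component variance at ~1 when effects are planted
    if cfg.unit_variance and cfg.snp_effects:
        extra = np.zeros(5)
        for e in cfg.snp_effects:
            p = float(snp_meta["eaf"].iloc[e.snp]) if "eaf" in snp_meta else dosages[:, e.snp].mean() / 2
            extra[e.component] += 2.0 * p * (1.0 - p) * e.beta**2
        base *= np.sqrt(np.clip(1.0 - extra, 0.05, None))[None, :]

    disease_scores = base.copy()
    for e in cfg.snp_effects:
        g = dosages[:, e.snp]
        disease_scores[:, e.component] += e.beta * g + e.beta_female * g * sex

    diagnosis = simulate_diagnosis(
        disease_scores, cfg.diag_coeffs, cfg.diag_thresholds, seed=cfg.seed
    )

    scores = disease_scores + sex[:, None] * cfg.sex_shifts[None, :]

    noise = rng.standard_normal((n, 6)) * np.sqrt(cfg.uniqueness)[None, :]
    latent_markers = scores @ cfg.loading_matrix.T + noise

    study_codes = np.searchsorted(np.unique(study), study)
    intercepts = rng.normal(0.0, 0.5, size=(cfg.n_studies, 6))
    raw = _distort(latent_markers + intercepts[study_codes], cfg.distortion)

    if cfg.missing_rate > 0:
        miss = rng.random((n, 6)) < cfg.missing_rate
        # keep at least 4 of the 6 analytes observed per participant
        excess = miss.sum(axis=1) > 2
        for i in np.where(excess)[0]:
            idx = np.where(miss[i])[0]
            miss[i, idx[2:]] = False
        raw = np.where(miss, np.nan, raw)

    sample_ids = np.array([f"S{i + 1:05d}" for i in range(n)])
    biomarkers = pd.DataFrame(raw, columns=list(MARKER_NAMES), index=sample_ids)

    return CohortData(
        sample_ids=sample_ids,
        dosages=dosages,
        snp_meta=snp_meta,
        sex=sex,
        age=age,
        ancestry=ancestry,
        study=study,
        diagnosis=diagnosis,
        biomarkers=biomarkers,
        pc_scores_true=scores,
        truth=cfg,
    )


def simulate_cohort(config: SimConfig) -> CohortData:
    """Full cohort draw: genotypes then phenotypes, reproducible from config."""
    rng = _spawn(config.seed, 0)
    sex = (rng.random(config.n_samples) < _FEMALE_FRACTION).astype(int)
    dos, meta = simulate_genotypes(
        config.n_samples,
        config.n_snps,
        config.maf_range,
        x_fraction=config.x_fraction,
        seed=config.seed,
        sex=sex,
    )
    return simulate_phenotypes(dos, meta, config, sex=sex)


def make_gene_annotation(
    snp_meta: pd.DataFrame, snps_per_gene: int = 10
) -> pd.DataFrame:
    """Tile 1-based inclusive gene intervals over the simulated SNP map."""
    rows = []
    g = 0
    for chrom, grp in snp_meta.groupby("chrom", sort=False):
        pos = np.sort(grp["pos"].to_numpy())
        for start in range(0, len(pos), snps_per_gene):
            block = pos[start : start + snps_per_gene]
            g += 1
            rows.append(
                {
                    "gene": f"GENE{g:04d}",
                    "chrom": chrom,
                    "start": int(block[0]),
                    "end": int(block[-1]),
                }
            )
    return pd.DataFrame(rows)
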
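"""Mediation of SNP effects on a latent ordinal Alzheimer outcome.

The ordinal control/MCI/AD diagnosis is modeled as the categorization of a
continuous latent disease scale ("latent AD") at two probit thresholds.  A
single three-category indicator makes the item-factor-analysis formulation
equivalent to an ordinal probit regression: the latent response has unit
residual variance, and reported coefficients are re-standardized to the
latent-AD SD scale by dividing by sqrt(Var(linear predictor) + 1).

The mediation path model for one SNP:

* a-paths: OLS of each of the five biomarker components on allele dosage
  (plus covariates);
* b-paths and the direct path: joint ordinal probit of diagnosis on all five
  components plus dosage (plus covariates);
* mediation through component j = a_j * b_j on the latent-AD SD scale;
  joint mediation = sum over components; total = joint + direct; proportion
  mediated = joint / total, reported only when both share a sign.

Inference is by nonparametric bootstrap over individuals, because products of
linear and probit coefficients have skewed sampling distributions at realistic
effect sizes.  The probit likelihood is fitted with an analytic gradient so
thousands of warm-started bootstrap refits stay cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)

__all__ = [
    "LatentADModel",
    "Decomposition",
    "MediationResult",
    "ProbitFit",
    "fit_ordinal_probit",
    "fit_latent_ad",
    "decompose",
    "fit_mediation",
    "fit_moderated_mediation",
]

_CLIP = 1e-300


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# ordinal probit core
# ---------------------------------------------------------------------------


@dataclass
class ProbitFit:
    """Maximum-likelihood ordinal probit fit (latent-response formulation)."""

    beta: np.ndarray  # slopes, latent residual SD fixed to 1
    thresholds: np.ndarray  # K-1 increasing cutpoints
    cov: np.ndarray | None  # covariance of (beta, thresholds)
    loglik: float
    n: int
    theta: np.ndarray  # internal parametrization, for warm starts
    converged: bool = True

    @property
    def beta_se(self) -> np.ndarray:
        if self.cov is None:
            return np.full_like(self.beta, np.nan)
        return np.sqrt(np.clip(np.diag(self.cov)[: len(self.beta)], 0, None))


def _unpack(theta: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    beta = theta[:p]
    tau = np.concatenate([[theta[p]], theta[p] + np.cumsum(np.exp(theta[p + 1:]))])
    return beta, tau


def _make_objective(y: np.ndarray, X: np.ndarray, K: int):
    n, p = X.shape
    y = np.asarray(y, dtype=int)

    def negll_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        beta, tau = _unpack(theta, p)
        eta = X @ beta
        big = 1e30
        upper = np.concatenate([tau, [big]])[y] - eta
        lower = np.concatenate([[-big], tau])[y] - eta
        Pu, Pl = stats.norm.cdf(upper), stats.norm.cdf(lower)
        prob = np.clip(Pu - Pl, _CLIP, None)
        phi_u, phi_l = stats.norm.pdf(upper), stats.norm.pdf(lower)

        d_eta = (phi_u - phi_l) / prob  # d negll / d eta
        g_beta = X.T @ d_eta
        # d negll / d tau_k: -phi_u/prob where tau_k is the upper cut,
        # +phi_l/prob where it is the lower cut
        g_tau = np.zeros(K - 1)
        for k in range(K - 1):
            g_tau[k] = -(phi_u[y == k] / prob[y == k]).sum()
            g_tau[k] += (phi_l[y == k + 1] / prob[y == k + 1]).sum()
        # chain rule into (tau1, log-diffs)
        g_theta_tau = np.empty(K - 1)
        g_theta_tau[0] = g_tau.sum()
        for j in range(1, K - 1):
            g_theta_tau[j] = g_tau[j:].sum() * np.exp(theta[p + j])
        return float(-np.log(prob).sum()), np.concatenate([g_beta, g_theta_tau])

    return negll_grad


def _start_params(y: np.ndarray, p: int, K: int) -> np.ndarray:
    props = np.bincount(y, minlength=K) / len(y)
    props = np.clip(props, 1e-3, None)
    cum = np.cumsum(props)[:-1] / props.sum()
    tau0 = stats.norm.ppf(np.clip(cum, 1e-4, 1 - 1e-4))
    diffs = np.clip(np.diff(tau0), 1e-3, None)
    return np.concatenate([np.zeros(p), [tau0[0]], np.log(diffs)])


def fit_ordinal_probit(
    y: np.ndarray,
    X: np.ndarray,
    start: np.ndarray | None = None,
    with_cov: bool = True,
) -> ProbitFit:
    """Fit an ordinal probit by BFGS with analytic gradients.

    ``y`` holds category codes 0..K-1 (all categories present); ``X`` the
    predictor matrix without intercept (absorbed by the thresholds).
    """
    y = np.asarray(y, dtype=int)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n, p = X.shape
    cats = np.unique(y)
    K = len(cats)
    if K < 2:
        raise ConvergenceError("diagnosis must have at least 2 observed categories")
    recode = {c: i for i, c in enumerate(cats)}
    y = np.array([recode[c] for c in y])

    f = _make_objective(y, X, K)
    theta0 = start if start is not None else _start_params(y, p, K)
    res = optimize.minimize(f, theta0, jac=True, method="BFGS",
                            options={"gtol": 1e-6, "maxiter": 300})
    if not res.success and np.linalg.norm(res.jac) > 1e-2:
        raise ConvergenceError(
            f"ordinal probit failed to converge (gradient norm "
            f"{np.linalg.norm(res.jac):.3g})"
        )
    beta, tau = _unpack(res.x, p)

    cov = None
    if with_cov:
        # observed information via finite differences of the analytic gradient,
        # transformed from the internal parametrization to (beta, tau)
        m = len(res.x)
        H = np.zeros((m, m))
        eps = 1e-5
        for j in range(m):
            step = np.zeros(m)
            step[j] = eps
            gp = f(res.x + step)[1]
            gm = f(res.x - step)[1]
            H[:, j] = (gp - gm) / (2 * eps)
        H = 0.5 * (H + H.T)
        try:
            cov_theta = np.linalg.inv(H)
            J = np.zeros((m, m))
            J[:p, :p] = np.eye(p)
            for k in range(K - 1):
                J[p + k, p] = 1.0
                for j in range(1, k + 1):
                    J[p + k, p + j] = np.exp(res.x[p + j])
            cov = J @ cov_theta @ J.T
        except np.linalg.LinAlgError:
            cov = None
    return ProbitFit(beta=beta, thresholds=tau, cov=cov,
                     loglik=-res.fun, n=n, theta=res.x, converged=res.success)


# ---------------------------------------------------------------------------
# latent AD model
# ---------------------------------------------------------------------------


@dataclass
class LatentADModel:
    """Ordinal probit for diagnosis with coefficients on the latent-AD SD scale.

    ``coefficients`` are standardized (per SD of the predictor, per SD of
    latent AD); ``coef_per_unit`` keeps the per-raw-unit scale needed for
    mediation products.  Thresholds are reported on the standardized scale,
    where the latent-AD variance is fixed to 1.
    """

    thresholds: np.ndarray
    coefficients: pd.Series
    coef_per_unit: pd.Series
    covariate_coefficients: pd.Series
    denom: float  # sqrt(Var(linear predictor) + 1)
    se: pd.Series | None = None
    n: int = 0
    fit: ProbitFit | None = None


def fit_latent_ad(
    diagnosis: np.ndarray,
    predictors: pd.DataFrame | None = None,
    covariates: pd.DataFrame | None = None,
    with_cov: bool = True,
) -> LatentADModel:
    """Ordinal probit of diagnosis on predictors, standardized to latent SD.

    With no predictors or covariates the thresholds are simply the normal
    quantiles of the cumulative category proportions.
    """
    y = np.asarray(diagnosis)
    if len(np.unique(y)) < 2:
        raise ConvergenceError("diagnosis must have at least 2 observed categories")
    pred = pd.DataFrame(predictors) if predictors is not None else pd.DataFrame(index=range(len(y)))
    cov = pd.DataFrame(covariates) if covariates is not None else pd.DataFrame(index=range(len(y)))

    if pred.shape[1] == 0 and cov.shape[1] == 0:
        K = len(np.unique(y))
        props = np.bincount(pd.factorize(y, sort=True)[0], minlength=K) / len(y)
        tau = stats.norm.ppf(np.cumsum(props)[:-1])
        empty = pd.Series(dtype=float)
        return LatentADModel(tau, empty, empty, empty, 1.0, None, len(y), None)

    X = np.column_stack([pred.to_numpy(float), cov.to_numpy(float)]) \
        if cov.shape[1] else pred.to_numpy(float)
    if pred.shape[1] == 0:
        X = cov.to_numpy(float)
    names = list(pred.columns) + list(cov.columns)
    fit = fit_ordinal_probit(y, X, with_cov=with_cov)

    eta = X @ fit.beta
    denom = float(np.sqrt(np.var(eta) + 1.0))
    sds = X.std(axis=0, ddof=1)
    std_all = pd.Series(fit.beta * sds / denom, index=names)
    per_unit = pd.Series(fit.beta / denom, index=names)
    se_all = None
    if fit.cov is not None:
        se_all = pd.Series(fit.beta_se * sds / denom, index=names)
    np_pred = pred.shape[1]
    return LatentADModel(
        thresholds=fit.thresholds / denom,
        coefficients=std_all.iloc[:np_pred],
        coef_per_unit=per_unit.iloc[:np_pred],
        covariate_coefficients=std_all.iloc[np_pred:],
        denom=denom,
        se=None if se_all is None else se_all.iloc[:np_pred],
        n=fit.n,
        fit=fit,
    )


# ---------------------------------------------------------------------------
# effect decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class Decomposition:
    per_pc: np.ndarray  # mediation through each component
    joint: float  # sum of per-component mediation
    direct: float
    total: float  # joint + direct, exactly
    proportion: float | None  # joint / total when signs agree, else None

    def __eq__(self, other) -> bool:
        if not isinstance(other, Decomposition):
            return NotImplemented
        return (
            np.array_equal(self.per_pc, other.per_pc)
            and (self.joint, self.direct, self.total, self.proportion)
            == (other.joint, other.direct, other.total, other.proportion)
        )


def decompose(
    a_paths: np.ndarray,
    b_paths: np.ndarray | None = None,
    direct: float = 0.0,
) -> Decomposition:
    """Assemble the mediation decomposition (pure arithmetic).

    With ``b_paths`` given, per-component mediation is the elementwise product
    a_j * b_j; with ``b_paths=None`` the first argument is taken to already
    hold per-component mediation effects.  The proportion mediated is
    joint/total, defined only when joint and total share a sign (and total is
    nonzero); a zero joint effect gives proportion 0 when a direct effect
    exists.
    """
    a = np.asarray(a_paths, dtype=float)
    per_pc = a * np.asarray(b_paths, dtype=float) if b_paths is not None else a
    joint = float(per_pc.sum())
    total = joint + float(direct)
    if total == 0.0:
        proportion = None
    elif joint == 0.0:
        proportion = 0.0
    elif np.sign(joint) != np.sign(total):
        proportion = None
    else:
        proportion = joint / total
    return Decomposition(per_pc, joint, float(direct), total, proportion)


# ---------------------------------------------------------------------------
# mediation models
# ---------------------------------------------------------------------------


@dataclass
class MediationResult:
    snp: str
    a_paths: np.ndarray  # component change per effect allele
    b_paths: np.ndarray  # latent-AD change per component unit
    estimate: Decomposition
    se: dict = field(default_factory=dict)
    p: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)
    n_boot: int = 0
    n_boot_failed: int = 0
    sex_specific: dict | None = None  # {'male': Decomposition, 'female': ..., 'interaction_p': ...}
    moderation_flag: bool = False
    selected: str = "main"
    component_names: tuple[str, ...] = ()


def _design(g, cov_arr, extra_cols=()):
    n = len(g)
    cols = [np.ones(n), np.asarray(g, float)] + [np.asarray(c, float) for c in extra_cols]
    if cov_arr is not None and cov_arr.shape[1]:
        cols.append(cov_arr)
    return np.column_stack(cols)


def _point_estimates(
    g: np.ndarray,
    pcs: np.ndarray,
    y: np.ndarray,
    cov_arr: np.ndarray | None,
    probit_start: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """(a_paths, b_per_unit, direct, probit theta) for one mediation fit."""
    Xa = _design(g, cov_arr)
    coefs, *_ = np.linalg.lstsq(Xa, pcs, rcond=None)
    a = coefs[1]  # dosage row

    Xb = np.column_stack([pcs, np.asarray(g, float)[:, None]])
    if cov_arr is not None and cov_arr.shape[1]:
        Xb = np.column_stack([Xb, cov_arr])
    fit = fit_ordinal_probit(y, Xb, start=probit_start, with_cov=False)
    eta = Xb @ fit.beta
    denom = float(np.sqrt(np.var(eta) + 1.0))
    k = pcs.shape[1]
    b = fit.beta[:k] / denom
    direct = float(fit.beta[k] / denom)
    return a, b, direct, fit.theta


def fit_mediation(
    dosage: np.ndarray,
    pc_scores: pd.DataFrame | np.ndarray,
    diagnosis: np.ndarray,
    covariates: pd.DataFrame | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    snp: str = "snp",
) -> MediationResult:
    """Single-SNP mediation through the biomarker components.

    a-paths by OLS of each component on dosage (+ covariates); b-paths and the
    direct path from a joint ordinal probit of diagnosis on components and
    dosage (+ covariates), re-standardized to the latent-AD SD scale.
    Bootstrap (resampling individuals) provides SEs, normal-approximation
    p-values, and CIs for the products and sums.
    """
    g = np.asarray(dosage, dtype=float)
    pcs_df = pd.DataFrame(pc_scores)
    pcs = pcs_df.to_numpy(float)
    y = np.asarray(diagnosis)
    cov_arr = None if covariates is None else pd.DataFrame(covariates).to_numpy(float)

    a, b, direct, theta = _point_estimates(g, pcs, y, cov_arr)
    est = decompose(a, b, direct)

    rng = np.random.default_rng(seed)
    n = len(g)
    draws = {"per_pc": [], "joint": [], "direct": [], "total": []}
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if len(np.unique(y[idx])) < 2:
            failed += 1
            continue
        try:
            ab, bb, db, _ = _point_estimates(
                g[idx], pcs[idx], y[idx],
                None if cov_arr is None else cov_arr[idx],
                probit_start=theta,
            )
        except (ConvergenceError, np.linalg.LinAlgError):
            failed += 1
            continue
        d = decompose(ab, bb, db)
        draws["per_pc"].append(d.per_pc)
        draws["joint"].append(d.joint)
        draws["direct"].append(d.direct)
        draws["total"].append(d.total)

    se: dict = {}
    pvals: dict = {}
    ci: dict = {}
    if draws["joint"]:
        per = np.asarray(draws["per_pc"])
        se["per_pc"] = per.std(axis=0, ddof=1)
        for key in ("joint", "direct", "total"):
            se[key] = float(np.std(draws[key], ddof=1))
        point = {"per_pc": est.per_pc, "joint": est.joint,
                 "direct": est.direct, "total": est.total}
        for key, s in se.items():
            v = np.asarray(point[key], dtype=float)
            s_arr = np.asarray(s, dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(s_arr > 0, v / s_arr, np.inf * np.sign(v))
            pv = 2 * stats.norm.sf(np.abs(z))
            pvals[key] = pv if np.ndim(v) else float(pv)
            ci[key] = (v - 1.96 * s_arr, v + 1.96 * s_arr)

    return MediationResult(
        snp=snp,
        a_paths=a,
        b_paths=b,
        estimate=est,
        se=se,
        p=pvals,
        ci=ci,
        n_boot=len(draws["joint"]),
        n_boot_failed=failed,
        component_names=tuple(pcs_df.columns.astype(str)),
    )


def fit_moderated_mediation(
    dosage: np.ndarray,
    pc_scores: pd.DataFrame | np.ndarray,
    diagnosis: np.ndarray,
    covariates: pd.DataFrame | None = None,
    sex: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    snp: str = "snp",
    include_interactions: bool = True,
    moderation_alpha: float = 0.05,
) -> MediationResult:
    """Mediation with dosage-by-sex product terms on every SNP path.

    Male path estimates are the base dosage terms, female estimates base plus
    interaction (sex coded female = 1).  If any SNP pathway's interaction is
    nominally significant the sex-specific decompositions are selected for
    reporting; otherwise the main-model results are presented (both are
    carried in the result).  With ``include_interactions=False`` the model
    reduces exactly to :func:`fit_mediation`.
    """
    if not include_interactions:
        return fit_mediation(dosage, pc_scores, diagnosis, covariates,
                             n_boot=n_boot, seed=seed, snp=snp)
    if sex is None:
        raise ValueError("sex vector required for moderated mediation")
    sex = np.asarray(sex, dtype=float)
    if len(np.unique(sex)) < 2:
        raise ValueError("both sexes must be represented")
    g = np.asarray(dosage, dtype=float)
    pcs_df = pd.DataFrame(pc_scores)
    pcs = pcs_df.to_numpy(float)
    y = np.asarray(diagnosis)
    k = pcs.shape[1]
    cov_arr = None if covariates is None else pd.DataFrame(covariates).to_numpy(float)

    # a-equations with product terms: PC_j ~ 1 + g + sex + g*sex + covariates
    Xa = _design(g, cov_arr, extra_cols=[sex, g * sex])
    n, p_a = Xa.shape
    coefs, *_ = np.linalg.lstsq(Xa, pcs, rcond=None)
    resid = pcs - Xa @ coefs
    sigma2 = (resid**2).sum(axis=0) / (n - p_a)
    xtx_inv = np.linalg.inv(Xa.T @ Xa)
    a_male = coefs[1]
    a_int = coefs[3]  # g*sex column
    a_female = a_male + a_int
    se_a_int = np.sqrt(xtx_inv[3, 3] * sigma2)
    p_a_int = 2 * stats.t.sf(np.abs(a_int) / se_a_int, n - p_a)

    # joint probit with product term on the direct path
    Xb = np.column_stack([pcs, g[:, None], sex[:, None], (g * sex)[:, None]])
    if cov_arr is not None and cov_arr.shape[1]:
        Xb = np.column_stack([Xb, cov_arr])
    fit = fit_ordinal_probit(y, Xb, with_cov=True)
    eta = Xb @ fit.beta
    denom = float(np.sqrt(np.var(eta) + 1.0))
    b = fit.beta[:k] / denom
    direct_male = float(fit.beta[k] / denom)
    d_int = float(fit.beta[k + 2])
    direct_female = float((fit.beta[k] + fit.beta[k + 2]) / denom)
    se_d_int = fit.beta_se[k + 2] if fit.cov is not None else np.nan
    p_d_int = (
        float(2 * stats.norm.sf(abs(d_int) / se_d_int))
        if np.isfinite(se_d_int) and se_d_int > 0
        else 1.0
    )

    interaction_p = np.append(p_a_int, p_d_int)
    flag = bool((interaction_p < moderation_alpha).any())

    male = decompose(a_male, b, direct_male)
    female = decompose(a_female, b, direct_female)

    main = fit_mediation(dosage, pcs_df, diagnosis, covariates,
                         n_boot=n_boot, seed=seed, snp=snp)
    main.sex_specific = {
        "male": male,
        "female": female,
        "a_male": a_male,
        "a_female": a_female,
        "b_paths": b,
        "interaction_p": interaction_p,
    }
    main.moderation_flag = flag
    main.selected = "sex_specific" if flag else "main"
    return main
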
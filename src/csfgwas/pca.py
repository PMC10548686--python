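"""Biomarker principal-component phenotypes.

Six CSF analytes are turned into five orthogonally rotated component scores:

1. rank-based inverse normal transformation (Blom offsets) within each study,
2. leave-out cross-validation over matrix cells to pick the component count,
3. regularized iterative PCA imputation of missing cells,
4. PCA of the correlation matrix with Kaiser-normalized varimax rotation,
5. regression-method component scores (weights R^-1 Lambda).

Loadings are structure coefficients (marker-component correlations); signs and
column order are fixed by anchor markers (tau, Abeta, NfL, YKL-40, Ng) so the
components keep their conventional interpretation across fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import COMPONENT_NAMES, MARKER_NAMES

__all__ = [
    "BiomarkerPanel",
    "PCModel",
    "PCScores",
    "inverse_normal_transform",
    "select_n_components",
    "impute_iterative_pca",
    "fit_varimax_pca",
    "compute_scores",
    "compare_group_loadings",
    "fit_component_pipeline",
    "tucker_congruence",
]

# component slot -> anchor marker index (tau, abeta, nfl, ykl40, ng)
_ANCHORS = (0, 2, 3, 4, 5)


class TransformError(ValueError):
    pass


class ImputationError(RuntimeError):
    pass


@dataclass
class BiomarkerPanel:
    """n x 6 analyte matrix with missingness, study labels, and sex."""

    values: np.ndarray
    marker_names: tuple[str, ...] = MARKER_NAMES
    group: np.ndarray | None = None  # per-sample study label
    sex: np.ndarray | None = None  # female = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.marker_names):
            raise ValueError("values must be n x len(marker_names)")
        if self.group is None:
            self.group = np.zeros(self.values.shape[0], dtype=int)
        self.group = np.asarray(self.group)

    @property
    def mask(self) -> np.ndarray:
        """True where a cell is missing."""
        return np.isnan(self.values)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def filter_min_observed(self, min_observed: int = 4) -> "BiomarkerPanel":
        """Retain participants with at least ``min_observed`` analytes measured."""
        keep = (~self.mask).sum(axis=1) >= min_observed
        return BiomarkerPanel(
            self.values[keep],
            self.marker_names,
            self.group[keep],
            None if self.sex is None else np.asarray(self.sex)[keep],
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, group=None, sex=None
    ) -> "BiomarkerPanel":
        return cls(df.to_numpy(float), tuple(df.columns), group, sex)


@dataclass
class PCModel:
    """Fitted rotated PCA: loadings, rotation metadata, and scoring weights."""

    loadings: np.ndarray  # p x k structure coefficients
    variance_explained: np.ndarray  # k-vector, sums of squared loadings / p
    k: int
    marker_names: tuple[str, ...]
    rotation: dict = field(default_factory=dict)
    imputed_matrix: np.ndarray | None = None
    score_method: str = "regression"
    # frozen scoring state
    means: np.ndarray | None = None
    stds: np.ndarray | None = None
    corr: np.ndarray | None = None
    score_scale: np.ndarray | None = None

    def loading_table(self) -> pd.DataFrame:
        cols = [f"PC{j + 1}" for j in range(self.k)]
        return pd.DataFrame(self.loadings, index=list(self.marker_names), columns=cols)


@dataclass
class PCScores:
    scores: np.ndarray  # n x k, SD units
    component_names: tuple[str, ...]

    def to_frame(self, index=None) -> pd.DataFrame:
        cols = [f"PC{j + 1}" for j in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, columns=cols, index=index)


def inverse_normal_transform(
    values: np.ndarray, group: np.ndarray | None = None
) -> np.ndarray:
    """Blom rank-based inverse normal transform within groups.

    Non-missing values are replaced by Phi^-1((rank - 3/8) / (n + 1/4)) with
    average ranks for ties, separately per group; missing cells stay missing.
    """
    x = np.asarray(values, dtype=float).copy()
    if group is None:
        group = np.zeros(len(x), dtype=int)
    group = np.asarray(group)
    for g in np.unique(group):
        sel = group == g
        obs = sel & ~np.isnan(x)
        n_obs = int(obs.sum())
        if n_obs < 2:
            raise TransformError(
                f"group {g!r} has {n_obs} non-missing values; need at least 2"
            )
        r = stats.rankdata(x[obs], method="average")
        x[obs] = stats.norm.ppf((r - 0.375) / (n_obs + 0.25))
    return x


def _standardize_observed(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = np.nanmean(X, axis=0)
    stds = np.nanstd(X, axis=0, ddof=1)
    stds = np.where(stds > 0, stds, 1.0)
    return (X - means) / stds, means, stds


def impute_iterative_pca(
    X: np.ndarray,
    k: int,
    regularization: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> np.ndarray:
    """Complete a matrix by regularized iterative PCA (EM-style).

    Alternates a rank-``k`` truncated SVD on the current completed matrix --
    with retained singular values shrunk toward the noise level sigma by
    sigma_l <- (sigma_l^2 - regularization * sigma_noise^2) / sigma_l --
    and refilling of the missing cells only, until the largest absolute change
    in an imputed cell falls below ``tol``.  Observed cells are returned
    unchanged, on the original scale.
    """
    X = np.asarray(X, dtype=float)
    miss = np.isnan(X)
    if not miss.any():
        return X.copy()
    if miss.all(axis=0).any():
        bad = int(np.where(miss.all(axis=0))[0][0])
        raise ImputationError(f"column {bad} is entirely missing")

    Z, means, stds = _standardize_observed(X)
    Z = np.where(miss, 0.0, Z)
    n, p = Z.shape
    k = int(k)
    # rows grouped by missingness pattern so the refill solve is batched
    pattern_key = miss @ (1 << np.arange(p))
    patterns = {}
    for key in np.unique(pattern_key[pattern_key > 0]):
        rows = np.where(pattern_key == key)[0]
        patterns[key] = (rows, miss[rows[0]])
    for _ in range(max_iter):
        mu = Z.mean(axis=0)
        if k == 0:
            new = np.where(miss, mu[None, :], Z)
        else:
            _, s, Vt = np.linalg.svd(Z - mu, full_matrices=False)
            s2 = s**2
            noise = s2[k:].mean() if k < len(s2) else 0.0
            shrunk = np.clip((s2[:k] - regularization * noise), 0.0, None) / s2[:k]
            # symmetric smoother: fitted row = mu + (x - mu) W
            W = (Vt[:k].T * shrunk) @ Vt[:k]
            new = Z.copy()
            for rows, m in patterns.values():
                o = ~m
                # exact fixed point of the refill step for the current W:
                # (I - W)_MM (x_M - mu_M) = W_MO (x_O - mu_O)
                A = np.eye(int(m.sum())) - W[np.ix_(m, m)]
                B = W[np.ix_(m, o)] @ (Z[np.ix_(rows, o)] - mu[o]).T
                try:
                    xm = np.linalg.solve(A, B)
                except np.linalg.LinAlgError:
                    xm = np.linalg.lstsq(A, B, rcond=None)[0]
                new[np.ix_(rows, m)] = mu[m] + xm.T
        delta = float(np.abs(new - Z)[miss].max()) if miss.any() else 0.0
        Z = new
        if delta < tol:
            break
    else:
        raise ImputationError(
            f"iterative PCA imputation did not converge after {max_iter} "
            f"iterations (last max change {delta:.3g})"
        )
    out = Z * stds + means
    out[~miss] = X[~miss]  # observed cells pass through bit-identically
    return out


def select_n_components(
    panel: BiomarkerPanel | np.ndarray,
    k_max: int,
    n_folds: int | None = 10,
    regularization: float = 1.0,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Pick the component count by cross-validation over held-out cells.

    Observed cells are partitioned into folds (``n_folds=None`` gives true
    leave-one-cell-out); each fold is masked, the matrix re-imputed at rank k,
    and the prediction MSE accumulated on the standardized scale.  Returns the
    argmin k over 0..k_max together with the CV error curve (index = k).
    """
    X = panel.values if isinstance(panel, BiomarkerPanel) else np.asarray(panel, float)
    p = X.shape[1]
    if k_max >= p:
        raise ValueError(f"k_max must be < number of markers ({p})")

    Z, _, _ = _standardize_observed(X)
    obs = np.argwhere(~np.isnan(X))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(obs))
    n_folds_eff = len(obs) if n_folds is None else min(n_folds, len(obs))
    folds = np.array_split(order, n_folds_eff)

    errors = np.zeros(k_max + 1)
    counts = np.zeros(k_max + 1)
    for k in range(k_max + 1):
        sse = 0.0
        m = 0
        for fold in folds:
            Xf = X.copy()
            rows, cols = obs[fold, 0], obs[fold, 1]
            Xf[rows, cols] = np.nan
            if np.isnan(Xf).all(axis=0).any():
                continue  # degenerate fold in tiny matrices
            try:
                comp = impute_iterative_pca(Xf, k, regularization=regularization)
            except ImputationError:
                continue
            # error on the original standardized scale
            _, means, stds = _standardize_observed(X)
            zc = (comp[rows, cols] - means[cols]) / stds[cols]
            sse += float(((zc - Z[rows, cols]) ** 2).sum())
            m += len(fold)
        errors[k] = sse / m if m else np.inf
        counts[k] = m
    best = int(np.argmin(errors))
    return best, errors


def _varimax(A: np.ndarray, tol: float = 1e-10, max_iter: int = 500) -> tuple[np.ndarray, int]:
    """Classical varimax: iterative pairwise planar rotations to convergence.

    The pairwise angle update handles symmetric configurations where
    gradient-projection solvers stall at a saddle (e.g., two perfectly
    correlated blocks whose unrotated loadings are exactly balanced).
    """
    L = A.copy()
    p, k = L.shape
    if k < 2:
        return L, 0
    for it in range(max_iter):
        changed = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                u = L[:, i] ** 2 - L[:, j] ** 2
                v = 2.0 * L[:, i] * L[:, j]
                num = 2.0 * (u @ v - u.sum() * v.sum() / p)
                den = (u @ u - v @ v) - (u.sum() ** 2 - v.sum() ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < tol:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                Li = c * L[:, i] + s * L[:, j]
                L[:, j] = -s * L[:, i] + c * L[:, j]
                L[:, i] = Li
                changed = max(changed, abs(phi))
        if changed < tol:
            break
    return L, it + 1


def _varimax_kaiser(A: np.ndarray) -> tuple[np.ndarray, dict]:
    """Varimax rotation with Kaiser row normalization."""
    h = np.sqrt((A**2).sum(axis=1))
    h = np.where(h > 0, h, 1.0)
    L, n_iter = _varimax(A / h[:, None])
    return L * h[:, None], {"kaiser_normalized": True, "iterations": n_iter}


def _align_components(
    L: np.ndarray, marker_names: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Order components by anchor markers and fix anchor signs positive.

    With the canonical six markers and k = 5, slots follow the anchor list
    (tau, abeta, nfl, ykl40, ng); otherwise components are ordered by
    variance explained.  Returns (loadings, order, signs).
    """
    p, k = L.shape
    canonical = tuple(marker_names) == MARKER_NAMES and k == 5
    if canonical:
        order = []
        remaining = list(range(k))
        for anchor in _ANCHORS:
            j = max(remaining, key=lambda c: abs(L[anchor, c]))
            order.append(j)
            remaining.remove(j)
        order = np.array(order)
        anchors = np.array(_ANCHORS)
    else:
        ve = (L**2).sum(axis=0)
        order = np.argsort(-ve)
        anchors = np.abs(L[:, order]).argmax(axis=0)
    L = L[:, order]
    signs = np.where(L[anchors, np.arange(k)] < 0, -1.0, 1.0)
    return L * signs, order, signs


def fit_varimax_pca(X: np.ndarray, k: int) -> PCModel:
    """PCA of the correlation matrix with varimax-rotated structure loadings."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("fit_varimax_pca requires a complete matrix; impute first")
    n, p = X.shape
    if n < k:
        raise ValueError("need at least k samples")
    Z, means, stds = _standardize_observed(X)
    R = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    if evals[k - 1] <= 1e-10:
        raise ValueError("correlation matrix is rank-deficient for the requested k")
    A = evecs[:, :k] * np.sqrt(evals[:k])
    if k > 1:
        L, rot = _varimax_kaiser(A)
    else:
        L, rot = A.copy(), {"kaiser_normalized": False}
    marker_names = MARKER_NAMES if p == 6 else tuple(f"m{j + 1}" for j in range(p))
    L, order, signs = _align_components(L, marker_names)
    model = PCModel(
        loadings=L,
        variance_explained=(L**2).sum(axis=0) / p,
        k=k,
        marker_names=marker_names,
        rotation=rot,
        imputed_matrix=X.copy(),
        means=means,
        stds=stds,
        corr=R,
    )
    # freeze the score scale on the estimation sample
    W = _score_weights(model)
    S = Z @ W
    model.score_scale = S.std(axis=0, ddof=1)
    model.score_scale = np.where(model.score_scale > 0, model.score_scale, 1.0)
    return model


def _score_weights(model: PCModel, method: str | None = None) -> np.ndarray:
    method = method or model.score_method
    L, R = model.loadings, model.corr
    if method == "regression":
        return np.linalg.solve(R, L)
    if method == "bartlett":
        # weights = Psi^-1 L (L' Psi^-1 L)^-1 with Psi the uniquenesses
        psi = np.clip(1.0 - (L**2).sum(axis=1), 1e-3, None)
        Lp = L / psi[:, None]
        return Lp @ np.linalg.inv(L.T @ Lp)
    raise ValueError(f"unknown score method {method!r}")


def compute_scores(
    model: PCModel, X: np.ndarray, marker_names: tuple[str, ...] | None = None
) -> PCScores:
    """Component scores for a completed matrix under a frozen model.

    No refitting occurs: standardization constants, scoring weights, and the
    score scale all come from the estimation sample, so the same model can be
    applied to an external cohort.
    """
    if marker_names is not None and tuple(marker_names) != tuple(model.marker_names):
        raise ValueError(
            f"marker names {tuple(marker_names)} do not match the fitted model"
        )
    X = np.asarray(X, dtype=float)
    Z = (X - model.means) / model.stds
    S = (Z @ _score_weights(model)) / model.score_scale
    names = (
        COMPONENT_NAMES
        if model.k == 5 and tuple(model.marker_names) == MARKER_NAMES
        else tuple(f"PC{j + 1}" for j in range(model.k))
    )
    return PCScores(scores=S, component_names=names)


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity between two loading vectors."""
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def fit_component_pipeline(
    panel: BiomarkerPanel,
    k: int | None = None,
    k_max: int = 5,
    regularization: float = 1.0,
    transform: bool = True,
    seed: int = 0,
) -> tuple[PCModel, PCScores]:
    """INT -> (CV rank selection) -> imputation -> varimax PCA -> scores."""
    panel = panel.filter_min_observed(4)
    X = panel.values
    if transform:
        X = np.column_stack(
            [inverse_normal_transform(X[:, j], panel.group) for j in range(X.shape[1])]
        )
    if k is None:
        k, _ = select_n_components(X, k_max, regularization=regularization, seed=seed)
        k = max(k, 1)
    completed = impute_iterative_pca(X, k, regularization=regularization)
    model = fit_varimax_pca(completed, k)
    scores = compute_scores(model, completed)
    return model, scores


def compare_group_loadings(
    panel: BiomarkerPanel,
    k: int = 5,
    groups: np.ndarray | None = None,
    indifference: float = 0.04,
    seed: int = 0,
) -> dict:
    """Fit the full pipeline per group and tabulate loading differences.

    Components of the second group are matched to the first by maximal Tucker
    congruence (greedy, sign-aligned).  Differences smaller than
    ``indifference`` in absolute value are flagged 'indifferent'.
    """
    labels = np.asarray(groups if groups is not None else panel.sex)
    if labels is None:
        raise ValueError("no grouping variable available")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {list(uniq)}")
    models: dict = {}
    for g in uniq:
        sel = labels == g
        if int(sel.sum()) < 6:
            raise ValueError(f"group {g!r} has fewer than 6 samples")
        sub = BiomarkerPanel(
            panel.values[sel], panel.marker_names, panel.group[sel]
        )
        models[g], _ = fit_component_pipeline(sub, k=k, seed=seed)

    La, Lb = models[uniq[0]].loadings, models[uniq[1]].loadings
    # greedy congruence matching of group-b components onto group-a slots
    remaining = list(range(k))
    order, signs = [], []
    for j in range(k):
        cong = [tucker_congruence(La[:, j], Lb[:, c]) for c in remaining]
        best = int(np.argmax(np.abs(cong)))
        order.append(remaining.pop(best))
        signs.append(np.sign(cong[best]) or 1.0)
    Lb_aligned = Lb[:, order] * np.asarray(signs)[None, :]

    diff = La - Lb_aligned
    cols = [f"PC{j + 1}" for j in range(k)]
    table = pd.DataFrame(diff, index=list(panel.marker_names), columns=cols)
    return {
        "models": models,
        "difference": table,
        "indifferent": table.abs() < indifference,
        "congruence": np.array(
            [tucker_congruence(La[:, j], Lb_aligned[:, j]) for j in range(k)]
        ),
    }
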
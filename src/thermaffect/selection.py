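"""Feature ranking: PCA loadings, ANOVA F, diagonal NCA weights, naive Bayes.

All four rankers return a :class:`RankingResult` with a full permutation of
feature indices (best first) and a per-feature score. Default selection
depths mirror the evaluation protocol: top 50 for PCA/ANOVA, top 10 for
NCA/NB.

PCA does not natively rank original features; here each feature is scored by
the largest absolute loading it attains across the components retained to
95% explained variance (standardized data), so that the selected columns are
original features, which is what the downstream column counts refer to. A
component-projection mode is available via :func:`pca_project` for
completeness.

The NCA ranker is the diagonal (feature-weight) variant: it maximizes the
expected leave-one-out soft-neighbor classification accuracy

    F(w) = 1/n sum_i sum_{j != i, y_j = y_i} p_ij  -  lambda * ||w||^2,
    p_ij = exp(-d_ij) / sum_{l != i} exp(-d_il),
    d_ij = sum_k w_k^2 (x_ik - x_jk)^2,

with an analytic gradient and L-BFGS-B. Features are ranked by |w|.
scikit-learn's NCA learns a full linear map and cannot rank individual
features, hence the in-package objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.decomposition import PCA
from sklearn.feature_selection import f_classif
from sklearn.model_selection import StratifiedKFold

from .core import ValidationError
from .features import FeatureTable

METHODS = ("PCA", "ANOVA", "NCA", "NB")
DEFAULT_K = {"PCA": 50, "ANOVA": 50, "NCA": 10, "NB": 10}


@dataclass
class RankingResult:
    """Ordered feature indices + per-feature scores from one selector."""

    method: str
    order: np.ndarray  # permutation of range(n_features), best first
    scores: np.ndarray  # aligned with the original feature indices
    k_selected: int
    converged: bool = True
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        n = self.scores.size
        if sorted(self.order.tolist()) != list(range(n)):
            raise ValidationError("ranking order is not a permutation of the feature indices")
        if not 1 <= self.k_selected <= n:
            raise ValidationError(f"k_selected={self.k_selected} outside [1, {n}]")

    @property
    def top(self) -> np.ndarray:
        return self.order[: self.k_selected]


def _as_xy(table, labels=None) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(table, FeatureTable):
        return table.X, table.y
    X = np.asarray(table, dtype=np.float64)
    y = None if labels is None else np.asarray(labels)
    return X, y


def _rank(scores: np.ndarray) -> np.ndarray:
    # stable descending sort; ties broken by original index
    return np.argsort(-scores, kind="stable")


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    usable = sd > 0
    Z = np.zeros_like(X)
    Z[:, usable] = (X[:, usable] - mu[usable]) / sd[usable]
    return Z, usable


def rank_anova(table, labels=None, k: int | None = None) -> RankingResult:
    """Per-feature one-way ANOVA F statistic, ranked descending.

    F is scale-free, so the ranking is invariant to per-feature rescaling.
    Features that are constant both within and between classes score 0.
    """
    X, y = _as_xy(table, labels)
    if y is None:
        raise ValidationError("rank_anova requires class labels")
    if len(np.unique(y)) < 2:
        raise ValidationError("rank_anova requires at least two classes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, _ = f_classif(X, y)
    f = np.nan_to_num(f, nan=0.0, posinf=np.finfo(float).max)
    return RankingResult("ANOVA", _rank(f), f, k or min(DEFAULT_K["ANOVA"], X.shape[1]))


def rank_pca(table, k: int | None = None, var_target: float = 0.95) -> RankingResult:
    """Score features by their maximum |loading| over retained components.

    Loadings follow the factor-analysis convention: component weight times
    the component's standard deviation, i.e. the correlation between the
    (standardized) feature and the component — so alignment with a
    high-variance component outranks alignment with a minor one. Columns are
    standardized first; components are retained until ``var_target`` of the
    variance is explained (always at least one). Constant columns are
    dropped from the decomposition and scored 0.
    """
    X, _ = _as_xy(table)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("rank_pca needs >= 2 rows and >= 2 features")
    Z, usable = _standardize(X)
    scores = np.zeros(X.shape[1])
    if usable.any():
        pca = PCA()
        pca.fit(Z[:, usable])
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_keep = int(np.searchsorted(cum, var_target) + 1)
        n_keep = min(n_keep, pca.components_.shape[0])
        sdevs = np.sqrt(pca.explained_variance_[:n_keep])
        loadings = (np.abs(pca.components_[:n_keep]) * sdevs[:, None]).max(axis=0)
        scores[usable] = loadings
    return RankingResult(
        "PCA",
        _rank(scores),
        scores,
        k or min(DEFAULT_K["PCA"], X.shape[1]),
        info={"n_components": int(n_keep) if usable.any() else 0},
    )


def pca_project(table, var_target: float = 0.95) -> tuple[np.ndarray, PCA]:
    """Alternative PCA mode: project standardized data onto the retained PCs."""
    X, _ = _as_xy(table)
    Z, usable = _standardize(X)
    pca = PCA()
    scores = pca.fit_transform(Z[:, usable])
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, var_target) + 1)
    return scores[:, :n_keep], pca


def _nca_objective(w, D2, same, lam):
    """Negative regularized NCA objective and gradient; D2 is (n, n, p)."""
    n = D2.shape[0]
    w2 = w * w
    d = D2 @ w2  # (n, n) weighted squared distances
    np.fill_diagonal(d, np.inf)
    d = d - d.min(axis=1, keepdims=True)  # row-wise shift for stable softmax
    K = np.exp(-d)
    np.fill_diagonal(K, 0.0)
    denom = K.sum(axis=1)
    denom[denom == 0] = 1.0
    P = K / denom[:, None]
    p_i = (P * same).sum(axis=1)
    f = p_i.mean() - lam * float(w2.sum())

    # dF/dw_k = 2 w_k / n * sum_i [ p_i * sum_l P_il D2_ilk - sum_{j in c_i} P_ij D2_ijk ]
    A = P * p_i[:, None] - P * same
    grad = (2.0 * w / n) * np.einsum("il,ilk->k", A, D2) - 2.0 * lam * w
    return -f, -grad


def rank_nca(
    table,
    labels=None,
    learn_rate: float | None = None,
    max_iter: int = 50,
    seed: int = 0,
    reg: float | None = None,
    k: int | None = None,
) -> RankingResult:
    """Diagonal-weighted NCA feature ranking (|weight| descending).

    ``learn_rate`` is accepted for interface compatibility but unused: the
    optimizer is quasi-Newton (L-BFGS-B), which needs no step size. ``seed``
    perturbs the all-ones initial weights slightly to break exact ties.
    ``reg`` defaults to 1/n, which drives uninformative weights toward zero.
    Non-convergence is flagged on the result rather than raised; the partial
    weights are still returned.
    """
    X, y = _as_xy(table, labels)
    if y is None:
        raise ValidationError("rank_nca requires class labels")
    n, p = X.shape
    Z, usable = _standardize(X)
    _, y_codes = np.unique(y, return_inverse=True)
    same = (y_codes[:, None] == y_codes[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)

    diff = Z[:, None, :] - Z[None, :, :]
    D2 = diff * diff  # (n, n, p)

    lam = (1.0 / n) if reg is None else float(reg)
    rng = np.random.default_rng(seed)
    w0 = 1.0 + 0.01 * rng.standard_normal(p)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            _nca_objective,
            w0,
            args=(D2, same, lam),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-10, "gtol": 1e-6},
        )
    w = np.abs(res.x)
    w[~usable] = 0.0
    return RankingResult(
        "NCA",
        _rank(w),
        w,
        k or min(DEFAULT_K["NCA"], p),
        converged=bool(res.success),
        info={"n_iter": int(res.nit), "objective": float(-res.fun)},
    )


def _nb_cv_accuracy(X: np.ndarray, y_codes: np.ndarray, n_classes: int, cv, var_floor: float):
    """Vectorized per-feature Gaussian NB cross-validated accuracy."""
    n, p = X.shape
    correct = np.zeros(p)
    total = 0
    for train, test in cv:
        mus = np.empty((n_classes, p))
        vars_ = np.empty((n_classes, p))
        priors = np.empty(n_classes)
        for c in range(n_classes):
            block = X[train][y_codes[train] == c]
            priors[c] = len(block) / len(train)
            mus[c] = block.mean(axis=0)
            vars_[c] = np.maximum(block.var(axis=0, ddof=0), var_floor)
        xt = X[test]  # (m, p)
        # log-likelihood per class: (n_classes, m, p)
        ll = (
            -0.5 * np.log(2 * np.pi * vars_)[:, None, :]
            - (xt[None] - mus[:, None, :]) ** 2 / (2 * vars_[:, None, :])
            + np.log(priors)[:, None, None]
        )
        pred = ll.argmax(axis=0)  # (m, p)
        correct += (pred == y_codes[test][:, None]).sum(axis=0)
        total += len(test)
    return correct / total


def rank_nb(
    table,
    labels=None,
    n_folds: int = 5,
    seed: int = 0,
    var_floor: float = 1e-9,
    k: int | None = None,
) -> RankingResult:
    """Score each feature by its single-feature Gaussian NB CV accuracy.

    Each feature is scored independently (adding features never changes an
    existing feature's score). Degenerate per-class variances are floored at
    ``var_floor``.
    """
    X, y = _as_xy(table, labels)
    if y is None:
        raise ValidationError("rank_nb requires class labels")
    classes, y_codes = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValidationError("rank_nb requires at least two classes")
    n_folds = min(n_folds, int(np.bincount(y_codes).min()))
    skf = StratifiedKFold(n_splits=max(2, n_folds), shuffle=True, random_state=seed)
    acc = _nb_cv_accuracy(X, y_codes, len(classes), skf.split(X, y_codes), var_floor)
    return RankingResult("NB", _rank(acc), acc, k or min(DEFAULT_K["NB"], X.shape[1]))


def select_top(result: RankingResult, table, k: int | None = None):
    """Subset the table (or array) to the top-k ranked features, best first.

    Idempotent in the sense that re-selecting the full width is a pure
    column reordering.
    """
    k = result.k_selected if k is None else int(k)
    if isinstance(table, FeatureTable):
        width = table.data.shape[1]
        if k > width:
            raise ValidationError(f"k={k} exceeds table width {width}")
        cols = [table.data.columns[i] for i in result.order[:k]]
        return FeatureTable(
            table.data[cols], table.labels, table.layout_id,
            {**table.provenance, "selector": result.method, "k": k},
        )
    X = np.asarray(table)
    if k > X.shape[1]:
        raise ValidationError(f"k={k} exceeds table width {X.shape[1]}")
    return X[:, result.order[:k]]


RANKERS = {
    "pca": lambda X, y, seed: rank_pca(X),
    "anova": lambda X, y, seed: rank_anova(X, y),
    "nca": lambda X, y, seed: rank_nca(X, y, seed=seed),
    "nb": lambda X, y, seed: rank_nb(X, y, seed=seed),
}
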
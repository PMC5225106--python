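"""Mean-centering/UV scaling, PCA, and NIPALS PLS-DA with validation.

The supervised workflow mirrors the classical chemometrics recipe:
unit-variance scale the feature matrix, fit partial least squares
against a centered class-indicator response, score features by VIP,
and validate with stratified 7-fold cross-validated Q-squared plus a
class-label permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import NormalizedTable

logger = logging.getLogger(__name__)

__all__ = [
    "ScaledMatrix",
    "PCAResult",
    "PLSDAResult",
    "uv_scale",
    "run_pca",
    "run_plsda",
    "vip_scores",
]


@dataclass
class ScaledMatrix:
    """UV-scaled matrix with the statistics needed to back-transform."""

    x: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    excluded: tuple[str, ...] = ()

    @property
    def samples(self) -> pd.Index:
        return self.x.index


def uv_scale(table: NormalizedTable | pd.DataFrame, log2: bool = False) -> ScaledMatrix:
    """Mean-center and unit-variance scale each feature column.

    Uses the n-1 sample standard deviation.  Zero-variance columns are
    excluded with a warning rather than producing NaN columns.  With
    ``log2`` the values are log2-transformed first (strictly positive
    input required).
    """
    values = table.values if isinstance(table, NormalizedTable) else table
    if values.shape[0] < 2:
        raise ValueError("UV scaling needs at least 2 samples")
    if log2:
        if (values <= 0).any().any():
            raise ValueError("log2 transform requires strictly positive values")
        values = np.log2(values)
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    constant = sds.index[sds == 0]
    if len(constant):
        logger.warning("excluding %d zero-variance feature(s): %s",
                       len(constant), list(constant))
    keep = sds.index.difference(constant, sort=False)
    x = (values[keep] - means[keep]) / sds[keep]
    return ScaledMatrix(x=x, means=means[keep], sds=sds[keep],
                        excluded=tuple(constant))


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> None:
    """Deterministic sign convention: each loading vector's largest-
    magnitude element is positive.  Operates in place."""
    for a in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # features x components
    explained_variance_ratio: np.ndarray  # fraction per retained component

    def explained_percent(self, component: int) -> float:
        """Explained variance of one component on the percent scale."""
        return 100.0 * float(self.explained_variance_ratio[component])


def run_pca(scaled: ScaledMatrix, n_components: int | None = None) -> PCAResult:
    """PCA via singular value decomposition of the scaled matrix."""
    x = scaled.x.to_numpy(dtype=float)
    n, p = x.shape
    max_rank = min(n - 1, p)
    if n_components is None:
        n_components = max_rank
    if not 1 <= n_components <= max_rank:
        raise ValueError(f"n_components must be in [1, {max_rank}]")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float(np.sum(s**2))
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T
    _fix_signs(scores, loadings)
    ratio = (s[:n_components] ** 2) / total
    comp_names = [f"PC{a + 1}" for a in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=scaled.x.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=scaled.x.columns, columns=comp_names),
        explained_variance_ratio=ratio,
    )


def _class_indicator(classes: pd.Series | np.ndarray) -> tuple[np.ndarray, list]:
    """Centered class-indicator response: one +/- column for two classes,
    centered one-hot for more."""
    labels = pd.Series(classes).astype(str)
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    if len(levels) == 2:
        y = np.where(labels.to_numpy() == levels[1], 1.0, 0.0)[:, None]
    else:
        y = np.stack([(labels.to_numpy() == lv).astype(float) for lv in levels], axis=1)
    return y - y.mean(axis=0), levels


def _nipals(x: np.ndarray, y: np.ndarray, n_components: int,
            tol: float = 1e-10, max_iter: int = 500):
    """NIPALS PLS2 with X- and Y-deflation per component.

    Returns (W, T, P, Q) with column a holding the a-th weight, score,
    X-loading and Y-loading vectors.
    """
    xa = x.copy()
    ya = y.copy()
    n, p = x.shape
    m = y.shape[1]
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((m, n_components))
    for a in range(n_components):
        u = ya[:, int(np.argmax(np.sum(ya**2, axis=0)))]
        if not np.any(u):
            break
        t = q = None
        t_old = None
        for _ in range(max_iter):
            w = xa.T @ u
            norm_w = np.linalg.norm(w)
            if norm_w == 0:
                break
            w /= norm_w
            t = xa @ w
            tt = float(t @ t)
            if tt == 0:
                break
            q = ya.T @ t / tt
            qq = float(q @ q)
            if qq == 0:
                break
            u = ya @ q / qq
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * max(
                np.linalg.norm(t), 1e-300
            ):
                break
            t_old = t
        if t is None or q is None:
            break
        tt = float(t @ t)
        if tt == 0:
            break
        p_a = xa.T @ t / tt
        W[:, a] = w
        T[:, a] = t
        P[:, a] = p_a
        Q[:, a] = q
        xa = xa - np.outer(t, p_a)
        ya = ya - np.outer(t, q)
    return W, T, P, Q


def _pls_coefficients(W: np.ndarray, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Regression coefficients B with Y_hat = X @ B for deflated weights."""
    pw = P.T @ W
    w_star = W @ np.linalg.pinv(pw)
    return w_star @ Q.T


@dataclass
class PLSDAResult:
    """Fitted PLS-DA model with validation statistics.

    ``r2x``/``r2y`` are cumulative explained fractions per component;
    ``q2`` is the cumulative cross-validated predictive fraction.
    """

    weights: pd.DataFrame        # features x components (w_a)
    scores: pd.DataFrame         # samples x components (t_a)
    x_loadings: pd.DataFrame     # features x components (p_a)
    y_loadings: np.ndarray       # responses x components (q_a)
    r2x: np.ndarray
    r2y: np.ndarray
    q2: np.ndarray
    vip: pd.Series
    permutation_p: float | None
    permutation_q2: np.ndarray | None
    class_levels: list = field(default_factory=list)
    n_components: int = 0

    @property
    def q2_cum(self) -> float:
        return float(self.q2[self.n_components - 1])


def _stratified_folds(labels: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded stratified fold assignment; every class spread over folds."""
    fold = np.empty(labels.shape[0], dtype=int)
    for lv in np.unique(labels):
        idx = np.where(labels == lv)[0]
        rng.shuffle(idx)
        if len(idx) < n_folds:
            logger.warning("class %r has %d member(s) < %d folds; stratifying anyway",
                           lv, len(idx), n_folds)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def _cv_q2(x: np.ndarray, y: np.ndarray, labels: np.ndarray, n_components: int,
           n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Cumulative Q2 per component count from stratified K-fold CV.

    Q2(A) = 1 - PRESS(A)/SS with SS the squared deviation of held-out
    responses from their training-fold mean.
    """
    folds = _stratified_folds(labels, n_folds, rng)
    press = np.zeros(n_components)
    ss = 0.0
    for k in range(n_folds):
        test = folds == k
        train = ~test
        if len(np.unique(labels[train])) < 2:
            raise ValueError(f"CV fold {k} leaves a single class in training data")
        x_mean = x[train].mean(axis=0)
        y_mean = y[train].mean(axis=0)
        xt, yt = x[train] - x_mean, y[train] - y_mean
        W, T, P, Q = _nipals(xt, yt, n_components)
        xe = x[test] - x_mean
        for a in range(1, n_components + 1):
            B = _pls_coefficients(W[:, :a], P[:, :a], Q[:, :a])
            resid = (y[test] - y_mean) - xe @ B
            press[a - 1] += float(np.sum(resid**2))
        ss += float(np.sum((y[test] - y_mean) ** 2))
    return 1.0 - press / ss


def run_plsda(
    scaled: ScaledMatrix,
    classes,
    n_components: int | None = None,
    cv_folds: int = 7,
    n_perm: int = 100,
    seed: int = 0,
    max_components: int = 10,
) -> PLSDAResult:
    """Fit PLS-DA on a UV-scaled matrix with CV and permutation validation.

    When ``n_components`` is None the model keeps the smallest count
    whose incremental Q2 falls below 0.01 (capped at ``max_components``).
    The permutation test refits the full pipeline on label-shuffled data
    ``n_perm`` times and reports p = (1 + #{perm Q2 >= observed}) /
    (n_perm + 1).  Set ``n_perm=0`` to skip it.
    """
    x = scaled.x.to_numpy(dtype=float)
    labels = pd.Series(classes).astype(str).to_numpy()
    if labels.shape[0] != x.shape[0]:
        raise ValueError("classes length must match sample count")
    y, levels = _class_indicator(labels)
    rng = np.random.default_rng(seed)

    cap = min(max_components, x.shape[0] - 1, x.shape[1])
    a_max = n_components if n_components is not None else cap
    if not 1 <= a_max <= min(x.shape[0] - 1, x.shape[1]):
        raise ValueError("n_components out of range")

    q2 = _cv_q2(x, y, labels, a_max, cv_folds, np.random.default_rng(seed))
    if n_components is None:
        a = 1
        while a < a_max and (q2[a] - q2[a - 1]) >= 0.01:
            a += 1
    else:
        a = n_components

    W, T, P, Q = _nipals(x, y, a)
    ssx = float(np.sum(x**2))
    ssy = float(np.sum(y**2))
    r2x = np.cumsum(np.sum(T**2, axis=0) * np.sum(P**2, axis=0)) / ssx
    # per-component explained Y variation: ||t_a||^2 ||q_a||^2
    ssy_a = np.sum(T**2, axis=0) * np.sum(Q**2, axis=0)
    r2y = np.cumsum(ssy_a) / ssy

    comp_names = [f"LV{i + 1}" for i in range(a)]
    result = PLSDAResult(
        weights=pd.DataFrame(W, index=scaled.x.columns, columns=comp_names),
        scores=pd.DataFrame(T, index=scaled.x.index, columns=comp_names),
        x_loadings=pd.DataFrame(P, index=scaled.x.columns, columns=comp_names),
        y_loadings=Q,
        r2x=r2x,
        r2y=r2y,
        q2=q2[:a],
        vip=pd.Series(dtype=float),
        permutation_p=None,
        permutation_q2=None,
        class_levels=levels,
        n_components=a,
    )
    result.vip = vip_scores(result)

    if n_perm > 0:
        observed = result.q2_cum
        perm_q2 = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(labels.shape[0])
            y_p, _ = _class_indicator(labels[perm])
            perm_q2[i] = _cv_q2(
                x, y_p, labels[perm], a, cv_folds,
                np.random.default_rng(rng.integers(2**31 - 1)),
            )[a - 1]
        result.permutation_q2 = perm_q2
        result.permutation_p = float((1 + np.sum(perm_q2 >= observed)) / (n_perm + 1))
    return result


def vip_scores(model: PLSDAResult) -> pd.Series:
    """Variable influence on projection.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ) with
    SSY_a = ||q_a||^2 t_a.t_a; mean(VIP^2) over features is 1 by
    construction.
    """
    if model.n_components < 1:
        raise ValueError("model has no fitted components")
    W = model.weights.to_numpy()
    T = model.scores.to_numpy()
    Q = np.atleast_2d(model.y_loadings)
    p = W.shape[0]
    ssy_a = np.sum(T**2, axis=0) * np.sum(Q**2, axis=0)
    w_norm = W / np.linalg.norm(W, axis=0, keepdims=True)
    vip = np.sqrt(p * (w_norm**2 @ ssy_a) / float(np.sum(ssy_a)))
    return pd.Series(vip, index=model.weights.index, name="VIP")
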
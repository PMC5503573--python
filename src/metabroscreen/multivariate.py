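"""Supervised and unsupervised separation analysis: OPLS-DA and LLE.

OPLS-DA (orthogonal projections to latent structures, discriminant flavour)
splits the X variation into a single predictive component correlated with
the +/-1 class vector and ``n_orth`` orthogonal components that model
structured variation unrelated to class.  Diagnostics follow the usual
conventions: R2X/R2Y are cumulative explained fractions on the training
data; Q2 is the cross-validated prediction of y.

LLE (locally linear embedding) reconstructs each sample from its k nearest
neighbours with weights summing to one and finds the low-dimensional
coordinates preserving those weights — the bottom nonconstant eigenvectors
of (I-W)'(I-W).

Both are implemented here directly (NIPALS-style deflation for OPLS,
dense eigendecomposition for LLE); external libraries serve only as test
oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.spatial.distance import cdist

__all__ = ["OplsModel", "LleEmbedding", "fit_oplsda", "lle_embed"]


@dataclass
class OplsModel:
    """A fitted OPLS-DA model with one predictive component.

    Scores/weights/loadings are stored in the preprocessed (centred, scaled)
    space; ``predict`` applies the stored preprocessing to new samples.
    """

    x_mean: np.ndarray
    x_scale: np.ndarray
    kept_columns: np.ndarray  # indices of non-constant ions used by the model
    y_mean: float
    predictive_scores: np.ndarray          # (n,)
    predictive_weights: np.ndarray         # (p,)
    predictive_loadings: np.ndarray        # (p,)
    y_loading: float
    orthogonal_scores: np.ndarray          # (n, n_orth)
    orthogonal_weights: np.ndarray         # (p, n_orth)
    orthogonal_loadings: np.ndarray        # (p, n_orth)
    r2x_cum: float
    r2y_cum: float
    q2_cum: float

    @property
    def n_orth(self) -> int:
        return self.orthogonal_scores.shape[1]

    def _preprocess(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, self.kept_columns]
        return (X - self.x_mean) / self.x_scale

    def transform(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predictive and orthogonal scores for new samples."""
        E = self._preprocess(X)
        t_orth = np.empty((E.shape[0], self.n_orth))
        for j in range(self.n_orth):
            t = E @ self.orthogonal_weights[:, j]
            E = E - np.outer(t, self.orthogonal_loadings[:, j])
            t_orth[:, j] = t
        t_pred = E @ self.predictive_weights
        return t_pred, t_orth

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Continuous class prediction (sign gives the class, case = +)."""
        t_pred, _ = self.transform(X)
        return t_pred * self.y_loading + self.y_mean


def _scale_vectors(X: np.ndarray, scaling: str) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if scaling == "uv":
        return sd
    if scaling == "pareto":
        return np.sqrt(sd)
    if scaling == "none":
        return np.ones(X.shape[1])
    raise ValueError(f"unknown scaling {scaling!r}; use 'uv', 'pareto' or 'none'")


def _fit_opls_core(
    E: np.ndarray, y: np.ndarray, n_orth: int
) -> tuple[np.ndarray, ...]:
    """NIPALS O-PLS on preprocessed E, centred y. Returns components and deflated E."""
    n, p = E.shape
    W_o = np.zeros((p, n_orth))
    P_o = np.zeros((p, n_orth))
    T_o = np.zeros((n, n_orth))
    yy = float(y @ y)
    for j in range(n_orth):
        w = E.T @ y / yy
        nw = np.linalg.norm(w)
        if nw == 0:
            # no y-correlated variation left: orthogonal extraction impossible
            W_o, P_o, T_o = W_o[:, :j], P_o[:, :j], T_o[:, :j]
            break
        w /= nw
        t = E @ w
        pl = E.T @ t / float(t @ t)
        w_o = pl - float(w @ pl) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            W_o, P_o, T_o = W_o[:, :j], P_o[:, :j], T_o[:, :j]
            break
        w_o /= n_wo
        t_o = E @ w_o
        p_o = E.T @ t_o / float(t_o @ t_o)
        E = E - np.outer(t_o, p_o)
        W_o[:, j], P_o[:, j], T_o[:, j] = w_o, p_o, t_o

    w = E.T @ y / yy
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("y is uncorrelated with every ion; no predictive component")
    w /= nw
    t = E @ w
    tt = float(t @ t)
    pl = E.T @ t / tt
    c = float(y @ t) / tt
    return w, t, pl, c, W_o, P_o, T_o, E


def fit_oplsda(
    X: np.ndarray,
    y: np.ndarray,
    n_pred: int = 1,
    n_orth: int = 2,
    scaling: str = "uv",
    cv_folds: int = 7,
    cv_seed: int = 0,
) -> OplsModel:
    """Fit OPLS-DA with one predictive and ``n_orth`` orthogonal components.

    Parameters
    ----------
    X : (n_samples, n_ions) intensity slice (training split).
    y : class labels encoded +1 (case) / -1 (control); any two-valued
        vector is re-encoded internally.
    scaling : 'uv' (unit variance, default), 'pareto' or 'none'; X is always
        mean-centred and the preprocessing parameters are stored.
    cv_folds : folds for the Q2 cross-validation (stratified over classes).

    Constant ion columns are dropped with a warning before scaling.
    """
    if n_pred != 1:
        raise ValueError("only a single predictive component is supported")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on the number of samples")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("y must contain exactly two classes")
    y_pm = np.where(y == classes.max(), 1.0, -1.0)
    if min((y_pm == 1).sum(), (y_pm == -1).sum()) < 3:
        raise ValueError("need at least 3 samples per group")
    if X.shape[0] < n_orth + 2:
        raise ValueError("fewer samples than requested components")

    keep = np.flatnonzero(X.std(axis=0, ddof=1) > 0)
    if keep.size < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - keep.size} constant ion columns before scaling",
            RuntimeWarning,
            stacklevel=2,
        )
    if keep.size == 0:
        raise ValueError("all ion columns are constant")
    Xk = X[:, keep]

    x_mean = Xk.mean(axis=0)
    x_scale = _scale_vectors(Xk, scaling)
    x_scale = np.where(x_scale > 0, x_scale, 1.0)
    E0 = (Xk - x_mean) / x_scale
    y_mean = float(y_pm.mean())
    yc = y_pm - y_mean

    w, t, pl, c, W_o, P_o, T_o, E_final = _fit_opls_core(E0, yc, n_orth)

    ssx = float((E0**2).sum())
    modelled = float((np.outer(t, pl) ** 2).sum())
    for j in range(T_o.shape[1]):
        modelled += float((np.outer(T_o[:, j], P_o[:, j]) ** 2).sum())
    r2x = modelled / ssx if ssx > 0 else 0.0

    ssy = float((yc**2).sum())
    resid_y = yc - t * c
    r2y = 1.0 - float(resid_y @ resid_y) / ssy if ssy > 0 else 0.0

    q2 = _q2_cv(Xk, y_pm, n_orth, scaling, cv_folds, cv_seed)

    return OplsModel(
        x_mean=x_mean,
        x_scale=x_scale,
        kept_columns=keep,
        y_mean=y_mean,
        predictive_scores=t,
        predictive_weights=w,
        predictive_loadings=pl,
        y_loading=c,
        orthogonal_scores=T_o,
        orthogonal_weights=W_o,
        orthogonal_loadings=P_o,
        r2x_cum=r2x,
        r2y_cum=r2y,
        q2_cum=q2,
    )


def _q2_cv(
    X: np.ndarray, y_pm: np.ndarray, n_orth: int, scaling: str,
    cv_folds: int, cv_seed: int,
) -> float:
    """Q2 by stratified k-fold cross-validated prediction of y."""
    n = X.shape[0]
    rng = np.random.default_rng(cv_seed)
    folds = np.empty(n, dtype=int)
    for cls in (1.0, -1.0):
        idx = rng.permutation(np.flatnonzero(y_pm == cls))
        folds[idx] = np.arange(idx.size) % cv_folds
    press = 0.0
    yc_all = y_pm - y_pm.mean()
    ss = float(yc_all @ yc_all)
    for f in range(cv_folds):
        tr = folds != f
        te = ~tr
        if not te.any():
            continue
        if min((y_pm[tr] == 1).sum(), (y_pm[tr] == -1).sum()) < 1:
            continue
        Xtr = X[tr]
        keep = np.flatnonzero(Xtr.std(axis=0, ddof=1) > 0)
        mean = Xtr[:, keep].mean(axis=0)
        scale = _scale_vectors(Xtr[:, keep], scaling)
        scale = np.where(scale > 0, scale, 1.0)
        Etr = (Xtr[:, keep] - mean) / scale
        ym = float(y_pm[tr].mean())
        ytr = y_pm[tr] - ym
        try:
            w, t, pl, c, W_o, P_o, _, _ = _fit_opls_core(Etr, ytr, n_orth)
        except ValueError:
            continue
        Ete = (X[te][:, keep] - mean) / scale
        for j in range(W_o.shape[1]):
            t_o = Ete @ W_o[:, j]
            Ete = Ete - np.outer(t_o, P_o[:, j])
        yhat = (Ete @ w) * c + ym
        press += float(((y_pm[te] - yhat) ** 2).sum())
    return 1.0 - press / ss if ss > 0 else 0.0


@dataclass
class LleEmbedding:
    """k-NN reconstruction weights and the 2-D (or d-D) coordinates."""

    k_neighbors: int
    reconstruction_weights: np.ndarray  # (n, n), rows sum to 1, k-sparse
    coordinates: np.ndarray             # (n, d)


def lle_embed(
    X: np.ndarray,
    k: int = 12,
    d: int = 2,
    reg: float = 1e-3,
    standardize: bool = True,
) -> LleEmbedding:
    """Locally linear embedding of samples over the selected candidate ions.

    Neighbours by Euclidean distance; reconstruction weights solve the
    constrained least squares (rows sum to 1) with Tikhonov regularisation
    ``reg * trace(C) / k`` on the local Gram matrix C; the embedding is the
    bottom ``d`` nonconstant eigenvectors of (I-W)'(I-W).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples {n}")
    if k < 1:
        raise ValueError("k must be at least 1")
    if standardize:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    dist = cdist(X, X)
    np.fill_diagonal(dist, np.inf)
    # stable k-NN: sort distances, ties broken by index
    neighbors = np.argsort(dist, axis=1, kind="stable")[:, :k]

    W = np.zeros((n, n))
    for i in range(n):
        nb = neighbors[i]
        Z = X[nb] - X[i]
        C = Z @ Z.T
        trace = np.trace(C)
        C = C + np.eye(k) * (reg * trace / k if trace > 0 else reg)
        w = linalg.solve(C, np.ones(k), assume_a="pos")
        W[i, nb] = w / w.sum()

    M = (np.eye(n) - W).T @ (np.eye(n) - W)
    vals, vecs = linalg.eigh(M)
    # skip the bottom (constant) eigenvector; take the next d
    coords = vecs[:, 1 : d + 1]
    return LleEmbedding(k_neighbors=k, reconstruction_weights=W, coordinates=coords)
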
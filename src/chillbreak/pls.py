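"""Partial least squares regression (PLS1, NIPALS) with VIP scores.

Used to regress bloom dates on daily chill/heat accumulation profiles.
Predictors are centred and scaled to unit sample variance; the response is
centred.  Zero-variance predictor columns (e.g. autumn days with no chill
accumulation anywhere in the record) are excluded from the fit and get
coefficient 0 and VIP 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSResult", "nipals_pls", "vip_scores"]

_EPS = 1e-12


@dataclass
class PLSResult:
    """Fitted PLS1 model on centred/scaled predictors and centred response.

    ``coefficients`` are the regression weights B such that
    ``y_centred ≈ X_scaled @ B``; ``vip`` are variable-importance-in-
    projection scores (mean VIP² over informative predictors is 1 by
    construction, so VIP > 0.8 is the usual importance cut-off).
    """

    coefficients: np.ndarray
    vip: np.ndarray
    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    valid: np.ndarray = field(repr=False)  # non-zero-variance column mask
    x_weights: np.ndarray = field(repr=False)  # W (p_valid × A), unit columns
    x_scores: np.ndarray = field(repr=False)  # T (n × A)
    x_loadings: np.ndarray = field(repr=False)  # P (p_valid × A)
    y_loadings: np.ndarray = field(repr=False)  # q (A,)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xs = (X[:, self.valid] - self.x_mean[self.valid]) / self.x_scale[self.valid]
        return self.y_mean + Xs @ self.coefficients[self.valid]


def nipals_pls(X, y, n_components: int = 2) -> PLSResult:
    """Fit a PLS1 regression by the NIPALS algorithm.

    Components are extracted greedily: the weight vector ``w_a`` maximises
    covariance between the X-score ``t_a = X w_a`` and the residual
    response; X and y are deflated after each component.  Extraction stops
    early when the residual covariance vanishes (e.g. a constant response
    yields zero components and an all-zero coefficient vector).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be (n, p) with y of length n")
    n, p = X.shape
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=1) if n > 1 else np.zeros(p)
    valid = x_std > _EPS
    p_valid = int(valid.sum())
    max_rank = min(n - 1, p_valid)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds the maximum rank {max_rank}"
        )
    y_mean = float(y.mean())

    Xw = (X[:, valid] - x_mean[valid]) / x_std[valid]
    yw = y - y_mean

    W = np.zeros((p_valid, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p_valid, n_components))
    q = np.zeros(n_components)
    Xd, yd = Xw.copy(), yw.copy()
    a = 0
    for a in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < _EPS:
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < _EPS:
            break
        P[:, a] = Xd.T @ t / tt
        q[a] = float(yd @ t) / tt
        W[:, a] = w
        T[:, a] = t
        Xd = Xd - np.outer(t, P[:, a])
        yd = yd - q[a] * t
        a += 1
    n_used = a
    W, T, P, q = W[:, :n_used], T[:, :n_used], P[:, :n_used], q[:n_used]

    coef = np.zeros(p)
    vip = np.zeros(p)
    if n_used > 0:
        coef[valid] = W @ np.linalg.solve(P.T @ W, q)
        vip[valid] = vip_scores(W, T, q, p_valid)
    return PLSResult(
        coefficients=coef,
        vip=vip,
        n_components=n_used,
        x_mean=x_mean,
        x_scale=np.where(valid, x_std, 1.0),
        y_mean=y_mean,
        valid=valid,
        x_weights=W,
        x_scores=T,
        x_loadings=P,
        y_loadings=q,
    )


def vip_scores(W: np.ndarray, T: np.ndarray, q: np.ndarray, p: int) -> np.ndarray:
    """Variable importance in projection.

    ``VIP_j = sqrt( p · Σ_a SSY_a (w_ja / ‖w_a‖)² / Σ_a SSY_a )`` where
    ``SSY_a = q_a² t_aᵀt_a`` is the response variance explained by
    component ``a``.
    """
    ssy = q**2 * np.einsum("ia,ia->a", T, T)
    total = ssy.sum()
    if total < _EPS:
        return np.zeros(W.shape[0])
    wnorm2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    return np.sqrt(p * (wnorm2 @ ssy) / total)
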
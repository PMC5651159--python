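"""Probabilistic principal component analysis fitted by expectation-maximization.

The model ties a p-dimensional observation y to a k-dimensional latent
variable x through

    y = W x + mu + eps,    x ~ N(0, I_k),    eps ~ N(0, v I_p),

so marginally y ~ N(mu, W W^T + v I).  Classical PCA is the v -> 0
limit.  The residual variance v must stay positive, which requires the
latent dimension k to be smaller than the data rank.

Fitting maximises the marginal log-likelihood by EM.  With complete
data the iteration is carried out exactly in the r = min(n, p)
dimensional eigenbasis of the sample covariance (one thin SVD up
front), so each sweep costs O(p r k) regardless of p — this is what
makes 13 components on 1024-dimensional wavelet features cheap.  With
missing entries (NaN) the EM treats them as additional latent
variables and loops over samples.

The returned loadings are orthogonalised by SVD for reporting; only
their span is identifiable (W is free up to a right rotation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

_LOG2PI = np.log(2.0 * np.pi)
_V_FLOOR = 1e-15  # keeps the likelihood finite when data are exactly low-rank


@dataclass
class PPCAModel:
    W: np.ndarray            # p x k orthogonalised loadings
    mu: np.ndarray           # p-vector mean
    v: float                 # residual (isotropic) variance
    k: int
    p: int
    loglik_trace: np.ndarray  # per-iteration observed-data log-likelihood
    n_iter: int
    converged: bool
    tol: float
    seed: int
    explained_variance_ratio: float = float("nan")

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def _validate_k(n: int, p: int, k: int) -> None:
    limit = min(n - 1, p)
    if not 1 <= k < limit:
        raise ValueError(
            f"latent dimension k={k} must satisfy 1 <= k < min(n-1, p) = {limit}: "
            "the residual variance v must remain greater than 0, so k has to be "
            "smaller than the data rank"
        )


def fit_ppca(
    X: np.ndarray,
    k: int = 13,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
) -> PPCAModel:
    """Fit the PPCA model by EM.

    Missing entries may be encoded as NaN; they are handled by the
    missing-data EM.  Convergence is declared when the absolute
    log-likelihood improvement drops below ``tol``; running out of
    iterations sets ``converged=False`` on the model (a warning flag,
    not an error).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be an n x p matrix")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two samples")
    missing = np.isnan(X)
    if np.any(np.isinf(X)):
        raise ValueError("X contains infinities")
    _validate_k(n, p, k)

    if missing.any():
        return _fit_em_missing(X, missing, k, tol, max_iter, seed)
    return _fit_em_complete(X, k, tol, max_iter, seed)


def _init_W(p: int, k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return 0.01 * rng.standard_normal((p, k))


def _finalize(W, mu, v, k, p, trace, n_iter, converged, tol, seed, total_var) -> PPCAModel:
    # orthogonalise for reporting; the span is what is identifiable
    U, s, _ = np.linalg.svd(W, full_matrices=False)
    W_orth = U * s
    evr = float("nan")
    if total_var > 0:
        evr = float(np.sum(s**2) / total_var)
    return PPCAModel(
        W=W_orth, mu=mu, v=float(v), k=k, p=p,
        loglik_trace=np.asarray(trace), n_iter=n_iter, converged=converged,
        tol=tol, seed=seed, explained_variance_ratio=evr,
    )


def _fit_em_complete(X, k, tol, max_iter, seed) -> PPCAModel:
    n, p = X.shape
    mu = X.mean(axis=0)
    Xc = X - mu
    # thin SVD: sample covariance S = U diag(lam) U^T with r = min(n, p)
    U, sv, _ = np.linalg.svd(Xc.T, full_matrices=False)
    lam = sv**2 / n
    tr_S = float(lam.sum())

    W0 = _init_W(p, k, seed)
    B = U.T @ W0                      # coordinates of W in the eigenbasis
    G = W0.T @ W0                     # W^T W (init W has an out-of-basis part)
    v = tr_S / p                      # mean per-feature variance

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        M = G + v * np.eye(k)
        # observed-data log-likelihood at the current (W, v)
        WtSW = B.T @ (lam[:, None] * B)
        Minv = np.linalg.inv(M)
        logdet_C = (p - k) * np.log(v) + np.linalg.slogdet(M)[1]
        tr_CinvS = (tr_S - np.trace(Minv @ WtSW)) / v
        ll = -0.5 * n * (p * _LOG2PI + logdet_C + tr_CinvS)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        # EM sweep (Tipping-Bishop), expressed in the eigenbasis
        SW = lam[:, None] * B                      # S W
        B_new = SW @ np.linalg.inv(v * np.eye(k) + Minv @ WtSW)
        v = max((tr_S - np.trace((Minv @ B_new.T) @ SW)) / p, _V_FLOOR)
        B = B_new
        G = B.T @ B                                # W now lies in the eigenbasis

    W = U @ B
    return _finalize(W, mu, v, k, p, trace, it, converged, tol, seed, tr_S)


def _fit_em_missing(X, missing, k, tol, max_iter, seed) -> PPCAModel:
    n, p = X.shape
    obs = ~missing
    if not obs.any(axis=0).all():
        raise ValueError("every feature must be observed at least once")
    if not obs.any(axis=1).all():
        raise ValueError("every sample must have at least one observed entry")

    mu = np.where(obs, X, 0.0).sum(axis=0) / obs.sum(axis=0)
    col_var = np.nanvar(X, axis=0)
    total_var = float(col_var.sum())
    W = _init_W(p, k, seed)
    v = max(total_var / p, 1e-6)

    Ik = np.eye(k)
    # group samples by missingness pattern so the E-step runs batched
    pattern_groups: dict[bytes, np.ndarray] = {}
    for i in range(n):
        pattern_groups.setdefault(obs[i].tobytes(), []).append(i)
    groups = [(obs[idx[0]], np.asarray(idx)) for idx in
              (v_ for v_ in pattern_groups.values())]

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: posterior moments of x_i given the observed part of y_i
        xbar = np.zeros((n, k))
        Sx = np.zeros((n, k, k))
        ll = 0.0
        for o, idx in groups:
            Wo = W[o]
            Yo = X[np.ix_(idx, np.flatnonzero(o))] - mu[o]
            Mo = Wo.T @ Wo + v * Ik
            Mo_inv = np.linalg.inv(Mo)
            xb = Yo @ Wo @ Mo_inv
            xbar[idx] = xb
            Sx[idx] = v * Mo_inv
            # observed-data log-likelihood via the matrix-inversion lemma
            d = int(o.sum())
            logdet_C = (d - k) * np.log(v) + np.linalg.slogdet(Mo)[1]
            quad = ((Yo * Yo).sum() - np.einsum("ij,ij->", Yo @ Wo @ Mo_inv, Yo @ Wo)) / v
            ll += -0.5 * (len(idx) * (d * _LOG2PI + logdet_C) + quad)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

        # M-step: per-feature rows of W decouple over its observed samples
        mu_new = np.empty(p)
        W_new = np.empty_like(W)
        second = Sx + xbar[:, :, None] * xbar[:, None, :]
        for j in range(p):
            rows = obs[:, j]
            xb = xbar[rows]
            resid = X[rows, j] - xb @ W[j]
            mu_new[j] = resid.mean()
            A = second[rows].sum(axis=0)
            b = (X[rows, j] - mu_new[j]) @ xb
            W_new[j] = np.linalg.solve(A, b)
        # residual variance over all observed entries
        num = 0.0
        for j in range(p):
            rows = obs[:, j]
            xb = xbar[rows]
            e = X[rows, j] - xb @ W_new[j] - mu_new[j]
            num += float(e @ e) + float(
                np.einsum("i,nij,j->", W_new[j], Sx[rows], W_new[j])
            )
        v = max(num / obs.sum(), _V_FLOOR)
        mu, W = mu_new, W_new

    return _finalize(W, mu, v, k, p, trace, it, converged, tol, seed, total_var)


def transform(model: PPCAModel, Y: np.ndarray) -> np.ndarray:
    """Posterior-mean latent scores: (Y - mu) W (W^T W + v I)^{-1}."""
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if Y.shape[1] != model.p:
        raise ValueError(f"Y has {Y.shape[1]} columns, model expects {model.p}")
    M = model.W.T @ model.W + model.v * np.eye(model.k)
    return (Y - model.mu) @ model.W @ np.linalg.inv(M)


def fitted_marginal_cov(model: PPCAModel) -> np.ndarray:
    """The model's marginal covariance W W^T + v I (symmetric PD)."""
    return model.W @ model.W.T + model.v * np.eye(model.p)


def save_model(model: PPCAModel, path: Union[str, Path]) -> None:
    np.savez_compressed(
        path,
        W=model.W, mu=model.mu, v=model.v, k=model.k, p=model.p,
        loglik_trace=model.loglik_trace, n_iter=model.n_iter,
        converged=model.converged, tol=model.tol, seed=model.seed,
        explained_variance_ratio=model.explained_variance_ratio,
    )


def load_model(path: Union[str, Path]) -> PPCAModel:
    with np.load(path, allow_pickle=False) as f:
        return PPCAModel(
            W=f["W"], mu=f["mu"], v=float(f["v"]), k=int(f["k"]), p=int(f["p"]),
            loglik_trace=f["loglik_trace"], n_iter=int(f["n_iter"]),
            converged=bool(f["converged"]), tol=float(f["tol"]), seed=int(f["seed"]),
            explained_variance_ratio=float(f["explained_variance_ratio"]),
        )
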
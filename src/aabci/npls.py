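"""N-way partial least squares (NPLS) tensor regression.

Maps 4-way predictor tensors X (N, tau, f, s) to multivariate
responses Y (N, m) through a sequence of rank-1 multilinear factors:
for each factor a triplet of unit mode weights (w_tau, w_f, w_s) is
obtained as the best rank-1 approximation of the covariance tensor
between the centered predictors and the current response residual,
sample scores are the inner products of the centered tensors with
the rank-1 weight tensor, and the response is regressed on all
accumulated scores (deflation on Y only).

Two equivalent fitting paths are provided:

* :func:`npls_fit` works on the data arrays directly (no p x p
  matrices; preferred for batch training);
* :func:`fit_from_moments` works on second-moment accumulations
  (X'X, X'Y, sums); it is the engine behind the recursive
  exponentially weighted variant in :mod:`aabci.rew`.

For a univariate response and singleton tau/f modes the procedure
reduces to standard PLS1 (NIPALS), which serves as an external
cross-check in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_ALS_TOL = 1e-9
_ALS_MAX_ITER = 100
_Q_TOL = 1e-10
_Q_MAX_ITER = 100


@dataclass
class NplsModel:
    """Fitted NPLS regression model.

    Attributes
    ----------
    mode_shapes : (tau, f, s)
    n_factors : number of extracted factors (may be fewer than
        requested if the covariance tensor vanished early)
    w_tau, w_f, w_s : per-factor unit mode weights, shapes
        (n_factors, tau) / (n_factors, f) / (n_factors, s)
    coefs : list, coefs[k-1] has shape (k, m): regression map from
        the first k scores to the centered response.  Storing the
        whole path makes prediction with any truncated factor count
        cheap, which the recursive variant relies on.
    x_mean : (tau, f, s) stored predictor mean
    y_mean : (m,) stored response mean
    """

    mode_shapes: tuple[int, int, int]
    n_factors: int
    w_tau: np.ndarray
    w_f: np.ndarray
    w_s: np.ndarray
    coefs: list[np.ndarray]
    x_mean: np.ndarray
    y_mean: np.ndarray

    @property
    def n_targets(self) -> int:
        return self.y_mean.shape[0]

    def weight_vectors(self, n_factors: int | None = None) -> np.ndarray:
        """Flattened rank-1 weight tensors, shape (tau*f*s, k)."""
        k = self.n_factors if n_factors is None else min(n_factors, self.n_factors)
        cols = [
            np.einsum("i,j,k->ijk", self.w_tau[j], self.w_f[j], self.w_s[j]).ravel()
            for j in range(k)
        ]
        if not cols:
            return np.zeros((int(np.prod(self.mode_shapes)), 0))
        return np.stack(cols, axis=1)


def _hosvd_init(Z: np.ndarray) -> list[np.ndarray]:
    """Leading singular vector of each unfolding (sign fixed: first
    non-zero component positive) -- the ALS initializer."""
    ws = []
    for mode in range(3):
        mat = np.moveaxis(Z, mode, 0).reshape(Z.shape[mode], -1)
        u, _, _ = np.linalg.svd(mat, full_matrices=False)
        w = u[:, 0]
        nz = np.flatnonzero(np.abs(w) > 0)
        if nz.size and w[nz[0]] < 0:
            w = -w
        ws.append(w)
    return ws


def _als_sweep(Z: np.ndarray, ws: list[np.ndarray]) -> float:
    """One in-place ALS sweep over the three modes; returns the core
    value g = <Z, w1 o w2 o w3> (non-decreasing over sweeps)."""
    for mode, spec in enumerate(("ijk,j,k->i", "ijk,i,k->j", "ijk,i,j->k")):
        others = [ws[m] for m in range(3) if m != mode]
        v = np.einsum(spec, Z, *others)
        nrm = np.linalg.norm(v)
        if nrm == 0:
            return 0.0
        ws[mode] = v / nrm
    return float(np.einsum("ijk,i,j,k->", Z, *ws))


def _fix_signs(ws: list[np.ndarray]) -> None:
    # sign convention: first non-zero component of the time and
    # frequency weights positive, signs absorbed into the channel mode
    for mode in range(2):
        nz = np.flatnonzero(np.abs(ws[mode]) > 0)
        if nz.size and ws[mode][nz[0]] < 0:
            ws[mode] = -ws[mode]
            ws[2] = -ws[2]


def _rank1_als(Z: np.ndarray, tol: float = _ALS_TOL, max_iter: int = _ALS_MAX_ITER):
    """Best rank-1 approximation of a 3-way tensor by ALS from the
    HOSVD initializer; converged when the relative change of the core
    value drops below ``tol``."""
    ws = _hosvd_init(Z)
    g_old = np.einsum("ijk,i,j,k->", Z, *ws)
    for _ in range(max_iter):
        g = _als_sweep(Z, ws)
        if g == 0.0 or abs(g - g_old) <= tol * max(abs(g), 1e-30):
            break
        g_old = g
    _fix_signs(ws)
    g = float(np.einsum("ijk,i,j,k->", Z, *ws))
    return ws[0], ws[1], ws[2], g


def _extract_factor(C: np.ndarray, shapes: tuple[int, int, int]):
    """One NPLS factor from a (p, m) covariance matrix.

    For a univariate response the factor is the converged rank-1 ALS
    approximation of the covariance tensor.  For multivariate
    responses the response direction q and the mode weights are
    iterated jointly (one ALS sweep per q exchange, the standard
    NIPALS interleave), initialized from the covariance-dominant
    response column and the HOSVD of its tensor.
    """
    m = C.shape[1]
    q = _init_q(C)
    if m == 1:
        wt, wf, wsv, _ = _rank1_als(C[:, 0].reshape(shapes))
        w = np.einsum("i,j,k->ijk", wt, wf, wsv).ravel()
        return wt, wf, wsv, w
    ws = _hosvd_init((C @ q).reshape(shapes))
    g_old = np.inf
    for _ in range(_Q_MAX_ITER):
        Z = (C @ q).reshape(shapes)
        g = _als_sweep(Z, ws)
        w = np.einsum("i,j,k->ijk", *ws).ravel()
        qn = C.T @ w
        nrm = np.linalg.norm(qn)
        if nrm == 0:
            break
        qn = qn / nrm
        moved = np.linalg.norm(qn - q)
        q = qn
        if moved < _Q_TOL and abs(g - g_old) <= _ALS_TOL * max(abs(g), 1e-30):
            break
        g_old = g
    _fix_signs(ws)
    w = np.einsum("i,j,k->ijk", *ws).ravel()
    return ws[0], ws[1], ws[2], w


def _init_q(C: np.ndarray) -> np.ndarray:
    """Initial Y-score direction: response column with the largest
    covariance energy (deterministic, shared by both fitting paths)."""
    j = int(np.argmax(np.linalg.norm(C, axis=0)))
    q = np.zeros(C.shape[1])
    q[j] = 1.0
    return q


def npls_fit(X: np.ndarray, Y: np.ndarray, n_factors: int) -> NplsModel:
    """Fit an NPLS model on raw data arrays.

    Parameters
    ----------
    X : ndarray, shape (N, tau, f, s)
    Y : ndarray, shape (N, m) or (N,)
    n_factors : requested number of factors F (must satisfy F < N)
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim != 4:
        raise ValueError("X must be a 4-way array (N, tau, f, s)")
    N = X.shape[0]
    if Y.shape[0] != N:
        raise ValueError("X and Y disagree on the number of samples")
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    if n_factors >= N:
        raise ValueError(f"n_factors={n_factors} must be smaller than N={N}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite entries in X or Y")
    if np.allclose(Y.std(axis=0), 0.0):
        raise ValueError("zero-variance response: nothing to regress on")

    shapes = X.shape[1:]
    p = int(np.prod(shapes))
    Xm = X.reshape(N, p)
    x_mean = Xm.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = Xm - x_mean
    Yc = Y - y_mean
    m = Y.shape[1]

    Yres = Yc.copy()
    W = np.empty((p, 0))
    T = np.empty((N, 0))
    w_tau, w_f, w_s, coefs = [], [], [], []
    for _ in range(n_factors):
        C = Xc.T @ Yres  # (p, m) covariance with current residual
        if np.linalg.norm(C) < 1e-14:
            break
        wt, wf, wsv, w = _extract_factor(C, shapes)
        t = Xc @ w
        W = np.hstack([W, w[:, None]])
        T = np.hstack([T, t[:, None]])
        B, *_ = np.linalg.lstsq(T, Yc, rcond=None)
        w_tau.append(wt)
        w_f.append(wf)
        w_s.append(wsv)
        coefs.append(B)
        Yres = Yc - T @ B

    return NplsModel(
        mode_shapes=tuple(shapes),
        n_factors=len(coefs),
        w_tau=np.array(w_tau).reshape(len(coefs), shapes[0]),
        w_f=np.array(w_f).reshape(len(coefs), shapes[1]),
        w_s=np.array(w_s).reshape(len(coefs), shapes[2]),
        coefs=coefs,
        x_mean=x_mean.reshape(shapes),
        y_mean=y_mean,
    )


def fit_from_moments(
    sxx_c: np.ndarray,
    sxy_c: np.ndarray,
    x_mean: np.ndarray,
    y_mean: np.ndarray,
    mode_shapes: tuple[int, int, int],
    n_factors: int,
) -> NplsModel:
    """Fit an NPLS model from centered second-moment matrices.

    Parameters
    ----------
    sxx_c : (p, p) centered Gram matrix  sum_n xc_n xc_n'
    sxy_c : (p, m) centered cross-moments sum_n xc_n yc_n'
    x_mean, y_mean : stored means
    mode_shapes : (tau, f, s) with tau*f*s == p

    The factor sequence, score-space normal equations and Y-only
    deflation are algebraically identical to :func:`npls_fit`; with
    exact batch moments the two paths produce the same model up to
    floating-point noise.
    """
    p = sxx_c.shape[0]
    m = sxy_c.shape[1]
    W = np.empty((p, 0))
    w_tau, w_f, w_s, coefs = [], [], [], []
    Cres = sxy_c.copy()
    for _ in range(n_factors):
        if np.linalg.norm(Cres) < 1e-14:
            break
        wt, wf, wsv, w = _extract_factor(Cres, mode_shapes)
        W = np.hstack([W, w[:, None]])
        SW = sxx_c @ W  # (p, k)
        G = W.T @ SW  # score-space normal equations T'T
        H = W.T @ sxy_c  # T'Yc
        B, *_ = np.linalg.lstsq(G, H, rcond=None)
        w_tau.append(wt)
        w_f.append(wf)
        w_s.append(wsv)
        coefs.append(B)
        Cres = sxy_c - SW @ B

    return NplsModel(
        mode_shapes=tuple(mode_shapes),
        n_factors=len(coefs),
        w_tau=np.array(w_tau).reshape(len(coefs), mode_shapes[0]),
        w_f=np.array(w_f).reshape(len(coefs), mode_shapes[1]),
        w_s=np.array(w_s).reshape(len(coefs), mode_shapes[2]),
        coefs=coefs,
        x_mean=np.asarray(x_mean, dtype=float).reshape(mode_shapes),
        y_mean=np.asarray(y_mean, dtype=float),
    )


def rank1_tensor_regression(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Exact single-component multilinear regression by ALS.

    Minimizes ``||y_c - b <X_c, u o v o w>||^2`` over unit mode
    vectors (u, v, w) and the scalar slope b, alternating exact
    least-squares solves per mode from the NPLS factor as the
    initializer.  For data generated noiselessly from a rank-1 weight
    tensor this recovers the generating mode vectors (up to paired
    sign flips), which the covariance-based PLS factor only
    approximates at finite N.

    Returns ``(u, v, w, b)`` with unit-norm mode vectors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    N = X.shape[0]
    shapes = X.shape[1:]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    init = npls_fit(X, y, 1)
    ws = [init.w_tau[0].copy(), init.w_f[0].copy(), init.w_s[0].copy()]
    prev = np.inf
    for _ in range(max_iter):
        for mode in range(3):
            others = [ws[m] for m in range(3) if m != mode]
            idx = [m + 1 for m in range(3) if m != mode]
            A = np.tensordot(
                np.tensordot(Xc, others[1], axes=([idx[1]], [0])),
                others[0],
                axes=([idx[0]], [0]),
            )  # (N, d_mode): y ~ A @ (b * w_mode)
            sol, *_ = np.linalg.lstsq(A, yc, rcond=None)
            nrm = np.linalg.norm(sol)
            if nrm == 0:
                break
            ws[mode] = sol / nrm
        t = np.einsum("nijk,i,j,k->n", Xc, *ws)
        b = float(t @ yc / (t @ t)) if t @ t > 0 else 0.0
        sse = float(np.sum((yc - b * t) ** 2))
        if prev - sse <= tol * max(prev, 1e-30):
            break
        prev = sse
    for mode in range(2):
        nz = np.flatnonzero(np.abs(ws[mode]) > 0)
        if nz.size and ws[mode][nz[0]] < 0:
            ws[mode] = -ws[mode]
            ws[2] = -ws[2]
    t = np.einsum("nijk,i,j,k->n", Xc, *ws)
    b = float(t @ yc / (t @ t)) if t @ t > 0 else 0.0
    return ws[0], ws[1], ws[2], b


def npls_predict(
    model: NplsModel, X: np.ndarray, n_factors: int | None = None
) -> np.ndarray:
    """Predict responses for a stack of tensors.

    Parameters
    ----------
    model : fitted :class:`NplsModel`
    X : ndarray, shape (N, tau, f, s) matching the model's modes
    n_factors : optionally truncate the factor sequence (capped at
        the model's extracted count); with 0 factors the prediction
        is the stored response mean.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 3:
        X = X[None]
    if X.shape[1:] != model.mode_shapes:
        raise ValueError(
            f"mode-size mismatch: data {X.shape[1:]} vs model {model.mode_shapes}"
        )
    k = model.n_factors if n_factors is None else min(n_factors, model.n_factors)
    N = X.shape[0]
    if k == 0:
        return np.tile(model.y_mean, (N, 1))
    Xc = X.reshape(N, -1) - model.x_mean.ravel()
    T = Xc @ model.weight_vectors(k)
    return T @ model.coefs[k - 1] + model.y_mean
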
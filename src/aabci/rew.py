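"""Recursive exponentially weighted NPLS (REW-NPLS).

Maintains constant-memory sufficient statistics (weighted sums,
cross-moments and the Gram matrix of flattened predictor tensors)
with a forgetting factor ``lam``; after each mini-batch update the
full NPLS model is re-extracted from the statistics for every
candidate factor count 1..f_max, and the operating factor count
``f_star`` is re-selected by a prequential (test-then-train)
squared-error estimate: each incoming batch is scored with the
*previous* model before it is absorbed, so the error estimate is an
honest out-of-sample quantity.

With ``lam = 1`` the statistics are exact batch accumulations, and a
single update from the zero-initialized state reproduces the batch
NPLS fit -- the module's primary oracle.

The state before any update predicts the zero vector (decoders are
started "from scratch" in the auto-adaptive loop).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .npls import NplsModel, fit_from_moments, npls_predict


@dataclass
class RewNplsState:
    mode_shapes: tuple[int, int, int]
    n_targets: int
    lam: float = 1.0
    err_lam: float = 0.9
    f_max: int = 20
    n_eff: float = 0.0
    sx: np.ndarray = None  # (p,)   weighted sum of x
    sy: np.ndarray = None  # (m,)   weighted sum of y
    sxy: np.ndarray = None  # (p, m) weighted sum of x y'
    sxx: np.ndarray = None  # (p, p) weighted sum of x x'
    val_errors: np.ndarray = None  # (f_max,) prequential error sums
    val_weight: float = 0.0
    f_star: int = 1
    n_updates: int = 0
    model: NplsModel | None = None

    @property
    def p(self) -> int:
        return int(np.prod(self.mode_shapes))


def rew_init(
    mode_shapes: tuple[int, int, int],
    n_targets: int,
    lam: float = 1.0,
    f_max: int = 20,
    err_lam: float = 0.9,
) -> RewNplsState:
    """Zero-initialized recursive decoder state.

    ``lam`` is the forgetting factor of the sufficient statistics in
    (0, 1] (1 = no forgetting); ``f_max`` the largest candidate factor
    count; ``err_lam`` the forgetting factor of the prequential
    factor-validation error (kept below 1 by default so factor
    selection tracks the decoder's current quality rather than
    averaging in its untrained early history).
    """
    if not (0.0 < lam <= 1.0):
        raise ValueError("forgetting factor lam must lie in (0, 1]")
    if not (0.0 < err_lam <= 1.0):
        raise ValueError("forgetting factor err_lam must lie in (0, 1]")
    if f_max < 1:
        raise ValueError("f_max must be >= 1")
    p = int(np.prod(mode_shapes))
    return RewNplsState(
        mode_shapes=tuple(mode_shapes),
        n_targets=int(n_targets),
        lam=float(lam),
        err_lam=float(err_lam),
        f_max=int(f_max),
        sx=np.zeros(p),
        sy=np.zeros(n_targets),
        sxy=np.zeros((p, n_targets)),
        sxx=np.zeros((p, p)),
        val_errors=np.zeros(f_max),
    )


def rew_predict(state: RewNplsState, X: np.ndarray) -> np.ndarray:
    """Predict with the current model at the selected factor count.

    Before the first update the output is the zero vector for any
    input.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 3:
        X = X[None]
    if X.shape[1:] != state.mode_shapes:
        raise ValueError(
            f"mode-size mismatch: data {X.shape[1:]} vs state {state.mode_shapes}"
        )
    if state.model is None:
        return np.zeros((X.shape[0], state.n_targets))
    return npls_predict(state.model, X, n_factors=state.f_star)


def rew_update(state: RewNplsState, X_batch: np.ndarray, Y_batch: np.ndarray) -> RewNplsState:
    """Absorb a labeled mini-batch (in place) and re-extract the model.

    Order of operations: (1) prequential scoring of the batch with the
    previous model for every candidate factor count, with the same
    forgetting applied to the error accumulators; (2) exponential decay
    and augmentation of the sufficient statistics; (3) model
    re-extraction and ``f_star`` re-selection (ties go to the smaller
    count).  An empty batch leaves the state unchanged.
    """
    X_batch = np.asarray(X_batch, dtype=float)
    Y_batch = np.asarray(Y_batch, dtype=float)
    if Y_batch.ndim == 1:
        Y_batch = Y_batch[:, None]
    if X_batch.shape[0] == 0:
        return state
    if X_batch.shape[1:] != state.mode_shapes:
        raise ValueError("batch tensor modes do not match the state")
    if Y_batch.shape != (X_batch.shape[0], state.n_targets):
        raise ValueError("batch label shape does not match the state")

    n = X_batch.shape[0]
    Xm = X_batch.reshape(n, -1)

    # prequential factor validation with the PREVIOUS model
    errs = np.empty(state.f_max)
    for k in range(1, state.f_max + 1):
        if state.model is None:
            pred = np.zeros((n, state.n_targets))
        else:
            pred = npls_predict(state.model, X_batch, n_factors=k)
        errs[k - 1] = np.sum((Y_batch - pred) ** 2)
    state.val_errors = state.err_lam * state.val_errors + errs
    state.val_weight = state.err_lam * state.val_weight + n
    state.f_star = int(np.argmin(state.val_errors)) + 1

    # exponentially weighted sufficient statistics
    lam = state.lam
    state.n_eff = lam * state.n_eff + n
    state.sx = lam * state.sx + Xm.sum(axis=0)
    state.sy = lam * state.sy + Y_batch.sum(axis=0)
    state.sxy = lam * state.sxy + Xm.T @ Y_batch
    state.sxx = lam * state.sxx + Xm.T @ Xm

    x_mean = state.sx / state.n_eff
    y_mean = state.sy / state.n_eff
    sxy_c = state.sxy - np.outer(state.sx, state.sy) / state.n_eff
    sxx_c = state.sxx - np.outer(state.sx, state.sx) / state.n_eff
    state.model = fit_from_moments(
        sxx_c, sxy_c, x_mean, y_mean, state.mode_shapes, state.f_max
    )
    state.f_star = min(state.f_star, max(state.model.n_factors, 1))
    state.n_updates += 1
    return state
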
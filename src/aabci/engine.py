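"""The auto-adaptive loop: certainty gating and label estimation.

The cMTP decoder's continuous output on its own training set is
modeled as a mixture of two Gaussians, one per correctness class.
Inclusion thresholds are placed one (configurable ``a``) standard
deviation into each tail:

    th_corr = mu_corr + a * sigma_corr
    th_err  = mu_err  - a * sigma_err

During free use, an epoch whose score exceeds ``th_corr`` is treated
as certainly correct, one below ``th_err`` as certainly erroneous,
and everything in between is dropped.  Accepted epochs are relabeled
into control-decoder training targets:

* phi1 (discrete): dummy encoding of the control decoder's most
  probable class if correct, of its second most probable class if
  erroneous;
* phi2 (continuous): the control decoder's output itself, correct
  epochs only.

Because only the tails of the two score distributions are kept, the
accuracy of the correctness calls among accepted epochs exceeds the
decoder's unconditional accuracy -- the mechanism that makes the
estimated labels good enough to train a control decoder.

:func:`run_pseudo_online` replays a recorded session stream in time
order, gates and relabels each epoch, and updates a REW-NPLS control
decoder every quantum of labeled data (150 epochs = 15 s), comparing
three conditions: supervised (true labels), auto-adaptive (estimated
labels), and shuffled-cMTP (estimated labels with the correctness
scores permuted; the chance control).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
import warnings

import numpy as np
import pandas as pd

from .cmtp import DISCARD, cmtp_scores, label_epochs
from .npls import NplsModel
from .rew import RewNplsState, rew_predict, rew_update
from .simulator import SessionStream, angular_deviation_deg


class Gate(Enum):
    CORRECT = 1
    ERROR = 0
    DISCARD = -1


@dataclass
class ThresholdPair:
    """Per-class Gaussian fits of the cMTP score and the derived
    inclusion thresholds."""

    mu_err: float
    sigma_err: float
    mu_corr: float
    sigma_corr: float
    a: float = 1.0

    @property
    def th_err(self) -> float:
        return self.mu_err - self.a * self.sigma_err

    @property
    def th_corr(self) -> float:
        return self.mu_corr + self.a * self.sigma_corr

    @property
    def usable(self) -> bool:
        return self.th_err < self.th_corr


def fit_thresholds(
    scores: np.ndarray, labels: np.ndarray, a: float = 1.0
) -> ThresholdPair:
    """Fit the two-Gaussian certainty model on cMTP training scores.

    ``labels`` are the true binary correctness labels of the training
    set; per class the sample mean and standard deviation are taken.
    A zero-variance class is accepted with a warning (its threshold
    collapses onto the mean).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    err = scores[labels == 0]
    corr = scores[labels == 1]
    if err.size < 2 or corr.size < 2:
        raise ValueError("need at least two samples of each correctness class")
    pair = ThresholdPair(
        mu_err=float(err.mean()),
        sigma_err=float(err.std(ddof=0)),
        mu_corr=float(corr.mean()),
        sigma_corr=float(corr.std(ddof=0)),
        a=float(a),
    )
    if pair.sigma_err == 0.0 or pair.sigma_corr == 0.0:
        warnings.warn("zero-variance correctness class: threshold collapses to the mean")
    return pair


def gate(score: float, thr: ThresholdPair) -> Gate:
    """Three-way certainty gate (strict inequalities; boundary scores
    are discarded).  With degenerate thresholds (th_err >= th_corr)
    every sample is discarded and a warning is emitted."""
    if not thr.usable:
        warnings.warn("degenerate thresholds (th_err >= th_corr): discarding all samples")
        return Gate.DISCARD
    if score > thr.th_corr:
        return Gate.CORRECT
    if score < thr.th_err:
        return Gate.ERROR
    return Gate.DISCARD


def gate_array(scores: np.ndarray, thr: ThresholdPair) -> np.ndarray:
    """Vectorized gate; returns int codes (1 correct, 0 error, -1 discard)."""
    scores = np.asarray(scores, dtype=float)
    out = np.full(len(scores), Gate.DISCARD.value, dtype=int)
    if not thr.usable:
        warnings.warn("degenerate thresholds (th_err >= th_corr): discarding all samples")
        return out
    out[scores > thr.th_corr] = Gate.CORRECT.value
    out[scores < thr.th_err] = Gate.ERROR.value
    return out


def relabel_phi1(
    score: float, control_scores: np.ndarray, thr: ThresholdPair
) -> np.ndarray | None:
    """Discrete relabeling: one-hot of the most probable class when
    estimated correct, of the second most probable class when
    estimated erroneous, None otherwise.  Argmax ties break to the
    lowest class index."""
    control_scores = np.asarray(control_scores, dtype=float)
    m = control_scores.shape[0]
    if m < 2:
        raise ValueError("phi1 needs at least two classes")
    g = gate(score, thr)
    if g is Gate.DISCARD:
        return None
    order = np.argsort(-control_scores, kind="stable")
    cls = order[0] if g is Gate.CORRECT else order[1]
    label = np.zeros(m)
    label[cls] = 1.0
    return label


def relabel_phi2(
    score: float, control_output: np.ndarray, thr: ThresholdPair
) -> np.ndarray | None:
    """Continuous relabeling: the control output itself for epochs
    estimated correct; erroneous and ambiguous epochs are dropped.
    A zero control output, if accepted, is kept as-is (documented
    hazard: it contributes a zero training target)."""
    if gate(score, thr) is not Gate.CORRECT:
        return None
    return np.asarray(control_output, dtype=float).copy()


def _true_labels(stream: SessionStream) -> np.ndarray:
    """Supervised control-decoder targets from telemetry: dummy-encoded
    desired state (discrete) or the directed cursor-to-target distance
    (continuous)."""
    if stream.paradigm == "discrete":
        desired = np.asarray(stream.telemetry["desired_class"], dtype=int)
        m = stream.config.n_classes
        Y = np.zeros((len(desired), m))
        Y[np.arange(len(desired)), desired] = 1.0
        return Y
    tx = stream.telemetry["target_x"] - stream.telemetry["cursor_x"]
    ty = stream.telemetry["target_y"] - stream.telemetry["cursor_y"]
    return np.column_stack([tx, ty])


def _recorded_control_outputs(stream: SessionStream) -> np.ndarray:
    """Control-decoder outputs that actually drove the effector during
    acquisition (the outputs the user's perceived-correctness signal
    refers to)."""
    if stream.paradigm == "discrete":
        return np.asarray(stream.telemetry["control_scores"], dtype=float)
    return np.column_stack(
        [stream.telemetry["control_x"], stream.telemetry["control_y"]]
    )


def run_pseudo_online(
    streams: list[SessionStream] | SessionStream,
    cmtp_model: NplsModel,
    mode: str,
    rew_state: RewNplsState,
    thresholds: ThresholdPair | None = None,
    update_quantum: int = 150,
    seed: int = 0,
) -> tuple[RewNplsState, dict]:
    """Replay sessions in time order and train the control decoder.

    Parameters
    ----------
    streams : session(s) to replay, processed in the given order
    cmtp_model : fixed, pre-trained cMTP decoder
    mode : 'supervised' (true labels, every epoch), 'aabci'
        (gated + relabeled estimated labels) or 'shuffled' (as aabci
        but with the cMTP score sequence permuted within each
        session; the chance-level control)
    rew_state : control decoder state, updated in place (pass a
        freshly zero-initialized state to train from scratch)
    thresholds : required in 'aabci'/'shuffled' modes
    update_quantum : labeled epochs per decoder update (150 epochs =
        15 s at the 0.1 s epoch stride)
    seed : RNG seed for the shuffle permutation

    Returns
    -------
    (state, logs) where ``logs`` holds a per-epoch DataFrame
    (prediction made before any update that consumed the epoch, gate
    decision, estimated and true labels) and summary tallies of
    accepted-pool accuracies.
    """
    if isinstance(streams, SessionStream):
        streams = [streams]
    if mode not in ("supervised", "aabci", "shuffled"):
        raise ValueError(f"unknown mode '{mode}'")
    if mode in ("aabci", "shuffled") and thresholds is None:
        raise ValueError(f"mode '{mode}' requires fitted thresholds")
    rng = np.random.default_rng(seed)
    m = rew_state.n_targets

    frames = []
    pending_X: list[np.ndarray] = []
    pending_Y: list[np.ndarray] = []
    n_updates = 0
    update_log = []

    for stream in streams:
        X = stream.features
        if X.shape[1:] != rew_state.mode_shapes:
            raise ValueError("stream feature modes do not match the decoder state")
        Y_true = _true_labels(stream)
        if Y_true.shape[1] != m:
            raise ValueError("stream paradigm does not match the decoder state")
        scores = cmtp_scores(cmtp_model, X)
        gate_scores = scores.copy()
        if mode == "shuffled":
            gate_scores = gate_scores[rng.permutation(len(gate_scores))]
        recorded = _recorded_control_outputs(stream)
        true_cmtp = label_epochs(stream)

        # The estimated labels depend only on the recorded telemetry and
        # the fixed cMTP decoder, never on the decoder being trained, so
        # gate decisions and update boundaries are known up front and
        # predictions can be made segment-wise: every epoch is scored
        # with the state as it was BEFORE any update that consumed it.
        if mode == "supervised":
            codes = np.ones(len(X), dtype=int)
            est = Y_true.copy()
            accepted = np.ones(len(X), dtype=bool)
        else:
            codes = gate_array(gate_scores, thresholds)
            est = np.full((len(X), m), np.nan)
            accepted = np.zeros(len(X), dtype=bool)
            for i in np.flatnonzero(codes != Gate.DISCARD.value):
                if stream.paradigm == "discrete":
                    order = np.argsort(-recorded[i], kind="stable")
                    cls = order[0] if codes[i] == Gate.CORRECT.value else order[1]
                    est[i] = 0.0
                    est[i, cls] = 1.0
                    accepted[i] = True
                elif codes[i] == Gate.CORRECT.value:
                    est[i] = recorded[i]
                    accepted[i] = True

        preds = np.empty((len(X), m))
        update_index = np.empty(len(X), dtype=int)
        seg_start = 0
        for i in range(stream.n_epochs):
            if accepted[i]:
                pending_X.append(X[i])
                pending_Y.append(est[i])
            if len(pending_X) >= update_quantum:
                preds[seg_start : i + 1] = rew_predict(rew_state, X[seg_start : i + 1])
                update_index[seg_start : i + 1] = n_updates
                seg_start = i + 1
                rew_update(rew_state, np.stack(pending_X), np.stack(pending_Y))
                n_updates += 1
                update_log.append(
                    {
                        "update": n_updates,
                        "epoch_time": stream.times[i],
                        "batch_size": len(pending_X),
                        "f_star": rew_state.f_star,
                    }
                )
                pending_X, pending_Y = [], []
        if seg_start < stream.n_epochs:
            preds[seg_start:] = rew_predict(rew_state, X[seg_start:])
            update_index[seg_start:] = n_updates

        frames.append(
            pd.DataFrame(
                {
                    "session": stream.session_id,
                    "time": stream.times,
                    "cmtp_score": scores,
                    "gate_score": gate_scores,
                    "gate": codes,
                    "accepted": accepted,
                    "true_cmtp": true_cmtp,
                    "est_label": list(est),
                    "true_label": list(Y_true),
                    "pred": list(preds),
                    "update_index": update_index,
                }
            )
        )

    df = pd.concat(frames, ignore_index=True)
    logs = {
        "epochs": df,
        "updates": pd.DataFrame(update_log),
        "n_updates": n_updates,
    }
    logs.update(_accepted_pool_tallies(df, streams[0].paradigm))
    return rew_state, logs


def _accepted_pool_tallies(df: pd.DataFrame, paradigm: str) -> dict:
    """Accuracy tallies over the accepted pool.

    ``gate_accuracy``: among accepted epochs with a defined true cMTP
    label, how often the gate's correct/error call matched it (for the
    continuous paradigm, where only correct-gated epochs enter the
    pool, both the accepted-only and the accepted-plus-error-gated
    tallies are reported).  ``label_accuracy``: how often the
    estimated control label matched the true one (discrete: same
    class; continuous: within 60 degrees of the true direction).
    """
    out = {}
    acc = df[df["accepted"]]
    defined = acc[acc["true_cmtp"] != DISCARD]
    if len(defined):
        out["gate_accuracy"] = float(
            np.mean((defined["gate"] == Gate.CORRECT.value) == (defined["true_cmtp"] == 1))
        )
    else:
        out["gate_accuracy"] = np.nan
    gated = df[df["gate"] != Gate.DISCARD.value]
    gated_def = gated[gated["true_cmtp"] != DISCARD]
    if len(gated_def):
        out["gate_accuracy_incl_error_gated"] = float(
            np.mean(
                (gated_def["gate"] == Gate.CORRECT.value) == (gated_def["true_cmtp"] == 1)
            )
        )
    else:
        out["gate_accuracy_incl_error_gated"] = np.nan
    if len(acc):
        est = np.stack(acc["est_label"].to_numpy())
        true = np.stack(acc["true_label"].to_numpy())
        if paradigm == "discrete":
            out["label_accuracy"] = float(
                np.mean(np.argmax(est, axis=1) == np.argmax(true, axis=1))
            )
        else:
            ang = angular_deviation_deg(est, true)
            out["label_accuracy"] = float(np.mean(ang[~np.isnan(ang)] < 60.0))
    else:
        out["label_accuracy"] = np.nan
    out["n_accepted"] = int(len(acc))
    return out
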
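"""Ground-truth cMTP datasets: labeling, balancing, training, CV.

The continuous motor-task-performance (cMTP) decoder scores each
epoch's correctness from neural features.  Its supervised training
labels come from task telemetry:

* discrete paradigm -- an epoch is correct (1) iff the effector state
  equals the desired state; epochs containing data from 0 to 500 ms
  after an effector state change are discarded (reaction-time
  uncertainty);
* continuous paradigm -- the unsigned angle between each 0.1 s cursor
  displacement and the cursor-to-target direction is averaged over a
  trailing 0.5 s window; a mean above 90 degrees labels the epoch
  erroneous (0), below 60 degrees correct (1), anything in between
  (boundaries included) is discarded.

To prevent motor confounds in the discrete paradigm, each cMTP class
is oversampled so the motor-class histogram within it is uniform.
"""

from __future__ import annotations

import numpy as np

from .npls import NplsModel, npls_fit, npls_predict
from .simulator import (
    ANGLE_WINDOW_STEPS,
    SessionStream,
    angular_deviation_deg,
    correctness_from_mean_angle,
    windowed_mean_angle,
)

#: label value marking an epoch excluded from cMTP training
DISCARD = -1

#: post-change uncertainty horizon, s
STATE_CHANGE_EXCLUSION = 0.5


def label_discrete(
    telemetry: dict, epoch_len: float = 1.0
) -> np.ndarray:
    """Per-epoch cMTP labels for the discrete paradigm.

    Labels are 1 where the effector state matches the desired state,
    0 where it differs, and DISCARD when any sample of the epoch lies
    within (0, 500 ms] after an effector state change -- that is,
    when the time from the last state change to the epoch's end is
    positive and at most ``epoch_len + 0.5`` s.
    """
    for key in ("desired_class", "actual_class", "time_since_change"):
        if key not in telemetry:
            raise KeyError(f"telemetry is missing '{key}'")
    desired = np.asarray(telemetry["desired_class"])
    actual = np.asarray(telemetry["actual_class"])
    tsc = np.asarray(telemetry["time_since_change"], dtype=float)
    labels = (actual == desired).astype(int)
    discard = (tsc > 0) & (tsc <= epoch_len + STATE_CHANGE_EXCLUSION)
    labels[discard] = DISCARD
    return labels


def label_continuous(telemetry: dict, window: int = ANGLE_WINDOW_STEPS) -> np.ndarray:
    """Per-epoch cMTP labels for the continuous paradigm.

    Recomputes per-step angular deviations from telemetry (performed
    displacement vs the cursor-to-target vector at the step's start),
    averages them over the trailing ``window`` steps (0.5 s at the
    0.1 s update rate; steps with undefined angles are excluded from
    the mean), and applies the strict 60/90-degree rules.  Windows
    with no defined angle are discarded.  Windows never mix steps
    from different trials.
    """
    for key in ("disp_x", "disp_y", "cursor_x", "cursor_y", "target_x", "target_y"):
        if key not in telemetry:
            raise KeyError(f"telemetry is missing '{key}'")
    disp = np.column_stack([telemetry["disp_x"], telemetry["disp_y"]])
    cursor = np.column_stack([telemetry["cursor_x"], telemetry["cursor_y"]])
    target = np.column_stack([telemetry["target_x"], telemetry["target_y"]])
    angles = angular_deviation_deg(disp, target - cursor)
    trial = np.asarray(telemetry.get("trial", np.zeros(len(angles), dtype=int)))
    mean_ang = np.full(len(angles), np.nan)
    for tr in np.unique(trial):
        sel = trial == tr
        mean_ang[sel] = windowed_mean_angle(angles[sel], window)
    flags = correctness_from_mean_angle(mean_ang)
    labels = np.full(len(angles), DISCARD, dtype=int)
    labels[flags == 1] = 1
    labels[flags == -1] = 0
    return labels


def label_epochs(stream: SessionStream) -> np.ndarray:
    """Dispatch to the paradigm's labeling rule."""
    if stream.paradigm == "discrete":
        return label_discrete(stream.telemetry, stream.config.epoch_len)
    return label_continuous(stream.telemetry)


def motor_tags(stream: SessionStream, n_bins: int = 8) -> np.ndarray:
    """Motor-class tag per epoch: the desired class (discrete) or the
    angular bin of the performed displacement direction (continuous,
    diagnostics only; undefined displacements get tag -1)."""
    if stream.paradigm == "discrete":
        return np.asarray(stream.telemetry["desired_class"], dtype=int)
    dx = np.asarray(stream.telemetry["disp_x"], dtype=float)
    dy = np.asarray(stream.telemetry["disp_y"], dtype=float)
    ang = np.arctan2(dy, dx)  # (-pi, pi]
    tags = ((ang + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
    tags[(dx == 0) & (dy == 0)] = -1
    return tags


def balance_motor_distribution(
    labels: np.ndarray, tags: np.ndarray
) -> np.ndarray:
    """Oversampling indices making motor histograms uniform per class.

    Within each cMTP class, samples of under-represented motor classes
    are repeated (deterministically, by cycling through them in order)
    until every motor class reaches that cMTP class's maximum motor
    count.  Returns an index array into the input; an already-uniform
    input maps to itself.
    """
    labels = np.asarray(labels)
    tags = np.asarray(tags)
    keep = labels != DISCARD
    if not np.any(labels[keep] == 0) or not np.any(labels[keep] == 1):
        raise ValueError("both cMTP classes must be present for balancing")
    out = []
    for cls in (0, 1):
        cls_idx = np.flatnonzero(keep & (labels == cls))
        cls_tags = tags[cls_idx]
        counts = {t: np.sum(cls_tags == t) for t in np.unique(cls_tags)}
        target = max(counts.values())
        for t in sorted(counts):
            pool = cls_idx[cls_tags == t]
            reps = np.resize(pool, target)
            out.append(reps)
    return np.sort(np.concatenate(out))


def build_cmtp_dataset(
    streams: list[SessionStream], balance: bool | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (features, labels, session index) for cMTP training.

    DISCARD epochs are dropped; motor-class oversampling is applied
    for the discrete paradigm (the continuous paradigm passes through
    unchanged, matching the convention that continuous motor actions
    cannot be balanced by class repetition).
    """
    X_parts, y_parts, s_parts = [], [], []
    for si, stream in enumerate(streams):
        labels = label_epochs(stream)
        do_balance = (
            stream.paradigm == "discrete" if balance is None else balance
        )
        if do_balance:
            tags = motor_tags(stream)
            idx = balance_motor_distribution(labels, tags)
        else:
            idx = np.flatnonzero(labels != DISCARD)
        X_parts.append(stream.features[idx])
        y_parts.append(labels[idx])
        s_parts.append(np.full(len(idx), si))
    return (
        np.concatenate(X_parts),
        np.concatenate(y_parts),
        np.concatenate(s_parts),
    )


def train_cmtp(
    X: np.ndarray, y: np.ndarray, n_factors: int = 20
) -> NplsModel:
    """Train the binary cMTP decoder (NPLS on {0, 1} labels).

    The model's continuous output is the per-epoch correctness score
    consumed by the gating thresholds.
    """
    y = np.asarray(y)
    if DISCARD in y:
        raise ValueError("DISCARD labels must be removed before training")
    if len(np.unique(y)) < 2:
        raise ValueError("both cMTP classes must be present")
    return npls_fit(X, y.astype(float), n_factors)


def cmtp_scores(model: NplsModel, X: np.ndarray) -> np.ndarray:
    """Scalar correctness score per epoch."""
    return npls_predict(model, X)[:, 0]


def eval_cmtp_cv(
    streams: list[SessionStream],
    k: int = 5,
    n_factors: int = 20,
) -> np.ndarray:
    """Session-wise k-fold cross-validated ROC AUC of the cMTP decoder.

    Folds are unions of whole sessions with equal session counts (up
    to one); per fold the decoder is trained on the remaining
    sessions and scored on the held-out ones.
    """
    from sklearn.metrics import roc_auc_score

    from .evaluation import session_cv_folds

    if k > len(streams):
        raise ValueError("more folds than sessions")
    folds = session_cv_folds(len(streams), k)
    aucs = []
    for test_ids in folds:
        train_streams = [s for i, s in enumerate(streams) if i not in test_ids]
        test_streams = [streams[i] for i in test_ids]
        X, y, _ = build_cmtp_dataset(train_streams)
        model = train_cmtp(X, y, n_factors)
        Xt, yt, _ = build_cmtp_dataset(test_streams, balance=False)
        aucs.append(roc_auc_score(yt, cmtp_scores(model, Xt)))
    return np.asarray(aucs)
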
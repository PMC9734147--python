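"""Performance metrics and experiment-design utilities.

* Hand-Till multiclass generalization of the ROC AUC (average over
  unordered class pairs of the symmetrized pairwise separability);
* mean cosine similarity between predicted and optimal cursor
  trajectories;
* session-wise cross-validation folds and the three-split / six-role-
  permutation scheme used to evaluate the auto-adaptive framework.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

ROLES = ("cmtp_train", "control_train", "test")


@dataclass
class SplitPlan:
    """One role assignment of the three chronologically contiguous
    session groups."""

    permutation: int  # 1..6
    roles: dict  # role name -> tuple of session indices

    def sessions(self, role: str) -> tuple[int, ...]:
        return self.roles[role]


def multiclass_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Hand-Till M measure: multiclass ROC AUC.

    For every unordered class pair (i, j), A(i|j) is the probability
    that a class-i sample outranks a class-j sample on the class-i
    score column (ties count one half); the pair's separability is
    [A(i|j) + A(j|i)] / 2, and M is the mean over all pairs.  Equals
    the ordinary binary ROC AUC when m = 2, and is invariant under
    any strictly increasing transform of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise ValueError("scores must be (N, m) with m >= 2")
    classes = np.arange(scores.shape[1])
    present = np.unique(labels)
    missing = set(classes) - set(present)
    if missing:
        raise ValueError(f"classes absent from labels: {sorted(missing)}")
    pair_aucs = []
    for i, j in itertools.combinations(classes, 2):
        sel = (labels == i) | (labels == j)
        a_ij = roc_auc_score(labels[sel] == i, scores[sel, i])
        a_ji = roc_auc_score(labels[sel] == j, scores[sel, j])
        pair_aucs.append(0.5 * (a_ij + a_ji))
    return float(np.mean(pair_aucs))


def cosine_trajectory(pred: np.ndarray, optimal: np.ndarray) -> float:
    """Mean per-epoch cosine between predicted and optimal vectors.

    The optimal vector at each epoch is the directed distance from
    the cursor to the target.  Epochs where either vector is zero
    contribute 0 (a zero prediction conveys no directional agreement
    and keeping them holds N fixed across compared methods).
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    optimal = np.atleast_2d(np.asarray(optimal, dtype=float))
    if pred.shape != optimal.shape:
        raise ValueError("pred and optimal must have the same shape")
    pn = np.linalg.norm(pred, axis=1)
    on = np.linalg.norm(optimal, axis=1)
    ok = (pn > 0) & (on > 0)
    cos = np.zeros(len(pred))
    cos[ok] = np.einsum("ij,ij->i", pred[ok], optimal[ok]) / (pn[ok] * on[ok])
    return float(cos.mean())


def _balanced_groups(n: int, k: int) -> list[tuple[int, ...]]:
    """Contiguous partition of range(n) into k groups with sizes equal
    up to one (larger groups first)."""
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    groups, start = [], 0
    for s in sizes:
        groups.append(tuple(range(start, start + s)))
        start += s
    return groups


def session_cv_folds(n_sessions: int, k: int) -> list[tuple[int, ...]]:
    """Session-wise k-fold test sets (contiguous, sizes equal up to one)."""
    if k > n_sessions:
        raise ValueError("more folds than sessions")
    return _balanced_groups(n_sessions, k)


def make_three_splits(n_sessions: int) -> list[SplitPlan]:
    """All six role assignments of three contiguous session groups.

    Sessions are partitioned chronologically into three groups with
    sizes equal up to one; permuting the roles (cMTP training,
    control-decoder training, test) over the groups yields six plans,
    each covering every session exactly once.
    """
    if n_sessions < 3:
        raise ValueError("need at least three sessions")
    groups = _balanced_groups(n_sessions, 3)
    plans = []
    for p, perm in enumerate(itertools.permutations(range(3)), start=1):
        roles = {ROLES[r]: groups[g] for r, g in enumerate(perm)}
        plans.append(SplitPlan(permutation=p, roles=roles))
    return plans
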
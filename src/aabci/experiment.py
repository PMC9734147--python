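"""Canned comparison of control-decoder training methods.

For each seed: synthetic sessions are generated with a recording
controller of intermediate accuracy (emulating data acquired under an
already-functional decoder), the sessions are partitioned into three
chronologically contiguous splits, the cMTP decoder is trained on one
split, the control decoder is trained from scratch on a second split
in each requested mode (supervised / auto-adaptive / shuffled-cMTP),
and the result is evaluated on the third split -- multiclass ROC AUC
for the discrete paradigm, trajectory cosine similarity for the
continuous one.  Optionally all six role permutations of the splits
are run.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cmtp import build_cmtp_dataset, cmtp_scores, train_cmtp
from .config import ExperimentConfig, save_config
from .engine import fit_thresholds, run_pseudo_online, _true_labels
from .evaluation import SplitPlan, cosine_trajectory, make_three_splits, multiclass_auc
from .rew import rew_init, rew_predict
from .simulator import (
    NoisyCenterOutController,
    NoisyDiscreteController,
    SimConfig,
    make_templates,
    simulate_centerout_session,
    simulate_discrete_session,
)

_SEED_MOD = 2**31 - 1


def _sub_seed(seed: int, *salts: int) -> int:
    s = int(seed)
    for salt in salts:
        s = (s * 1_000_003 + salt * 7919 + 17) % _SEED_MOD
    return s


def generate_recorded_sessions(
    cfg: ExperimentConfig, seed: int
) -> list:
    """Sessions recorded under a noisy controller of intermediate skill."""
    rng = np.random.default_rng(_sub_seed(seed, 1))
    templates = make_templates(cfg.simulator, rng, paradigm=cfg.paradigm)
    streams = []
    for i in range(cfg.n_sessions):
        srng = np.random.default_rng(_sub_seed(seed, 2, i))
        if cfg.paradigm == "discrete":
            controller = NoisyDiscreteController(cfg.recorded_accuracy)
            streams.append(
                simulate_discrete_session(
                    cfg.simulator,
                    templates,
                    controller,
                    cfg.session_duration,
                    session_id=f"s{i:02d}",
                    rng=srng,
                )
            )
        else:
            controller = NoisyCenterOutController(cfg.recorded_error_rate)
            streams.append(
                simulate_centerout_session(
                    cfg.simulator,
                    templates,
                    controller,
                    cfg.trials_per_session,
                    session_id=f"s{i:02d}",
                    rng=srng,
                )
            )
    return streams


def evaluate_control(state, test_streams, paradigm: str) -> float:
    """Test-split metric of a trained control decoder."""
    preds, labels = [], []
    for stream in test_streams:
        preds.append(rew_predict(state, stream.features))
        labels.append(_true_labels(stream))
    pred = np.concatenate(preds)
    true = np.concatenate(labels)
    if paradigm == "discrete":
        return multiclass_auc(pred, np.argmax(true, axis=1))
    return cosine_trajectory(pred, true)


def run_split(
    cfg: ExperimentConfig,
    streams: list,
    plan: SplitPlan,
    modes: tuple,
    seed: int,
) -> list[dict]:
    """Train/evaluate every requested mode on one role assignment."""
    cmtp_streams = [streams[i] for i in plan.sessions("cmtp_train")]
    train_streams = [streams[i] for i in plan.sessions("control_train")]
    test_streams = [streams[i] for i in plan.sessions("test")]

    Xc, yc, _ = build_cmtp_dataset(cmtp_streams)
    cmtp_model = train_cmtp(Xc, yc, cfg.cmtp_factors)
    thresholds = fit_thresholds(cmtp_scores(cmtp_model, Xc), yc, cfg.a)

    shape = cfg.simulator.feature_shape
    m = cfg.simulator.n_classes if cfg.paradigm == "discrete" else 2
    rows = []
    for mode in modes:
        state = rew_init(shape, m, lam=cfg.lam, f_max=cfg.f_max)
        state, logs = run_pseudo_online(
            train_streams,
            cmtp_model,
            mode,
            state,
            thresholds=thresholds,
            update_quantum=cfg.update_quantum,
            seed=_sub_seed(seed, 3, plan.permutation),
        )
        rows.append(
            {
                "seed": seed,
                "permutation": plan.permutation,
                "mode": mode,
                "metric": evaluate_control(state, test_streams, cfg.paradigm),
                "n_updates": logs["n_updates"],
                "n_accepted": logs["n_accepted"],
                "gate_accuracy": logs["gate_accuracy"],
                "gate_accuracy_incl_error_gated": logs[
                    "gate_accuracy_incl_error_gated"
                ],
                "label_accuracy": logs["label_accuracy"],
            }
        )
    return rows


def run_experiment(
    cfg: ExperimentConfig,
    out_dir: str | Path | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Full comparison over seeds (and optionally all permutations).

    Returns one row per (seed, permutation, mode) with the test
    metric and the accepted-pool accuracy tallies; optionally writes
    the metric table, a JSON summary, the exact config used and the
    comparison figures into ``out_dir``.
    """
    rows = []
    for s in range(cfg.n_seeds):
        seed = _sub_seed(base_seed, 100 + s)
        streams = generate_recorded_sessions(cfg, seed)
        plans = make_three_splits(len(streams))
        if not cfg.all_permutations:
            plans = plans[:1]
        for plan in plans:
            rows.extend(run_split(cfg, streams, plan, cfg.modes, seed))
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "metrics.csv", index=False)
        save_config(cfg, out_dir / "config.yaml")
        summary = summarize(df)
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
        try:
            plot_mode_comparison(df, cfg.paradigm, out_dir / "mode_comparison.png")
        except Exception:  # plotting must never sink a finished run
            pass
    return df


def summarize(df: pd.DataFrame) -> dict:
    """Per-mode mean/SD/median of the test metric, plus rank-sum
    p-values of the auto-adaptive condition against the other two."""
    from scipy.stats import mannwhitneyu

    out = {"per_mode": {}}
    for mode, grp in df.groupby("mode"):
        out["per_mode"][mode] = {
            "mean": float(grp["metric"].mean()),
            "sd": float(grp["metric"].std(ddof=1)) if len(grp) > 1 else 0.0,
            "median": float(grp["metric"].median()),
            "n": int(len(grp)),
        }
    have = set(df["mode"])
    if {"aabci", "shuffled"} <= have:
        a = df.loc[df["mode"] == "aabci", "metric"]
        b = df.loc[df["mode"] == "shuffled", "metric"]
        out["aabci_vs_shuffled_p"] = float(
            mannwhitneyu(a, b, alternative="two-sided").pvalue
        )
    if {"aabci", "supervised"} <= have:
        a = df.loc[df["mode"] == "aabci", "metric"]
        b = df.loc[df["mode"] == "supervised", "metric"]
        out["aabci_vs_supervised_p"] = float(
            mannwhitneyu(a, b, alternative="two-sided").pvalue
        )
    return out


def plot_mode_comparison(df: pd.DataFrame, paradigm: str, path: str | Path) -> None:
    """Bar chart (mean +- SD per training method) of the test metric."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [m for m in ("supervised", "aabci", "shuffled") if m in set(df["mode"])]
    means = [df.loc[df["mode"] == m, "metric"].mean() for m in order]
    sds = [df.loc[df["mode"] == m, "metric"].std(ddof=1) for m in order]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(order, means, yerr=sds, capsize=4, color=["#4c72b0", "#dd8452", "#937860"])
    ax.set_ylabel("multiclass AUC" if paradigm == "discrete" else "cosine similarity")
    ax.set_title(f"control decoder, {paradigm} paradigm")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_direction_histogram(stream, labels, path: str | Path, n_bins: int = 16) -> None:
    """Polar histogram of cursor-displacement directions per
    correctness class (continuous-paradigm diagnostic)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ang = np.arctan2(stream.telemetry["disp_y"], stream.telemetry["disp_x"])
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    width = 2 * np.pi / n_bins
    for cls, color, name in ((1, "#4c72b0", "correct"), (0, "#c44e52", "error")):
        h, _ = np.histogram(ang[labels == cls], bins=edges)
        ax.bar(edges[:-1] + width / 2, h, width=width, alpha=0.5, color=color, label=name)
    ax.legend(loc="upper right", bbox_to_anchor=(1.2, 1.1))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
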
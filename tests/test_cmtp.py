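"""cMTP labeling rules, motor balancing, decoder training and CV."""

import numpy as np
import pytest

from aabci.cmtp import (
    DISCARD,
    balance_motor_distribution,
    build_cmtp_dataset,
    cmtp_scores,
    eval_cmtp_cv,
    label_continuous,
    label_discrete,
    train_cmtp,
)
from aabci.simulator import (
    NoisyDiscreteController,
    SimConfig,
    make_templates,
    simulate_discrete_session,
)


def discrete_telemetry(desired, actual, tsc):
    return {
        "desired_class": np.asarray(desired),
        "actual_class": np.asarray(actual),
        "time_since_change": np.asarray(tsc, dtype=float),
    }


def continuous_telemetry(angles_deg, step=0.01):
    """Telemetry whose per-step deviation equals the requested angles:
    target far on +x, displacements rotated by the angle."""
    n = len(angles_deg)
    rad = np.deg2rad(angles_deg)
    return {
        "cursor_x": np.zeros(n),
        "cursor_y": np.zeros(n),
        "target_x": np.full(n, 1.0),
        "target_y": np.zeros(n),
        "disp_x": step * np.cos(rad),
        "disp_y": step * np.sin(rad),
        "trial": np.zeros(n, dtype=int),
    }


class TestLabelDiscrete:
    def test_match_and_mismatch(self):
        t = discrete_telemetry([1, 1, 2], [1, 3, 2], [np.inf, np.inf, np.inf])
        assert list(label_discrete(t)) == [1, 0, 1]

    def test_recent_state_change_discards(self):
        # an epoch whose data includes any sample from (0, 500 ms]
        # after a state change is excluded: that is every epoch ending
        # within 1.5 s of the change (1 s epoch + 0.5 s horizon)
        t = discrete_telemetry([0] * 4, [0] * 4, [0.3, 1.3, 1.5, 1.51])
        assert list(label_discrete(t)) == [DISCARD, DISCARD, DISCARD, 1]

    def test_missing_telemetry_rejected(self):
        with pytest.raises(KeyError):
            label_discrete({"desired_class": np.zeros(3)})

    def test_exhaustive_offset_grid(self):
        # state-change offsets 0..1000 ms in 10 ms steps against the
        # printed rule, applied at the epoch's end time
        offsets = np.arange(0.0, 1.001, 0.01)
        t = discrete_telemetry(
            np.zeros(len(offsets), int), np.zeros(len(offsets), int), offsets
        )
        labels = label_discrete(t)
        for off, lab in zip(offsets, labels):
            # change off seconds before epoch end; epoch covers
            # [end-1, end]; excluded iff (change, change+0.5] meets it
            contains_uncertain = (off > 0) and (off <= 1.5)
            assert (lab == DISCARD) == contains_uncertain


class TestLabelContinuous:
    def test_straight_at_target_is_correct(self):
        t = continuous_telemetry([0.0] * 8)
        assert np.all(label_continuous(t) == 1)

    def test_straight_away_is_error(self):
        t = continuous_telemetry([180.0] * 8)
        assert np.all(label_continuous(t) == 0)

    def test_dead_zone_discarded(self):
        t = continuous_telemetry([75.0] * 8)
        assert np.all(label_continuous(t) == DISCARD)

    def test_exhaustive_angle_grid(self):
        # constant deviation 0..180 degrees in 1 degree steps: the
        # windowed mean equals the constant, so the strict 60/90 rules
        # apply directly.  The exact 60/90 boundaries are checked on
        # the thresholding rule itself (below): the geometric
        # construction cannot represent them exactly (cos/arccos
        # round-trip error ~1e-14 degrees).
        for ang in range(0, 181):
            if ang in (60, 90):
                continue
            t = continuous_telemetry([float(ang)] * 6)
            lab = label_continuous(t)[-1]
            if ang < 60:
                assert lab == 1, ang
            elif ang > 90:
                assert lab == 0, ang
            else:
                assert lab == DISCARD, ang

    def test_boundary_angles_discard_under_strict_rule(self):
        from aabci.simulator import correctness_from_mean_angle

        flags = correctness_from_mean_angle(np.array([59.999, 60.0, 90.0, 90.001]))
        assert list(flags) == [1, 0, 0, -1]

    def test_zero_displacement_steps_excluded_from_window(self):
        t = continuous_telemetry([0.0] * 6)
        t["disp_x"][2] = 0.0  # undefined angle at step 2
        labels = label_continuous(t)
        assert np.all(labels == 1)  # remaining window steps all at 0 deg

    def test_all_undefined_window_discarded(self):
        t = continuous_telemetry([0.0] * 3)
        t["disp_x"][:] = 0.0
        assert np.all(label_continuous(t) == DISCARD)

    def test_windowed_mean_straddles_thresholds(self):
        # five steps averaging (30+30+30+30+180)/5 = 60 exactly: the
        # strict rule discards the boundary
        t = continuous_telemetry([30.0, 30.0, 30.0, 30.0, 180.0])
        assert label_continuous(t)[-1] == DISCARD


class TestBalancing:
    def test_oversampling_reaches_uniform_histogram(self):
        labels = np.array([0] * 15 + [1] * 12)
        tags = np.array([0] * 10 + [1] * 5 + [0] * 7 + [1] * 3 + [2] * 2)
        idx = balance_motor_distribution(labels, tags)
        for cls in (0, 1):
            sel = idx[labels[idx] == cls]
            counts = np.bincount(tags[sel])
            counts = counts[counts > 0]
            assert len(set(counts)) == 1  # uniform within the class

    def test_example_counts(self):
        # error-class motor counts {7, 3, 5, 7} -> 4 x 7 = 28 samples
        labels = np.array([0] * 22 + [1] * 4)
        tags = np.array([0] * 7 + [1] * 3 + [2] * 5 + [3] * 7 + [0, 1, 2, 3])
        idx = balance_motor_distribution(labels, tags)
        assert np.sum(labels[idx] == 0) == 28

    def test_uniform_input_unchanged(self):
        labels = np.array([0, 0, 1, 1])
        tags = np.array([0, 1, 0, 1])
        idx = balance_motor_distribution(labels, tags)
        assert np.array_equal(idx, np.arange(4))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            balance_motor_distribution(np.array([1, 1, 1]), np.array([0, 1, 0]))


class TestTraining:
    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((20, 2, 2, 2))
        with pytest.raises(ValueError):
            train_cmtp(X, np.ones(20, dtype=int), 2)

    def test_discard_labels_rejected(self):
        X = np.random.default_rng(0).standard_normal((20, 2, 2, 2))
        y = np.array([0, 1] * 10)
        y[3] = DISCARD
        with pytest.raises(ValueError):
            train_cmtp(X, y, 2)

    def test_label_flip_mirrors_auc(self, discrete_stream):
        from sklearn.metrics import roc_auc_score

        X, y, _ = build_cmtp_dataset([discrete_stream])
        model = train_cmtp(X, y, 5)
        flipped = train_cmtp(X, 1 - y, 5)
        s, sf = cmtp_scores(model, X), cmtp_scores(flipped, X)
        a = roc_auc_score(y, s)
        af = roc_auc_score(y, sf)
        assert a == pytest.approx(1.0 - roc_auc_score(y, -s), abs=1e-12)
        assert af == pytest.approx(1.0 - a, abs=1e-6)

    def test_high_snr_cmtp_is_decodable(self):
        cfg = SimConfig(n_channels=4, cmtp_snr=5.0)
        rng = np.random.default_rng(0)
        tpl = make_templates(cfg, rng)
        streams = [
            simulate_discrete_session(
                cfg, tpl, NoisyDiscreteController(0.65), 120.0,
                session_id=f"s{i}", rng=np.random.default_rng(50 + i),
            )
            for i in range(5)
        ]
        aucs = eval_cmtp_cv(streams, k=5, n_factors=10)
        assert aucs.mean() > 0.9

    def test_zero_snr_cmtp_is_chance(self):
        aucs = []
        for seed in range(10):
            cfg = SimConfig(n_channels=4, cmtp_snr=0.0)
            tpl = make_templates(cfg, np.random.default_rng(seed))
            streams = [
                simulate_discrete_session(
                    cfg, tpl, NoisyDiscreteController(0.65), 90.0,
                    session_id=f"s{i}",
                    rng=np.random.default_rng(1000 + 10 * seed + i),
                )
                for i in range(2)
            ]
            Xa, ya, _ = build_cmtp_dataset([streams[0]])
            model = train_cmtp(Xa, ya, 5)
            from sklearn.metrics import roc_auc_score

            Xb, yb, _ = build_cmtp_dataset([streams[1]], balance=False)
            aucs.append(roc_auc_score(yb, cmtp_scores(model, Xb)))
        assert abs(np.mean(aucs) - 0.5) < 0.05


class TestSnrMonotonicity:
    def test_cmtp_test_auc_increases_with_snr(self):
        # seed-averaged held-out AUC of the cMTP decoder must be
        # monotone in the correctness-correlate SNR (Spearman rho > 0.9
        # across 5 SNR levels x 5 seeds)
        from scipy.stats import spearmanr
        from sklearn.metrics import roc_auc_score

        snrs = [0.0, 0.2, 0.4, 0.8, 1.6]
        mean_aucs = []
        for snr in snrs:
            aucs = []
            for seed in range(5):
                cfg = SimConfig(n_channels=4, cmtp_snr=snr)
                tpl = make_templates(cfg, np.random.default_rng(seed))
                tr = simulate_discrete_session(
                    cfg, tpl, NoisyDiscreteController(0.65), 120.0,
                    rng=np.random.default_rng(300 + seed),
                )
                te = simulate_discrete_session(
                    cfg, tpl, NoisyDiscreteController(0.65), 90.0,
                    rng=np.random.default_rng(400 + seed),
                )
                X, y, _ = build_cmtp_dataset([tr])
                model = train_cmtp(X, y, 8)
                Xt, yt, _ = build_cmtp_dataset([te], balance=False)
                aucs.append(roc_auc_score(yt, cmtp_scores(model, Xt)))
            mean_aucs.append(np.mean(aucs))
        rho = spearmanr(snrs, mean_aucs).statistic
        assert rho > 0.9


class TestSessionCv:
    def test_fold_structure(self):
        from aabci.evaluation import session_cv_folds

        folds = session_cv_folds(10, 5)
        assert [len(f) for f in folds] == [2] * 5
        covered = sorted(i for f in folds for i in f)
        assert covered == list(range(10))

    def test_more_folds_than_sessions_rejected(self, discrete_stream):
        with pytest.raises(ValueError):
            eval_cmtp_cv([discrete_stream], k=5)
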
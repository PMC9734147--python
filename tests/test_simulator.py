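"""Closed-loop session generator: determinism, kinematics, consistency."""

import numpy as np
import pytest

from aabci.cmtp import DISCARD, label_epochs
from aabci.features import FREQS_DEFAULT, morlet_features
from aabci.simulator import (
    NoisyCenterOutController,
    NoisyDiscreteController,
    OracleCenterOutController,
    RandomCenterOutController,
    SimConfig,
    ZeroController,
    angular_deviation_deg,
    generate_raw_signal,
    make_templates,
    simulate_centerout_session,
    simulate_discrete_session,
)


def small_cfg(**kw):
    return SimConfig(n_channels=4, **kw)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(epoch_stride=2.0)
        with pytest.raises(ValueError):
            SimConfig(speed_cap=0.0)
        with pytest.raises(ValueError):
            SimConfig(n_targets=1)

    def test_default_geometry_matches_recording_setup(self):
        cfg = SimConfig()
        assert cfg.feature_shape == (10, 15, 64)
        assert cfg.sampling_rate == 586.0
        assert cfg.speed_cap == 0.08


class TestTemplates:
    def test_templates_unit_norm_and_independent(self):
        cfg = small_cfg()
        tpl = make_templates(cfg, np.random.default_rng(0))
        all_t = np.concatenate([tpl.intent_templates, tpl.cmtp_template[None]])
        flat = all_t.reshape(len(all_t), -1)
        assert np.allclose(np.linalg.norm(flat, axis=1), 1.0)
        gram = flat @ flat.T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 0.5


class TestDiscreteSession:
    def test_seeded_determinism(self):
        cfg = small_cfg(seed=3)
        runs = []
        for _ in range(2):
            tpl = make_templates(cfg, np.random.default_rng(5))
            s = simulate_discrete_session(
                cfg, tpl, NoisyDiscreteController(0.7), 30.0,
                rng=np.random.default_rng(9),
            )
            runs.append(s)
        assert np.array_equal(runs[0].features, runs[1].features)
        for k in runs[0].telemetry:
            assert np.array_equal(runs[0].telemetry[k], runs[1].telemetry[k])

    def test_epoch_grid(self, discrete_stream):
        assert discrete_stream.times[0] == pytest.approx(1.0)
        assert np.allclose(np.diff(discrete_stream.times), 0.1)

    def test_too_short_duration_rejected(self):
        cfg = small_cfg()
        tpl = make_templates(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError):
            simulate_discrete_session(cfg, tpl, NoisyDiscreteController(0.7), 0.5)

    def test_wrong_controller_output_rejected(self):
        cfg = small_cfg()
        tpl = make_templates(cfg, np.random.default_rng(0))
        bad = lambda f, i, r: np.zeros(7)
        with pytest.raises(ValueError):
            simulate_discrete_session(cfg, tpl, bad, 10.0)

    def test_closed_loop_consistency_with_labeling(self, discrete_stream):
        # generator's internal correctness flag must agree with the
        # labels recomputed from telemetry on all non-discarded epochs
        labels = label_epochs(discrete_stream)
        flag = discrete_stream.telemetry["correct_flag"]
        keep = labels != DISCARD
        assert np.array_equal(labels[keep] == 1, flag[keep] == 1)

    def test_high_snr_stream_is_decodable(self, small_config):
        # supervised decoding sanity: at very high intent SNR a batch
        # decoder trained on the stream separates the classes nearly
        # perfectly
        from aabci.evaluation import multiclass_auc
        from aabci.npls import npls_fit, npls_predict

        cfg = small_cfg(intent_snr=50.0)
        tpl = make_templates(cfg, np.random.default_rng(1))
        tr = simulate_discrete_session(
            cfg, tpl, NoisyDiscreteController(0.7), 120.0,
            rng=np.random.default_rng(2),
        )
        te = simulate_discrete_session(
            cfg, tpl, NoisyDiscreteController(0.7), 60.0,
            rng=np.random.default_rng(3),
        )
        d = tr.telemetry["desired_class"]
        Y = np.zeros((len(d), cfg.n_classes))
        Y[np.arange(len(d)), d] = 1.0
        model = npls_fit(tr.features, Y, 5)
        auc = multiclass_auc(
            npls_predict(model, te.features), te.telemetry["desired_class"]
        )
        assert auc > 0.95

    def test_zero_snr_stream_is_chance_level(self):
        from aabci.evaluation import multiclass_auc
        from aabci.npls import npls_fit, npls_predict

        aucs = []
        for seed in range(10):
            cfg = small_cfg(intent_snr=0.0, cmtp_snr=0.0)
            tpl = make_templates(cfg, np.random.default_rng(seed))
            tr = simulate_discrete_session(
                cfg, tpl, NoisyDiscreteController(0.7), 60.0,
                rng=np.random.default_rng(100 + seed),
            )
            te = simulate_discrete_session(
                cfg, tpl, NoisyDiscreteController(0.7), 60.0,
                rng=np.random.default_rng(200 + seed),
            )
            d = tr.telemetry["desired_class"]
            Y = np.zeros((len(d), cfg.n_classes))
            Y[np.arange(len(d)), d] = 1.0
            model = npls_fit(tr.features, Y, 3)
            aucs.append(
                multiclass_auc(
                    npls_predict(model, te.features),
                    te.telemetry["desired_class"],
                )
            )
        assert abs(np.mean(aucs) - 0.5) < 0.05


class TestCenterOutSession:
    def test_oracle_controller_acquires_every_trial(self):
        cfg = small_cfg()
        tpl = make_templates(cfg, np.random.default_rng(0), "continuous")
        s = simulate_centerout_session(
            cfg, tpl, OracleCenterOutController(), 5,
            rng=np.random.default_rng(1),
        )
        assert np.all(s.telemetry["acquired"])
        # straight-line kinematics bound: distance / (cap * dt) steps
        bound = int(np.ceil(cfg.ring_radius / (cfg.speed_cap * 0.1))) + 1
        for tr in np.unique(s.telemetry["trial"]):
            assert np.sum(s.telemetry["trial"] == tr) <= bound

    def test_zero_controller_times_out_every_trial(self):
        cfg = small_cfg(trial_timeout=3.0)
        tpl = make_templates(cfg, np.random.default_rng(0), "continuous")
        s = simulate_centerout_session(
            cfg, tpl, ZeroController(), 3, rng=np.random.default_rng(1)
        )
        assert not np.any(s.telemetry["acquired"])
        assert np.all(np.bincount(s.telemetry["trial"]) == 30)

    def test_speed_saturation(self, continuous_stream):
        disp = np.column_stack(
            [continuous_stream.telemetry["disp_x"], continuous_stream.telemetry["disp_y"]]
        )
        speeds = np.linalg.norm(disp, axis=1) / 0.1
        assert np.max(speeds) <= continuous_stream.config.speed_cap + 1e-12

    def test_random_controller_step_angles_uniform(self):
        # per-step angular deviation of an isotropic controller is
        # uniform on [0, 180]: a third of steps fall below 60 degrees
        cfg = small_cfg(trial_timeout=10.0)
        tpl = make_templates(cfg, np.random.default_rng(0), "continuous")
        s = simulate_centerout_session(
            cfg, tpl, RandomCenterOutController(), 20,
            rng=np.random.default_rng(2),
        )
        disp = np.column_stack([s.telemetry["disp_x"], s.telemetry["disp_y"]])
        opt = np.column_stack(
            [
                s.telemetry["target_x"] - s.telemetry["cursor_x"],
                s.telemetry["target_y"] - s.telemetry["cursor_y"],
            ]
        )
        ang = angular_deviation_deg(disp, opt)
        frac = np.mean(ang[~np.isnan(ang)] < 60.0)
        assert abs(frac - 1.0 / 3.0) < 0.1

    def test_closed_loop_consistency_with_labeling(self, continuous_stream):
        labels = label_epochs(continuous_stream)
        flag = continuous_stream.telemetry["correct_flag"]
        keep = labels != DISCARD
        assert np.array_equal(labels[keep], (flag[keep] == 1).astype(int))

    def test_n_trials_validated(self):
        cfg = small_cfg()
        tpl = make_templates(cfg, np.random.default_rng(0), "continuous")
        with pytest.raises(ValueError):
            simulate_centerout_session(cfg, tpl, ZeroController(), 0)


class TestRawSignalMode:
    def test_zero_mixture_zero_noise_gives_silence(self):
        cfg = small_cfg(intent_snr=0.0, cmtp_snr=0.0, noise_scale=0.0)
        tpl = make_templates(cfg, np.random.default_rng(0))
        sig = generate_raw_signal(
            cfg, tpl, np.zeros(cfg.n_classes), 0.0, np.random.default_rng(1)
        )
        assert sig.shape == (586, 4)
        assert np.all(sig == 0)

    def test_same_rng_state_gives_identical_signal(self):
        cfg = small_cfg()
        tpl = make_templates(cfg, np.random.default_rng(0))
        intent = np.eye(cfg.n_classes)[1]
        s1 = generate_raw_signal(cfg, tpl, intent, 1.0, np.random.default_rng(7))
        s2 = generate_raw_signal(cfg, tpl, intent, 1.0, np.random.default_rng(7))
        assert np.array_equal(s1, s2)

    def test_band_outside_nyquist_rejected(self):
        cfg = small_cfg(sampling_rate=200.0)
        tpl = make_templates(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError):
            generate_raw_signal(
                cfg, tpl, np.eye(cfg.n_classes)[0], 1.0, np.random.default_rng(1)
            )

    def test_raw_mode_session_runs_end_to_end(self):
        # raw-signal sessions go through synthesis + Morlet extraction
        # per epoch and must keep the closed-loop label consistency
        cfg = small_cfg(raw_mode=True)
        tpl = make_templates(cfg, np.random.default_rng(5))
        s = simulate_discrete_session(
            cfg, tpl, NoisyDiscreteController(0.7), 5.0,
            rng=np.random.default_rng(6),
        )
        assert s.features.shape == (41, 10, 15, 4)
        assert np.all(s.features >= 0)  # wavelet magnitudes
        labels = label_epochs(s)
        keep = labels != DISCARD
        flag = s.telemetry["correct_flag"]
        assert np.array_equal(labels[keep] == 1, flag[keep] == 1)

    def test_template_cells_surface_in_morlet_features(self):
        # raw-mode synthesis must put energy where the template says:
        # the strongest template cell dominates its (window, band,
        # channel) neighborhood of the extracted feature tensor
        cfg = small_cfg(intent_snr=20.0, cmtp_snr=0.0, noise_scale=0.0)
        tpl = make_templates(cfg, np.random.default_rng(3))
        intent = np.eye(cfg.n_classes)[0]
        sig = generate_raw_signal(cfg, tpl, intent, 0.0, np.random.default_rng(4))
        feats = morlet_features(sig, cfg.sampling_rate)
        t0 = tpl.intent_templates[0]
        k, j, c = np.unravel_index(np.argmax(t0), t0.shape)
        # at the hot cell's channel, the hot band should carry the most
        # energy in the hot time window
        assert np.argmax(feats[k, :, c]) == j
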
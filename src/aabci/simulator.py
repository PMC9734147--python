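"""Closed-loop synthetic session generator for two motor-BCI paradigms.

Stands in for private clinical ECoG recordings: task dynamics (a
4-state discrete effector driven by cued motor imagery, and a 2D
center-out cursor task) are simulated together with neural feature
tensors conditioned on the user's motor intent and on the momentary
correctness of the effector's behavior.

Each epoch's feature tensor is

    X = intent_snr * T_intent + cmtp_snr * c * T_cmtp + noise,

where ``T_intent`` is the unit-norm template of the currently desired
motor state (discrete) or the linear combination of two
degree-of-freedom templates weighted by the unit intent direction
(continuous), ``T_cmtp`` is the template of the perceived-correctness
correlate, ``c`` is +1 on correct epochs, -1 on erroneous epochs and 0
when correctness is ambiguous under the labeling conventions, and the
noise is i.i.d. standard Gaussian in feature space.

Two generation modes exist: a fast feature-level mode (templates
injected directly into feature space; default) and a raw-signal mode
in which band-limited oscillatory bursts are synthesized at 586 Hz and
passed through the Morlet feature extractor, exercising the feature
module end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .features import FREQS_DEFAULT, N_TAU_DEFAULT, morlet_features

#: per-step angular-deviation thresholds of the labeling convention, degrees
ANGLE_CORRECT_DEG = 60.0
ANGLE_ERROR_DEG = 90.0
#: trailing window over which the angular deviation is averaged, steps
ANGLE_WINDOW_STEPS = 5


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic sessions.

    Defaults mirror the recording setup being emulated: 64 epidural
    electrodes sampled at 586 Hz, 1 s epochs strided by 0.1 s, a
    4-state discrete effector, an 8-target center-out task with a
    0.08 m/s speed saturation and 0.1 s control updates.
    """

    n_channels: int = 64
    sampling_rate: float = 586.0
    epoch_len: float = 1.0
    epoch_stride: float = 0.1
    n_classes: int = 4
    n_targets: int = 8
    speed_cap: float = 0.08
    target_radius: float = 0.02
    ring_radius: float = 0.15
    workspace_radius: float = 0.2
    trial_timeout: float = 15.0
    block_len: float = 5.0
    n_tau: int = N_TAU_DEFAULT
    n_freqs: int = len(FREQS_DEFAULT)
    intent_snr: float = 2.0
    cmtp_snr: float = 0.5
    noise_scale: float = 1.0
    raw_mode: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.epoch_stride > self.epoch_len:
            raise ValueError("epoch_stride must not exceed epoch_len")
        if self.speed_cap <= 0:
            raise ValueError("speed_cap must be positive")
        if self.n_targets < 2:
            raise ValueError("n_targets must be >= 2")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    @property
    def feature_shape(self) -> tuple[int, int, int]:
        return (self.n_tau, self.n_freqs, self.n_channels)


@dataclass
class GroundTruthTemplates:
    """Unit-norm feature-space signatures of intent and correctness.

    ``intent_templates`` holds one (tau, f, s) tensor per motor class
    (discrete paradigm) or per continuous degree of freedom
    (continuous paradigm, 2 tensors).  ``cmtp_template`` is the
    correctness correlate.  Templates have disjoint support, hence are
    mutually orthogonal, so intent and cMTP decoding cannot trivially
    alias.
    """

    intent_templates: np.ndarray  # (k, tau, f, s)
    cmtp_template: np.ndarray  # (tau, f, s)
    noise_scale: float = 1.0


@dataclass
class SessionStream:
    """Time-ordered epochs of one session with task telemetry."""

    session_id: str
    paradigm: str  # 'discrete' | 'continuous'
    times: np.ndarray  # (N,) epoch end times, s
    features: np.ndarray  # (N, tau, f, s)
    telemetry: dict  # paradigm-dependent arrays, one row per epoch
    config: SimConfig

    @property
    def n_epochs(self) -> int:
        return len(self.times)


def make_templates(
    config: SimConfig,
    rng: np.random.Generator,
    paradigm: str = "discrete",
    cells_per_template: int = 24,
) -> GroundTruthTemplates:
    """Draw sparse non-negative unit-norm templates with disjoint support.

    Random cells of the (tau, f, s) grid are partitioned among the
    intent templates and the cMTP template, so all pairwise cosines
    are exactly zero (well below the < 0.5 independence requirement)
    and raw-mode synthesis can treat template values as band
    amplitudes.
    """
    k = config.n_classes if paradigm == "discrete" else 2
    shape = config.feature_shape
    p = int(np.prod(shape))
    need = (k + 1) * cells_per_template
    if need > p:
        raise ValueError("feature grid too small for the requested templates")
    cells = rng.choice(p, size=need, replace=False)
    tensors = []
    for i in range(k + 1):
        t = np.zeros(p)
        idx = cells[i * cells_per_template : (i + 1) * cells_per_template]
        t[idx] = rng.uniform(0.5, 1.0, size=cells_per_template)
        t /= np.linalg.norm(t)
        tensors.append(t.reshape(shape))
    return GroundTruthTemplates(
        intent_templates=np.stack(tensors[:k]),
        cmtp_template=tensors[k],
        noise_scale=config.noise_scale,
    )


# ---------------------------------------------------------------------------
# controllers


class OracleDiscreteController:
    """Always activates the desired state (scores one-hot on intent)."""

    def __call__(self, features, intent, rng):
        m = len(intent)
        return np.asarray(intent, dtype=float)


class NoisyDiscreteController:
    """Sticky noisy decoder: re-decides the effector state when the
    cue changes and occasionally in between (``switch_rate`` per
    0.1 s step), choosing the desired state with probability
    ``accuracy`` and a uniformly random other state otherwise.  The
    emitted score vector has the chosen state on top plus sub-unit
    random scores, so a second-best class is defined as for a real
    decoder.  Stickiness matters: a state that flipped every step
    would leave no epoch outside the 500 ms post-change exclusion."""

    def __init__(self, accuracy: float, switch_rate: float = 0.05):
        self.accuracy = float(accuracy)
        self.switch_rate = float(switch_rate)
        self._choice: int | None = None
        self._desired: int | None = None

    def __call__(self, features, intent, rng):
        m = len(intent)
        desired = int(np.argmax(intent))
        if (
            self._choice is None
            or desired != self._desired
            or rng.random() < self.switch_rate
        ):
            if rng.random() < self.accuracy:
                self._choice = desired
            else:
                others = [i for i in range(m) if i != desired]
                self._choice = others[rng.integers(len(others))]
        self._desired = desired
        scores = rng.uniform(0.0, 0.5, size=m)
        scores[self._choice] += 1.0
        return scores


class OracleCenterOutController:
    """Moves straight at the target at full speed (output along
    target - cursor, large enough to saturate the speed cap)."""

    def __init__(self, gain: float = 1e3):
        self.gain = float(gain)

    def __call__(self, features, intent, rng):
        return self.gain * np.asarray(intent, dtype=float)


class NoisyCenterOutController:
    """Episodic noisy decoder for the center-out task.

    Alternates between well-controlled episodes (angular error around
    0 with SD ``good_sigma``) and mis-controlled episodes (error
    around ``bad_mean`` degrees, random sign), with geometric episode
    lengths of mean ``dwell_steps`` control steps and a long-run
    mis-control fraction of ``error_rate``.  Episodes of seconds-long
    persistence are what give the trailing-window labeling rule both
    clearly correct and clearly erroneous epochs, as with a real
    mid-performance decoder."""

    def __init__(
        self,
        error_rate: float = 0.4,
        good_sigma: float = 35.0,
        bad_mean: float = 140.0,
        bad_sigma: float = 30.0,
        dwell_steps: int = 20,
        speed: float = 1.0,
    ):
        self.error_rate = float(error_rate)
        self.good_sigma = np.deg2rad(good_sigma)
        self.bad_mean = np.deg2rad(bad_mean)
        self.bad_sigma = np.deg2rad(bad_sigma)
        self.dwell_steps = int(dwell_steps)
        self.speed = float(speed)
        self._bad: bool | None = None
        self._sign = 1.0

    def __call__(self, features, intent, rng):
        intent = np.asarray(intent, dtype=float)
        nrm = np.linalg.norm(intent)
        if nrm == 0:
            return np.zeros(2)
        if self._bad is None or rng.random() < 1.0 / self.dwell_steps:
            self._bad = rng.random() < self.error_rate
            self._sign = 1.0 if rng.random() < 0.5 else -1.0
        if self._bad:
            err = self._sign * self.bad_mean + rng.normal(0.0, self.bad_sigma)
        else:
            err = rng.normal(0.0, self.good_sigma)
        theta = np.arctan2(intent[1], intent[0]) + err
        return self.speed * np.array([np.cos(theta), np.sin(theta)])


class RandomCenterOutController:
    """Isotropic random full-speed direction, ignoring the task."""

    def __call__(self, features, intent, rng):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        return np.array([np.cos(theta), np.sin(theta)])


class ZeroController:
    def __call__(self, features, intent, rng):
        return np.zeros(2)


# ---------------------------------------------------------------------------
# raw-signal synthesis

_BAND_GAIN_CACHE: dict = {}


def _band_gains(fs: float, freqs: tuple, n_cycles: float) -> np.ndarray:
    """Morlet magnitude response to a unit-amplitude sinusoid per
    band (cached): used to equalize synthesis across bands so the
    extracted feature tensor is proportional to the requested
    template mixture."""
    key = (fs, freqs, n_cycles)
    if key not in _BAND_GAIN_CACHE:
        from .features import morlet_transform

        n = int(round(fs))
        t = np.arange(n) / fs
        gains = np.empty(len(freqs))
        for j, fj in enumerate(freqs):
            sig = np.cos(2.0 * np.pi * fj * t)[:, None]
            mag = morlet_transform(sig, fs, np.array(freqs), n_cycles)
            lo, hi = n // 4, 3 * n // 4  # away from edges
            gains[j] = mag[lo:hi, j, 0].mean()
        _BAND_GAIN_CACHE[key] = gains
    return _BAND_GAIN_CACHE[key]


def generate_raw_signal(
    config: SimConfig,
    templates: GroundTruthTemplates,
    intent: np.ndarray,
    correctness: float,
    rng: np.random.Generator,
    freqs: np.ndarray = FREQS_DEFAULT,
) -> np.ndarray:
    """One-second multichannel signal realizing a template mixture.

    Each positive cell (window, band, channel) of the mixture

        M = intent_snr * sum_i intent_i T_i + cmtp_snr * c * T_cmtp

    becomes an oscillatory burst at the band's central frequency whose
    amplitude is proportional to the cell value during that 100 ms
    window (negative mixture values are clipped: an erroneous epoch
    silences rather than inverts the correctness cells).  Pink-ish
     1/f noise is added at ``noise_scale``.  The Morlet feature tensor
    of the output has expectation proportional to ``clip(M, 0)`` plus
    the noise floor.
    """
    freqs = np.asarray(freqs, dtype=float)
    fs = config.sampling_rate
    if np.max(freqs) * 2.0 > fs:
        raise ValueError("requested band exceeds the Nyquist frequency")
    intent = np.asarray(intent, dtype=float)
    mix = config.intent_snr * np.tensordot(intent, templates.intent_templates, axes=1)
    mix = mix + config.cmtp_snr * correctness * templates.cmtp_template
    mix = np.clip(mix, 0.0, None)

    n = int(round(config.epoch_len * fs))
    t = np.arange(n) / fs
    n_tau = mix.shape[0]
    bounds = np.round(np.linspace(0, n, n_tau + 1)).astype(int)
    sig = np.zeros((n, config.n_channels))
    win_idx = np.empty(n, dtype=int)
    for k in range(n_tau):
        win_idx[bounds[k] : bounds[k + 1]] = k
    gains = _band_gains(fs, tuple(freqs), 7.0)
    for j, fj in enumerate(freqs):
        amp = mix[:, j, :] / gains[j]  # (n_tau, s), gain-equalized
        if not np.any(amp):
            continue
        phase = rng.uniform(0.0, 2.0 * np.pi, size=config.n_channels)
        carrier = np.cos(2.0 * np.pi * fj * t[:, None] + phase[None, :])
        sig += amp[win_idx, :] * carrier
    if config.noise_scale > 0:
        white = rng.standard_normal((n, config.n_channels))
        spec = np.fft.rfft(white, axis=0)
        f_axis = np.fft.rfftfreq(n, 1.0 / fs)
        shaping = 1.0 / np.sqrt(np.maximum(f_axis, 1.0))
        pink = np.fft.irfft(spec * shaping[:, None], n=n, axis=0)
        pink /= pink.std() if pink.std() > 0 else 1.0
        sig += config.noise_scale * pink
    return sig


def _epoch_features(config, templates, intent, correctness, rng):
    """One epoch's feature tensor in the configured generation mode."""
    if config.raw_mode:
        sig = generate_raw_signal(config, templates, intent, correctness, rng)
        return morlet_features(sig, config.sampling_rate, n_tau=config.n_tau)
    mix = config.intent_snr * np.tensordot(
        np.asarray(intent, dtype=float), templates.intent_templates, axes=1
    )
    mix = mix + config.cmtp_snr * correctness * templates.cmtp_template
    noise = config.noise_scale * rng.standard_normal(config.feature_shape)
    return mix + noise


# ---------------------------------------------------------------------------
# paradigm 1: discrete multi-state effector


def simulate_discrete_session(
    config: SimConfig,
    templates: GroundTruthTemplates,
    controller,
    duration: float,
    session_id: str = "sess",
    rng: np.random.Generator | None = None,
) -> SessionStream:
    """Closed-loop session of the 4-state discrete paradigm.

    The cue schedule is a sequence of fixed-length blocks cycling
    through the classes in random order; the effector state at each
    epoch is the controller's argmax computed on the *previous*
    epoch's features (one-step feedback delay).  Features encode the
    desired state and the correctness of the current effector state.
    """
    if duration < config.epoch_len:
        raise ValueError("duration shorter than one epoch")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.n_classes
    stride = config.epoch_stride
    n_epochs = int(np.floor((duration - config.epoch_len) / stride + 1e-9)) + 1
    times = config.epoch_len + stride * np.arange(n_epochs)

    # cue schedule: blocks cycling all classes in random order
    n_blocks = int(np.ceil(duration / config.block_len)) + 1
    order = []
    while len(order) < n_blocks:
        order.extend(rng.permutation(m).tolist())
    desired = np.array(
        [order[int(t // config.block_len)] for t in times], dtype=int
    )

    actual = np.empty(n_epochs, dtype=int)
    scores_log = np.empty((n_epochs, m))
    feats = np.empty((n_epochs,) + config.feature_shape)
    tsc = np.empty(n_epochs)  # time since last actual-state change, at epoch end
    last_change = -np.inf
    prev_feat = None
    prev_actual = None
    for i in range(n_epochs):
        intent = np.zeros(m)
        intent[desired[i]] = 1.0
        if prev_feat is None:
            scores = np.asarray(controller(None, intent, rng), dtype=float)
        else:
            scores = np.asarray(controller(prev_feat, intent, rng), dtype=float)
        if scores.shape != (m,):
            raise ValueError(
                f"controller returned {scores.shape}, expected ({m},) scores"
            )
        actual[i] = int(np.argmax(scores))
        scores_log[i] = scores
        if prev_actual is not None and actual[i] != prev_actual:
            last_change = times[i] - stride  # state switched at the step boundary
        prev_actual = actual[i]
        tsc[i] = times[i] - last_change
        correct = 1.0 if actual[i] == desired[i] else -1.0
        feats[i] = _epoch_features(config, templates, intent, correct, rng)
        prev_feat = feats[i]

    telemetry = {
        "desired_class": desired,
        "actual_class": actual,
        "time_since_change": tsc,
        "control_scores": scores_log,
        "correct_flag": np.where(actual == desired, 1, -1).astype(int),
    }
    return SessionStream(session_id, "discrete", times, feats, telemetry, config)


# ---------------------------------------------------------------------------
# paradigm 2: 2D center-out cursor


def angular_deviation_deg(disp: np.ndarray, optimal: np.ndarray) -> np.ndarray:
    """Unsigned angle (degrees) between performed displacements and
    optimal (cursor-to-target) directions; NaN where either vector is
    zero (undefined angle)."""
    disp = np.atleast_2d(disp)
    optimal = np.atleast_2d(optimal)
    dn = np.linalg.norm(disp, axis=1)
    on = np.linalg.norm(optimal, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", disp, optimal) / (dn * on)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ang[(dn == 0) | (on == 0)] = np.nan
    return ang


def windowed_mean_angle(angles: np.ndarray, window: int = ANGLE_WINDOW_STEPS) -> np.ndarray:
    """Trailing mean of per-step angular deviations.

    NaN steps (undefined angles) are excluded from each window's mean;
    a window with no defined step yields NaN.
    """
    angles = np.asarray(angles, dtype=float)
    out = np.full(len(angles), np.nan)
    for i in range(len(angles)):
        w = angles[max(0, i - window + 1) : i + 1]
        w = w[~np.isnan(w)]
        if w.size:
            out[i] = w.mean()
    return out


def correctness_from_mean_angle(mean_angle: np.ndarray) -> np.ndarray:
    """Ternary correctness from windowed mean deviation: +1 below 60
    degrees, -1 above 90 degrees, 0 in between or undefined (the same
    convention the cMTP labeling applies; boundary values are
    ambiguous)."""
    mean_angle = np.asarray(mean_angle, dtype=float)
    c = np.zeros(len(mean_angle), dtype=int)
    with np.errstate(invalid="ignore"):
        c[mean_angle < ANGLE_CORRECT_DEG] = 1
        c[mean_angle > ANGLE_ERROR_DEG] = -1
    return c


def simulate_centerout_session(
    config: SimConfig,
    templates: GroundTruthTemplates,
    controller,
    n_trials: int,
    session_id: str = "sess",
    rng: np.random.Generator | None = None,
) -> SessionStream:
    """Closed-loop 2D center-out session.

    Every 0.1 s the controller's 2-vector output is rescaled so its
    norm does not exceed ``speed_cap`` and integrated into the cursor
    position; a trial ends at target acquisition (distance below
    ``target_radius``) or at ``trial_timeout``.  The correctness flag
    driving feature generation is recomputed from the same trailing
    0.5 s mean angular deviation the labeling rules use.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dt = config.epoch_stride
    max_steps = int(round(config.trial_timeout / dt))
    target_angles = 2.0 * np.pi * np.arange(config.n_targets) / config.n_targets

    rows = {
        k: []
        for k in (
            "cursor_x",
            "cursor_y",
            "target_x",
            "target_y",
            "disp_x",
            "disp_y",
            "control_x",
            "control_y",
            "mean_angle",
            "correct_flag",
            "trial",
            "acquired",
        )
    }
    feats = []
    prev_feat = None
    t_now = config.epoch_len
    times = []
    for trial in range(n_trials):
        a = target_angles[rng.integers(config.n_targets)]
        target = config.ring_radius * np.array([np.cos(a), np.sin(a)])
        cursor = np.zeros(2)
        step_angles = []
        acquired = False
        for step in range(max_steps):
            optimal = target - cursor
            out = np.asarray(controller(prev_feat, optimal, rng), dtype=float)
            if out.shape != (2,):
                raise ValueError("controller must return a 2-vector")
            speed = np.linalg.norm(out)
            v = out if speed <= config.speed_cap else out * (config.speed_cap / speed)
            disp = v * dt
            new_cursor = cursor + disp
            r = np.linalg.norm(new_cursor)
            if r > config.workspace_radius:
                new_cursor *= config.workspace_radius / r
                disp = new_cursor - cursor
            ang = angular_deviation_deg(disp[None], optimal[None])[0]
            step_angles.append(ang)
            mean_ang = windowed_mean_angle(np.array(step_angles))[-1]
            flag = correctness_from_mean_angle(np.array([mean_ang]))[0]
            intent_dir = optimal / np.linalg.norm(optimal) if np.linalg.norm(optimal) else np.zeros(2)
            feat = _epoch_features(config, templates, intent_dir, float(flag), rng)
            feats.append(feat)
            times.append(t_now)
            t_now += dt
            rows["cursor_x"].append(cursor[0])
            rows["cursor_y"].append(cursor[1])
            rows["target_x"].append(target[0])
            rows["target_y"].append(target[1])
            rows["disp_x"].append(disp[0])
            rows["disp_y"].append(disp[1])
            rows["control_x"].append(out[0])
            rows["control_y"].append(out[1])
            rows["mean_angle"].append(mean_ang)
            rows["correct_flag"].append(flag)
            rows["trial"].append(trial)
            cursor = new_cursor
            prev_feat = feat
            if np.linalg.norm(target - cursor) < config.target_radius:
                acquired = True
                break
        rows["acquired"].extend([acquired] * len(step_angles))

    telemetry = {k: np.asarray(v) for k, v in rows.items()}
    return SessionStream(
        session_id,
        "continuous",
        np.asarray(times),
        np.stack(feats),
        telemetry,
        config,
    )
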
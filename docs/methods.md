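# Methods

This note documents the models and procedures implemented in `aabci`,
the assumptions behind them, the defaults and why they were chosen,
and what the synthetic data does and does not establish.

## The auto-adaptive decoding loop

A motor BCI maps per-epoch neural feature tensors to effector
commands through a *control decoder*. Supervised (re)calibration of
that decoder requires knowing the user's intent, which interrupts
free use. The auto-adaptive loop removes that requirement with a
second, binary decoder of *continuous motor-task performance*
(cMTP): a tensor regression trained once, supervised, to score from
neural features whether the effector's current behavior matches the
user's intent. During free use, epochs whose cMTP score is far
enough into either tail of its score distribution are treated as
certainly-correct or certainly-erroneous; those epochs, relabeled
from the control decoder's own output, form training batches that
update the control decoder online. No externally supplied label
enters the loop after the cMTP decoder is trained.

Two paradigms are supported end to end:

* **discrete** — a 4-state effector driven by motor imagery; control
  labels are one-hot state encodings, performance is the Hand–Till
  multiclass ROC AUC;
* **continuous** — a 2D center-out cursor (8 targets, 0.08 m/s speed
  saturation, 0.1 s update rate); control labels are the directed
  cursor-to-target distance, performance is the mean cosine between
  predicted and optimal (cursor-to-target) vectors.

## Feature tensors

Epochs of 1 s, strided by 0.1 s (90% overlap) and labeled by their
end time, are decomposed per channel with a complex Morlet continuous
wavelet transform at central frequencies 10–150 Hz in 10 Hz steps
(15 bands). Magnitudes are averaged in ten non-overlapping 100 ms
windows, giving a (10, 15, s) tensor per epoch — 9600 features at
s = 64 channels.

The Morlet width is not dictated by the processing chain; the default
is ~7 cycles per wavelet (a time-bandwidth product sigma_t·f ≈ 1.11),
the common compromise between time and frequency resolution in the
10–150 Hz range; it is configurable. The preferred path transforms
the whole recording once and slices epochs out of the transform, so
overlapping epochs share coefficients and no per-epoch edge artifacts
arise; a per-epoch mode with reflection padding exists for streaming
use. Below ~40 Hz the wavelet support exceeds the epoch, so the two
paths genuinely differ there (documented in the tests). No channel
or band normalization is applied at this stage; centering happens
inside the decoders.

## NPLS tensor regression

The control and cMTP decoders are N-way partial least squares
regressions from (N, tau, f, s) tensors to (N, m) responses. Per
factor, the covariance tensor between centered predictors and the
current response residual is reduced to its best rank-1 approximation
(alternating least squares from an HOSVD initializer; for
multivariate responses the response direction and mode weights are
iterated jointly, one ALS sweep per exchange). Sample scores are
inner products with the rank-1 weight tensor; the response is
regressed on all accumulated scores and deflated on Y only. Both X
and Y are centered; no variance scaling is applied (band-power scales
are meaningful). Signs are fixed by forcing the first non-zero
component of the time and frequency weights positive, absorbed into
the channel weights; fitted values are invariant to this convention.

Numerical choices: ALS converges on a relative change of the core
value below 1e-9 (at most 100 sweeps); a vanishing covariance tensor
stops factor extraction early; regression in score space uses least
squares on the accumulated-score normal equations. With singleton
time and frequency modes the procedure reduces exactly to matrix
PLS1, which the test-suite verifies against an external
implementation to 1e-8.

The cMTP decoder uses 20 factors by default (exposed as a plain
parameter). `rank1_tensor_regression` additionally provides the
exact single-component estimator (ALS on the regression objective,
initialized from the NPLS factor) for parameter-recovery settings
where the generating rank-1 weights themselves are wanted: the PLS
covariance factor is consistent but finite-sample-noisy, while the
regression ALS recovers noiseless rank-1 weights essentially exactly.

## REW-NPLS: recursive updates with forgetting

The online control decoder maintains exponentially weighted sufficient
statistics — weighted sums of x, y, x·y' and the Gram matrix x·x' of
flattened tensors — decayed by a forgetting factor `lam` at each
mini-batch and re-fits the NPLS model from those moments after every
update. Because the moment-based fit is algebraically identical to
the batch fit, `lam = 1` reproduces batch NPLS exactly (the module's
primary oracle, tested to 1e-6 and observed at ~1e-15). Memory is
constant in the number of updates. The p × p Gram matrix makes the
recursion practical for the moderate feature counts used here
(hundreds to a few thousand); at the full 9600 features it costs
~700 MB, which is the price of an exact moment-based recursion.

The factor count is re-selected after every update from a prequential
(test-then-train) squared-error estimate: each incoming batch is
scored with the *previous* model at every candidate count 1..f_max
before being absorbed, so the estimate is honestly out-of-sample.
The error accumulator has its own forgetting factor (`err_lam`,
default 0.9) so selection tracks the decoder's current quality;
without it the untrained early history would pin the selection at one
factor indefinitely. Ties go to the smaller count. Defaults:
`lam = 1` (no forgetting; drift experiments set it below 1
explicitly), `f_max = 20`.

A freshly initialized state predicts the zero vector — decoders in
the auto-adaptive loop are trained strictly from scratch.

## cMTP labeling rules

* Discrete: an epoch is correct iff the effector state equals the
  desired state; epochs containing any data from the interval
  (0, 500 ms] after an effector state change are discarded
  (reaction-time uncertainty), i.e. every epoch whose end lies within
  `epoch_len + 0.5 s` after the change. The exclusion applies to
  effector-state changes, not cue changes.
* Continuous: per 0.1 s step, the unsigned angle between the
  performed displacement and the cursor-to-target vector at the
  step's start is averaged over a trailing 0.5 s (5-step) window that
  never crosses trial boundaries; a mean above 90° labels the epoch
  erroneous, below 60° correct, anything in [60°, 90°] is discarded.
  Thresholds are strict; zero-length displacements have undefined
  angles and are excluded from the window mean (a window with no
  defined step is discarded). The trailing (causal) window keeps the
  rule usable online.

To prevent motor confounds in the discrete paradigm, each correctness
class is oversampled (deterministic cycling repetition) until its
motor-class histogram is uniform. Continuous motor actions are not
oversampled; an 8-bin displacement-direction tag is kept for
diagnostics only.

## Certainty gating and relabeling

The cMTP score on its own training set is modeled per class as a
Gaussian: `th_corr = mu_corr + a·sigma_corr`,
`th_err = mu_err − a·sigma_err`, with `a = 1` by default. Scores
above `th_corr` are treated as correct, below `th_err` as erroneous,
anything in between is dropped; inequalities are strict and
degenerate fits (`th_err ≥ th_corr`) discard everything with a
warning rather than crashing a session. Scores are used on the raw
regression scale (not clipped to [0, 1]); the Gaussian model lives on
that same scale. Keeping only the tails provably raises the accuracy
of the correctness calls among accepted epochs whenever the class
score distributions are overlapping Gaussians with
`mu_corr > mu_err` — the mechanism that makes estimated labels good
enough to train on (verified against the Gaussian-tail closed form).

Relabeling: φ1 (discrete) emits the one-hot encoding of the control
output's most probable class for correct-gated epochs and of its
second most probable class for error-gated ones (argmax ties break to
the lowest index); φ2 (continuous) keeps the control output itself
for correct-gated epochs only. A zero control output that passes the
gate is kept as-is (documented hazard).

In the pseudo-online replay the control output consumed by φ1/φ2 is
the *recorded* controller output stored in session telemetry — the
output that actually drove the effector and to which the user's
perceived-correctness signal refers. The adaptively trained decoder's
own prediction for every epoch is still computed and logged before
any update that consumes that epoch (the causality contract), and is
what the evaluation metrics are computed from.

Updates fire each time 150 accepted epochs (15 s of labeled data at
the 0.1 s epoch rate) have accumulated; a partial batch at session
end is not flushed. The shuffled-cMTP control condition permutes the
cMTP score sequence within each session (seeded) before gating,
preserving the score marginal while destroying its alignment with
the epochs.

## Synthetic sessions

The clinical recordings this pipeline was designed for are not
distributable, so the simulator generates closed-loop sessions with
known ground truth. Each epoch's feature tensor is

    X = intent_snr · T_intent + cmtp_snr · c · T_cmtp + noise,

with unit-norm sparse templates of disjoint support (hence exactly
orthogonal: intent and correctness correlates cannot trivially
alias), `c ∈ {+1, 0, −1}` the correctness flag computed by the *same*
windowed labeling conventions the pipeline uses (so generator flags
and recomputed labels agree exactly on non-discarded epochs), and
i.i.d. standard Gaussian feature noise. A raw-signal mode instead
synthesizes band-limited oscillatory bursts at 586 Hz whose per-band
amplitudes are gain-equalized so the extracted Morlet tensor is
proportional to the template mixture (negative mixture values are
clipped: an erroneous epoch silences rather than inverts the
correctness cells), plus 1/f-shaped noise; it exercises the feature
module end to end and is off by default for speed.

Sessions are "recorded" under controllers of intermediate skill,
emulating data acquired while an already-functional decoder drove the
effector:

* discrete — a sticky noisy decoder that re-decides the state at cue
  changes and at rate 0.05 per step, choosing the desired state with
  probability 0.65; persistence matters, since a state flipping every
  0.1 s step would leave no epoch outside the 500 ms exclusion;
* continuous — an episodic decoder alternating well-controlled
  episodes (angular error SD 35°) and mis-controlled episodes (error
  140° ± 30°, random sign, long-run fraction 0.4) with ~2 s dwell;
  episode persistence is what gives the windowed rule both clearly
  correct and clearly erroneous epochs.

Default geometry: workspace radius 0.2 m, target ring 0.15 m, target
radius 0.02 m, 15 s timeout — a full-speed straight path acquires a
target in ~17 steps. Cue blocks of 5 s cycle the four classes in
random order; idle periods are not simulated. Everything is driven
by a single seeded generator: identical config + seed gives
bit-identical sessions.

**SNR calibration (study conditions).** `cmtp_snr` is set so the
cMTP decoder attains intermediate, not ceiling, accuracy — the regime
the method is designed for: 0.5 at the default 64/8-channel
geometries and 0.4 at the 4-channel experiment scale, both giving
session-wise 5-fold CV AUC ≈ 0.63–0.68. `intent_snr = 2.0` puts
supervised control decoding at multiclass AUC ≈ 0.84 / cosine ≈ 0.7 —
good but short of ceiling. These were fixed from the cMTP CV AUC
band alone, before any training-method comparison was run.

## The canned experiment

For each seed, `n_sessions` sessions are generated and split into
three chronologically contiguous groups (sizes equal up to one);
one group trains the cMTP decoder (20 factors) and its gating
thresholds, a second trains the control decoder from scratch in each
mode (supervised / auto-adaptive / shuffled), and the third is the
test split. Optionally all six role permutations are run.
Chronological (not random) splits mirror session-wise separation and
probe temporal robustness; a seeded-random alternative is a config
switch.

Problem sizes: the default experiment uses 4 channels (600 features
per epoch), 3 sessions per seed of 1200 s (discrete) or 120 center-out
trials (continuous), and `f_max = 10` for the online decoder — sizes
chosen so the full 10-seed, two-paradigm comparison is a
minutes-scale computation on one CPU while leaving every rate and
threshold of the method (epoch geometry, 15 s update quantum, a = 1
gating, 60/90/500 ms labeling, 20 cMTP factors) at its reference
value. Under these conditions the comparison reproduces the
qualitative ordering supervised > auto-adaptive > shuffled on both
paradigms, with the auto-adaptive vs shuffled difference significant
by two-sided rank-sum at p < 0.05 over 10 seeds, and auto-adaptive
gate/label accuracies in the same ranges the method reports at
clinical scale.

## What the synthetic results do and do not show

The simulator realizes the assumptions the decoders rely on —
additive low-rank class templates, Gaussian feature noise, exactly
orthogonal intent and correctness correlates, binary correctness,
stationary statistics within a run. Real ECoG violates all of these
to some degree: correlated 1/f noise across bands and channels,
overlapping and drifting correlates, graded errors, inter-session
nonstationarity. Passing tests therefore establish the *internal*
correctness of the algorithms and the *mechanism* of the
auto-adaptive loop (gating boosts label quality; label quality
ranks the training methods), not clinical effect sizes. Known
limitations, by design: no biophysical forward model, no artifacts or
line noise, no inter-subject variability, no idle state in the
discrete paradigm, no online re-training of the cMTP decoder itself,
and binary (not graded) correctness.
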
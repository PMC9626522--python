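# Methods

This note documents the models implemented in `emgsar`, the assumptions
behind them, the synthetic data they are evaluated on, and the choices made
where the design was genuinely open.

## Signal model and blanking semantics

A recording is a multi-channel EMG series `x(t)` at a fixed rate (1 kHz in
all packaged protocols), a boolean blanking mask, the ordered sample
indices `t_k` at which each stimulation pulse ends, and optionally a
reference channel `u(t)` sampled from the stimulation line. Indices are
0-based and intervals half-open.

Blanked samples are acquired while the front-end suspends sampling during
pulse generation; whatever value they carry is meaningless. Every consumer
in the package therefore consults the mask: the filters pass blanked
samples through and exclude them from learning, the metrics exclude them
from RMSE/SNR sums, and feature extraction deletes them (concatenating the
remainder) before computing anything. In files written by real hardware the
held ADC value is whatever the device wrote; the synthetic generator stores
the clean EMG value with zero artifact there, which keeps the semi-synthetic
additivity identity exact.

Preprocessing is a 50 Hz IIR notch (quality factor 30 — a narrow standard
mains notch) followed by a 2nd-order Butterworth high-pass at 20 Hz,
applied causally by default because the deployment is real-time;
forward-backward filtering is available as an option. The reference channel
is left unfiltered (it is a stimulation measurement, not EMG). Whether
filtering runs before or after artifact removal is configurable; the
packaged evaluations filter nothing because the synthetic EMG is already
zero-mean and band-limited with no mains component.

## The two filters

**Template Subtraction** maintains, per channel, a length-`N` template
`W(i)` updated by a first-order exponential average of the *raw* post-pulse
waveform and subtracted sample-by-sample (update-then-subtract, which is
causal). Consequences that the tests pin down:

* with a strictly periodic identical artifact and no EMG, the residual
  after pulse `k` is exactly `(1−α)^k` of the artifact;
* the recursion equals the explicit exponentially weighted average
  `Σ_j α(1−α)^{k−j} x_j(i)` of past pulses (brute-force oracle);
* EMG occurring in the post-pulse window is learned into the template — no
  activity gating is applied — so TS injects a small noise floor of
  variance `σ²·α/(2−α)` per template tap.

**ε-NLMS** holds one weight vector per EMG channel, all driven by the
shared reference history. Each processed sample subtracts `wᵀu(t)` and
applies the normalized update with regularizer ε (default 1e-6, just large
enough to avoid division by zero on a silent reference). Weights persist
across pulses and the whole recording (adaptive filters accumulate
learning); `reset_per_pulse` exposes the stricter alternative. By default
the filter runs only within the `N` samples following each pulse end
(windowed mode, matching execution immediately after each pulse);
`window_only=False` runs it on every non-blanked sample.

Both filters re-arm when a new pulse arrives: the post-pulse window is
truncated at the next pulse end, and template entries not reached keep
their previous values. Template/weight initialization is zeros. Per-channel
hyperparameters are supported by the optimizer, but all packaged protocols
share one (α, N) across channels, as deployed. Defaults are the deployed
real-time values: TS α=0.06, ε-NLMS α=0.035, N=25.

The streaming shape of both algorithms is exposed through scikit-learn
style estimators (`TemplateSubtraction`, `EpsilonNLMS`): `fit` validates
parameters (they are online filters; there is no training pass),
`transform` runs the stream and leaves the final per-channel states in
`states_`.

## Synthetic data generator

The generator emulates the ingredients the evaluation needs, not muscle
biophysics:

* **EMG** — band-limited (20–450 Hz) Gaussian noise, amplitude-modulated by
  a movement schedule with ~50 ms activation ramps. Each movement class
  drives its channel at `emg_amplitude` (RMS 1.0 by default) with 0.15
  crosstalk elsewhere; rest is a 0.08 tonic baseline; per-channel gains
  (0.6–2.2) reproduce the large between-channel amplitude variance of
  implanted electrodes. An optional `secondary_drive` makes a movement also
  drive the next channel (shared muscles → confusable classes).
* **Artifacts** — pulse trains (20–50 Hz). Each pulse blanks 3 samples
  (~3 ms: the biphasic pulse plus front-end recovery; this value also
  reproduces the observed performance plateau at N ≥ 30 for 33-sample
  inter-pulse spacing) and is followed by an exponential tail with time
  constant 5 ms, scaled per channel with channel-specific sign
  (gains 1.0, −0.7, 0.5, −0.35 relative to `stim_amplitude`). A
  two-exponential tail, pulse-timing jitter, and per-pulse amplitude
  variation are available for harder conditions.
* **Reference** — the shared unit tail train scaled by `ref_gain`, plus
  2% measurement noise (a recorded stimulation channel is highly
  correlated with, not identical to, the artifact source). Per-channel
  artifacts are FIR-filtered copies of it, so an exact FIR relationship
  exists for ε-NLMS to identify; per-pulse amplitude variation multiplies
  reference and artifact alike, so a reference-driven filter can track it
  while a template average lags.
* **Superposition** — `corrupted = clean + artifact` exactly, making RMSE
  against the true clean signal and ΔSNR well defined.

Everything is deterministic given the config seed.

What the generator does *not* model: motor-unit action-potential structure,
volume conduction, electrode drift, amplifier saturation, nonstationary
artifact waveshape beyond the amplitude/timing jitter above. Passing tests
therefore demonstrate that the algorithms and the evaluation machinery
behave as the theory predicts under controlled conditions — not that any
particular clinical performance level will be attained on human recordings.

## Packaged study protocols (`emgsar.protocols`)

* **Optimization/sweep benchmark**: 32 records = 8 quiescent (rest) clean
  recordings × 4 stimulation settings (30/38/44/50 Hz at relative
  amplitudes 1.0/1.5/0.8/1.2). Records are 2 s — 60+ pulses, enough for
  both filters to converge at deployed learning rates, while keeping the
  exhaustive 20×40 grid (α log-spaced 0.005–0.5, N = 1–40, per channel,
  median RMSE objective, ties toward smaller α then smaller N) under a
  minute on one CPU. Rest-scenario clean signals mirror the semi-synthetic
  construction in which pure artifacts are superimposed on no-movement
  recordings.
* **Offline decoding benchmark**: 4 records of 16 s cycling the four
  movement classes in 1 s blocks; stimulation over the first half only, at
  14× the movement-EMG RMS ("strong artifacts"), so stimulation-free
  windows train the decoder and stimulation windows are scored in four
  conditions (clean / raw / TS / ε-NLMS). 25 training repetitions.
* **Motion Test emulation**: 20 Hz trains at 30× EMG RMS with 15% per-pulse
  amplitude variation and 1 sample of timing jitter — chosen, like the
  live protocol's titration, so stimulation impairs but does not abolish
  control. 5 classes (rest + 4 movements) × 5 trials, pooled over 3
  simulated participants (independent decoders and EMG), because a single
  network's predictions on far-out-of-distribution artifact features are
  arbitrary and single-decoder completion rates are dominated by that
  luck. Per-trial contraction effort varies uniformly in 0.85–1.1 of
  nominal.

## Decoder and features

Windows are 200 samples with 150 overlap (the real-time 200 ms/150 ms at
500 Hz variant is expressible through `WindowSpec.from_time`). Features per
channel: MAV, zero crossings, slope-sign changes, waveform length, computed
after blank removal; the ZC/SSC deadband θ defaults to 0. Window labels are
the majority movement class; a window counts as stimulated if any sample in
it is.

The decoder is a single hidden layer of 16 rectifier units with softmax
output, trained only on stimulation-free feature vectors: stratified
60/20/20 train/validation/test split, z-score normalization with statistics
from the training split only, and Gaussian augmentation at 10 dB per-vector
SNR applied to normalized training copies. Training runs epoch-wise (Adam,
via scikit-learn's MLP with `partial_fit`, so the explicit validation split
drives early stopping); stopping monitors validation log-loss — accuracy
saturates too early to be a useful monitor — with the best weights
restored. The packaged benchmarks use two augmentation copies and patience
of 60 epochs (max 500): with a single copy and short patience roughly a
quarter of repetitions end badly converged and condition accuracies spread
by ~20 percentage points, an artifact of the optimizer rather than of the
signals; the data protocol itself is unchanged.

## Metrics, scoring, and statistics

* `RMSE(x, x̂)` over non-blanked samples is the optimization objective
  (absolute, hence per-channel).
* `SNR(s, n) = 10·log10(Σs²/Σn²)`; `ΔSNR = SNR(x, x̂−x) − SNR(x, a)` is the
  amplitude-invariant comparison metric. Zero noise energy yields a `+inf`
  sentinel, zero signal energy `−inf`. Both metrics default to whole
  recordings excluding blanks; a windows-only restriction is available.
* Motion Test: each window's prediction is stamped at `w·step` seconds and
  a correct prediction credits one window step of cumulative correct time;
  a trial concludes when 1 s (non-continuous) accumulates within the 5 s
  limit, unsuccessful trials carry 5 s timed outcomes, and accuracy counts
  predictions issued up to conclusion only.
* Comparisons use the two-sided Wilcoxon rank-sum test (exact for small
  tie-free samples, tie-corrected normal approximation otherwise; an
  all-tied degenerate input returns p = 1) with Holm–Bonferroni step-down
  adjustment (monotone, capped at 1).

## Numerical and degenerate-input choices

Tolerances asserted in the tests follow the arithmetic: identities that are
exact in exact arithmetic are checked to 1e-9–1e-12; the semi-synthetic
additivity identity is checked at rounding level (1e-12) because
`(a+b)−a−b` is not bitwise zero in floating point. Median ΔSNR curves over
a finite benchmark carry Monte-Carlo fluctuation of order 0.01 dB, so the
monotone-in-N property is asserted with a 0.05 dB allowance, while the
plateau beyond the inter-pulse window is exact (the filter literally never
sees those template entries). Empty post-pulse segments, silent references,
all-blanked windows, single-class training sets, and empty prediction
streams raise typed errors rather than propagating NaNs.

## Known limitations

* TS learns movement EMG into its template; under proportional-intensity
  stimulation (amplitude tracking grip force) it lags by design — the
  generator's per-pulse amplitude variation emulates exactly this regime.
* ε-NLMS quality is bounded by reference fidelity; the injected reference
  noise scales with stimulation amplitude through the learned weights.
* The decoder's behavior on feature vectors far outside the training
  distribution (raw strong artifacts) is inherently arbitrary; ordering
  claims about raw-condition decoding are made on pooled medians, never on
  single windows.
* Completion in the Motion Test requires only 1 s of correct decoding in
  5 s, so completion rate saturates easily; completion time and movement
  accuracy are the finer-grained outcomes.
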
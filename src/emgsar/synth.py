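"""Synthetic EMG, stimulation-artifact trains, and semi-synthetic records.

The generator emulates the ingredients of a semi-synthetic evaluation of
stimulation-artifact removal:

* **EMG**: band-limited (default 20-450 Hz) Gaussian noise per channel,
  amplitude-modulated by a movement schedule. Each movement class drives
  "its" channel strongly with weak crosstalk onto the others; rest is a low
  tonic baseline. This captures the amplitude structure that time-domain
  EMG features and classifiers consume, not motor-unit physiology.
* **Artifacts**: stimulation pulse trains at 20-50 Hz. Each pulse blanks a
  few samples (acquisition suspended during pulse generation; values held)
  and is followed by an exponentially decaying tail with channel-specific
  amplitude and sign. A reference channel — a scaled copy of the shared
  tail generator, optionally convolved with a short FIR — reproduces the
  stimulation-line recording that drives the epsilon-NLMS filter, so a
  linear FIR relationship between reference and artifact exists by
  construction.
* **Superposition**: ``corrupted = clean + artifact`` exactly, so the
  ground-truth clean signal is known and RMSE / SNR-change metrics are
  well defined.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .signals import ConfigurationError, SignalRecording

__all__ = [
    "SynthConfig",
    "ArtifactTrain",
    "SemiSyntheticRecord",
    "generate_emg",
    "generate_artifact_train",
    "superimpose",
    "make_benchmark_set",
    "make_movement_set",
    "max_interpulse_samples",
]

#: movement-class inventory used throughout: 0 is rest, 1..4 map to the
#: hand-open / hand-close / pronate / supinate control channels.
CLASS_NAMES = ("rest", "hand_open", "hand_close", "pronate", "supinate")


@dataclass
class SynthConfig:
    """Generation parameters for synthetic recordings.

    Stimulation settings follow the study conditions: 1 kHz sampling,
    pulse trains in the 20-50 Hz range, blanked pulse spikes followed by
    exponential tails, per-channel artifact scaling, and a reference
    channel linearly related to the artifact.
    """

    sample_rate: float = 1000.0
    duration: float = 10.0
    n_channels: int = 4
    #: (class id, start s, end s); empty schedule = all rest
    movement_schedule: list[tuple[int, float, float]] = field(default_factory=list)
    emg_band: tuple[float, float] = (20.0, 450.0)
    #: RMS amplitude of an actively driven channel during movement
    emg_amplitude: float = 1.0
    #: tonic rest baseline RMS, as in quiescent muscle
    baseline_amplitude: float = 0.08
    #: crosstalk fraction of emg_amplitude seen on non-driven channels
    crosstalk: float = 0.15
    #: fraction of emg_amplitude a movement also drives onto the *next*
    #: channel (muscles shared between movements make classes confusable;
    #: 0 = each movement has a private muscle)
    secondary_drive: float = 0.0
    #: per-channel gain spread (multiplies all EMG on that channel)
    channel_gains: tuple[float, ...] | None = None
    stim_rate: float = 30.0
    stim_amplitude: float = 1.0
    #: per-channel artifact amplitude/sign relative to stim_amplitude
    artifact_gains: tuple[float, ...] | None = None
    tail_tau: float = 0.005
    tail_tau2: float | None = None  # optional slow second exponential
    tail_mix: float = 0.3
    blank_len: int = 3
    ref_gain: float = 1.0
    #: measurement-noise std on the reference channel (the stimulation line
    #: is sampled by a real ADC; its recording is highly correlated with,
    #: not identical to, the artifact source)
    ref_noise: float = 0.02
    #: FIR taps relating the reference to the artifact tails
    fir_taps: tuple[float, ...] = (1.0,)
    #: uniform jitter (in samples) applied to each pulse start
    pulse_jitter: int = 0
    #: relative std of per-pulse artifact amplitude variation. The scale
    #: factor multiplies reference and artifact alike (both originate from
    #: the stimulation pulse), so a reference-driven filter can track it
    #: while a template average lags behind.
    pulse_amp_jitter: float = 0.0
    stim_start: float | None = 0.0
    stim_stop: float | None = None  # None = end of recording
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or self.duration <= 0:
            raise ConfigurationError("sample_rate and duration must be positive")
        if self.stim_rate >= self.sample_rate / 2:
            raise ConfigurationError("stim_rate must be below the Nyquist rate")
        if self.blank_len < 0:
            raise ConfigurationError("blank_len must be >= 0")
        if self.tail_tau <= 0:
            raise ConfigurationError("tail_tau must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    def channel_gain_array(self) -> np.ndarray:
        if self.channel_gains is None:
            # spread of per-channel amplitudes, mirroring the large
            # between-channel variance of implanted recordings
            base = np.array([0.6, 1.0, 1.5, 2.2])
            g = np.resize(base, self.n_channels)
        else:
            g = np.asarray(self.channel_gains, dtype=float)
            if g.size != self.n_channels:
                raise ConfigurationError("channel_gains length must equal n_channels")
        return g

    def artifact_gain_array(self) -> np.ndarray:
        if self.artifact_gains is None:
            base = np.array([1.0, -0.7, 0.5, -0.35])
            g = np.resize(base, self.n_channels)
        else:
            g = np.asarray(self.artifact_gains, dtype=float)
            if g.size != self.n_channels:
                raise ConfigurationError("artifact_gains length must equal n_channels")
        return g


@dataclass
class ArtifactTrain:
    """Pure stimulation-artifact components of a recording."""

    artifact: np.ndarray  # (n_samples, n_channels)
    blank_mask: np.ndarray
    pulse_ends: np.ndarray
    reference: np.ndarray
    stim_labels: np.ndarray
    sample_rate: float


@dataclass
class SemiSyntheticRecord:
    """Clean signal, pure artifact, and their exact superposition."""

    clean: SignalRecording
    artifact: np.ndarray
    recording: SignalRecording  # corrupted = clean + artifact, with stim metadata

    @property
    def corrupted(self) -> np.ndarray:
        return self.recording.samples


def max_interpulse_samples(sample_rate: float, stim_rate: float) -> int:
    """Maximum number of samples between consecutive stimulation pulses.

    E.g. 1,000 Hz sampling with 30 Hz stimulation leaves at most 33 samples
    between pulses.
    """
    if stim_rate <= 0:
        raise ConfigurationError("stim_rate must be positive")
    return int(np.floor(sample_rate / stim_rate))


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------


def _envelopes(cfg: SynthConfig) -> np.ndarray:
    """Per-channel RMS envelope (n_samples, n_channels) from the schedule."""
    n, c = cfg.n_samples, cfg.n_channels
    gains = cfg.channel_gain_array()
    env = np.full((n, c), cfg.baseline_amplitude)
    for class_id, start, end in cfg.movement_schedule:
        i0 = max(0, int(round(start * cfg.sample_rate)))
        i1 = min(n, int(round(end * cfg.sample_rate)))
        if i1 <= i0 or class_id == 0:
            continue
        driven = (int(class_id) - 1) % c
        amp = np.full(c, cfg.crosstalk * cfg.emg_amplitude)
        amp[driven] = cfg.emg_amplitude
        if cfg.secondary_drive > 0:
            amp[(driven + 1) % c] = max(
                amp[(driven + 1) % c], cfg.secondary_drive * cfg.emg_amplitude
            )
        env[i0:i1, :] = np.maximum(env[i0:i1, :], amp[None, :])
    # ~50 ms raised-cosine smoothing avoids step discontinuities at class
    # boundaries (muscle activation ramps over tens of ms)
    win = int(round(0.05 * cfg.sample_rate))
    if win > 1:
        kernel = np.hanning(win)
        kernel /= kernel.sum()
        pad = np.pad(env, ((win, win), (0, 0)), mode="edge")
        env = np.apply_along_axis(lambda v: np.convolve(v, kernel, "same"), 0, pad)[
            win:-win
        ]
    return env * gains[None, :]


def _movement_labels(cfg: SynthConfig) -> np.ndarray:
    n = cfg.n_samples
    labels = np.zeros(n, dtype=np.intp)
    for class_id, start, end in cfg.movement_schedule:
        i0 = max(0, int(round(start * cfg.sample_rate)))
        i1 = min(n, int(round(end * cfg.sample_rate)))
        labels[i0:i1] = int(class_id)
    return labels


def generate_emg(cfg: SynthConfig) -> SignalRecording:
    """Band-limited Gaussian EMG, amplitude-modulated by the movement schedule.

    Rest periods carry a low tonic baseline; a movement class drives its
    associated channel at ``emg_amplitude`` (RMS) with ``crosstalk`` leakage
    onto the remaining channels. Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, c = cfg.n_samples, cfg.n_channels
    low, high = cfg.emg_band
    high = min(high, 0.45 * cfg.sample_rate)
    if low >= high:
        raise ConfigurationError("emg_band must satisfy low < high < Nyquist")
    sos = sps.butter(4, (low, high), btype="bandpass", fs=cfg.sample_rate, output="sos")
    white = rng.standard_normal((n + 200, c))
    shaped = sps.sosfilt(sos, white, axis=0)[200:]  # drop filter transient
    rms = np.sqrt(np.mean(shaped**2, axis=0))
    rms[rms == 0] = 1.0
    shaped /= rms[None, :]
    samples = shaped * _envelopes(cfg)
    return SignalRecording(
        samples=samples,
        sample_rate=cfg.sample_rate,
        movement_labels=_movement_labels(cfg),
        stim_labels=np.zeros(n, dtype=bool),
        channel_names=[f"ch{i}" for i in range(c)],
    )


# ---------------------------------------------------------------------------
# artifact trains
# ---------------------------------------------------------------------------


def generate_artifact_train(cfg: SynthConfig) -> ArtifactTrain:
    """Stimulation pulse train: blanked spikes followed by exponential tails.

    Each pulse blanks ``blank_len`` samples starting at the pulse onset; the
    first non-blanked sample is the pulse end ``t_k``. From ``t_k`` the
    artifact decays as ``A_c * exp(-i / (tail_tau * fs))`` per channel, with
    channel-specific amplitude and sign (optionally a two-exponential mix).
    The reference channel is the shared unit tail train scaled by
    ``ref_gain``; per-channel artifacts are FIR-filtered copies of it
    (``fir_taps``, default a single tap), mirroring a stimulation-line
    recording highly correlated with the artifact.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n, c = cfg.n_samples, cfg.n_channels
    fs = cfg.sample_rate
    period = int(round(fs / cfg.stim_rate))
    if cfg.blank_len >= period:
        raise ConfigurationError("blanking window overlaps the next pulse")

    start = int(round((cfg.stim_start or 0.0) * fs))
    stop = n if cfg.stim_stop is None else min(n, int(round(cfg.stim_stop * fs)))

    starts = np.arange(start, stop - cfg.blank_len - 1, period, dtype=np.intp)
    if cfg.pulse_jitter:
        jitter = rng.integers(-cfg.pulse_jitter, cfg.pulse_jitter + 1, size=starts.size)
        starts = np.sort(np.clip(starts + jitter, 0, stop - cfg.blank_len - 2))
        starts = starts[np.insert(np.diff(starts) > cfg.blank_len, 0, True)]

    blank_mask = np.zeros(n, dtype=bool)
    stim_labels = np.zeros(n, dtype=bool)
    unit = np.zeros(n)  # shared unit-amplitude tail generator g(t)
    pulse_ends = []
    decay = np.exp(-np.arange(n) / (cfg.tail_tau * fs))
    if cfg.tail_tau2 is not None:
        decay = (1 - cfg.tail_mix) * decay + cfg.tail_mix * np.exp(
            -np.arange(n) / (cfg.tail_tau2 * fs)
        )
    for k, s in enumerate(starts):
        tk = s + cfg.blank_len
        if tk >= n:
            break
        blank_mask[s:tk] = True
        pulse_ends.append(tk)
        scale = 1.0
        if cfg.pulse_amp_jitter > 0:
            scale = max(0.1, 1.0 + cfg.pulse_amp_jitter * rng.standard_normal())
        nxt = starts[k + 1] if k + 1 < starts.size else n
        span = min(n, nxt) - tk
        if span > 0:
            unit[tk:tk + span] += scale * decay[:span]
    if stop > start:
        stim_labels[start:stop] = True

    taps = np.asarray(cfg.fir_taps, dtype=float)
    shaped = np.convolve(unit, taps)[:n] if taps.size > 1 or taps[0] != 1.0 else unit
    gains = cfg.stim_amplitude * cfg.artifact_gain_array()
    artifact = shaped[:, None] * gains[None, :]
    artifact[blank_mask, :] = 0.0  # acquisition suspended: nothing reaches the EMG
    reference = cfg.ref_gain * unit
    if cfg.ref_noise > 0:
        reference = reference + cfg.ref_noise * cfg.ref_gain * rng.standard_normal(n)
    reference[blank_mask] = 0.0

    return ArtifactTrain(
        artifact=artifact,
        blank_mask=blank_mask,
        pulse_ends=np.asarray(pulse_ends, dtype=np.intp),
        reference=reference,
        stim_labels=stim_labels,
        sample_rate=fs,
    )


def superimpose(clean: SignalRecording, train: ArtifactTrain) -> SemiSyntheticRecord:
    """Superimpose pure artifacts onto artifact-free EMG.

    ``corrupted = clean + artifact`` holds exactly (machine precision), and
    the stimulation metadata (blank mask, pulse ends, reference, stim
    labels) is merged into the corrupted recording.
    """
    if train.artifact.shape != clean.samples.shape:
        raise ConfigurationError(
            f"shape mismatch: clean {clean.samples.shape} vs artifact {train.artifact.shape}"
        )
    if train.sample_rate != clean.sample_rate:
        raise ConfigurationError("sample_rate mismatch between clean signal and artifacts")
    corrupted = clean.replace(
        samples=clean.samples + train.artifact,
        blank_mask=train.blank_mask.copy(),
        pulse_ends=train.pulse_ends.copy(),
        reference=train.reference.copy(),
        stim_labels=train.stim_labels.copy(),
    )
    return SemiSyntheticRecord(clean=clean, artifact=train.artifact, recording=corrupted)


# ---------------------------------------------------------------------------
# benchmark sets
# ---------------------------------------------------------------------------

#: the four stimulation settings of the benchmark grid: (rate Hz, relative
#: amplitude), spanning the 30-50 Hz / amplitude range of the study
STIM_SETTINGS = ((30.0, 1.0), (38.0, 1.5), (44.0, 0.8), (50.0, 1.2))


def make_benchmark_set(
    cfg: SynthConfig | None = None,
    n_combinations: int = 32,
    seed: int | None = None,
) -> list[SemiSyntheticRecord]:
    """Semi-synthetic benchmark: rest-scenario EMG x stimulation settings.

    Clean signals are independently seeded rest recordings (quiescent EMG
    with per-channel amplitude spread); artifact trains cycle through the
    four stimulation settings in :data:`STIM_SETTINGS`. The Cartesian
    pairing of ``ceil(n/4)`` clean recordings with the 4 settings yields
    ``n_combinations`` records (default 32 = 8 clean x 4 settings).
    """
    if n_combinations < 1:
        raise ConfigurationError("n_combinations must be >= 1")
    cfg = cfg or SynthConfig(duration=2.0)
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    n_settings = len(STIM_SETTINGS)
    n_clean = int(np.ceil(n_combinations / n_settings))
    records = []
    for i in range(n_combinations):
        clean_idx, setting_idx = divmod(i, n_settings)
        rate, rel_amp = STIM_SETTINGS[setting_idx]
        clean_cfg = replace(cfg, movement_schedule=[], seed=cfg.seed + 101 * clean_idx)
        art_cfg = replace(
            clean_cfg,
            stim_rate=rate,
            stim_amplitude=cfg.stim_amplitude * rel_amp,
            seed=cfg.seed + 101 * clean_idx + 13 * setting_idx + 7,
        )
        records.append(superimpose(generate_emg(clean_cfg), generate_artifact_train(art_cfg)))
    assert len(records) == n_combinations
    return records


def make_movement_set(
    cfg: SynthConfig | None = None,
    n_records: int = 4,
    classes: tuple[int, ...] = (1, 2, 3, 4),
    segment: float = 0.75,
    seed: int | None = None,
) -> list[SemiSyntheticRecord]:
    """Semi-synthetic records with labelled movements for decoding studies.

    Each record cycles through ``classes`` in ``segment``-second blocks over
    the full duration; stimulation covers the first half only, so stim-free
    windows (for classifier training) and stim-contaminated windows (for
    evaluation) both exist for every class.
    """
    cfg = cfg or SynthConfig(duration=12.0)
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    records = []
    for i in range(n_records):
        schedule = []
        t = 0.0
        for class_id in itertools.cycle(classes):
            if t >= cfg.duration:
                break
            schedule.append((class_id, t, min(t + segment, cfg.duration)))
            t += segment
        rate, rel_amp = STIM_SETTINGS[i % len(STIM_SETTINGS)]
        clean_cfg = replace(cfg, movement_schedule=schedule, seed=cfg.seed + 211 * i)
        art_cfg = replace(
            clean_cfg,
            stim_rate=rate,
            stim_amplitude=cfg.stim_amplitude * rel_amp,
            stim_start=0.0,
            stim_stop=cfg.duration / 2,
            seed=cfg.seed + 211 * i + 5,
        )
        records.append(superimpose(generate_emg(clean_cfg), generate_artifact_train(art_cfg)))
    return records
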
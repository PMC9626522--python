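"""Canonical desk-scale study protocols.

These helpers freeze the synthetic study conditions used by the packaged
evaluations, so tests, scripts, and the command line all exercise the same
benchmark:

* :func:`benchmark_records` — the 32-record semi-synthetic set for RMSE
  optimization and SNR-improvement sensitivity sweeps: quiescent (rest)
  EMG with a per-channel amplitude spread, crossed with four stimulation
  settings spanning 30-50 Hz and an amplitude grid. Records are 2 s at
  1 kHz: long enough for both filters to converge at deployed learning
  rates (60+ pulses) while keeping an exhaustive 20 x 40 grid search
  tractable on one CPU.
* :func:`movement_records` / :func:`classifier_spec` — the offline
  decoding benchmark: four 16 s recordings cycling the four movement
  classes in 1 s blocks, stimulation over the first half only, with strong
  artifacts (14x the movement-EMG RMS) so raw decoding collapses while
  processed decoding recovers. The classifier settings (two 10 dB-SNR
  augmentation copies, long patience) train the small network to stable
  convergence; the data protocol — stimulation-free training, 60/20/20
  split, z-scoring from the training split — is unchanged.
* :func:`motion_test_config` — the real-time-protocol emulation: 20 Hz
  stimulation trains whose amplitude impairs but does not abolish control
  (30x movement EMG, with per-pulse amplitude variation and one sample of
  pulse-timing jitter, and a noisy reference channel). Under these
  conditions the raw-stimulation decoder mostly fails, template
  subtraction recovers most trials but lags the varying artifact, and the
  reference-driven filter tracks it at the cost of injected reference
  noise.
"""

from __future__ import annotations

from .mpr import ClassifierSpec
from .synth import SemiSyntheticRecord, SynthConfig, make_benchmark_set, make_movement_set

__all__ = [
    "benchmark_records",
    "movement_records",
    "classifier_spec",
    "motion_test_config",
    "DEPLOYED_TS",
    "DEPLOYED_NLMS",
]

#: deployed real-time hyperparameters (alpha, N)
DEPLOYED_TS = (0.06, 25)
DEPLOYED_NLMS = (0.035, 25)


def benchmark_records(seed: int = 0, n_combinations: int = 32) -> list[SemiSyntheticRecord]:
    """The 32-record rest-EMG benchmark for optimization and sweeps."""
    return make_benchmark_set(SynthConfig(duration=2.0, seed=seed), n_combinations)


def movement_records(seed: int = 0, n_records: int = 4) -> list[SemiSyntheticRecord]:
    """Strong-artifact movement recordings for offline decoding studies."""
    cfg = SynthConfig(duration=16.0, stim_amplitude=14.0, seed=seed)
    return make_movement_set(cfg, n_records=n_records, segment=1.0)


def classifier_spec(repetitions: int = 25, seed: int = 0) -> ClassifierSpec:
    """Decoder training settings used by the packaged benchmarks."""
    return ClassifierSpec(
        n_augment=2,
        max_epochs=500,
        patience=60,
        repetitions=repetitions,
        seed=seed,
    )


def motion_test_config(seed: int = 0) -> SynthConfig:
    """Stimulation conditions for the simulated Motion Test."""
    return SynthConfig(
        duration=5.2,
        stim_rate=20.0,
        stim_amplitude=30.0,
        crosstalk=0.35,
        pulse_jitter=1,
        pulse_amp_jitter=0.15,
        seed=seed,
    )
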
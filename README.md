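# emgsar

Real-time **stimulation-artifact removal (SAR)** for stimulation-synchronized
EMG, with a complete desk-scale evaluation stack that runs entirely on
synthetic data.

Closed-loop neuroprosthetic systems decode motor intent from implanted EMG
electrodes while delivering neurostimulation to nearby nerves for sensory
feedback. Each stimulation pulse couples into the EMG channels as a large
artifact: the acquisition hardware *blanks* (suspends sampling during) the
pulse itself, but a long exponential tail survives in the signal and
degrades myoelectric pattern recognition. This package is for researchers
and engineers building or evaluating such bi-directional interfaces.

## Algorithms

Both filters run sample-by-sample, re-arming at each stimulation pulse end
`t_k`, and ignore blanked samples.

**Template Subtraction (TS)** keeps a per-sample exponential average of the
post-pulse waveform and subtracts it:

```
W_k(i) = (1 − α) · W_{k−1}(i) + α · x(t_k + i − 1),   i = 1..N
x̂(t_k + i − 1) = x(t_k + i − 1) − W_k(i)
```

**ε-NLMS** predicts the artifact as a learned FIR combination of the last
`N` samples of a reference channel `u(t)` recorded from the stimulation
line, with the normalized LMS update:

```
x̂(t) = x(t) − wᵀu(t)
w ← w + α / (ε + ‖u(t)‖²) · u(t) · x̂(t)
```

The evaluation stack implements the surrounding methodology: semi-synthetic
signal construction (`corrupted = clean + artifact`, so the ground truth is
known), RMSE-based exhaustive hyperparameter optimization per channel,
ΔSNR = SNR_out − SNR_in sensitivity sweeps with quartile summaries,
MAV/ZC/SSC/WL feature extraction with blanked-sample removal and a
one-hidden-layer (ReLU → softmax) movement decoder, Motion Test outcome
scoring (completion rate/time, movement accuracy, selection time), and
Wilcoxon rank-sum statistics with Holm–Bonferroni correction.

## Worked example

```python
import numpy as np
from emgsar import (SynthConfig, generate_emg, generate_artifact_train,
                    superimpose, ts_apply, nlms_apply, delta_snr)

cfg = SynthConfig(duration=2.0, stim_rate=30.0, seed=1)
semi = superimpose(generate_emg(cfg), generate_artifact_train(cfg))

for name, cleaned in [
    ("TS   ", ts_apply(semi.recording, alpha=0.06, length=25).samples),
    ("eNLMS", nlms_apply(semi.recording, alpha=0.035, length=25).samples),
]:
    d = np.median([
        delta_snr(semi.clean.samples[:, c], semi.artifact[:, c], cleaned[:, c],
                  semi.recording.blank_mask)
        for c in range(4)
    ])
    print(f"{name} dSNR improvement: {d:+.2f} dB")
```

prints

```
TS    dSNR improvement: +8.88 dB
eNLMS dSNR improvement: +9.67 dB
```

i.e. on this 2-second rest recording with 30 Hz stimulation, both filters
remove roughly an order of magnitude more artifact energy than they inject,
at the deployed real-time parameters (TS α=0.06, ε-NLMS α=0.035, N=25).

Estimator-style front ends (`TemplateSubtraction`, `EpsilonNLMS`,
`EmgPatternClassifier`) expose the same operations with scikit-learn
`get_params`/`set_params`/`fit`/`transform` conventions, and the `emg-sar`
command line covers the pipeline end to end
(`synth`, `preprocess`, `denoise`, `optimize`, `sweep`, `mpr-eval`,
`motion-test`).

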
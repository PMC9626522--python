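"""Shared fixtures: expensive benchmark objects are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

import emgsar
from emgsar.protocols import (
    benchmark_records,
    classifier_spec,
    motion_test_config,
    movement_records,
)


@pytest.fixture(scope="session")
def benchmark32():
    """The canonical 32-record rest-EMG benchmark."""
    return benchmark_records(seed=1)


@pytest.fixture(scope="session")
def ts_n_sweep(benchmark32):
    """TS SNR-improvement sweep over N at the deployed learning rate."""
    return emgsar.sensitivity_sweep(
        benchmark32, "ts", vary="N", values=np.arange(1, 41), fixed={"alpha": 0.06}
    )


@pytest.fixture(scope="session")
def alpha_sweeps(benchmark32):
    """Learning-rate sweeps for both algorithms at N=25."""
    values = np.geomspace(0.005, 0.5, 10)
    return {
        algo: emgsar.sensitivity_sweep(
            benchmark32, algo, vary="alpha", values=values, fixed={"N": 25}
        )
        for algo in ("ts", "nlms")
    }


@pytest.fixture(scope="session")
def mpr_experiment():
    """Offline decoding comparison on the strong-artifact movement set."""
    records = movement_records(seed=3)
    spec = classifier_spec(repetitions=25, seed=0)
    return emgsar.offline_pr_experiment(records, spec=spec)


@pytest.fixture(scope="session")
def motion_result():
    """Simulated Motion Test under the real-time-protocol conditions."""
    return emgsar.simulate_motion_test(
        motion_test_config(),
        trials_per_class=5,
        seed=1,
        clf_spec=classifier_spec(seed=1),
    )


@pytest.fixture
def simple_recording():
    """Small deterministic 2-channel recording with two pulses."""
    rng = np.random.default_rng(42)
    n = 400
    samples = rng.standard_normal((n, 2))
    mask = np.zeros(n, dtype=bool)
    mask[100:103] = True
    mask[200:203] = True
    return emgsar.SignalRecording(
        samples=samples,
        sample_rate=1000.0,
        blank_mask=mask,
        pulse_ends=np.array([103, 203]),
        reference=rng.standard_normal(n),
        movement_labels=np.zeros(n, dtype=int),
        stim_labels=mask.copy(),
    )
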
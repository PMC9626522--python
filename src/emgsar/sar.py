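"""Streaming stimulation-artifact-removal (SAR) filters.

Two real-time algorithms, both pulse-aligned and blanking-aware:

Template Subtraction (TS)
    Maintains, for each of the ``N`` samples following a stimulation-pulse
    end, a first-order exponential average of the raw post-pulse waveform

        ``W_k(i) = (1 - alpha) * W_{k-1}(i) + alpha * x(t_k + i - 1)``

    and subtracts it from the incoming signal,

        ``xhat(t_k + i - 1) = x(t_k + i - 1) - W_k(i)``.

    The template is learned from the *raw* signal (never from the cleaned
    output), so with a strictly periodic artifact and zero EMG the residual
    after pulse ``k`` decays geometrically as ``(1 - alpha)^k``.

epsilon-NLMS
    A normalized least-mean-squares adaptive filter driven by a reference
    channel ``u(t)`` sampled from the stimulation line. With ``u(t)`` the
    vector of the ``N`` most recent reference samples,

        ``xhat(t) = x(t) - w^T u(t)``
        ``w <- w + alpha / (epsilon + ||u(t)||^2) * u(t) * xhat(t)``

    The regularizer ``epsilon > 0`` keeps the update finite when the
    reference is silent.

Both filters re-arm at every new stimulation pulse ("reset to start over"
once a new pulse is detected): the template index restarts, and with the
default windowed mode the NLMS filter processes only the ``N`` samples
following each pulse end. Blanked samples are passed through untouched and
excluded from all learning. Samples outside any post-pulse window pass
through unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .signals import ConfigurationError, SignalRecording

__all__ = [
    "TemplateState",
    "NlmsState",
    "SarResult",
    "ts_update",
    "ts_apply",
    "nlms_step",
    "nlms_apply",
    "TemplateSubtraction",
    "EpsilonNLMS",
]


# ---------------------------------------------------------------------------
# states
# ---------------------------------------------------------------------------


@dataclass
class TemplateState:
    """Per-channel template-subtraction state.

    ``template[i]`` is the learned artifact amplitude at sample ``i`` (0-based)
    after a pulse end; ``cursor`` counts samples elapsed since the last pulse
    end (``inf`` before the first pulse).
    """

    template: np.ndarray
    alpha: float
    cursor: float = math.inf

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=float)
        if self.template.ndim != 1 or self.template.size < 1:
            raise ConfigurationError("template must be a 1-d array of length N >= 1")
        if not 0 < self.alpha <= 1:
            raise ConfigurationError("alpha must be in (0, 1]")

    @property
    def length(self) -> int:
        return self.template.size

    @classmethod
    def zeros(cls, length: int, alpha: float) -> "TemplateState":
        return cls(template=np.zeros(int(length)), alpha=alpha)


@dataclass
class NlmsState:
    """Per-channel epsilon-NLMS state.

    ``ref_buffer[0]`` holds the most recent reference sample ``u(t)``,
    ``ref_buffer[j]`` holds ``u(t - j)``. Weights and buffer start at zero.
    """

    weights: np.ndarray
    alpha: float
    epsilon: float = 1e-6
    ref_buffer: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1 or self.weights.size < 1:
            raise ConfigurationError("weights must be a 1-d array of length N >= 1")
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be positive")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be positive")
        if self.ref_buffer is None:
            self.ref_buffer = np.zeros_like(self.weights)
        else:
            self.ref_buffer = np.asarray(self.ref_buffer, dtype=float)
            if self.ref_buffer.shape != self.weights.shape:
                raise ConfigurationError("ref_buffer must match weights in length")

    @property
    def length(self) -> int:
        return self.weights.size

    @classmethod
    def zeros(cls, length: int, alpha: float, epsilon: float = 1e-6) -> "NlmsState":
        return cls(weights=np.zeros(int(length)), alpha=alpha, epsilon=epsilon)


@dataclass
class SarResult:
    """Cleaned recording plus the final per-channel filter states."""

    cleaned: SignalRecording
    final_states: list

    @property
    def samples(self) -> np.ndarray:
        return self.cleaned.samples


# ---------------------------------------------------------------------------
# single-channel reference operations
# ---------------------------------------------------------------------------


def ts_update(
    state: TemplateState,
    post_pulse_segment: np.ndarray,
    blank: np.ndarray | None = None,
) -> TemplateState:
    """One template update from the raw post-pulse segment of a single pulse.

    Element ``i`` of the segment is the raw sample ``x(t_k + i)``. Segments
    shorter than ``N`` (truncated by the next pulse) update only the covered
    entries; entries beyond the segment keep their previous values. Samples
    flagged in ``blank`` are skipped. Entries beyond ``N`` are never stored.
    An empty segment returns the state unchanged.
    """
    seg = np.asarray(post_pulse_segment, dtype=float).ravel()
    if seg.size == 0:
        return TemplateState(state.template.copy(), state.alpha, cursor=state.cursor)
    n = min(seg.size, state.length)
    new = state.template.copy()
    keep = np.ones(n, dtype=bool)
    if blank is not None:
        keep &= ~np.asarray(blank, dtype=bool).ravel()[:n]
    a = state.alpha
    new[:n][keep] = (1.0 - a) * new[:n][keep] + a * seg[:n][keep]
    return TemplateState(new, a, cursor=float(seg.size))


def nlms_step(state: NlmsState, x_t: float, u_t: float) -> tuple[float, NlmsState]:
    """One epsilon-NLMS sample: push ``u_t``, subtract the estimate, adapt.

    Returns ``(xhat_t, new_state)``; the input state is left untouched.
    """
    u = np.empty_like(state.ref_buffer)
    u[0] = u_t
    u[1:] = state.ref_buffer[:-1]
    est = float(state.weights @ u)
    xhat = float(x_t) - est
    denom = state.epsilon + float(u @ u)
    w = state.weights + (state.alpha / denom) * u * xhat
    return xhat, NlmsState(w, state.alpha, state.epsilon, ref_buffer=u)


# ---------------------------------------------------------------------------
# whole-recording application
# ---------------------------------------------------------------------------


def _pulse_windows(rec: SignalRecording, length: int):
    """Yield half-open post-pulse windows ``(t_k, stop)``.

    Each window covers at most ``length`` samples after pulse end ``t_k``
    and is truncated by the next pulse (re-arm on new pulse) and the end of
    the recording.
    """
    pe = rec.pulse_ends
    n = rec.n_samples
    for k, tk in enumerate(pe):
        nxt = pe[k + 1] if k + 1 < pe.size else n
        stop = min(tk + length, nxt, n)
        if stop > tk:
            yield int(tk), int(stop)


def ts_apply(rec: SignalRecording, alpha: float = 0.06, length: int = 25) -> SarResult:
    """Run Template Subtraction over every channel of a recording.

    The template is updated from the raw signal, then subtracted, sample by
    sample within each post-pulse window. Blanked samples pass through and
    are excluded from learning; samples outside post-pulse windows pass
    through unchanged. Channels are processed independently with their own
    template state; ``alpha`` and ``length`` are shared.
    """
    if not 0 < alpha <= 1:
        raise ConfigurationError("alpha must be in (0, 1]")
    length = int(length)
    if length < 1:
        raise ConfigurationError("template length N must be >= 1")

    x = rec.samples
    n, c = x.shape
    xhat = x.copy()
    w = np.zeros((c, length))
    blank = rec.blank_mask
    cursor = math.inf
    for tk, stop in _pulse_windows(rec, length):
        m = ~blank[tk:stop]
        idx = np.flatnonzero(m) + tk
        ti = idx - tk  # template indices
        seg = x[idx, :]
        w[:, ti] = (1.0 - alpha) * w[:, ti] + alpha * seg.T
        xhat[idx, :] = seg - w[:, ti].T
        cursor = float(n - tk)

    states = [TemplateState(w[j].copy(), alpha, cursor=cursor) for j in range(c)]
    return SarResult(cleaned=rec.replace(samples=xhat), final_states=states)


def nlms_apply(
    rec: SignalRecording,
    alpha: float = 0.035,
    epsilon: float = 1e-6,
    length: int = 25,
    window_only: bool = True,
    reset_per_pulse: bool = False,
) -> SarResult:
    """Run the epsilon-NLMS filter over every channel of a recording.

    One weight vector per EMG channel, all driven by the shared reference.
    With ``window_only`` (default) the filter runs only on the ``length``
    samples following each pulse end, re-arming at each new pulse — matching
    execution immediately after each neurostimulation pulse; otherwise it
    runs on every non-blanked sample. Weights persist across pulses unless
    ``reset_per_pulse`` is set. Blanked samples pass through without any
    weight update; the reference history buffer always tracks the recorded
    reference stream.
    """
    if alpha <= 0:
        raise ConfigurationError("alpha must be positive")
    if epsilon <= 0:
        raise ConfigurationError("epsilon must be positive")
    length = int(length)
    if length < 1:
        raise ConfigurationError("filter length N must be >= 1")
    if rec.reference is None:
        raise ConfigurationError("epsilon-NLMS requires a reference channel")

    x = rec.samples
    n, c = x.shape
    u_stream = rec.reference
    blank = rec.blank_mask
    xhat = x.copy()
    w = np.zeros((c, length))
    buf = np.zeros(length)

    active = np.zeros(n, dtype=bool)
    if window_only:
        for tk, stop in _pulse_windows(rec, length):
            active[tk:stop] = True
    else:
        active[:] = True
    active &= ~blank

    reset_at = set(int(t) for t in rec.pulse_ends) if reset_per_pulse else ()

    # The reference buffer must advance on every sample (it is a history of
    # the recorded stream), so the loop covers all samples; the adaptive
    # arithmetic only runs where `active`.
    run = np.flatnonzero(active)
    prev = 0
    for t in run:
        seg = u_stream[prev:t + 1]
        if seg.size >= length:
            buf = seg[-1:-length - 1:-1].copy()
        else:
            buf[seg.size:] = buf[:-seg.size].copy()
            buf[:seg.size] = seg[::-1]
        prev = t + 1
        if t in reset_at:
            w[:] = 0.0
        denom = epsilon + float(buf @ buf)
        est = w @ buf
        e = x[t, :] - est
        xhat[t, :] = e
        w += (alpha / denom) * np.outer(e, buf)
    # flush remaining reference history into the buffer for the final state
    seg = u_stream[prev:]
    if seg.size >= length:
        buf = seg[-1:-length - 1:-1].copy()
    elif seg.size:
        buf[seg.size:] = buf[:-seg.size].copy()
        buf[:seg.size] = seg[::-1]

    states = [
        NlmsState(w[j].copy(), alpha, epsilon, ref_buffer=buf.copy()) for j in range(c)
    ]
    return SarResult(cleaned=rec.replace(samples=xhat), final_states=states)


# ---------------------------------------------------------------------------
# estimator-style front ends
# ---------------------------------------------------------------------------


class _SarEstimator(BaseEstimator):
    """Shared scaffolding: stateless streaming transformers over recordings.

    ``transform`` runs the filter front-to-back on a recording and returns
    the cleaned :class:`SignalRecording`; the final per-channel filter
    states are exposed as ``states_`` afterwards. ``fit`` only validates
    parameters (these are online filters — there is no separate training
    pass), which keeps the classes composable with sklearn-style pipelines
    and parameter search.
    """

    def fit(self, recording: SignalRecording, y=None):
        self._validate()
        return self

    def transform(self, recording: SignalRecording) -> SignalRecording:
        result = self._run(recording)
        self.states_ = result.final_states
        return result.cleaned

    def fit_transform(self, recording: SignalRecording, y=None) -> SignalRecording:
        return self.fit(recording).transform(recording)

    # subclasses provide _validate / _run


class TemplateSubtraction(_SarEstimator):
    """Template-subtraction artifact removal as a recording transformer.

    Parameters mirror the deployed real-time configuration: learning rate
    ``alpha`` (default 0.06) and template length ``length`` (default 25
    samples).
    """

    def __init__(self, alpha: float = 0.06, length: int = 25):
        self.alpha = alpha
        self.length = length

    def _validate(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ConfigurationError("alpha must be in (0, 1]")
        if int(self.length) < 1:
            raise ConfigurationError("length must be >= 1")

    def _run(self, recording: SignalRecording) -> SarResult:
        return ts_apply(recording, alpha=self.alpha, length=self.length)


class EpsilonNLMS(_SarEstimator):
    """epsilon-NLMS artifact removal as a recording transformer.

    Defaults mirror the deployed real-time configuration: ``alpha=0.035``,
    ``length=25``, ``epsilon=1e-6``, windowed execution after each pulse.
    """

    def __init__(
        self,
        alpha: float = 0.035,
        epsilon: float = 1e-6,
        length: int = 25,
        window_only: bool = True,
        reset_per_pulse: bool = False,
    ):
        self.alpha = alpha
        self.epsilon = epsilon
        self.length = length
        self.window_only = window_only
        self.reset_per_pulse = reset_per_pulse

    def _validate(self) -> None:
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be positive")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be positive")
        if int(self.length) < 1:
            raise ConfigurationError("length must be >= 1")

    def _run(self, recording: SignalRecording) -> SarResult:
        return nlms_apply(
            recording,
            alpha=self.alpha,
            epsilon=self.epsilon,
            length=self.length,
            window_only=self.window_only,
            reset_per_pulse=self.reset_per_pulse,
        )
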
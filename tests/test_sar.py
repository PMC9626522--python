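"""The two artifact-removal filters: recursions, convergence, causality."""

import numpy as np
import pytest

from emgsar import (
    ConfigurationError,
    EpsilonNLMS,
    NlmsState,
    SignalRecording,
    TemplateState,
    TemplateSubtraction,
    nlms_apply,
    nlms_step,
    ts_apply,
    ts_update,
)


def periodic_artifact_recording(tail, period=40, n_pulses=12, first=50, n_channels=1, clean=None):
    """Zero (or given) clean signal plus an identical artifact after every pulse."""
    n = first + period * n_pulses + period
    x = np.zeros((n, n_channels)) if clean is None else clean.copy()
    pulse_ends = np.arange(first, first + period * n_pulses, period)
    for t in pulse_ends:
        x[t : t + tail.size, :] += tail[:, None]
    return SignalRecording(x, 1000.0, pulse_ends=pulse_ends)


class TestTemplateUpdate:
    def test_alpha_one_copies_segment(self):
        state = TemplateState(np.array([5.0, -3.0, 9.0]), alpha=1.0)
        new = ts_update(state, np.array([1.0, 2.0]))
        np.testing.assert_allclose(new.template, [1.0, 2.0, 9.0])

    def test_halfway_average(self):
        state = TemplateState(np.array([0.0, 0.0]), alpha=0.5)
        new = ts_update(state, np.array([2.0, 4.0]))
        np.testing.assert_allclose(new.template, [1.0, 2.0])

    def test_repeated_segment_geometric_form(self):
        alpha = 0.3
        s = np.array([1.0, -2.0, 0.5, 3.0])
        state = TemplateState.zeros(4, alpha)
        for k in range(1, 9):
            state = ts_update(state, s)
            np.testing.assert_allclose(state.template, (1 - (1 - alpha) ** k) * s, atol=1e-12)

    def test_empty_segment_unchanged(self):
        state = TemplateState(np.array([1.0, 2.0]), alpha=0.5)
        new = ts_update(state, np.array([]))
        np.testing.assert_array_equal(new.template, state.template)

    def test_blanked_entries_skipped(self):
        state = TemplateState(np.array([4.0, 4.0]), alpha=0.5)
        new = ts_update(state, np.array([0.0, 0.0]), blank=np.array([True, False]))
        np.testing.assert_allclose(new.template, [4.0, 2.0])

    def test_entries_beyond_n_never_stored(self):
        state = TemplateState.zeros(2, 0.5)
        new = ts_update(state, np.arange(5.0))
        assert new.length == 2


class TestTemplateSubtractionApply:
    def test_no_pulses_is_identity(self):
        rng = np.random.default_rng(1)
        rec = SignalRecording(rng.standard_normal((300, 2)), 1000.0)
        out = ts_apply(rec, alpha=0.5, length=20)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_geometric_residual_decay(self):
        tail = 3.0 * np.exp(-np.arange(30) / 6.0)
        rec = periodic_artifact_recording(tail, period=40, n_pulses=10)
        out = ts_apply(rec, alpha=0.5, length=30)
        norm = np.linalg.norm(tail)
        for k, t in enumerate(rec.pulse_ends, start=1):
            residual = np.linalg.norm(out.samples[t : t + 30, 0])
            assert residual == pytest.approx(0.5**k * norm, abs=1e-9)

    def test_zero_signal_zero_artifact_untouched(self):
        rec = periodic_artifact_recording(np.zeros(10), n_pulses=5)
        out = ts_apply(rec, alpha=0.06, length=25)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_recursion_matches_exponentially_weighted_average(self):
        """Recursive template equals the brute-force weighted sum of past pulses."""
        rng = np.random.default_rng(7)
        alpha, N, n_pulses = 0.21, 8, 20
        segments = rng.standard_normal((n_pulses, N))
        rec = periodic_artifact_recording(np.zeros(1), period=N, n_pulses=n_pulses)
        x = np.zeros((rec.n_samples, 1))
        for k, t in enumerate(rec.pulse_ends):
            x[t : t + N, 0] = segments[k]
        rec = rec.replace(samples=x)
        out = ts_apply(rec, alpha=alpha, length=N)
        # independent oracle: W_k(i) = sum_j alpha (1-alpha)^(k-j) x_j(i)
        for k, t in enumerate(rec.pulse_ends):
            expected = sum(
                alpha * (1 - alpha) ** (k - j) * segments[j] for j in range(k + 1)
            )
            np.testing.assert_allclose(x[t : t + N, 0] - out.samples[t : t + N, 0],
                                       expected, atol=1e-12)

    def test_vectorized_apply_matches_scalar_updates(self):
        """Multi-channel apply agrees with the per-channel reference recursion."""
        rng = np.random.default_rng(5)
        n, c, N, alpha = 500, 3, 12, 0.4
        x = rng.standard_normal((n, c))
        pulse_ends = np.array([40, 60, 90, 140, 200, 300])
        mask = np.zeros(n, dtype=bool)
        mask[[41, 62, 63, 145]] = True
        rec = SignalRecording(x, 1000.0, blank_mask=mask, pulse_ends=pulse_ends)
        out = ts_apply(rec, alpha=alpha, length=N)
        for ch in range(c):
            state = TemplateState.zeros(N, alpha)
            expected = x[:, ch].copy()
            for k, t in enumerate(pulse_ends):
                nxt = pulse_ends[k + 1] if k + 1 < pulse_ends.size else n
                stop = min(t + N, nxt, n)
                seg = x[t:stop, ch]
                b = mask[t:stop]
                state = ts_update(state, seg, blank=b)
                expected[t:stop][~b] = (seg - state.template[: stop - t])[~b]
            np.testing.assert_allclose(out.samples[:, ch], expected, atol=1e-12)

    def test_blanked_samples_pass_through(self):
        tail = np.full(10, 2.0)
        rec = periodic_artifact_recording(tail, period=20, n_pulses=4)
        mask = np.zeros(rec.n_samples, dtype=bool)
        mask[rec.pulse_ends[1] + 2] = True
        rec = rec.replace(blank_mask=mask)
        out = ts_apply(rec, alpha=1.0, length=10)
        t = rec.pulse_ends[1] + 2
        assert out.samples[t, 0] == rec.samples[t, 0]

    def test_parameter_validation(self):
        rec = SignalRecording(np.zeros(50), 1000.0)
        with pytest.raises(ConfigurationError):
            ts_apply(rec, alpha=0.0)
        with pytest.raises(ConfigurationError):
            ts_apply(rec, alpha=1.5)
        with pytest.raises(ConfigurationError):
            ts_apply(rec, length=0)

    def test_causality_prefix_property(self):
        rng = np.random.default_rng(11)
        rec = periodic_artifact_recording(
            np.exp(-np.arange(15) / 4.0),
            period=30,
            n_pulses=8,
            clean=rng.standard_normal((50 + 30 * 9, 1)),
        )
        full = ts_apply(rec, alpha=0.3, length=15).samples
        cut = 171
        prefix = rec.replace(
            samples=rec.samples[:cut],
            blank_mask=rec.blank_mask[:cut],
            pulse_ends=rec.pulse_ends[rec.pulse_ends < cut],
        )
        part = ts_apply(prefix, alpha=0.3, length=15).samples
        np.testing.assert_allclose(part, full[:cut], atol=1e-12)


class TestNlmsStep:
    def test_zero_history_passthrough(self):
        state = NlmsState.zeros(4, alpha=0.5)
        xhat, new = nlms_step(state, 3.0, 0.0)
        assert xhat == 3.0
        np.testing.assert_array_equal(new.weights, state.weights)

    def test_exact_cancellation_when_weights_match(self):
        w = np.array([0.7])
        state = NlmsState(w, alpha=0.1)
        clean, artifact, u = 0.25, 0.7 * 2.0, 2.0
        xhat, _ = nlms_step(state, clean + artifact, u)
        assert xhat == pytest.approx(clean, abs=1e-12)

    def test_scalar_convergence(self):
        """N=1 weight converges to the true gain for a constant reference."""
        state = NlmsState.zeros(1, alpha=0.1, epsilon=1e-6)
        for _ in range(200):
            _, state = nlms_step(state, 0.7 * 1.0, 1.0)
        assert abs(state.weights[0] - 0.7) < 1e-3

    def test_input_state_not_mutated(self):
        state = NlmsState.zeros(3, alpha=0.5)
        nlms_step(state, 1.0, 1.0)
        np.testing.assert_array_equal(state.weights, np.zeros(3))
        np.testing.assert_array_equal(state.ref_buffer, np.zeros(3))


class TestNlmsApply:
    def _recording(self, n=800, n_pulses=None, seed=2, ref=None, clean=None):
        period, blank = 33, 3
        starts = np.arange(20, n - blank - 1, period)
        pe = starts + blank
        mask = np.zeros(n, dtype=bool)
        for s in starts:
            mask[s : s + blank] = True
        x = np.zeros((n, 1)) if clean is None else clean
        if ref is None:
            ref = np.zeros(n)
        return SignalRecording(x, 1000.0, blank_mask=mask, pulse_ends=pe, reference=ref)

    def test_zero_reference_is_identity(self):
        rng = np.random.default_rng(3)
        rec = self._recording(clean=rng.standard_normal((800, 1)))
        out = nlms_apply(rec, alpha=0.5, length=10)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_missing_reference_rejected(self):
        rec = SignalRecording(np.zeros(100), 1000.0, pulse_ends=[10])
        with pytest.raises(ConfigurationError, match="reference"):
            nlms_apply(rec)

    def test_passivity_on_silence(self):
        rec = self._recording()
        out = nlms_apply(rec, alpha=0.5, length=10)
        np.testing.assert_array_equal(out.samples, np.zeros_like(rec.samples))
        for st in out.final_states:
            np.testing.assert_array_equal(st.weights, np.zeros(10))

    def test_causality_prefix_property(self):
        rng = np.random.default_rng(9)
        n = 800
        ref = rng.standard_normal(n)
        art = np.convolve(ref, [1.0, 0.5])[:n]
        rec = self._recording(ref=ref, clean=art[:, None].copy())
        full = nlms_apply(rec, alpha=0.2, length=8).samples
        cut = 391
        prefix = rec.replace(
            samples=rec.samples[:cut],
            blank_mask=rec.blank_mask[:cut],
            pulse_ends=rec.pulse_ends[rec.pulse_ends < cut],
            reference=rec.reference[:cut],
        )
        part = nlms_apply(prefix, alpha=0.2, length=8).samples
        np.testing.assert_allclose(part, full[:cut], atol=1e-12)

    def test_weights_reset_per_pulse_option(self):
        rng = np.random.default_rng(4)
        n = 400
        ref = rng.standard_normal(n)
        art = 0.8 * ref
        rec = self._recording(n=n, ref=ref, clean=art[:, None].copy())
        persist = nlms_apply(rec, alpha=0.3, length=4)
        reset = nlms_apply(rec, alpha=0.3, length=4, reset_per_pulse=True)
        # persistent weights keep learning across pulses; resetting re-learns
        # from zero each pulse, so late residuals are larger
        t = rec.pulse_ends[-1]
        assert np.sum(reset.samples[t : t + 4] ** 2) > np.sum(
            persist.samples[t : t + 4] ** 2
        )


class TestEstimators:
    def test_sklearn_param_interface(self):
        ts = TemplateSubtraction(alpha=0.1, length=10)
        assert ts.get_params() == {"alpha": 0.1, "length": 10}
        ts.set_params(alpha=0.2)
        assert ts.alpha == 0.2
        nlms = EpsilonNLMS()
        assert nlms.get_params()["alpha"] == 0.035

    def test_transform_matches_apply(self, simple_recording):
        est = TemplateSubtraction(alpha=0.3, length=12)
        cleaned = est.fit_transform(simple_recording)
        direct = ts_apply(simple_recording, alpha=0.3, length=12)
        np.testing.assert_array_equal(cleaned.samples, direct.samples)
        assert len(est.states_) == simple_recording.n_channels

    def test_invalid_params_raise_on_fit(self, simple_recording):
        with pytest.raises(ConfigurationError):
            TemplateSubtraction(alpha=2.0).fit(simple_recording)
        with pytest.raises(ConfigurationError):
            EpsilonNLMS(epsilon=0.0).fit(simple_recording)
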
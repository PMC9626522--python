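"""Metrics, grid optimization, sensitivity sweeps, and statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgsar import (
    SignalRecording,
    delta_snr,
    holm_bonferroni,
    optimize_hyperparameters,
    rank_sum_test,
    rmse,
    sensitivity_sweep,
    snr,
)
from emgsar.synth import ArtifactTrain, SemiSyntheticRecord, SynthConfig, generate_emg, superimpose


class TestRmse:
    def test_identical_inputs_zero(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_known_value(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(math.sqrt(12.5))

    def test_constant_offset(self):
        x = np.arange(10.0)
        assert rmse(x, x + 1.75) == pytest.approx(1.75)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            rmse([1.0], [1.0, 2.0])

    def test_mask_excludes_samples(self):
        x = np.zeros(4)
        xhat = np.array([0.0, 100.0, 0.0, 0.0])
        mask = np.array([False, True, False, False])
        assert rmse(x, xhat, mask) == 0.0


class TestSnr:
    def test_equal_energy_zero_db(self):
        s = np.array([1.0, -1.0, 2.0])
        assert snr(s, s[::-1]) == pytest.approx(0.0)

    def test_tenth_amplitude_twenty_db(self):
        s = np.random.default_rng(0).standard_normal(100)
        assert snr(s, s / 10.0) == pytest.approx(20.0)

    def test_zero_noise_positive_infinity(self):
        assert snr([1.0, 2.0], [0.0, 0.0]) == math.inf

    def test_zero_signal_negative_infinity(self):
        assert snr([0.0, 0.0], [1.0]) == -math.inf


class TestDeltaSnr:
    def test_no_removal_zero_db(self):
        rng = np.random.default_rng(1)
        clean = rng.standard_normal(50)
        artifact = rng.standard_normal(50)
        assert delta_snr(clean, artifact, clean + artifact) == pytest.approx(0.0)

    def test_known_energies_twenty_db(self):
        clean = np.full(100, 1.0)  # energy 100
        artifact = np.zeros(100)
        artifact[0] = 1.0  # energy 1
        cleaned = clean.copy()
        cleaned[0] += 0.1  # residual energy 0.01
        assert delta_snr(clean, artifact, cleaned) == pytest.approx(20.0)

    def test_added_noise_negative(self):
        clean = np.ones(10)
        artifact = 0.1 * np.ones(10)
        cleaned = clean + 0.5  # residual larger than artifact
        assert delta_snr(clean, artifact, cleaned) < 0

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        clean = rng.standard_normal(64)
        artifact = rng.standard_normal(64)
        cleaned = clean + 0.3 * rng.standard_normal(64)
        base = delta_snr(clean, artifact, cleaned)
        for scale in (1e-3, 7.2, 1e4):
            scaled = delta_snr(
                scale * clean, scale * artifact, scale * clean + scale * (cleaned - clean)
            )
            assert scaled == pytest.approx(base, rel=1e-9)


def _tiny_records(n_records=3, with_pulses=True, seed=0):
    records = []
    for i in range(n_records):
        cfg = SynthConfig(duration=0.5, seed=seed + i, stim_amplitude=1.5)
        clean = generate_emg(cfg)
        if with_pulses:
            from emgsar.synth import generate_artifact_train

            records.append(superimpose(clean, generate_artifact_train(cfg)))
        else:
            n = clean.n_samples
            train = ArtifactTrain(
                artifact=np.zeros_like(clean.samples),
                blank_mask=np.zeros(n, bool),
                pulse_ends=np.empty(0, dtype=np.intp),
                reference=np.zeros(n),
                stim_labels=np.zeros(n, bool),
                sample_rate=cfg.sample_rate,
            )
            records.append(superimpose(clean, train))
    return records


class TestOptimization:
    def test_single_grid_point_returned(self):
        records = _tiny_records(2)
        res = optimize_hyperparameters(
            records, "ts", alpha_grid=np.array([0.3]), n_grid=np.array([7])
        )
        assert res.best == [(0.3, 7)] * records[0].clean.n_channels

    def test_no_pulses_all_tied_smallest_returned(self):
        records = _tiny_records(2, with_pulses=False)
        res = optimize_hyperparameters(
            records, "ts", alpha_grid=np.array([0.05, 0.2]), n_grid=np.array([3, 9])
        )
        assert res.best == [(0.05, 3)] * records[0].clean.n_channels

    def test_attains_exhaustive_minimum_both_algorithms(self):
        """Self-oracle: returned point matches an independent grid re-evaluation."""
        from emgsar import nlms_apply, ts_apply

        records = _tiny_records(3)
        alpha_grid = np.array([0.05, 0.2, 0.6])
        n_grid = np.array([4, 12])
        for algo, apply_fn in (("ts", ts_apply), ("nlms", None)):
            res = optimize_hyperparameters(records, algo, alpha_grid, n_grid)
            for c, (a_star, n_star) in enumerate(res.best):
                best_val = None
                for a in alpha_grid:
                    for n in n_grid:
                        vals = []
                        for rec in records:
                            if algo == "ts":
                                cleaned = ts_apply(rec.recording, float(a), int(n)).samples
                            else:
                                cleaned = nlms_apply(
                                    rec.recording, alpha=float(a), length=int(n)
                                ).samples
                            mask = rec.recording.blank_mask
                            vals.append(
                                rmse(rec.clean.samples[:, c], cleaned[:, c], mask)
                            )
                        med = float(np.median(vals))
                        if best_val is None or med < best_val - 1e-15:
                            best_val = med
                idx_a = np.flatnonzero(alpha_grid == a_star)[0]
                idx_n = np.flatnonzero(n_grid == n_star)[0]
                assert res.median_rmse[idx_a, idx_n, c] == pytest.approx(best_val, rel=1e-9)
                assert res.median_rmse[:, :, c].min() == pytest.approx(best_val, rel=1e-9)


class TestSweep:
    def test_single_record_quartiles_collapse(self):
        cfg = SynthConfig(duration=0.5, seed=1, n_channels=1)
        from emgsar.synth import generate_artifact_train

        record = superimpose(generate_emg(cfg), generate_artifact_train(cfg))
        res = sensitivity_sweep([record], "ts", vary="alpha", values=np.array([0.1, 0.3]))
        for q in res.quartiles:
            assert q[0] == q[1] == q[2]

    def test_quartiles_ordered(self, alpha_sweeps):
        for sweep in alpha_sweeps.values():
            assert np.all(sweep.quartiles[:, 0] <= sweep.quartiles[:, 1])
            assert np.all(sweep.quartiles[:, 1] <= sweep.quartiles[:, 2])


def _rank_sum_enumeration(a, b):
    """Exact two-sided rank-sum p-value by enumerating all group assignments."""
    combined = np.concatenate([a, b])
    n = len(a)
    ranks = np.argsort(np.argsort(combined)) + 1.0
    observed = ranks[:n].sum()
    stats = [
        sum(ranks[list(idx)]) for idx in itertools.combinations(range(len(combined)), n)
    ]
    stats = np.asarray(stats)
    mean = stats.mean()
    p = np.mean(np.abs(stats - mean) >= abs(observed - mean) - 1e-12)
    return float(p)


class TestRankSum:
    def test_disjoint_samples_exact_p(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        assert rank_sum_test([2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_exact_mode_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n, m = rng.integers(2, 9, size=2)
            # distinct values keep both routes in the exact regime
            vals = rng.permutation(40)[: n + m].astype(float)
            a, b = vals[:n], vals[n:]
            assert rank_sum_test(a, b) == pytest.approx(
                _rank_sum_enumeration(a, b), abs=1e-12
            )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestHolmBonferroni:
    def test_step_down_arithmetic(self):
        np.testing.assert_allclose(holm_bonferroni([0.01, 0.04]), [0.02, 0.04])

    def test_monotone_and_capped(self):
        p = np.array([0.04, 0.001, 0.9, 0.02, 0.6])
        adj = holm_bonferroni(p)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, size=7)
        _, adj, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(holm_bonferroni(p), adj, atol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10))
    def test_adjusted_never_below_raw(self, pvals):
        adj = holm_bonferroni(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
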
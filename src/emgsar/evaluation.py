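"""RMSE / SNR-improvement metrics, hyperparameter grids, and statistics.

Artifact-removal quality is measured on semi-synthetic records, where the
true artifact-free signal ``x(t)`` is known:

* **RMSE** between ``x(t)`` and the estimated artifact-free signal
  ``xhat(t)`` is the optimization objective for hyperparameter selection
  (it tracks absolute reconstruction error, so it is optimized per channel
  where amplitudes differ widely);
* **SNR improvement** ``dSNR = SNR(x, xhat - x) - SNR(x, a)`` in dB is the
  amplitude-invariant comparison metric: it contrasts the residual error
  energy after processing with the artifact energy before. SNR is the
  energy-ratio decibel form ``10 log10(sum s^2 / sum n^2)``.

Blanked samples carry no physiological information and are excluded from
both sums by default. Grid optimization is exhaustive, selecting the
(alpha, N) point minimizing the median RMSE across records, per channel;
sensitivity sweeps summarize per-record dSNR with quartile curves.
Nonparametric comparisons use the two-sided Wilcoxon rank-sum test with
Holm-Bonferroni step-down correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from . import sar as _sar
from .signals import ConfigurationError
from .synth import SemiSyntheticRecord

__all__ = [
    "EvalMetrics",
    "OptimizationResult",
    "SweepResult",
    "rmse",
    "snr",
    "delta_snr",
    "evaluate_record",
    "optimize_hyperparameters",
    "sensitivity_sweep",
    "rank_sum_test",
    "holm_bonferroni",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_N_GRID",
]

#: default hyperparameter grids bracketing the deployed values
#: (TS alpha=0.06, NLMS alpha=0.035, N=25)
DEFAULT_ALPHA_GRID = np.geomspace(0.005, 0.5, 20)
DEFAULT_N_GRID = np.arange(1, 41)


@dataclass
class EvalMetrics:
    """Per-channel artifact-removal quality measures."""

    rmse: float
    snr_in: float
    snr_out: float
    delta_snr: float


def _masked(x: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if mask is None:
        return x
    mask = np.asarray(mask, dtype=bool)
    return x[~mask]


def rmse(x: np.ndarray, xhat: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Root-mean-square error between two equal-length sequences.

    Samples flagged in ``mask`` (e.g. blanked) are excluded.
    """
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {xhat.shape}")
    if x.size < 1:
        raise ValueError("rmse requires at least one sample")
    d = _masked(x - xhat, mask)
    return float(np.sqrt(np.mean(d**2)))


def snr(signal: np.ndarray, noise: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Energy-ratio SNR in decibels: ``10 log10(sum s^2 / sum n^2)``.

    Zero noise energy returns ``+inf`` (perfect reconstruction); zero
    signal energy returns ``-inf``.
    """
    s = _masked(signal, mask)
    n = _masked(noise, mask)
    es = float(np.sum(s**2))
    en = float(np.sum(n**2))
    if es == 0.0:
        return -math.inf
    if en == 0.0:
        return math.inf
    return 10.0 * math.log10(es / en)


def delta_snr(
    clean: np.ndarray,
    artifact: np.ndarray,
    cleaned: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """SNR improvement in dB: ``SNR(x, xhat - x) - SNR(x, a)``.

    Positive values mean the filter removed more artifact energy than it
    introduced; negative values mean it added net noise. Depends only on
    relative energies, not absolute amplitude. Infinite sentinels
    propagate (e.g. zero residual gives ``+inf``).
    """
    clean = np.asarray(clean, dtype=float)
    cleaned = np.asarray(cleaned, dtype=float)
    out = snr(clean, cleaned - clean, mask)
    inn = snr(clean, artifact, mask)
    if math.isinf(out) and math.isinf(inn) and out == inn:
        return math.nan
    return out - inn


def _run_algo(record: SemiSyntheticRecord, algo: str, alpha: float, n: int, **kw) -> np.ndarray:
    if algo == "ts":
        return _sar.ts_apply(record.recording, alpha=alpha, length=n).samples
    if algo == "nlms":
        return _sar.nlms_apply(record.recording, alpha=alpha, length=n, **kw).samples
    raise ConfigurationError(f"unknown algorithm {algo!r}; expected 'ts' or 'nlms'")


def evaluate_record(
    record: SemiSyntheticRecord,
    cleaned: np.ndarray,
    exclude_blanks: bool = True,
) -> list[EvalMetrics]:
    """Per-channel metrics for one semi-synthetic record and its cleaned output."""
    mask = record.recording.blank_mask if exclude_blanks else None
    out = []
    for c in range(record.clean.n_channels):
        x = record.clean.samples[:, c]
        a = record.artifact[:, c]
        xh = cleaned[:, c]
        out.append(
            EvalMetrics(
                rmse=rmse(x, xh, mask),
                snr_in=snr(x, a, mask),
                snr_out=snr(x, xh - x, mask),
                delta_snr=delta_snr(x, a, xh, mask),
            )
        )
    return out


# ---------------------------------------------------------------------------
# grid optimization
# ---------------------------------------------------------------------------


@dataclass
class OptimizationResult:
    """Exhaustive-grid hyperparameter selection output.

    ``median_rmse[i, j, c]`` is the median across records of the RMSE for
    ``alpha_grid[i]``, ``n_grid[j]`` on channel ``c``; ``best`` holds the
    per-channel ``(alpha, N)`` minimizer (ties resolved toward smaller
    alpha, then smaller N).
    """

    alpha_grid: np.ndarray
    n_grid: np.ndarray
    median_rmse: np.ndarray
    best: list[tuple[float, int]]


def optimize_hyperparameters(
    records: list[SemiSyntheticRecord],
    algo: str = "ts",
    alpha_grid: np.ndarray | None = None,
    n_grid: np.ndarray | None = None,
    exclude_blanks: bool = True,
    **algo_kw,
) -> OptimizationResult:
    """Exhaustive (alpha, N) grid search minimizing median RMSE per channel.

    Every grid point is evaluated on every record; for each channel the
    point minimizing the median across-record RMSE is returned. Grid points
    whose median ties the minimum (to ~1e-9 relative) resolve to the
    smallest alpha, then the smallest N.
    """
    if not records:
        raise ValueError("records must be nonempty")
    alpha_grid = np.asarray(DEFAULT_ALPHA_GRID if alpha_grid is None else alpha_grid, float)
    n_grid = np.asarray(DEFAULT_N_GRID if n_grid is None else n_grid, int)
    if alpha_grid.size == 0 or n_grid.size == 0:
        raise ValueError("grids must be nonempty")
    n_channels = records[0].clean.n_channels
    med = np.empty((alpha_grid.size, n_grid.size, n_channels))
    for i, a in enumerate(alpha_grid):
        for j, n in enumerate(n_grid):
            vals = np.empty((len(records), n_channels))
            for r, rec in enumerate(records):
                cleaned = _run_algo(rec, algo, float(a), int(n), **algo_kw)
                mask = rec.recording.blank_mask if exclude_blanks else None
                d = rec.clean.samples - cleaned
                dm = d[~mask] if mask is not None else d
                vals[r] = np.sqrt(np.mean(dm**2, axis=0))
            med[i, j] = np.median(vals, axis=0)

    best: list[tuple[float, int]] = []
    order_a = np.argsort(alpha_grid, kind="stable")
    order_n = np.argsort(n_grid, kind="stable")
    for c in range(n_channels):
        grid = med[:, :, c]
        m = grid.min()
        tol = max(1e-15, 1e-9 * abs(m))
        found = None
        for i in order_a:
            for j in order_n:
                if grid[i, j] <= m + tol:
                    found = (float(alpha_grid[i]), int(n_grid[j]))
                    break
            if found:
                break
        best.append(found)
    return OptimizationResult(alpha_grid=alpha_grid, n_grid=n_grid, median_rmse=med, best=best)


# ---------------------------------------------------------------------------
# sensitivity sweeps
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    """One-parameter sensitivity sweep with quartile summaries.

    ``delta_snr[v, r, c]`` is the SNR improvement for grid value ``v`` on
    record ``r``, channel ``c``; ``quartiles[v]`` are the (q25, q50, q75)
    pooled over records and channels.
    """

    vary: str
    values: np.ndarray
    delta_snr: np.ndarray
    quartiles: np.ndarray

    def median(self) -> np.ndarray:
        return self.quartiles[:, 1]

    def iqr_width(self) -> np.ndarray:
        return self.quartiles[:, 2] - self.quartiles[:, 0]


def sensitivity_sweep(
    records: list[SemiSyntheticRecord],
    algo: str = "ts",
    vary: str = "alpha",
    values: np.ndarray | None = None,
    fixed: dict | None = None,
    exclude_blanks: bool = True,
    **algo_kw,
) -> SweepResult:
    """Sweep one hyperparameter, holding the other fixed, and collect dSNR.

    ``vary`` is ``"alpha"`` or ``"N"``; ``fixed`` supplies the other
    parameter (defaults: alpha=0.06 for TS / 0.035 for NLMS, N=25).
    """
    if vary not in ("alpha", "N"):
        raise ConfigurationError("vary must be 'alpha' or 'N'")
    if not records:
        raise ValueError("records must be nonempty")
    fixed = dict(fixed or {})
    default_alpha = 0.06 if algo == "ts" else 0.035
    if values is None:
        values = DEFAULT_ALPHA_GRID if vary == "alpha" else DEFAULT_N_GRID
    values = np.asarray(values)
    n_channels = records[0].clean.n_channels
    out = np.empty((values.size, len(records), n_channels))
    for v, val in enumerate(values):
        alpha = float(val) if vary == "alpha" else float(fixed.get("alpha", default_alpha))
        n = int(fixed.get("N", 25)) if vary == "alpha" else int(val)
        for r, rec in enumerate(records):
            cleaned = _run_algo(rec, algo, alpha, n, **algo_kw)
            mask = rec.recording.blank_mask if exclude_blanks else None
            for c in range(n_channels):
                out[v, r, c] = delta_snr(
                    rec.clean.samples[:, c], rec.artifact[:, c], cleaned[:, c], mask
                )
    quart = np.percentile(out.reshape(values.size, -1), [25, 50, 75], axis=1).T
    return SweepResult(vary=vary, values=values, delta_snr=out, quartiles=quart)


# ---------------------------------------------------------------------------
# nonparametric statistics
# ---------------------------------------------------------------------------


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact for small tie-free samples, normal approximation with tie
    correction otherwise. Degenerate all-tied data returns p = 1.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return 1.0
    res = spstats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(min(1.0, res.pvalue))


def holm_bonferroni(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float).ravel()
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
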
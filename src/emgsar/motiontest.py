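"""Motion Test simulation and outcome metrics.

The Motion Test is a timed decoding task: the user must hold the target
movement for a cumulative 1 s (non-continuous) of correct per-window
predictions within a 5 s limit. Four outcomes are scored per trial:

* **completed** — whether the cumulative requirement was met in time;
* **completion time** — timestamp at which it was met (5 s if not);
* **movement accuracy** — fraction of correct predictions issued before the
  trial concluded;
* **selection time** — timestamp of the first correct prediction (5 s if
  none).

Timestamp convention: the prediction of window ``w`` (1-based) is stamped
at ``w * step`` seconds, and each correct prediction contributes one window
step of cumulative correct time.

:func:`simulate_motion_test` runs the protocol offline end to end on
synthetic recordings: a decoder trained on stimulation-free data predicts
windows from per-trial recordings under four conditions — no stimulation,
raw stimulation, and stimulation processed by each artifact-removal
algorithm — and the outcomes are pooled and compared nonparametrically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import evaluation as _eval
from . import sar as _sar
from .mpr import ClassifierSpec, EmgPatternClassifier, WindowSpec, feature_matrix, window_signal
from .signals import SignalRecording
from .synth import SynthConfig, generate_artifact_train, generate_emg, superimpose

__all__ = [
    "MotionTrial",
    "TrialOutcome",
    "score_trial",
    "completion_rate",
    "run_motion_test",
    "simulate_motion_test",
    "MotionTestResult",
]

CONDITIONS = ("none", "stim", "ts", "nlms")


@dataclass
class MotionTrial:
    """Target class plus an ordered per-window prediction stream."""

    target: int
    times: np.ndarray  # seconds, non-decreasing
    predictions: np.ndarray  # predicted class per window
    time_limit: float = 5.0
    required: float = 1.0
    step: float = 0.05

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.predictions = np.asarray(self.predictions).ravel()
        if self.times.size != self.predictions.size:
            raise ValueError("times and predictions must have equal length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        if self.time_limit <= self.required:
            raise ValueError("time_limit must exceed the required correct time")


@dataclass
class TrialOutcome:
    """Scored outcomes of one trial; timed outcomes capped at the limit."""

    target: int
    completed: bool
    completion_time: float
    accuracy: float
    selection_time: float


def score_trial(trial: MotionTrial) -> TrialOutcome:
    """Score one trial from its prediction stream.

    Each correct prediction adds one window step of cumulative correct
    time; the trial concludes when the cumulative requirement is reached.
    Unsuccessful trials have both timed outcomes set to the limit.
    Accuracy counts only predictions issued up to (and including) the
    concluding one.
    """
    if trial.times.size == 0:
        raise ValueError("prediction stream is empty")
    cum = 0.0
    n_issued = 0
    n_correct = 0
    selection = None
    completion = None
    for t, p in zip(trial.times, trial.predictions):
        if t > trial.time_limit + 1e-12:
            break
        n_issued += 1
        if p == trial.target:
            n_correct += 1
            if selection is None:
                selection = float(t)
            cum += trial.step
            if cum >= trial.required - 1e-12:
                completion = float(t)
                break
    if n_issued == 0:
        raise ValueError("no predictions issued within the time limit")
    completed = completion is not None
    return TrialOutcome(
        target=int(trial.target),
        completed=completed,
        completion_time=min(completion, trial.time_limit) if completed else trial.time_limit,
        accuracy=n_correct / n_issued,
        selection_time=min(selection, trial.time_limit)
        if selection is not None
        else trial.time_limit,
    )


def completion_rate(outcomes: list[TrialOutcome]) -> float:
    """Percentage of trials completed successfully."""
    if not outcomes:
        raise ValueError("no outcomes")
    return 100.0 * float(np.mean([o.completed for o in outcomes]))


@dataclass
class MotionTestResult:
    """Per-condition outcome tables, pooled rates, and statistics."""

    outcomes: pd.DataFrame  # condition, trial, target, completed, times...
    completion_rates: dict[str, float]
    comparisons: list[tuple[str, str, str, float, float]]  # metric, a, b, p, p_adj


def run_motion_test(
    classifier: EmgPatternClassifier,
    trial_recordings: dict[str, list[tuple[int, SignalRecording]]],
    window: WindowSpec | None = None,
    time_limit: float = 5.0,
    required: float = 1.0,
    threshold: float = 0.0,
    compare_with: str = "stim",
) -> MotionTestResult:
    """Score Motion Test trials for each condition's recordings.

    ``trial_recordings`` maps a condition name to ``(target, recording)``
    trials. Each recording is windowed, features are extracted with blanked
    samples removed, and the classifier's prediction stream is scored.
    Outcome metrics are compared between conditions with rank-sum tests
    and Holm-Bonferroni correction (each condition against
    ``compare_with``).
    """
    window = window or WindowSpec()
    rows = []
    per_condition: dict[str, list[TrialOutcome]] = {}
    for cond, trials in trial_recordings.items():
        outs = []
        for idx, (target, rec) in enumerate(trials):
            step = window.stride / rec.sample_rate
            windows = window_signal(rec, window)
            X, _, _ = feature_matrix(windows, threshold)
            preds = classifier.predict(X)
            times = step * np.arange(1, len(preds) + 1)
            trial = MotionTrial(
                target=target,
                times=times,
                predictions=preds,
                time_limit=time_limit,
                required=required,
                step=step,
            )
            out = score_trial(trial)
            outs.append(out)
            rows.append(
                {
                    "condition": cond,
                    "trial": idx,
                    "target": target,
                    "completed": out.completed,
                    "completion_time": out.completion_time,
                    "accuracy": out.accuracy,
                    "selection_time": out.selection_time,
                }
            )
        per_condition[cond] = outs

    rates = {c: completion_rate(o) for c, o in per_condition.items()}
    frame = pd.DataFrame(rows)

    comparisons: list[tuple[str, str, str, float, float]] = []
    metrics = ("completed", "completion_time", "accuracy", "selection_time")
    pairs = [
        (a, compare_with)
        for a in per_condition
        if a != compare_with and compare_with in per_condition
    ]
    raw = []
    for metric in metrics:
        for a, b in pairs:
            va = frame.loc[frame.condition == a, metric].to_numpy(dtype=float)
            vb = frame.loc[frame.condition == b, metric].to_numpy(dtype=float)
            raw.append((metric, a, b, _eval.rank_sum_test(va, vb)))
    if raw:
        adj = _eval.holm_bonferroni([p for *_, p in raw])
        comparisons = [(m, a, b, p, q) for (m, a, b, p), q in zip(raw, adj)]
    return MotionTestResult(outcomes=frame, completion_rates=rates, comparisons=comparisons)


def simulate_motion_test(
    cfg: SynthConfig | None = None,
    classes: tuple[int, ...] = (0, 1, 2, 3, 4),
    trials_per_class: int = 3,
    conditions: tuple[str, ...] = CONDITIONS,
    ts_params: tuple[float, int] = (0.06, 25),
    nlms_params: tuple[float, int] = (0.035, 25),
    window: WindowSpec | None = None,
    clf_spec: ClassifierSpec | None = None,
    train_duration: float = 6.0,
    trial_duration: float = 5.2,
    time_limit: float = 5.0,
    required: float = 1.0,
    effort_range: tuple[float, float] = (0.85, 1.1),
    n_participants: int = 3,
    seed: int = 0,
) -> MotionTestResult:
    """End-to-end simulated Motion Test on synthetic recordings.

    For each simulated participant, a decoder is first trained on that
    participant's stimulation-free recordings of every class (including
    rest). Then, for each target class and trial, a clean recording and a
    stimulation-artifact train are generated; the four conditions share
    them — "none" uses the clean signal, "stim" the raw superposition,
    "ts"/"nlms" the superposition processed by the respective algorithm.
    Trial order is randomized (seeded). Outcomes are pooled across
    participants, as in a multi-participant session.

    Contraction strength varies per trial (uniform in ``effort_range``
    times the nominal movement amplitude): users do not reproduce training
    effort exactly, so weak-effort trials are marginal even without
    stimulation, and any residual artifact tips them into failure.
    """
    cfg = cfg or SynthConfig(duration=trial_duration, stim_rate=20.0)
    window = window or WindowSpec()
    clf_spec = clf_spec or ClassifierSpec()

    frames = []
    for participant in range(n_participants):
        result = _simulate_one_participant(
            cfg,
            classes,
            trials_per_class,
            conditions,
            ts_params,
            nlms_params,
            window,
            clf_spec,
            train_duration,
            trial_duration,
            time_limit,
            required,
            effort_range,
            seed + 7919 * participant,
        )
        frame = result.outcomes.copy()
        frame["participant"] = participant
        frames.append(frame)
    pooled = pd.concat(frames, ignore_index=True)
    rates = {
        c: 100.0 * float(pooled.loc[pooled.condition == c, "completed"].mean())
        for c in conditions
    }
    comparisons: list[tuple[str, str, str, float, float]] = []
    raw = []
    for metric in ("completed", "completion_time", "accuracy", "selection_time"):
        for cond in conditions:
            if cond == "stim" or "stim" not in conditions:
                continue
            va = pooled.loc[pooled.condition == cond, metric].to_numpy(dtype=float)
            vb = pooled.loc[pooled.condition == "stim", metric].to_numpy(dtype=float)
            raw.append((metric, cond, "stim", _eval.rank_sum_test(va, vb)))
    if raw:
        adj = _eval.holm_bonferroni([p for *_, p in raw])
        comparisons = [(m, a, b, p, q) for (m, a, b, p), q in zip(raw, adj)]
    return MotionTestResult(outcomes=pooled, completion_rates=rates, comparisons=comparisons)


def _simulate_one_participant(
    cfg,
    classes,
    trials_per_class,
    conditions,
    ts_params,
    nlms_params,
    window,
    clf_spec,
    train_duration,
    trial_duration,
    time_limit,
    required,
    effort_range,
    seed,
) -> MotionTestResult:
    rng = np.random.default_rng(seed)

    # -- train on stimulation-free data ------------------------------------
    Xs, ys = [], []
    for ci, class_id in enumerate(classes):
        tr_cfg = replace(
            cfg,
            duration=train_duration,
            movement_schedule=[] if class_id == 0 else [(class_id, 0.0, train_duration)],
            seed=seed + 1000 + ci,
        )
        rec = generate_emg(tr_cfg)
        if rec.movement_labels is None or class_id == 0:
            rec = rec.replace(movement_labels=np.full(rec.n_samples, class_id, dtype=np.intp))
        X, y, _ = feature_matrix(window_signal(rec, window))
        Xs.append(X)
        ys.append(y)
    clf = EmgPatternClassifier(
        hidden_units=clf_spec.hidden_units,
        augment_snr_db=clf_spec.augment_snr_db,
        max_epochs=clf_spec.max_epochs,
        patience=clf_spec.patience,
        random_state=seed,
    ).fit(np.vstack(Xs), np.concatenate(ys))

    # -- build trials ------------------------------------------------------
    targets = np.repeat(np.asarray(classes), trials_per_class)
    rng.shuffle(targets)
    trial_recordings: dict[str, list[tuple[int, SignalRecording]]] = {
        c: [] for c in conditions
    }
    for ti, target in enumerate(targets):
        effort = float(rng.uniform(*effort_range)) if target != 0 else 1.0
        t_cfg = replace(
            cfg,
            duration=trial_duration,
            movement_schedule=[] if target == 0 else [(int(target), 0.0, trial_duration)],
            emg_amplitude=cfg.emg_amplitude * effort,
            stim_start=0.0,
            stim_stop=None,
            seed=seed + 5000 + 17 * ti,
        )
        clean = generate_emg(t_cfg)
        train = generate_artifact_train(t_cfg)
        semi = superimpose(clean, train)
        variants = {}
        if "none" in conditions:
            variants["none"] = clean
        if "stim" in conditions:
            variants["stim"] = semi.recording
        if "ts" in conditions:
            variants["ts"] = _sar.ts_apply(semi.recording, *ts_params).cleaned
        if "nlms" in conditions:
            variants["nlms"] = _sar.nlms_apply(
                semi.recording, alpha=nlms_params[0], length=nlms_params[1]
            ).cleaned
        for cond, rec in variants.items():
            trial_recordings[cond].append((int(target), rec))

    return run_motion_test(
        clf, trial_recordings, window=window, time_limit=time_limit, required=required
    )
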
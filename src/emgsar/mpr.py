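"""Myoelectric pattern recognition: windowing, features, classifier.

The decoding pipeline mirrors standard real-time myoelectric control:
sliding windows of 200 samples with 150 samples of overlap; the four
classic time-domain features per channel — Mean Absolute Value (MAV),
Zero Crossings (ZC), Slope Sign Changes (SSC) and Waveform Length (WL) —
computed after removing blanked samples from the window (they carry no
physiological information, only held ADC values); and a one-hidden-layer
neural network (rectifier hidden units, softmax output).

Training uses only feature vectors from stimulation-free windows, split
60/20/20 into train/validation/test; features are z-scored with statistics
from the training split only, and the training copies are augmented with
additive Gaussian noise at 10 dB per-vector SNR. Early stopping monitors
the validation split. Feature vectors from stimulation-contaminated
windows — raw, and processed by each artifact-removal algorithm — are then
scored by the trained network, and the whole procedure is repeated to
average over split/initialization randomness.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from . import evaluation as _eval
from . import sar as _sar
from .signals import ConfigurationError, SignalRecording
from .synth import SemiSyntheticRecord

__all__ = [
    "WindowSpec",
    "Window",
    "FeatureVector",
    "ClassifierSpec",
    "window_signal",
    "extract_features",
    "feature_matrix",
    "EmgPatternClassifier",
    "train_classifier",
    "evaluate_conditions",
    "offline_pr_experiment",
    "UnusableWindowError",
]

FEATURE_NAMES = ("mav", "zc", "ssc", "wl")


class UnusableWindowError(ValueError):
    """Raised when a window has no usable (non-blanked) samples."""


@dataclass
class WindowSpec:
    """Sliding-window geometry: 200-sample windows, 150-sample overlap."""

    length: int = 200
    overlap: int = 150

    def __post_init__(self) -> None:
        self.length = int(self.length)
        self.overlap = int(self.overlap)
        if self.length < 1:
            raise ConfigurationError("window length must be >= 1")
        if not 0 <= self.overlap < self.length:
            raise ConfigurationError("overlap must satisfy 0 <= overlap < length")

    @property
    def stride(self) -> int:
        return self.length - self.overlap

    @classmethod
    def from_time(cls, length_s: float, overlap_s: float, sample_rate: float) -> "WindowSpec":
        """Build a sample-unit spec from a time-unit one (e.g. 200 ms / 150 ms)."""
        return cls(
            length=int(round(length_s * sample_rate)),
            overlap=int(round(overlap_s * sample_rate)),
        )


@dataclass
class Window:
    """One analysis window with its blanking slice and majority labels."""

    samples: np.ndarray  # (length, n_channels)
    blank: np.ndarray  # (length,)
    start: int
    label: int | None = None  # majority movement class
    stim: bool = False  # any stimulation present in the window


def window_signal(rec: SignalRecording, spec: WindowSpec | None = None) -> list[Window]:
    """Slice a recording into overlapping windows.

    Windows start every ``stride`` samples; each carries its blank-mask
    slice, the majority movement label, and a stimulation flag (True if any
    sample in the window is stimulation-labelled). A recording shorter than
    one window yields an empty list.
    """
    spec = spec or WindowSpec()
    n = rec.n_samples
    windows: list[Window] = []
    for start in range(0, n - spec.length + 1, spec.stride):
        stop = start + spec.length
        label = None
        if rec.movement_labels is not None:
            seg = rec.movement_labels[start:stop]
            label = int(np.bincount(seg).argmax())
        stim = bool(rec.stim_labels[start:stop].any()) if rec.stim_labels is not None else False
        windows.append(
            Window(
                samples=rec.samples[start:stop],
                blank=rec.blank_mask[start:stop],
                start=start,
                label=label,
                stim=stim,
            )
        )
    return windows


@dataclass
class FeatureVector:
    """Per-window features, ``4 * n_channels`` values ordered channel-major
    (mav, zc, ssc, wl per channel)."""

    values: np.ndarray
    start: int
    label: int | None
    stim: bool


def _features_1d(x: np.ndarray, threshold: float) -> tuple[float, float, float, float]:
    mav = float(np.mean(np.abs(x)))
    if x.size < 2:
        return mav, 0.0, 0.0, 0.0
    d = np.diff(x)
    wl = float(np.sum(np.abs(d)))
    zc = float(np.count_nonzero((x[:-1] * x[1:] < 0) & (np.abs(d) >= threshold)))
    if x.size < 3:
        return mav, zc, 0.0, wl
    left = x[1:-1] - x[:-2]
    right = x[1:-1] - x[2:]
    ssc = float(
        np.count_nonzero(
            (left * right > 0)
            & ((np.abs(left) >= threshold) | (np.abs(right) >= threshold))
        )
    )
    return mav, zc, ssc, wl


def extract_features(window: Window, threshold: float = 0.0) -> FeatureVector:
    """MAV / ZC / SSC / WL per channel, after dropping blanked samples.

    Blanked samples are removed and the remaining sequence concatenated
    before feature computation (held ADC values would otherwise bias every
    feature). ``threshold`` is the ZC/SSC deadband. A fully blanked window
    raises :class:`UnusableWindowError`.
    """
    keep = ~window.blank
    if not keep.any():
        raise UnusableWindowError(f"window at {window.start} has only blanked samples")
    x = window.samples[keep, :]
    vals = np.empty(4 * x.shape[1])
    for c in range(x.shape[1]):
        vals[4 * c : 4 * c + 4] = _features_1d(x[:, c], threshold)
    return FeatureVector(values=vals, start=window.start, label=window.label, stim=window.stim)


def feature_matrix(
    windows: list[Window], threshold: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack window features into ``(X, labels, stim_flags)`` arrays."""
    feats = [extract_features(w, threshold) for w in windows]
    X = np.vstack([f.values for f in feats])
    y = np.asarray([-1 if f.label is None else f.label for f in feats], dtype=np.intp)
    stim = np.asarray([f.stim for f in feats], dtype=bool)
    return X, y, stim


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------


@dataclass
class ClassifierSpec:
    """Training configuration for the one-hidden-layer decoder."""

    hidden_units: int = 16
    train_fraction: float = 0.6
    val_fraction: float = 0.2
    test_fraction: float = 0.2
    augment_snr_db: float = 10.0
    n_augment: int = 1
    repetitions: int = 100
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("train/val/test fractions must sum to 1")


class EmgPatternClassifier(BaseEstimator, ClassifierMixin):
    """One-hidden-layer (ReLU -> softmax) movement decoder.

    ``fit`` performs the full training protocol on stimulation-free feature
    vectors: a random stratified 60/20/20 train/validation/test split,
    z-score normalization with training-split statistics, 10 dB-SNR
    Gaussian augmentation of the training copies, and epoch-wise gradient
    training with early stopping on validation accuracy (best weights
    restored). The held-out test accuracy is exposed as
    ``test_accuracy_``. Deterministic given ``random_state``.
    """

    def __init__(
        self,
        hidden_units: int = 16,
        train_fraction: float = 0.6,
        val_fraction: float = 0.2,
        test_fraction: float = 0.2,
        augment_snr_db: float = 10.0,
        n_augment: int = 1,
        max_epochs: int = 200,
        patience: int = 20,
        random_state: int | None = None,
    ):
        self.hidden_units = hidden_units
        self.train_fraction = train_fraction
        self.val_fraction = val_fraction
        self.test_fraction = test_fraction
        self.augment_snr_db = augment_snr_db
        self.n_augment = n_augment
        self.max_epochs = max_epochs
        self.patience = patience
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _augment(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Noisy copies at ``augment_snr_db`` per-vector SNR (post-normalization)."""
        energy = np.sum(X**2, axis=1, keepdims=True)
        sigma = np.sqrt(energy / (X.shape[1] * 10 ** (self.augment_snr_db / 10.0)))
        copies = [X + sigma * rng.standard_normal(X.shape) for _ in range(self.n_augment)]
        return np.vstack(copies)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "EmgPatternClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).ravel()
        classes = np.unique(y)
        if classes.size < 2:
            raise ConfigurationError("training requires at least 2 classes")
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("train/val/test fractions must sum to 1")
        seed = 0 if self.random_state is None else int(self.random_state)
        rng = np.random.default_rng(seed)

        holdout = self.val_fraction + self.test_fraction
        X_tr, X_rest, y_tr, y_rest = train_test_split(
            X, y, test_size=holdout, random_state=seed, stratify=y
        )
        X_va, X_te, y_va, y_te = train_test_split(
            X_rest,
            y_rest,
            test_size=self.test_fraction / holdout,
            random_state=seed + 1,
            stratify=y_rest,
        )

        self.scaler_ = StandardScaler().fit(X_tr)
        Xn_tr = self.scaler_.transform(X_tr)
        Xn_va = self.scaler_.transform(X_va)
        Xn_te = self.scaler_.transform(X_te)

        X_fit = np.vstack([Xn_tr, self._augment(Xn_tr, rng)])
        y_fit = np.concatenate([y_tr] * (1 + self.n_augment))

        mlp = MLPClassifier(
            hidden_layer_sizes=(int(self.hidden_units),),
            activation="relu",
            solver="adam",
            random_state=seed,
            max_iter=1,
            warm_start=False,
        )
        # early stopping monitors validation log-loss (finer-grained than
        # accuracy); best weights are restored at the end
        best_loss, best_weights, since_best = np.inf, None, 0
        class_index = {c: i for i, c in enumerate(classes)}
        y_va_idx = np.asarray([class_index[v] for v in y_va])
        order = np.arange(X_fit.shape[0])
        for epoch in range(int(self.max_epochs)):
            rng.shuffle(order)
            mlp.partial_fit(X_fit[order], y_fit[order], classes=classes)
            proba = np.clip(mlp.predict_proba(Xn_va), 1e-12, 1.0)
            loss = -float(np.mean(np.log(proba[np.arange(y_va_idx.size), y_va_idx])))
            if loss < best_loss - 1e-12:
                best_loss = loss
                best_weights = (
                    copy.deepcopy(mlp.coefs_),
                    copy.deepcopy(mlp.intercepts_),
                )
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        if best_weights is not None:
            mlp.coefs_, mlp.intercepts_ = best_weights
        self.mlp_ = mlp
        self.classes_ = classes
        self.n_epochs_ = epoch + 1
        self.validation_loss_ = best_loss
        self.validation_accuracy_ = float(np.mean(mlp.predict(Xn_va) == y_va))
        self.test_accuracy_ = float(np.mean(mlp.predict(Xn_te) == y_te))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.mlp_.predict(self.scaler_.transform(np.asarray(X, dtype=float)))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.mlp_.predict_proba(self.scaler_.transform(np.asarray(X, dtype=float)))

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y).ravel()))

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        """Serialize weights and normalization statistics to a JSON container."""
        payload = {
            "hidden_units": int(self.hidden_units),
            "classes": self.classes_.tolist(),
            "scaler_mean": self.scaler_.mean_.tolist(),
            "scaler_scale": self.scaler_.scale_.tolist(),
            "coefs": [w.tolist() for w in self.mlp_.coefs_],
            "intercepts": [b.tolist() for b in self.mlp_.intercepts_],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "EmgPatternClassifier":
        payload = json.loads(Path(path).read_text())
        clf = cls(hidden_units=payload["hidden_units"])
        clf.classes_ = np.asarray(payload["classes"])
        scaler = StandardScaler()
        scaler.mean_ = np.asarray(payload["scaler_mean"])
        scaler.scale_ = np.asarray(payload["scaler_scale"])
        scaler.var_ = scaler.scale_**2
        scaler.n_features_in_ = scaler.mean_.size
        clf.scaler_ = scaler
        mlp = MLPClassifier(hidden_layer_sizes=(payload["hidden_units"],), activation="relu")
        mlp.coefs_ = [np.asarray(w) for w in payload["coefs"]]
        mlp.intercepts_ = [np.asarray(b) for b in payload["intercepts"]]
        mlp.n_layers_ = len(mlp.coefs_) + 1
        # sklearn's binary convention: a single logistic output unit
        mlp.n_outputs_ = int(np.asarray(mlp.intercepts_[-1]).size)
        mlp.classes_ = clf.classes_
        mlp.out_activation_ = "logistic" if mlp.n_outputs_ == 1 else "softmax"
        mlp._label_binarizer = None
        # rebuild the label binarizer so predict() works after loading
        from sklearn.preprocessing import LabelBinarizer

        lb = LabelBinarizer()
        lb.fit(clf.classes_)
        mlp._label_binarizer = lb
        clf.mlp_ = mlp
        return clf


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec | None = None,
    random_state: int | None = None,
) -> tuple[EmgPatternClassifier, dict]:
    """Train the decoder per the standard protocol; return (model, report)."""
    spec = spec or ClassifierSpec()
    clf = EmgPatternClassifier(
        hidden_units=spec.hidden_units,
        train_fraction=spec.train_fraction,
        val_fraction=spec.val_fraction,
        test_fraction=spec.test_fraction,
        augment_snr_db=spec.augment_snr_db,
        n_augment=spec.n_augment,
        max_epochs=spec.max_epochs,
        patience=spec.patience,
        random_state=spec.seed if random_state is None else random_state,
    ).fit(X, y)
    report = {
        "test_accuracy": clf.test_accuracy_,
        "validation_accuracy": clf.validation_accuracy_,
        "n_epochs": clf.n_epochs_,
    }
    return clf, report


# ---------------------------------------------------------------------------
# condition evaluation
# ---------------------------------------------------------------------------


@dataclass
class ConditionEvaluation:
    """Repeated-training accuracies per condition, with summary statistics."""

    accuracies: dict[str, np.ndarray]
    comparisons: list[tuple[str, str, float, float]]  # (a, b, p, p_adjusted)

    def summary(self) -> dict[str, tuple[float, float, float]]:
        """Median and quartiles (q25, q50, q75) of accuracy per condition."""
        return {
            k: tuple(np.percentile(v, [25, 50, 75])) for k, v in self.accuracies.items()
        }


def evaluate_conditions(
    train_X: np.ndarray,
    train_y: np.ndarray,
    conditions: dict[str, tuple[np.ndarray, np.ndarray]],
    spec: ClassifierSpec | None = None,
    pairs: list[tuple[str, str]] | None = None,
) -> ConditionEvaluation:
    """Repeat train/evaluate cycles and score every condition each time.

    Each repetition re-splits and re-trains the decoder on the
    stimulation-free features, then computes the total accuracy (fraction
    of correct predictions) on every condition's feature set using the
    repetition's model and its training-split normalization. Rank-sum
    comparisons between condition accuracy distributions are
    Holm-Bonferroni corrected.
    """
    spec = spec or ClassifierSpec()
    accs: dict[str, list[float]] = {name: [] for name in conditions}
    for rep in range(spec.repetitions):
        clf = EmgPatternClassifier(
            hidden_units=spec.hidden_units,
            train_fraction=spec.train_fraction,
            val_fraction=spec.val_fraction,
            test_fraction=spec.test_fraction,
            augment_snr_db=spec.augment_snr_db,
            n_augment=spec.n_augment,
            max_epochs=spec.max_epochs,
            patience=spec.patience,
            random_state=spec.seed + rep,
        ).fit(train_X, train_y)
        for name, (Xc, yc) in conditions.items():
            accs[name].append(clf.score(Xc, yc))
    accuracies = {k: np.asarray(v) for k, v in accs.items()}

    if pairs is None:
        names = list(conditions)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    pvals = [_eval.rank_sum_test(accuracies[a], accuracies[b]) for a, b in pairs]
    adj = _eval.holm_bonferroni(pvals) if pvals else np.empty(0)
    comparisons = [(a, b, p, q) for (a, b), p, q in zip(pairs, pvals, adj)]
    return ConditionEvaluation(accuracies=accuracies, comparisons=comparisons)


def offline_pr_experiment(
    records: list[SemiSyntheticRecord],
    ts_params: tuple[float, int] = (0.06, 25),
    nlms_params: tuple[float, int] = (0.035, 25),
    window: WindowSpec | None = None,
    spec: ClassifierSpec | None = None,
    threshold: float = 0.0,
) -> ConditionEvaluation:
    """End-to-end offline decoding comparison on semi-synthetic records.

    Stimulation-free windows (where corrupted == clean) train the decoder;
    stimulation-contaminated windows are scored in four conditions: the
    ground-truth clean signal, the raw corrupted signal, and the corrupted
    signal processed by each artifact-removal algorithm.
    """
    window = window or WindowSpec()
    spec = spec or ClassifierSpec()
    train_X, train_y = [], []
    cond_X: dict[str, list[np.ndarray]] = {k: [] for k in ("clean", "raw", "ts", "nlms")}
    cond_y: dict[str, list[np.ndarray]] = {k: [] for k in cond_X}
    for rec in records:
        corrupted = rec.recording
        ts_clean = _sar.ts_apply(corrupted, *ts_params).cleaned
        nl_clean = _sar.nlms_apply(corrupted, alpha=nlms_params[0], length=nlms_params[1]).cleaned
        variants = {
            "clean": corrupted.replace(samples=rec.clean.samples),
            "raw": corrupted,
            "ts": ts_clean,
            "nlms": nl_clean,
        }
        for name, variant in variants.items():
            X, y, stim = feature_matrix(window_signal(variant, window), threshold)
            if name == "raw":
                train_X.append(X[~stim])
                train_y.append(y[~stim])
            cond_X[name].append(X[stim])
            cond_y[name].append(y[stim])
    Xtr = np.vstack(train_X)
    ytr = np.concatenate(train_y)
    conditions = {
        name: (np.vstack(cond_X[name]), np.concatenate(cond_y[name])) for name in cond_X
    }
    pairs = [
        ("clean", "raw"),
        ("raw", "ts"),
        ("raw", "nlms"),
        ("clean", "ts"),
        ("clean", "nlms"),
        ("ts", "nlms"),
    ]
    return evaluate_conditions(Xtr, ytr, conditions, spec, pairs)
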
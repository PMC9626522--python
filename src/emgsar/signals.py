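"""Containers, blanking semantics, preprocessing and file I/O for
stimulation-synchronized EMG.

The central object is :class:`SignalRecording`: a multi-channel EMG time
series sampled at a fixed rate, together with the bookkeeping that
closed-loop neurostimulation imposes on it — a per-sample *blanking* mask
(samples acquired while the acquisition front-end was suspended during
pulse generation; their values are held and carry no physiological
information), the sample indices at which each stimulation pulse ends, and
an optional reference channel sampled from the stimulation line itself.

Conventions
-----------
* sample indices are 0-based; intervals are half-open ``[start, end)``;
* ``samples`` is shaped ``(n_samples, n_channels)`` — one column per channel;
* blanked samples hold their last value in ``samples`` and are flagged in
  ``blank_mask``; downstream code must consult the mask, never sentinels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps


class FormatError(ValueError):
    """A file or container violates the recording layout or its invariants."""


class ConfigurationError(ValueError):
    """A parameter combination is invalid for the given recording."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SignalRecording:
    """Multi-channel EMG aligned with stimulation metadata.

    Parameters
    ----------
    samples : array of shape (n_samples, n_channels)
        Per-channel amplitudes in arbitrary (but fixed per file) units.
    sample_rate : float
        Sampling rate in Hz.
    blank_mask : bool array of shape (n_samples,), optional
        True where the sample was acquired during blanking.
    pulse_ends : int array, optional
        Strictly increasing sample indices ``t_k`` at which stimulation
        pulse *k* ends, i.e. the first sample where the artifact tail is
        present in the EMG.
    reference : array of shape (n_samples,), optional
        Stimulation-channel reference ``u(t)`` aligned with ``samples``.
    channel_names : list of str, optional
    movement_labels : int array of shape (n_samples,), optional
        Per-sample movement class id (0 = rest by convention).
    stim_labels : bool array of shape (n_samples,), optional
        Per-sample stimulation-presence flag.
    """

    samples: np.ndarray
    sample_rate: float
    blank_mask: np.ndarray | None = None
    pulse_ends: np.ndarray | None = None
    reference: np.ndarray | None = None
    channel_names: list[str] | None = None
    movement_labels: np.ndarray | None = None
    stim_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if x.ndim != 2:
            raise FormatError("samples must be 1- or 2-dimensional")
        self.samples = x
        n = x.shape[0]

        if not np.isfinite(self.sample_rate) or self.sample_rate <= 0:
            raise FormatError("sample_rate must be a positive finite number")
        self.sample_rate = float(self.sample_rate)

        if self.blank_mask is None:
            self.blank_mask = np.zeros(n, dtype=bool)
        else:
            self.blank_mask = np.asarray(self.blank_mask, dtype=bool).ravel()
            if self.blank_mask.shape[0] != n:
                raise FormatError("blank_mask length does not match samples")

        if self.pulse_ends is None:
            self.pulse_ends = np.empty(0, dtype=np.intp)
        else:
            pe = np.asarray(self.pulse_ends, dtype=np.intp).ravel()
            if pe.size and (np.any(np.diff(pe) <= 0)):
                raise FormatError("pulse_ends must be strictly increasing")
            if pe.size and (pe[0] < 0 or pe[-1] >= n):
                raise FormatError("pulse_ends out of range for recording length")
            self.pulse_ends = pe

        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float).ravel()
            if ref.shape[0] != n:
                raise FormatError("reference length does not match samples")
            self.reference = ref

        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(x.shape[1])]
        else:
            self.channel_names = [str(c) for c in self.channel_names]
            if len(self.channel_names) != x.shape[1]:
                raise FormatError("channel_names length does not match channels")

        if self.movement_labels is not None:
            lab = np.asarray(self.movement_labels, dtype=np.intp).ravel()
            if lab.shape[0] != n:
                raise FormatError("movement_labels length does not match samples")
            self.movement_labels = lab

        if self.stim_labels is not None:
            st = np.asarray(self.stim_labels, dtype=bool).ravel()
            if st.shape[0] != n:
                raise FormatError("stim_labels length does not match samples")
            self.stim_labels = st

    # -- convenience -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return np.arange(self.n_samples) / self.sample_rate

    def replace(self, **changes) -> "SignalRecording":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


@dataclass
class PreprocessConfig:
    """Causal mains-notch + high-pass chain applied before artifact removal.

    Defaults: 50 Hz notch (quality 30) against mains interference and a
    2nd-order 20 Hz Butterworth high-pass removing bias and motion drift.
    """

    notch_hz: float = 50.0
    notch_quality: float = 30.0
    highpass_hz: float = 20.0
    highpass_order: int = 2
    zero_phase: bool = False

    def __post_init__(self) -> None:
        if self.notch_hz <= 0:
            raise ConfigurationError("notch_hz must be positive")
        if self.notch_quality <= 0:
            raise ConfigurationError("notch_quality must be positive")
        if self.highpass_hz <= 0:
            raise ConfigurationError("highpass_hz must be positive")
        if int(self.highpass_order) < 1:
            raise ConfigurationError("highpass_order must be >= 1")
        self.highpass_order = int(self.highpass_order)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def preprocess(rec: SignalRecording, cfg: PreprocessConfig | None = None) -> SignalRecording:
    """Notch- then high-pass-filter every EMG channel of a recording.

    Filtering is causal (single pass) by default, matching the real-time
    deployment; set ``cfg.zero_phase=True`` for forward-backward filtering.
    Blanking mask, pulse indices, labels and the reference channel are
    carried through unchanged.
    """
    cfg = cfg or PreprocessConfig()
    nyq = rec.sample_rate / 2.0
    if cfg.notch_hz >= nyq:
        raise ConfigurationError(
            f"notch_hz={cfg.notch_hz} must be below the Nyquist rate {nyq}"
        )
    if cfg.highpass_hz >= nyq:
        raise ConfigurationError(
            f"highpass_hz={cfg.highpass_hz} must be below the Nyquist rate {nyq}"
        )

    b_notch, a_notch = sps.iirnotch(cfg.notch_hz, cfg.notch_quality, fs=rec.sample_rate)
    sos_hp = sps.butter(
        cfg.highpass_order, cfg.highpass_hz, btype="highpass", fs=rec.sample_rate, output="sos"
    )
    x = rec.samples
    if cfg.zero_phase:
        y = sps.filtfilt(b_notch, a_notch, x, axis=0)
        y = sps.sosfiltfilt(sos_hp, y, axis=0)
    else:
        y = sps.lfilter(b_notch, a_notch, x, axis=0)
        y = sps.sosfilt(sos_hp, y, axis=0)
    return rec.replace(samples=y)


# ---------------------------------------------------------------------------
# blanking
# ---------------------------------------------------------------------------


def blank_segments(rec_or_mask: SignalRecording | np.ndarray) -> list[tuple[int, int]]:
    """Maximal half-open ``[start, end)`` intervals where the blank mask is True.

    Accepts either a recording or a raw boolean mask. Intervals are
    disjoint, sorted, and their union reproduces the mask exactly.
    """
    if isinstance(rec_or_mask, SignalRecording):
        mask = rec_or_mask.blank_mask
    else:
        mask = np.asarray(rec_or_mask, dtype=bool).ravel()
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    return list(zip(starts.tolist(), ends.tolist()))


def segments_to_mask(segments: Sequence[tuple[int, int]], n_samples: int) -> np.ndarray:
    """Inverse of :func:`blank_segments`: rebuild a boolean mask from intervals."""
    mask = np.zeros(n_samples, dtype=bool)
    for s, e in segments:
        mask[s:e] = True
    return mask


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_TEXT_SUFFIXES = {".csv": ",", ".tsv": "\t", ".txt": "\t"}
_HDF5_SUFFIXES = {".h5", ".hdf5"}

_RESERVED_COLUMNS = ("reference", "blank", "movement", "stim")


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def _resolve_format(path: Path, format_hint: str | None) -> str:
    if format_hint is not None:
        hint = format_hint.lower()
        if hint in ("h5", "hdf5"):
            return "hdf5"
        if hint in ("csv", "tsv", "txt", "text"):
            return "text"
        raise FormatError(f"unknown format hint {format_hint!r}")
    if path.suffix.lower() in _HDF5_SUFFIXES:
        return "hdf5"
    if path.suffix.lower() in _TEXT_SUFFIXES:
        return "text"
    raise FormatError(f"cannot infer format from suffix {path.suffix!r}")


def write_recording(rec: SignalRecording, path: str | Path, format_hint: str | None = None) -> None:
    """Write a recording either as delimited text + JSON sidecar or HDF5.

    The layout is chosen from ``format_hint`` or the file suffix:
    ``.csv/.tsv/.txt`` (text) or ``.h5/.hdf5`` (hierarchical container).
    """
    path = Path(path)
    fmt = _resolve_format(path, format_hint)
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("emg", data=rec.samples)
            f.create_dataset("blank_mask", data=rec.blank_mask.astype(np.uint8))
            if rec.reference is not None:
                f.create_dataset("reference", data=rec.reference)
            if rec.movement_labels is not None:
                f.create_dataset("movement_labels", data=rec.movement_labels.astype(np.int64))
            if rec.stim_labels is not None:
                f.create_dataset("stim_labels", data=rec.stim_labels.astype(np.uint8))
            f.attrs["sample_rate"] = rec.sample_rate
            f.attrs["pulse_ends"] = rec.pulse_ends.astype(np.int64)
            f.attrs["channel_names"] = [str(c) for c in rec.channel_names]
    else:
        sep = _TEXT_SUFFIXES[path.suffix.lower()]
        cols = {name: rec.samples[:, i] for i, name in enumerate(rec.channel_names)}
        if rec.reference is not None:
            cols["reference"] = rec.reference
        cols["blank"] = rec.blank_mask.astype(int)
        if rec.movement_labels is not None:
            cols["movement"] = rec.movement_labels
        if rec.stim_labels is not None:
            cols["stim"] = rec.stim_labels.astype(int)
        pd.DataFrame(cols).to_csv(path, sep=sep, index=False)
        sidecar = {
            "sample_rate": rec.sample_rate,
            "channel_names": list(rec.channel_names),
            "pulse_ends": rec.pulse_ends.tolist(),
        }
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path, format_hint: str | None = None) -> SignalRecording:
    """Read a recording written by :func:`write_recording`.

    Raises :class:`FormatError` naming the offending field on a missing
    sidecar, ragged columns, or violated invariants (e.g. non-monotone
    ``pulse_ends``).
    """
    path = Path(path)
    fmt = _resolve_format(path, format_hint)
    if fmt == "hdf5":
        import h5py

        if not path.exists():
            raise FormatError(f"file not found: {path}")
        with h5py.File(path, "r") as f:
            if "emg" not in f:
                raise FormatError("missing dataset 'emg'")
            samples = np.asarray(f["emg"], dtype=float)
            blank = np.asarray(f["blank_mask"], dtype=bool) if "blank_mask" in f else None
            reference = np.asarray(f["reference"], dtype=float) if "reference" in f else None
            movement = (
                np.asarray(f["movement_labels"], dtype=np.intp)
                if "movement_labels" in f
                else None
            )
            stim = np.asarray(f["stim_labels"], dtype=bool) if "stim_labels" in f else None
            if "sample_rate" not in f.attrs:
                raise FormatError("missing attribute 'sample_rate'")
            sample_rate = float(f.attrs["sample_rate"])
            pulse_ends = np.asarray(f.attrs.get("pulse_ends", []), dtype=np.intp)
            names = [
                c.decode() if isinstance(c, bytes) else str(c)
                for c in f.attrs.get("channel_names", [])
            ] or None
        return SignalRecording(
            samples=samples,
            sample_rate=sample_rate,
            blank_mask=blank,
            pulse_ends=pulse_ends,
            reference=reference,
            channel_names=names,
            movement_labels=movement,
            stim_labels=stim,
        )

    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FormatError(f"missing sidecar: {sidecar_file}")
    try:
        meta = json.loads(sidecar_file.read_text())
    except json.JSONDecodeError as exc:  # pragma: no cover - defensive
        raise FormatError(f"sidecar is not valid JSON: {exc}") from exc
    for key in ("sample_rate", "channel_names"):
        if key not in meta:
            raise FormatError(f"sidecar missing field '{key}'")
    sep = _TEXT_SUFFIXES[path.suffix.lower()]
    try:
        frame = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise FormatError(f"ragged columns in {path.name}: {exc}") from exc
    names = [str(c) for c in meta["channel_names"]]
    missing = [c for c in names if c not in frame.columns]
    if missing:
        raise FormatError(f"channel columns missing from table: {missing}")
    samples = frame[names].to_numpy(dtype=float)
    if samples.size and np.any(pd.isna(samples)):
        raise FormatError("ragged columns: NaN entries in channel data")
    reference = frame["reference"].to_numpy(dtype=float) if "reference" in frame else None
    blank = frame["blank"].to_numpy(dtype=bool) if "blank" in frame else None
    movement = frame["movement"].to_numpy(dtype=np.intp) if "movement" in frame else None
    stim = frame["stim"].to_numpy(dtype=bool) if "stim" in frame else None
    return SignalRecording(
        samples=samples,
        sample_rate=float(meta["sample_rate"]),
        blank_mask=blank,
        pulse_ends=np.asarray(meta.get("pulse_ends", []), dtype=np.intp),
        reference=reference,
        channel_names=names,
        movement_labels=movement,
        stim_labels=stim,
    )
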
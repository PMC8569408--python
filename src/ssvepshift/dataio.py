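"""Epoched-recording container and occipital electrode-grid geometry.

The recording unit throughout the package is a trials x channels x samples
array of microvolt EEG with a sampling rate, a per-trial stimulus-frequency
label, and the identity of each channel on a dense 3-row x 7-column
occipital grid (1.3 cm pitch, centred on Oz).  Recordings round-trip
through a plain ``.npy`` array plus a human-readable JSON sidecar.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "DimensionMismatchError",
    "LabelError",
    "FormatError",
    "EpochedRecording",
    "ElectrodeGrid",
    "channels_to_positions",
    "read_recording",
    "write_recording",
]


class ValidationError(ValueError):
    """Base class for recording-validation failures."""


class DimensionMismatchError(ValidationError):
    """Array dimensions inconsistent with the declared metadata."""


class LabelError(ValidationError):
    """A trial label does not index into the stimulus-frequency list."""


class FormatError(ValidationError):
    """On-disk container is missing or malformed."""


@dataclass
class EpochedRecording:
    """Epoched multichannel EEG: ``data[trial, channel, sample]`` in microvolts.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_samples)``.
    fs
        Sampling rate in Hz.
    channel_ids
        Grid channel numbers (1-21) in the order of the channel axis.
    labels
        Per-trial index into ``frequencies`` (the attended stimulus).
    frequencies
        Stimulus frequencies in Hz.
    subject_id
        Free-form subject identifier.
    """

    data: np.ndarray
    fs: float
    channel_ids: list[int]
    labels: np.ndarray
    frequencies: list[float]
    subject_id: str = "S01"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.channel_ids = [int(c) for c in self.channel_ids]
        self.frequencies = [float(f) for f in self.frequencies]
        if self.data.ndim != 3:
            raise DimensionMismatchError(
                f"data must be trials x channels x samples, got shape {self.data.shape}"
            )
        if self.data.shape[1] != len(self.channel_ids):
            raise DimensionMismatchError(
                f"{self.data.shape[1]} channel rows but {len(self.channel_ids)} channel ids"
            )
        if self.labels.ndim != 1 or self.labels.shape[0] != self.data.shape[0]:
            raise DimensionMismatchError(
                f"{self.labels.shape} labels for {self.data.shape[0]} trials"
            )
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= len(self.frequencies)
        ):
            raise LabelError(
                f"labels must lie in [0, {len(self.frequencies)}); "
                f"found range [{self.labels.min()}, {self.labels.max()}]"
            )
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.fs

    def select_channels(self, ids: list[int]) -> "EpochedRecording":
        """Restrict to the given grid channel ids (in the given order)."""
        index = {c: i for i, c in enumerate(self.channel_ids)}
        missing = [c for c in ids if c not in index]
        if missing:
            raise ValidationError(f"channels {missing} absent from recording")
        rows = [index[c] for c in ids]
        return replace(self, data=self.data[:, rows, :], channel_ids=list(ids))

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "EpochedRecording":
        return replace(self, data=data, fs=self.fs if fs is None else fs)


@dataclass(frozen=True)
class ElectrodeGrid:
    """The 3 x 7 occipital electrode grid with 1.3 cm pitch, centred on Oz.

    Channels are numbered column-major: ``channel = (col - 1) * 3 + row``
    with rows 1-3 top-to-bottom and columns 1-7 left-to-right.  This is the
    unique 3 x 7 numbering for which the three overlapping 9-channel groups
    (left 1-9, middle 7-15, right 13-21) are columns 1-3 / 3-5 / 5-7 and the
    nominal 10-20 positions O1, Oz, O2 (channels 5, 11, 17) sit on the
    middle row at columns 2, 4 and 6.
    """

    n_rows: int = 3
    n_cols: int = 7
    pitch_cm: float = 1.3
    anchors: dict = field(
        default_factory=lambda: {5: "O1", 11: "Oz", 17: "O2"}
    )

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    def channel_of(self, row: int, col: int) -> int:
        if not (1 <= row <= self.n_rows and 1 <= col <= self.n_cols):
            raise ValidationError(f"grid position ({row}, {col}) out of bounds")
        return (col - 1) * self.n_rows + row

    def position_of(self, channel: int) -> tuple[int, int]:
        if not 1 <= channel <= self.n_channels:
            raise ValidationError(f"channel {channel} outside 1..{self.n_channels}")
        col, row0 = divmod(channel - 1, self.n_rows)
        return (row0 + 1, col + 1)

    def position_cm(self, channel: int) -> tuple[float, float]:
        """Physical (y, x) position in cm, origin at the top-left electrode."""
        row, col = self.position_of(channel)
        return ((row - 1) * self.pitch_cm, (col - 1) * self.pitch_cm)

    def distance_cm(self, a: int, b: int) -> float:
        ya, xa = self.position_cm(a)
        yb, xb = self.position_cm(b)
        return float(np.hypot(ya - yb, xa - xb))

    # overlapping shift groups: each spans three adjacent columns
    @property
    def left(self) -> list[int]:
        return list(range(1, 10))

    @property
    def middle(self) -> list[int]:
        return list(range(7, 16))

    @property
    def right(self) -> list[int]:
        return list(range(13, 22))


def channels_to_positions(grid: ElectrodeGrid, ids: list[int]) -> list[tuple[int, int]]:
    """Map grid channel ids to (row, column) positions."""
    return [grid.position_of(c) for c in ids]


def _paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in {".npy", ".json"}:
        base = base.with_suffix("")
    return base.with_suffix(".npy"), base.with_suffix(".json")


def write_recording(rec: EpochedRecording, path: str | Path) -> None:
    """Write a recording as ``<name>.npy`` + ``<name>.json`` sidecar."""
    array_path, meta_path = _paths(path)
    if array_path.exists() or meta_path.exists():
        logger.info("overwriting existing recording at %s", array_path.with_suffix(""))
    array_path.parent.mkdir(parents=True, exist_ok=True)
    np.save(array_path, rec.data)
    meta = {
        "fs": rec.fs,
        "channel_ids": rec.channel_ids,
        "labels": rec.labels.tolist(),
        "frequencies": rec.frequencies,
        "subject_id": rec.subject_id,
    }
    meta_path.write_text(json.dumps(meta, indent=1))


def read_recording(path: str | Path) -> EpochedRecording:
    """Read a recording written by :func:`write_recording` and validate it."""
    array_path, meta_path = _paths(path)
    if not array_path.exists():
        raise FormatError(f"missing array payload {array_path}")
    if not meta_path.exists():
        raise FormatError(f"missing JSON sidecar {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar {meta_path} is not valid JSON: {exc}") from exc
    required = {"fs", "channel_ids", "labels", "frequencies", "subject_id"}
    missing = required - meta.keys()
    if missing:
        raise FormatError(f"sidecar missing fields: {sorted(missing)}")
    data = np.load(array_path)
    return EpochedRecording(
        data=data,
        fs=meta["fs"],
        channel_ids=meta["channel_ids"],
        labels=np.asarray(meta["labels"]),
        frequencies=meta["frequencies"],
        subject_id=meta["subject_id"],
    )


def read_mat_recording(path: str | Path, fs: float = 256.0,
                       frequencies: list[float] | None = None) -> EpochedRecording:
    """Best-effort loader for a MATLAB-style deposited recording.

    Looks for a trials x channels x samples array and a label vector inside
    a ``.mat`` payload (v7 via :func:`scipy.io.loadmat`, v7.3 via h5py).
    This adapter is a convenience for working with externally deposited
    data; all tests and examples use the native container or the synthetic
    generator instead.
    """
    import scipy.io

    path = Path(path)
    try:
        payload = scipy.io.loadmat(path, squeeze_me=True)
        arrays = {k: np.asarray(v) for k, v in payload.items()
                  if not k.startswith("__")}
    except NotImplementedError:  # v7.3 = HDF5
        import h5py

        arrays = {}
        with h5py.File(path, "r") as h5:
            h5.visititems(
                lambda name, obj: arrays.__setitem__(name, np.asarray(obj))
                if isinstance(obj, h5py.Dataset) else None
            )
    data = next((a for a in arrays.values() if a.ndim == 3), None)
    if data is None:
        raise FormatError(f"no 3-D trials x channels x samples array found in {path}")
    labels = next(
        (a.ravel() for a in arrays.values()
         if a.ndim <= 2 and a.size == data.shape[0] and a is not data),
        None,
    )
    if labels is None:
        raise FormatError(f"no per-trial label vector found in {path}")
    labels = np.asarray(labels, dtype=float)
    if labels.min() >= 1:  # MATLAB 1-based class indices
        labels = labels - 1
    if frequencies is None:
        frequencies = [60 / 10, 60 / 9, 60 / 8, 60 / 6]
    return EpochedRecording(
        data=data,
        fs=fs,
        channel_ids=list(range(1, data.shape[1] + 1)),
        labels=labels.astype(int),
        frequencies=frequencies,
        subject_id=path.stem,
    )
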
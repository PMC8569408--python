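"""Electrode-shift channel combinations, per-combination accuracies, and
the ACA / RES robustness measures.

The 21-channel grid is split into three overlapping 9-channel groups
(left 1-9, middle 7-15, right 13-21), each holding one nominal electrode
(O1 = 5, Oz = 11, O2 = 17) and its eight shifted neighbours.  A channel
combination picks one channel per group in use:

* 1 channel  -> the 9 middle-group channels,
* 2 channels -> left x right, 81 combinations,
* 3 channels -> left x middle x right minus tuples with a repeated
  channel id (the groups overlap), 675 combinations.

Per subject and condition, the accuracy over every combination gives the
average classification accuracy across the shift (ACA, the mean) and the
robustness to electrode shift (RES = 1 - CV, CV the coefficient of
variation of the per-combination accuracies).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifiers import ClassifierConfig, predict_trials
from .dataio import ElectrodeGrid, EpochedRecording, ValidationError
from .preprocess import extract_window

logger = logging.getLogger(__name__)

__all__ = [
    "RobustnessResult",
    "enumerate_combinations",
    "accuracy_per_combination",
    "compute_aca",
    "compute_res",
    "evaluate_robustness",
    "shift_direction_map",
]


@dataclass
class RobustnessResult:
    """Per (subject, algorithm, n_channels, window) combination accuracies."""

    subject_id: str
    algorithm: str
    n_channels: int
    window_length: float
    combos: list[tuple[int, ...]]
    accuracies: np.ndarray

    @property
    def aca(self) -> float:
        return compute_aca(self.accuracies)

    @property
    def res(self) -> float:
        return compute_res(self.accuracies)

    def to_frame(self) -> pd.DataFrame:
        """One row per channel combination, tidy format."""
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "algorithm": self.algorithm,
                "n_channels": self.n_channels,
                "window_length": self.window_length,
                "combo": ["-".join(map(str, c)) for c in self.combos],
                "accuracy": self.accuracies,
            }
        )


def enumerate_combinations(grid: ElectrodeGrid, n_channels: int) -> list[tuple[int, ...]]:
    """All electrode-shift channel combinations for 1, 2 or 3 channels.

    Deterministic lexicographic order; tuples never contain a repeated
    channel id (overlapping-group products are filtered).
    """
    if n_channels == 1:
        return [(c,) for c in grid.middle]
    if n_channels == 2:
        return list(itertools.product(grid.left, grid.right))
    if n_channels == 3:
        return [
            combo
            for combo in itertools.product(grid.left, grid.middle, grid.right)
            if len(set(combo)) == 3
        ]
    raise ValidationError(f"n_channels must be 1, 2 or 3, got {n_channels}")


def accuracy_per_combination(
    rec: EpochedRecording,
    combos: list[tuple[int, ...]],
    config: ClassifierConfig,
    window_length: float | None = None,
) -> np.ndarray:
    """Fraction of trials classified correctly, for each combination.

    ``rec`` must already be preprocessed to the analysis band and contain
    every channel any combination references; all trials of the subject
    are pooled into a single accuracy per combination.
    """
    if window_length is not None:
        rec = extract_window(rec, window_length)
    index = {c: i for i, c in enumerate(rec.channel_ids)}
    missing = sorted({c for combo in combos for c in combo} - index.keys())
    if missing:
        raise ValidationError(f"channels {missing} absent from recording")
    labels = rec.labels
    freqs = tuple(rec.frequencies)
    out = np.empty(len(combos))
    for i, combo in enumerate(combos):
        rows = [index[c] for c in combo]
        preds = predict_trials(rec.data, rec.fs, freqs, config, channel_rows=rows)
        out[i] = float(np.mean(preds == labels))
    return out


def compute_aca(accuracies: np.ndarray) -> float:
    """Average classification accuracy across the electrode shift (mean)."""
    accuracies = np.asarray(accuracies, dtype=float)
    if accuracies.size == 0:
        raise ValidationError("cannot average an empty accuracy vector")
    return float(accuracies.mean())


def compute_res(accuracies: np.ndarray, ddof: int = 1) -> float:
    """Robustness to electrode shift: ``1 - CV`` of the accuracies.

    CV is the sample standard deviation (``ddof = 1``) over the mean; a
    constant vector gives RES exactly 1, a zero mean leaves CV undefined.
    """
    accuracies = np.asarray(accuracies, dtype=float)
    if accuracies.size == 0:
        raise ValidationError("cannot compute RES of an empty accuracy vector")
    mean = accuracies.mean()
    if mean <= 0:
        raise ValidationError("CV undefined: mean accuracy is zero")
    if accuracies.size == 1 or np.all(accuracies == accuracies[0]):
        return 1.0  # sd is exactly zero for a constant field
    sd = accuracies.std(ddof=ddof)
    return float(1.0 - sd / mean)


def subsample_combinations(combos: list[tuple[int, ...]],
                           max_combos: int | None) -> list[tuple[int, ...]]:
    """Deterministic evenly spaced subsample of a combination list."""
    if max_combos is None or max_combos >= len(combos):
        return combos
    idx = np.unique(np.linspace(0, len(combos) - 1, max_combos).round().astype(int))
    return [combos[i] for i in idx]


def evaluate_robustness(
    rec: EpochedRecording,
    config: ClassifierConfig,
    n_channels: int,
    window_length: float,
    grid: ElectrodeGrid | None = None,
    max_combos: int | None = None,
) -> RobustnessResult:
    """Full robustness evaluation for one subject / algorithm / condition."""
    grid = grid or ElectrodeGrid()
    combos = subsample_combinations(enumerate_combinations(grid, n_channels), max_combos)
    acc = accuracy_per_combination(rec, combos, config, window_length)
    return RobustnessResult(
        subject_id=rec.subject_id,
        algorithm=config.algorithm,
        n_channels=n_channels,
        window_length=window_length,
        combos=combos,
        accuracies=acc,
    )


def shift_direction_map(
    recs: EpochedRecording | list[EpochedRecording],
    config: ClassifierConfig,
    window_length: float,
    grid: ElectrodeGrid | None = None,
) -> np.ndarray:
    """Accuracy map when all three electrodes shift in the same direction.

    For each displacement ``(dr, dc)`` in the 3 x 3 king-move
    neighbourhood (including the unshifted centre), the three nominal
    electrodes O1/Oz/O2 move together on the grid; the resulting
    three-channel accuracy is averaged across subjects and the nine means
    are min-max normalized to [0, 1].  Row index is ``dr + 1`` (up,
    none, down), column index ``dc + 1`` (left, none, right).
    """
    if isinstance(recs, EpochedRecording):
        recs = [recs]
    grid = grid or ElectrodeGrid()
    anchor_pos = [grid.position_of(c) for c in sorted(grid.anchors)]
    raw = np.empty((3, 3))
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            channels = tuple(
                grid.channel_of(r + dr, c + dc) for r, c in anchor_pos
            )
            accs = [
                accuracy_per_combination(rec, [channels], config, window_length)[0]
                for rec in recs
            ]
            raw[dr + 1, dc + 1] = float(np.mean(accs))
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn("all nine shift accuracies equal; normalized map set to zeros")
        return np.zeros((3, 3))
    return (raw - lo) / (hi - lo)
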
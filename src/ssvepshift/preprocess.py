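"""Preprocessing: decimation to 256 Hz, zero-phase band-pass, windowing.

The analysis band is 4-52 Hz, realized as a third-order Butterworth
filter applied forward and backward (zero net phase, sixth-order
magnitude).  Decimation applies an anti-alias low-pass before taking
every k-th sample; naive striding would alias broadband noise into the
SSVEP band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .dataio import EpochedRecording, ValidationError

__all__ = ["PreprocessConfig", "decimate", "bandpass", "extract_window", "preprocess"]

DEFAULT_WINDOW_LENGTHS = (2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)


@dataclass
class PreprocessConfig:
    target_fs: float = 256.0
    band: tuple[float, float] = (4.0, 52.0)
    filter_order: int = 3
    window_lengths: tuple[float, ...] = DEFAULT_WINDOW_LENGTHS

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high < self.target_fs / 2:
            raise ValidationError(
                f"band {self.band} must satisfy 0 < low < high < Nyquist"
            )
        for wl in self.window_lengths:
            n = wl * self.target_fs
            if abs(n - round(n)) > 1e-9:
                raise ValidationError(
                    f"window length {wl} s is not an integer sample count at "
                    f"{self.target_fs} Hz"
                )


def decimate(rec: EpochedRecording, target_fs: float) -> EpochedRecording:
    """Anti-alias filter and downsample to ``target_fs``.

    The original rate must be an integer multiple of the target; the
    identity case is returned untouched.
    """
    ratio = rec.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValidationError(
            f"fs {rec.fs} is not an integer multiple of target {target_fs}"
        )
    q = round(ratio)
    if q == 1:
        return rec
    out = scipy.signal.decimate(rec.data, q, axis=-1, zero_phase=True)
    return rec.with_data(out, fs=target_fs)


def bandpass(rec: EpochedRecording, band: tuple[float, float] = (4.0, 52.0),
             order: int = 3) -> EpochedRecording:
    """Zero-phase Butterworth band-pass, applied per channel per trial.

    Forward-backward application cancels the phase response; trials are
    filtered independently along the sample axis, so there is no
    cross-trial leakage.
    """
    low, high = band
    if not 0 < low < high < rec.fs / 2:
        raise ValidationError(f"band {band} invalid for fs {rec.fs}")
    sos = scipy.signal.butter(order, band, btype="bandpass", fs=rec.fs, output="sos")
    out = scipy.signal.sosfiltfilt(sos, rec.data, axis=-1)
    return rec.with_data(out)


def extract_window(rec: EpochedRecording, length_s: float,
                   offset_s: float = 0.0) -> EpochedRecording:
    """Restrict every trial to ``[offset_s, offset_s + length_s)``."""
    if offset_s < 0:
        raise ValidationError("offset must be non-negative")
    if offset_s + length_s > rec.duration + 1e-9:
        raise ValidationError(
            f"window {offset_s}+{length_s} s exceeds trial duration {rec.duration} s"
        )
    start = round(offset_s * rec.fs)
    stop = start + round(length_s * rec.fs)
    if start == 0 and stop == rec.n_samples:
        return rec
    return rec.with_data(rec.data[:, :, start:stop])


def preprocess(rec: EpochedRecording,
               config: PreprocessConfig | None = None) -> EpochedRecording:
    """Decimate to the target rate then band-pass filter."""
    config = config or PreprocessConfig()
    rec = decimate(rec, config.target_fs)
    return bandpass(rec, config.band, config.filter_order)
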
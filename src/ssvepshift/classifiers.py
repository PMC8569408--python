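"""Five training-free SSVEP frequency classifiers with a uniform
score-then-argmax interface.

* CCA    -- maximal canonical correlation between the EEG window ``X``
  (channels x samples) and a harmonic sine/cosine reference ``Y``.
* ECCA   -- CCA on the delay-embedded EEG ``[X; X^tau]`` (circular shift).
* FBCCA  -- filter-bank CCA: sub-band CCA coefficients combined as
  ``sum_n w(n) * rho_n**2`` with ``w(n) = n**-a + b``.
* MSI    -- multivariate synchronization index (S-estimator): entropy of
  the eigenvalue spectrum of the whitened joint correlation matrix.
* EMSI   -- MSI on the delay-embedded EEG.

All scores are computed on mean-centred signals; covariance whitening
floors eigenvalues at ``eig_floor`` times the largest eigenvalue, so
duplicated or constant channels degrade gracefully instead of raising.
The decision rule is argmax over candidate frequencies with ties broken
toward the lowest frequency index.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.signal

from .dataio import ValidationError

__all__ = [
    "ALGORITHMS",
    "ClassifierConfig",
    "ReferenceSet",
    "make_reference",
    "cca_coefficient",
    "delay_embed",
    "msi_index",
    "fbcca_score",
    "scores",
    "classify",
    "predict_trials",
]

ALGORITHMS = ("CCA", "ECCA", "FBCCA", "MSI", "EMSI")

DEFAULT_FBCCA_BANDS = ((4.0, 52.0), (8.0, 52.0), (12.0, 52.0), (16.0, 52.0), (20.0, 52.0))


@dataclass(frozen=True)
class ClassifierConfig:
    """Algorithm choice plus the shared hyperparameters.

    ``nh`` harmonics in the reference set, circular delay ``tau`` samples
    for the extended variants, and the filter-bank weighting constants
    ``w(n) = n**-a + b`` over ``len(band_edges)`` sub-bands.
    """

    algorithm: str = "CCA"
    nh: int = 4
    tau: int = 1
    fbcca_a: float = 1.25
    fbcca_b: float = 0.25
    fbcca_band_edges: tuple[tuple[float, float], ...] = DEFAULT_FBCCA_BANDS
    filter_order: int = 3
    eig_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValidationError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )
        if self.tau < 0:
            raise ValidationError("tau must be non-negative")
        if self.nh < 1:
            raise ValidationError("nh must be at least 1")

    @property
    def n_subbands(self) -> int:
        return len(self.fbcca_band_edges)

    def subband_weight(self, n: int) -> float:
        """``w(n) = n**-a + b`` for sub-band index ``n`` (1-based)."""
        return n ** (-self.fbcca_a) + self.fbcca_b


def make_reference(f: float, nh: int, fs: float, m: int) -> np.ndarray:
    """Harmonic reference matrix: ``2*nh`` rows of unit sin/cos pairs.

    Row order is ``sin(2 pi k f t / fs), cos(2 pi k f t / fs)`` for
    harmonics ``k = 1..nh`` with ``t = 1..m``.
    """
    if nh * f >= fs / 2:
        raise ValidationError(
            f"harmonic {nh}x{f:.3f} Hz at or above Nyquist {fs / 2:.1f} Hz"
        )
    if m < 2 * nh:
        raise ValidationError(f"window of {m} samples cannot support 2x{nh} references")
    t = np.arange(1, m + 1) / fs
    rows = []
    for k in range(1, nh + 1):
        arg = 2 * np.pi * k * f * t
        rows.append(np.sin(arg))
        rows.append(np.cos(arg))
    return np.asarray(rows)


@lru_cache(maxsize=512)
def _reference_parts(f: float, nh: int, fs: float, m: int,
                     eig_floor: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centred reference, its whitened form, and the whitened covariance.

    Returns ``(Yc, Zy, C22w)`` with ``Zy = C22^-1/2 @ Yc`` and
    ``C22w = Zy @ Zy.T / m``.  Cached per (frequency, window) pair: the
    robustness sweeps reuse each reference thousands of times.
    """
    y = make_reference(f, nh, fs, m)
    yc = y - y.mean(axis=1, keepdims=True)
    c22 = yc @ yc.T / m
    w2 = _inv_sqrt_psd(c22, eig_floor)
    if w2 is None:  # cannot happen for a genuine sinusoid set; defensive
        raise ValidationError("degenerate reference covariance")
    zy = w2 @ yc
    return yc, zy, zy @ zy.T / m


def _inv_sqrt_psd(c: np.ndarray, floor_rel: float) -> np.ndarray | None:
    """Symmetric inverse square root with relative eigenvalue flooring.

    Returns None when the matrix is numerically zero (e.g. an all-zero
    trial), which callers map to a zero score.
    """
    lam, vec = np.linalg.eigh(c)
    lam_max = lam[-1]
    if not np.isfinite(lam_max) or lam_max <= 0:
        return None
    lam = np.maximum(lam, floor_rel * lam_max)
    return (vec / np.sqrt(lam)) @ vec.T


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=1, keepdims=True)


def _cca_from_parts(xc: np.ndarray, zy: np.ndarray, eig_floor: float) -> float:
    m = xc.shape[1]
    c11 = xc @ xc.T / m
    w1 = _inv_sqrt_psd(c11, eig_floor)
    if w1 is None:
        return 0.0
    k = w1 @ (xc @ zy.T) / m
    rho = np.linalg.svd(k, compute_uv=False)[0]
    return float(np.clip(rho, 0.0, 1.0))


def _msi_from_parts(xc: np.ndarray, zy: np.ndarray, c22w: np.ndarray,
                    eig_floor: float) -> float:
    m = xc.shape[1]
    n = xc.shape[0]
    p = n + zy.shape[0]
    c11 = xc @ xc.T / m
    w1 = _inv_sqrt_psd(c11, eig_floor)
    if w1 is None:
        return 0.0
    r = np.empty((p, p))
    r[:n, :n] = w1 @ c11 @ w1
    k = w1 @ (xc @ zy.T) / m
    r[:n, n:] = k
    r[n:, :n] = k.T
    r[n:, n:] = c22w
    lam = np.linalg.eigvalsh(r)
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total <= 0:
        return 0.0
    lam_n = lam / total
    nz = lam_n > 0
    entropy = float(np.sum(lam_n[nz] * np.log(lam_n[nz])))
    s = 1.0 + entropy / np.log(p)
    return float(np.clip(s, 0.0, 1.0))


def cca_coefficient(x: np.ndarray, y: np.ndarray, eig_floor: float = 1e-12) -> float:
    """Maximal canonical correlation between ``x`` and ``y`` rows.

    Computed as the largest singular value of the whitened
    cross-covariance ``Cxx^-1/2 Cxy Cyy^-1/2`` after per-row centring.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ValidationError(
            f"sample counts differ: X has {x.shape[1]}, Y has {y.shape[1]}"
        )
    xc, yc = _center(x), _center(y)
    m = xc.shape[1]
    c22 = yc @ yc.T / m
    w2 = _inv_sqrt_psd(c22, eig_floor)
    if w2 is None:
        return 0.0
    return _cca_from_parts(xc, w2 @ yc, eig_floor)


def msi_index(x: np.ndarray, y: np.ndarray, eig_floor: float = 1e-12) -> float:
    """Multivariate synchronization index (S-estimator) of ``x`` and ``y``.

    Builds the joint correlation matrix ``C`` of the centred signals,
    whitens the diagonal blocks (``R = U C U^T``), and maps the entropy
    of the normalized eigenvalue spectrum to ``[0, 1]``: 0 for
    independent signals (flat spectrum), 1 for complete synchronization
    (single non-zero eigenvalue).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ValidationError(
            f"sample counts differ: X has {x.shape[1]}, Y has {y.shape[1]}"
        )
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite input")
    xc, yc = _center(x), _center(y)
    m = xc.shape[1]
    c22 = yc @ yc.T / m
    w2 = _inv_sqrt_psd(c22, eig_floor)
    if w2 is None:
        return 0.0
    zy = w2 @ yc
    return _msi_from_parts(xc, zy, zy @ zy.T / m, eig_floor)


def delay_embed(x: np.ndarray, tau: int) -> np.ndarray:
    """Stack ``x`` with its circular right-shift by ``tau`` samples.

    The shift moves the final ``tau`` samples to the front; ``tau = 0``
    degenerates to duplicating the channels.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if tau >= x.shape[1]:
        raise ValidationError(f"tau {tau} must be smaller than {x.shape[1]} samples")
    if tau < 0:
        raise ValidationError("tau must be non-negative")
    return np.vstack([x, np.roll(x, tau, axis=1)])


@lru_cache(maxsize=64)
def _band_sos(low: float, high: float, order: int, fs: float):
    return scipy.signal.butter(order, (low, high), btype="bandpass", fs=fs,
                               output="sos")


def fbcca_score(x: np.ndarray, f: float, fs: float,
                config: ClassifierConfig) -> float:
    """Filter-bank CCA score ``sum_n w(n) * rho_n**2`` for frequency ``f``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    m = x.shape[1]
    _, zy, _ = _reference_parts(f, config.nh, fs, m, config.eig_floor)
    total = 0.0
    for n, band in enumerate(config.fbcca_band_edges, start=1):
        sos = _band_sos(band[0], band[1], config.filter_order, fs)
        xb = scipy.signal.sosfiltfilt(sos, x, axis=-1)
        rho = _cca_from_parts(_center(xb), zy, config.eig_floor)
        total += config.subband_weight(n) * rho**2
    return total


@dataclass(frozen=True)
class ReferenceSet:
    """Lazy per-frequency harmonic reference matrices for one sampling rate."""

    frequencies: tuple[float, ...]
    nh: int = 4
    fs: float = 256.0

    def matrix(self, f: float, m: int) -> np.ndarray:
        return make_reference(f, self.nh, self.fs, m)


def scores(trial: np.ndarray, refs: ReferenceSet,
           config: ClassifierConfig) -> np.ndarray:
    """Score a single channels x samples trial against every frequency."""
    x = np.atleast_2d(np.asarray(trial, dtype=float))
    m = x.shape[1]
    fs = refs.fs
    if config.algorithm == "FBCCA":
        return np.array([fbcca_score(x, f, fs, config) for f in refs.frequencies])
    if config.algorithm in ("ECCA", "EMSI"):
        x = delay_embed(x, config.tau)
    xc = _center(x)
    out = np.empty(len(refs.frequencies))
    for i, f in enumerate(refs.frequencies):
        _, zy, c22w = _reference_parts(f, config.nh, fs, m, config.eig_floor)
        if config.algorithm in ("MSI", "EMSI"):
            out[i] = _msi_from_parts(xc, zy, c22w, config.eig_floor)
        else:
            out[i] = _cca_from_parts(xc, zy, config.eig_floor)
    return out


def classify(trial: np.ndarray, refs: ReferenceSet,
             config: ClassifierConfig) -> int:
    """Index of the winning stimulus frequency (ties -> lowest index)."""
    return int(np.argmax(scores(trial, refs, config)))


def predict_trials(data: np.ndarray, fs: float, frequencies: tuple[float, ...],
                   config: ClassifierConfig,
                   channel_rows: list[int] | None = None) -> np.ndarray:
    """Predicted frequency index for every trial of a data array.

    ``data`` is trials x channels x samples; ``channel_rows`` selects a
    subset of channel rows (all by default).  For FBCCA the sub-band
    filtering of the full array is hoisted out of the per-trial loop,
    which matters when the same recording is scored for hundreds of
    channel combinations.
    """
    data = np.asarray(data, dtype=float)
    if channel_rows is not None:
        data = data[:, channel_rows, :]
    refs = ReferenceSet(tuple(frequencies), nh=config.nh, fs=fs)
    if config.algorithm != "FBCCA":
        return np.array([classify(data[t], refs, config)
                         for t in range(data.shape[0])])

    m = data.shape[2]
    banks = [
        scipy.signal.sosfiltfilt(_band_sos(b[0], b[1], config.filter_order, fs),
                                 data, axis=-1)
        for b in config.fbcca_band_edges
    ]
    zys = [_reference_parts(f, config.nh, fs, m, config.eig_floor)[1]
           for f in frequencies]
    weights = [config.subband_weight(n) for n in range(1, config.n_subbands + 1)]
    preds = np.empty(data.shape[0], dtype=int)
    for t in range(data.shape[0]):
        centred = [_center(bank[t]) for bank in banks]
        trial_scores = np.zeros(len(frequencies))
        for i, zy in enumerate(zys):
            trial_scores[i] = sum(
                w * _cca_from_parts(xb, zy, config.eig_floor) ** 2
                for w, xb in zip(weights, centred)
            )
        preds[t] = int(np.argmax(trial_scores))
    return preds
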
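"""Synthetic SSVEP recordings over the dense occipital grid.

Each trial is a phase-locked harmonic stack at one of four stimulus
frequencies (60/10, 60/9, 60/8, 60/6 Hz -- exact rationals of the 60 Hz
monitor refresh), spatially weighted by a smooth Gaussian gain field so
that electrodes displaced from the focus position see a lower SNR, plus
1/f^beta background noise (independent per channel, with an optional
common-mode component shared across channels).

The generator defines the study conditions for every downstream stage:
classifier sanity checks, electrode-shift robustness, and statistics all
run on its output, so its defaults are fixed and documented rather than
tuned per experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataio import ElectrodeGrid, EpochedRecording, ValidationError

__all__ = [
    "DEFAULT_FREQUENCIES",
    "SimulationConfig",
    "spatial_gain",
    "simulate_recording",
    "simulate_study",
]

#: Stimulus frequencies as exact rationals of the 60 Hz refresh rate.
DEFAULT_FREQUENCIES = (60 / 10, 60 / 9, 60 / 8, 60 / 6)


@dataclass
class SimulationConfig:
    """Conditions for one simulated study.

    Defaults mirror the acquisition protocol emulated here: four
    pattern-reversal stimuli, 5 s trials, 25 trials per frequency per
    subject (20 trials x 5 sessions pooled), a 21-electrode 3 x 7 grid at
    1.3 cm pitch centred on Oz.  ``snr_db`` is broadband signal power at
    the focus electrode over total noise power; ``gain_sigma`` is the
    spatial spread (cm) of the SSVEP gain field.
    """

    n_subjects: int = 1
    trials_per_frequency: int = 25
    stimulus_frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    trial_length: float = 5.0
    fs: float = 256.0
    n_harmonics_signal: int = 4
    harmonic_decay: float = 1.0
    snr_db: float = -15.0
    gain_sigma: float = 2.0
    gain_sigma_col: float | None = None  # None -> isotropic; inf -> row-focused band
    focus_position: tuple[int, int] = (2, 4)  # Oz, middle row centre column
    noise_exponent: float = 1.0
    common_mode_weight: float = 0.3
    phase_jitter: float = 2 * math.pi
    alpha_amplitude: float = 0.0  # optional 10 Hz background oscillator
    seed: int = 0
    grid: ElectrodeGrid = field(default_factory=ElectrodeGrid)

    def __post_init__(self) -> None:
        n = self.trial_length * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValidationError(
                f"trial_length x fs = {n} is not an integer sample count"
            )
        nyquist = self.fs / 2
        top = max(self.stimulus_frequencies) * self.n_harmonics_signal
        if top >= nyquist:
            raise ValidationError(
                f"harmonic {top:.2f} Hz at or above Nyquist {nyquist:.2f} Hz"
            )
        if not self.gain_sigma > 0:
            raise ValidationError("gain_sigma must be positive")
        if math.isnan(self.snr_db):
            raise ValidationError("snr_db must not be NaN")
        r, c = self.focus_position
        self.grid.channel_of(r, c)  # raises if out of bounds

    @property
    def n_samples(self) -> int:
        return round(self.trial_length * self.fs)

    @property
    def n_trials(self) -> int:
        return self.trials_per_frequency * len(self.stimulus_frequencies)


def spatial_gain(grid: ElectrodeGrid, focus: tuple[int, int], sigma: float,
                 sigma_col: float | None = None) -> np.ndarray:
    """Per-channel SSVEP gain: Gaussian of physical distance from the focus.

    By default isotropic, ``gain = exp(-d^2 / (2 sigma^2))`` with ``d``
    the distance in cm from the focus electrode; the focus channel has
    gain exactly 1.  With ``sigma_col`` the horizontal spread decouples
    from the vertical one; ``sigma_col = inf`` yields a row-focused band
    (the occipital midline O1-Oz-O2 strip responds uniformly and gain
    falls off only with vertical displacement).
    """
    if not sigma > 0:
        raise ValidationError("sigma must be positive")
    if sigma_col is None:
        sigma_col = sigma
    if not sigma_col > 0:
        raise ValidationError("sigma_col must be positive")
    fr, fc = focus
    focus_channel = grid.channel_of(fr, fc)
    fy, fx = grid.position_cm(focus_channel)
    gains = np.empty(grid.n_channels)
    for i, ch in enumerate(range(1, grid.n_channels + 1)):
        y, x = grid.position_cm(ch)
        e = (y - fy) ** 2 / sigma**2
        if not math.isinf(sigma_col):
            e += (x - fx) ** 2 / sigma_col**2
        gains[i] = math.exp(-0.5 * e)
    return gains


def _colored_noise(rng: np.random.Generator, shape: tuple[int, ...],
                   beta: float, fs: float) -> np.ndarray:
    """Unit-variance 1/f^beta Gaussian noise along the last axis."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-beta / 2.0)
    white = rng.standard_normal(shape[:-1] + (freqs.size,)) + 1j * rng.standard_normal(
        shape[:-1] + (freqs.size,)
    )
    white[..., 0] = 0.0
    noise = np.fft.irfft(white * scale, n=n, axis=-1)
    sd = noise.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return noise / sd


def simulate_recording(config: SimulationConfig, subject: int = 0,
                       subject_id: str | None = None) -> EpochedRecording:
    """Simulate one subject's epoched recording.

    Each subject draws from an independent random substream derived from
    ``(config.seed, subject)``, so adding subjects never perturbs earlier
    ones.  Label order is a seeded permutation of the balanced label
    vector (every frequency appears exactly ``trials_per_frequency``
    times).
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, subject)))
    grid = config.grid
    n_trials, n_samples = config.n_trials, config.n_samples
    n_channels = grid.n_channels
    freqs = config.stimulus_frequencies

    labels = rng.permutation(np.repeat(np.arange(len(freqs)), config.trials_per_frequency))
    gains = spatial_gain(grid, config.focus_position, config.gain_sigma,
                         config.gain_sigma_col)

    # harmonic stack with amplitude k^-gamma; power at the focus electrode
    k = np.arange(1, config.n_harmonics_signal + 1)
    harmonic_amp = k ** (-config.harmonic_decay)
    signal_power = float(np.sum(harmonic_amp**2) / 2.0)

    w = config.common_mode_weight
    noise_power = 1.0 + w**2
    if math.isinf(config.snr_db) and config.snr_db < 0:
        amp_scale = 0.0
    else:
        amp_scale = math.sqrt(noise_power * 10.0 ** (config.snr_db / 10.0) / signal_power)

    t = np.arange(1, n_samples + 1) / config.fs
    data = np.empty((n_trials, n_channels, n_samples))
    for trial in range(n_trials):
        f = freqs[labels[trial]]
        phi = rng.uniform(0.0, config.phase_jitter)
        s = np.zeros(n_samples)
        for kk, a in zip(k, harmonic_amp):
            s += a * np.sin(2 * math.pi * kk * f * t + phi)
        noise = _colored_noise(rng, (n_channels, n_samples),
                               config.noise_exponent, config.fs)
        if w > 0:
            common = _colored_noise(rng, (n_samples,), config.noise_exponent, config.fs)
            noise = noise + w * common[None, :]
        trial_data = gains[:, None] * (amp_scale * s)[None, :] + noise
        if config.alpha_amplitude > 0:
            alpha_phi = rng.uniform(0.0, 2 * math.pi)
            trial_data += config.alpha_amplitude * np.sin(
                2 * math.pi * 10.0 * t + alpha_phi
            )[None, :]
        data[trial] = trial_data

    if subject_id is None:
        subject_id = f"S{subject + 1:02d}"
    return EpochedRecording(
        data=data,
        fs=config.fs,
        channel_ids=list(range(1, n_channels + 1)),
        labels=labels,
        frequencies=list(freqs),
        subject_id=subject_id,
    )


def simulate_study(config: SimulationConfig) -> list[EpochedRecording]:
    """Simulate all ``config.n_subjects`` subjects."""
    return [simulate_recording(config, subject=i) for i in range(config.n_subjects)]
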
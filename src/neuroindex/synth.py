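"""Seeded synthetic generators: EC/EO EEG pairs, model PSD samples, ECG.

Everything here is a pure function of its configuration plus a seed, so the
whole pipeline is testable without any external recordings. The EEG
generator shapes white noise in the frequency domain: a 1/f^beta background
on every channel, a Gaussian-profile alpha component whose amplitude differs
between the eyes-closed and eyes-open conditions on the reactive occipital
channels, and a sensorimotor-band component on the central channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError
from .io_formats import Condition, Recording
from .predictor import ModelParams, model_psd
from .spectral import PSDEstimate

__all__ = ["SynthEEGConfig", "generate_eeg_pair", "sample_model_psd", "generate_ecg"]


@dataclass
class SynthEEGConfig:
    """Configuration of the EC/EO EEG pair generator."""

    duration_s: float = 180.0
    sample_rate_hz: float = 128.0
    labels: tuple[str, ...] = ("O1", "O2", "C3", "C4")
    background_exponent: float = 1.0
    background_scale: float = 1.0
    alpha_center_hz: float = 10.25
    alpha_bandwidth_hz: float = 2.0
    alpha_amp_ec: float = 2.0
    alpha_amp_eo: float = 0.3
    reactive_channels: tuple[str, ...] = ("O1", "O2")
    smr_center_hz: float = 11.0
    smr_bandwidth_hz: float = 2.0
    smr_amp: float = 1.5
    smr_channels: tuple[str, ...] = ("C3", "C4")
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 16:
            raise ConfigError(f"duration_s must be >= 16 s, got {self.duration_s}")
        if self.sample_rate_hz <= 0:
            raise ConfigError("sample_rate_hz must be positive")
        if not self.alpha_amp_ec >= self.alpha_amp_eo >= 0:
            raise ConfigError("require alpha_amp_ec >= alpha_amp_eo >= 0")
        if not set(self.reactive_channels) <= set(self.labels):
            raise ConfigError("reactive_channels must be a subset of labels")


def _shaped_noise(
    rng: np.random.Generator, n: int, fs: float, profile: np.ndarray
) -> np.ndarray:
    """Gaussian noise with the given rFFT amplitude profile, unit variance."""
    spec = (rng.standard_normal(profile.size) + 1j * rng.standard_normal(profile.size))
    spec *= profile
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = np.std(x)
    return x / sd if sd > 0 else x


def _pink_profile(freqs: np.ndarray, beta: float) -> np.ndarray:
    prof = np.zeros_like(freqs)
    prof[1:] = freqs[1:] ** (-beta / 2.0)
    return prof


def _band_profile(freqs: np.ndarray, center: float, bandwidth: float) -> np.ndarray:
    # Gaussian amplitude profile whose power FWHM equals `bandwidth`
    sd = bandwidth / 2.355
    return np.exp(-((freqs - center) ** 2) / (4.0 * sd**2))


def _render_condition(
    config: SynthEEGConfig, alpha_amp_reactive: float, seed_seq: np.random.SeedSequence
) -> np.ndarray:
    n = int(round(config.duration_s * config.sample_rate_hz))
    freqs = np.fft.rfftfreq(n, d=1.0 / config.sample_rate_hz)
    pink = _pink_profile(freqs, config.background_exponent)
    alpha = _band_profile(freqs, config.alpha_center_hz, config.alpha_bandwidth_hz)
    smr = _band_profile(freqs, config.smr_center_hz, config.smr_bandwidth_hz)

    data = np.empty((len(config.labels), n))
    child_seeds = seed_seq.spawn(len(config.labels))
    for row, (label, child) in enumerate(zip(config.labels, child_seeds)):
        rng = np.random.default_rng(child)
        x = config.background_scale * _shaped_noise(rng, n, config.sample_rate_hz, pink)
        a_amp = alpha_amp_reactive if label in config.reactive_channels else config.alpha_amp_eo
        if a_amp > 0:
            x = x + a_amp * _shaped_noise(rng, n, config.sample_rate_hz, alpha)
        if label in config.smr_channels and config.smr_amp > 0:
            x = x + config.smr_amp * _shaped_noise(rng, n, config.sample_rate_hz, smr)
        if config.noise_sd > 0:
            x = x + config.noise_sd * rng.standard_normal(n)
        data[row] = x
    return data


def generate_eeg_pair(config: SynthEEGConfig) -> tuple[Recording, Recording]:
    """Generate a seeded (eyes-closed, eyes-open) recording pair.

    The two conditions use independent seed-derived noise streams; the only
    systematic difference is the alpha amplitude on the reactive channels.
    """
    root = np.random.SeedSequence(config.seed)
    ec_seq, eo_seq = root.spawn(2)
    ec_data = _render_condition(config, config.alpha_amp_ec, ec_seq)
    eo_data = _render_condition(config, config.alpha_amp_eo, eo_seq)
    labels = list(config.labels)
    return (
        Recording(ec_data, config.sample_rate_hz, labels, Condition.EC),
        Recording(eo_data, config.sample_rate_hz, labels, Condition.EO),
    )


def sample_model_psd(
    params: ModelParams,
    freqs: np.ndarray,
    noise_sd_fraction: float = 0.0,
    seed: int = 0,
    channel: str = "C3",
) -> PSDEstimate:
    """Draw a noisy PSD directly from the spectral model on ``freqs`` (> 0).

    Multiplicative Gaussian noise of the given relative standard deviation,
    clipped so power stays positive; ``noise_sd_fraction = 0`` reproduces the
    model exactly.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ConfigError("model PSD sampling requires strictly positive frequencies")
    clean = model_psd(freqs, params)
    if noise_sd_fraction > 0:
        rng = np.random.default_rng(seed)
        eps = noise_sd_fraction * rng.standard_normal(freqs.size)
        power = np.clip(clean * (1.0 + eps), 1e-12 * np.max(clean), None)
    else:
        power = clean
    resolution = float(freqs[1] - freqs[0])
    return PSDEstimate(
        freqs_hz=freqs,
        power=power[np.newaxis, :],
        resolution_hz=resolution,
        epoch_seconds=1.0 / resolution,
        labels=[channel],
    )


def _gaussian(t: np.ndarray, center: float, sd: float) -> np.ndarray:
    return np.exp(-((t - center) ** 2) / (2.0 * sd**2))


def _ricker(t: np.ndarray, center: float, width: float) -> np.ndarray:
    u = (t - center) / width
    return (1.0 - u**2) * np.exp(-0.5 * u**2)


def generate_ecg(
    duration_s: float,
    sample_rate_hz: float,
    bpm: float,
    jitter_sd_s: float = 0.0,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic single-lead ECG plus ground-truth R-peak sample indices.

    Beats are placed at period 60/bpm (optionally jittered); each beat is a
    narrow Ricker-wavelet QRS with smaller Gaussian P and T bumps. The
    morphology is schematic, not biophysical - sufficient to exercise QRS
    detection against a known truth.
    """
    if not 20 < bpm < 240:
        raise ConfigError(f"bpm must lie in (20, 240), got {bpm}")
    if duration_s <= 0:
        raise ConfigError(f"duration_s must be positive, got {duration_s}")
    if sample_rate_hz <= 0:
        raise ConfigError("sample_rate_hz must be positive")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    period = 60.0 / bpm

    start, end_margin = 0.4, 0.4
    span = duration_s - start - end_margin
    if span < 0:
        raise ConfigError("duration too short to place any beat")
    n_beats = int(np.floor(span / period + 1e-9)) + 1
    nominal = start + np.arange(n_beats) * period
    if jitter_sd_s > 0:
        jittered = nominal + rng.normal(0.0, jitter_sd_s, size=n_beats)
        beat_times = jittered[(jittered > 0.3) & (jittered < duration_s - end_margin)]
    else:
        beat_times = nominal
    if beat_times.size == 0:
        raise ConfigError("duration too short to place any beat")

    x = np.zeros(n)
    for bt in beat_times:
        x += 1.00 * _ricker(t, bt, 0.012)          # QRS
        x += 0.12 * _gaussian(t, bt - 0.18, 0.025)  # P wave
        x += 0.25 * _gaussian(t, bt + 0.28, 0.060)  # T wave
    if noise_sd > 0:
        x += noise_sd * rng.standard_normal(n)

    truth = np.round(np.asarray(beat_times) * sample_rate_hz).astype(int)
    return x, truth
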
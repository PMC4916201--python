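"""Welch power spectral density estimation on fixed-length epochs.

The PSD is the common substrate of both analysis paths: the occipital
eyes-closed/eyes-open difference and the central-channel spectral-model fit.
Density scaling (power per Hz) is used throughout so the aperiodic power-law
component keeps a stable meaning across sample rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import DurationError, GridError, ParameterError
from .io_formats import Recording

__all__ = ["PSDEstimate", "welch_psd"]


@dataclass
class PSDEstimate:
    """Per-channel Welch PSD on a shared frequency grid.

    Attributes
    ----------
    freqs_hz
        Ascending, equally spaced frequency grid.
    power
        Channels x frequencies matrix, units of input^2 / Hz.
    resolution_hz
        Grid spacing; equals ``1 / epoch_seconds``.
    epoch_seconds
        Epoch length used by Welch's method.
    labels
        Channel labels, one per row of ``power``.
    """

    freqs_hz: np.ndarray
    power: np.ndarray
    resolution_hz: float
    epoch_seconds: float
    labels: list[str]

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if self.power.shape != (len(self.labels), self.freqs_hz.size):
            raise ValueError("power must be channels x frequencies")
        if np.any(self.power < 0):
            raise ValueError("PSD power must be non-negative")
        df = np.diff(self.freqs_hz)
        if self.freqs_hz.size > 1 and not np.allclose(df, self.resolution_hz):
            raise ValueError("frequency grid spacing must equal resolution_hz")

    def channel_index(self, label: str) -> int:
        lookup = {lab.lower(): i for i, lab in enumerate(self.labels)}
        key = label.lower()
        if key not in lookup:
            from .exceptions import ChannelNotFoundError

            raise ChannelNotFoundError(
                f"channel {label!r} not in PSD; available: {self.labels}"
            )
        return lookup[key]

    def channel_power(self, label: str) -> np.ndarray:
        return self.power[self.channel_index(label)]

    def same_grid(self, other: "PSDEstimate") -> bool:
        return self.freqs_hz.shape == other.freqs_hz.shape and np.array_equal(
            self.freqs_hz, other.freqs_hz
        )

    def require_same_grid(self, other: "PSDEstimate") -> None:
        if not self.same_grid(other):
            raise GridError("PSD frequency grids differ; no resampling is attempted")


def welch_psd(
    recording: Recording,
    epoch_seconds: float = 4.0,
    overlap_fraction: float = 0.5,
    window: str = "hann",
    detrend: str = "constant",
) -> PSDEstimate:
    """Estimate the PSD of every channel by Welch's method.

    Parameters
    ----------
    recording
        Input recording; duration must be at least ``2 * epoch_seconds``.
    epoch_seconds
        Epoch length in seconds; ``epoch_seconds * sample_rate`` must be an
        integer >= 8. The frequency resolution is ``1 / epoch_seconds``.
    overlap_fraction
        Fractional overlap between successive epochs, in [0, 1).
    window
        Taper name accepted by :func:`scipy.signal.get_window`.
    detrend
        Per-epoch detrending mode.

    Notes
    -----
    A trailing partial epoch is discarded, never zero-padded.
    """
    if not 0 <= overlap_fraction < 1:
        raise ParameterError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    nperseg_f = epoch_seconds * recording.sample_rate_hz
    nperseg = int(round(nperseg_f))
    if abs(nperseg_f - nperseg) > 1e-9 or nperseg < 8:
        raise ParameterError(
            f"epoch_seconds * sample_rate must be an integer >= 8, got {nperseg_f}"
        )
    min_duration = 2 * epoch_seconds
    if recording.duration_s < min_duration:
        raise DurationError(
            f"recording lasts {recording.duration_s:g} s; at least "
            f"{min_duration:g} s (two epochs of {epoch_seconds:g} s) required"
        )
    freqs, power = sps.welch(
        recording.data,
        fs=recording.sample_rate_hz,
        window=window,
        nperseg=nperseg,
        noverlap=int(nperseg * overlap_fraction),
        detrend=detrend,
        scaling="density",
        axis=-1,
    )
    return PSDEstimate(
        freqs_hz=freqs,
        power=power,
        resolution_hz=1.0 / epoch_seconds,
        epoch_seconds=epoch_seconds,
        labels=list(recording.labels),
    )
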
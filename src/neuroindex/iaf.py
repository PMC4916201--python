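"""Individual alpha frequency from eyes-closed minus eyes-open reactivity.

Closing the eyes enhances occipital alpha power, so the frequency at which
the EC-EO power difference peaks marks the subject's alpha rhythm. The IAF
is the mean of the per-channel peak frequencies (O1 and O2 by default), and
two 2-Hz-wide individualized sub-bands are laid out on either side of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, ParameterError
from .spectral import PSDEstimate

__all__ = ["IAFResult", "reactivity_spectrum", "estimate_iaf", "individual_bands"]

DEFAULT_CHANNELS = ("O1", "O2")
DEFAULT_SEARCH_BAND = (7.0, 14.0)


@dataclass
class IAFResult:
    """Outcome of an IAF estimation.

    ``valid`` is False when some channel shows no strictly positive EC-EO
    difference inside the search band; ``iaf_hz`` and the bands are then
    ``None``, never silently zero.
    """

    peak_hz_per_channel: dict[str, float]
    iaf_hz: float | None
    lower_band_hz: tuple[float, float] | None
    upper_band_hz: tuple[float, float] | None
    search_band_hz: tuple[float, float]
    valid: bool
    diff_spectra: dict[str, np.ndarray] = field(default_factory=dict)
    diagnostics: list[str] = field(default_factory=list)


def reactivity_spectrum(
    psd_ec: PSDEstimate, psd_eo: PSDEstimate, channel: str
) -> np.ndarray:
    """EC minus EO power at one channel, on the shared frequency grid.

    Negative entries are preserved (no clipping); grids must match exactly.
    """
    psd_ec.require_same_grid(psd_eo)
    return psd_ec.channel_power(channel) - psd_eo.channel_power(channel)


def _smooth3(x: np.ndarray) -> np.ndarray:
    # 3-bin moving average, edges handled by shrinking the window
    kernel = np.ones(3) / 3.0
    out = np.convolve(x, kernel, mode="same")
    out[0] = np.mean(x[:2])
    out[-1] = np.mean(x[-2:])
    return out


def estimate_iaf(
    psd_ec: PSDEstimate,
    psd_eo: PSDEstimate,
    channels: list[str] | tuple[str, ...] = DEFAULT_CHANNELS,
    search_band_hz: tuple[float, float] = DEFAULT_SEARCH_BAND,
    smooth: bool = False,
) -> IAFResult:
    """Estimate the IAF from the EC-EO difference at occipital channels.

    Per channel, the peak is the frequency of the maximum EC-EO difference
    inside ``search_band_hz`` (ties break toward the lower frequency). The
    IAF is the arithmetic mean of the per-channel peak frequencies and is
    valid only if every channel's peak difference is strictly positive.
    """
    psd_ec.require_same_grid(psd_eo)
    if psd_ec.epoch_seconds != psd_eo.epoch_seconds:
        raise ParameterError("EC and EO PSDs must use equal epoch_seconds")
    lo, hi = search_band_hz
    if not lo < hi:
        raise ParameterError(f"invalid search band {search_band_hz}")
    mask = (psd_ec.freqs_hz >= lo) & (psd_ec.freqs_hz <= hi)
    if not np.any(mask):
        raise ParameterError(f"search band {search_band_hz} is outside the PSD grid")
    band_freqs = psd_ec.freqs_hz[mask]

    peaks: dict[str, float] = {}
    diffs: dict[str, np.ndarray] = {}
    diagnostics: list[str] = []
    valid = True
    for ch in channels:
        diff = reactivity_spectrum(psd_ec, psd_eo, ch)
        diffs[ch] = diff
        band_diff = diff[mask]
        if smooth:
            band_diff = _smooth3(band_diff)
        idx = int(np.argmax(band_diff))  # argmax takes the first (lowest) maximum
        peaks[ch] = float(band_freqs[idx])
        if not band_diff[idx] > 0:
            valid = False
            diagnostics.append(
                f"channel {ch}: no strictly positive EC-EO difference in "
                f"[{lo:g}, {hi:g}] Hz"
            )

    if valid:
        iaf_hz = float(np.mean(list(peaks.values())))
        lower, upper = individual_bands(iaf_hz)
    else:
        iaf_hz, lower, upper = None, None, None
    return IAFResult(
        peak_hz_per_channel=peaks,
        iaf_hz=iaf_hz,
        lower_band_hz=lower,
        upper_band_hz=upper,
        search_band_hz=(float(lo), float(hi)),
        valid=valid,
        diff_spectra=diffs,
        diagnostics=diagnostics,
    )


def individual_bands(iaf_hz: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """The two individualized 2-Hz alpha sub-bands around the IAF.

    Returns ``((iaf - 2, iaf), (iaf, iaf + 2))``; requires ``iaf_hz > 2`` so
    the lower edge stays positive.
    """
    if not iaf_hz > 2:
        raise DomainError(f"iaf_hz must exceed 2 Hz to form bands, got {iaf_hz}")
    return (iaf_hz - 2.0, iaf_hz), (iaf_hz, iaf_hz + 2.0)
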
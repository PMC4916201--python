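"""ECG validation path: QRS detection, cardiac frequency, harmonic series.

The chain mirrors classic practice: zero-phase 0.1 Hz high-pass, the
Pan-Tompkins detector (band-pass, derivative, squaring, 150 ms moving-window
integration, adaptive dual thresholds with refractory period, T-wave slope
check and missed-beat search-back), NN-interval extraction with a
plausibility window, and the doubling series f_d(i) = s * 2**i that maps the
cardiac frequency s onto the canonical EEG band centers; i = 3 gives the
theoretical alpha center used as a cross-check of the EEG-derived IAF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .exceptions import DataError, DetectionError, DomainError, DurationError

__all__ = [
    "CardiacResult",
    "preprocess_ecg",
    "detect_r_peaks",
    "nn_intervals",
    "cardiac_frequency",
    "harmonic_frequency",
    "theoretical_iaf",
    "analyze_ecg",
]

# Pan-Tompkins constants (seconds unless noted); exposed for configuration.
BANDPASS_HZ = (5.0, 15.0)
INTEGRATION_WINDOW_S = 0.150
REFRACTORY_S = 0.200
TWAVE_CHECK_S = 0.360
SEARCHBACK_FACTOR = 1.66
DEFAULT_PLAUSIBILITY_S = (0.3, 2.0)


@dataclass
class CardiacResult:
    """R peaks, NN intervals, cardiac frequency and its harmonic series."""

    r_peak_indices: np.ndarray
    nn_intervals_s: np.ndarray
    s_hz: float
    harmonic_hz: dict[int, float]
    theoretical_iaf_hz: float
    n_discarded_nn: int = 0
    warnings: list[str] = field(default_factory=list)


def preprocess_ecg(signal: np.ndarray, sample_rate_hz: float) -> np.ndarray:
    """Zero-phase 0.1 Hz high-pass; removes DC and baseline drift.

    Requires at least 10 s of samples; sample rates below 100 Hz trigger a
    warning (QRS morphology is poorly resolved there).
    """
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 10 * sample_rate_hz:
        raise DurationError(
            f"ECG lasts {x.size / sample_rate_hz:g} s; at least 10 s required"
        )
    if sample_rate_hz < 100:
        warnings.warn(
            f"ECG sample rate {sample_rate_hz:g} Hz is below the recommended 100 Hz",
            stacklevel=2,
        )
    sos = sps.butter(2, 0.1, btype="highpass", fs=sample_rate_hz, output="sos")
    return sps.sosfiltfilt(sos, x)


def _bandpass(x: np.ndarray, fs: float) -> np.ndarray:
    sos = sps.butter(3, BANDPASS_HZ, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _derivative(x: np.ndarray, fs: float) -> np.ndarray:
    # five-point derivative, H(z) = (fs/8)(2 + z^-1 - z^-3 - 2 z^-4)
    kernel = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) * fs / 8.0
    return np.convolve(x, kernel, mode="same")


def detect_r_peaks(signal: np.ndarray, sample_rate_hz: float) -> np.ndarray:
    """Pan-Tompkins R-peak detection on a (preprocessed) single-lead ECG.

    Candidate peaks of the integrated signal are classified against adaptive
    signal/noise thresholds with a 200 ms refractory period; candidates
    within 360 ms of the previous beat must match at least half its maximal
    slope (T-wave rejection); a gap longer than 1.66 times the running RR
    average triggers a search-back at half threshold. Accepted peaks are
    refined to the local maximum of the input signal. All thresholds are
    relative, so detection is invariant to positive amplitude scaling.
    """
    x = np.asarray(signal, dtype=float).ravel()
    fs = float(sample_rate_hz)
    if x.size == 0 or np.allclose(x, x[0]):
        raise DetectionError("flat or empty signal: no QRS complexes found")

    bp = _bandpass(x, fs)
    der = _derivative(bp, fs)
    sq = der**2
    win = max(int(round(INTEGRATION_WINDOW_S * fs)), 1)
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY_S * fs))
    candidates, _ = sps.find_peaks(mwi, distance=max(refractory, 1))
    if candidates.size == 0:
        raise DetectionError("no candidate peaks in integrated signal")

    # learning phase: first 2 s initialize running estimates
    learn = mwi[: max(int(2 * fs), win)]
    spki = 0.25 * float(np.max(learn))
    npki = 0.5 * float(np.mean(learn))

    slope_win = max(int(round(0.075 * fs)), 1)

    def max_slope(i: int) -> float:
        a, b = max(i - slope_win, 0), min(i + slope_win + 1, der.size)
        return float(np.max(np.abs(der[a:b])))

    accepted: list[int] = []
    rr_history: list[float] = []
    last_unaccepted: list[int] = []

    def accept(i: int, from_searchback: bool = False) -> None:
        nonlocal spki
        if from_searchback:
            spki = 0.25 * mwi[i] + 0.75 * spki
        else:
            spki = 0.125 * mwi[i] + 0.875 * spki
        if accepted:
            rr_history.append((i - accepted[-1]) / fs)
            del rr_history[:-8]
        accepted.append(i)

    for cand in candidates:
        thr1 = npki + 0.25 * (spki - npki)
        v = mwi[cand]
        is_beat = v > thr1
        if is_beat and accepted:
            since_last = (cand - accepted[-1]) / fs
            if since_last < REFRACTORY_S:
                is_beat = False
            elif since_last < TWAVE_CHECK_S:
                # T waves rise at most half as steeply as the QRS before them
                if max_slope(cand) < 0.5 * max_slope(accepted[-1]):
                    is_beat = False
        if is_beat:
            accept(cand)
            last_unaccepted.clear()
        else:
            npki = 0.125 * v + 0.875 * npki
            last_unaccepted.append(cand)
            # search-back for a missed beat
            if accepted and rr_history:
                rr_avg = float(np.mean(rr_history))
                if (cand - accepted[-1]) / fs > SEARCHBACK_FACTOR * rr_avg:
                    thr2 = 0.5 * (npki + 0.25 * (spki - npki))
                    viable = [
                        c
                        for c in last_unaccepted
                        if mwi[c] > thr2 and (c - accepted[-1]) / fs >= REFRACTORY_S
                    ]
                    if viable:
                        best = max(viable, key=lambda c: mwi[c])
                        accept(best, from_searchback=True)
                        last_unaccepted.clear()

    if not accepted:
        raise DetectionError("no peaks exceeded the adaptive threshold")

    # refine: local maximum of the input signal around each integrated peak
    refine = max(int(round(0.10 * fs)), 1)
    refined = []
    for i in accepted:
        a, b = max(i - refine, 0), min(i + refine + 1, x.size)
        refined.append(a + int(np.argmax(x[a:b])))
    refined_arr = np.unique(np.asarray(refined, dtype=int))
    return refined_arr


def nn_intervals(
    r_peaks: np.ndarray,
    sample_rate_hz: float,
    plausibility_s: tuple[float, float] = DEFAULT_PLAUSIBILITY_S,
) -> np.ndarray:
    """Successive R-R differences in seconds, cleaned by a plausibility window.

    Intervals outside ``plausibility_s`` are discarded.
    """
    peaks = np.asarray(r_peaks)
    if peaks.size < 2:
        raise DataError(f"need at least 2 R peaks, got {peaks.size}")
    raw = np.diff(peaks) / float(sample_rate_hz)
    lo, hi = plausibility_s
    kept = raw[(raw >= lo) & (raw <= hi)]
    if kept.size == 0:
        raise DataError(
            f"all {raw.size} NN intervals fall outside the plausibility "
            f"window [{lo:g}, {hi:g}] s"
        )
    return kept


def cardiac_frequency(nn_s: np.ndarray) -> float:
    """Cardiac frequency: the inverse of the mean NN interval."""
    nn = np.asarray(nn_s, dtype=float)
    if nn.size == 0:
        raise DataError("empty NN-interval vector")
    return float(1.0 / np.mean(nn))


def harmonic_frequency(s_hz: float, i: int) -> float:
    """The doubling series f_d(i) = s * 2**i; i = 0 returns s itself."""
    if not s_hz > 0:
        raise DomainError(f"cardiac frequency must be positive, got {s_hz}")
    if int(i) != i or i < 0:
        raise DomainError(f"harmonic order must be a non-negative integer, got {i}")
    return float(s_hz * 2**int(i))


def theoretical_iaf(s_hz: float) -> float:
    """Theoretical alpha center from the cardiac frequency: 8 * s."""
    return harmonic_frequency(s_hz, 3)


def analyze_ecg(
    signal: np.ndarray,
    sample_rate_hz: float,
    plausibility_s: tuple[float, float] = DEFAULT_PLAUSIBILITY_S,
) -> CardiacResult:
    """Full chain: high-pass, detect, NN intervals, s, harmonics, alpha.

    Convenience wrapper over the individual operations; the harmonic series
    is reported for i = 0..5.
    """
    clean = preprocess_ecg(signal, sample_rate_hz)
    peaks = detect_r_peaks(clean, sample_rate_hz)
    raw_nn = np.diff(peaks) / sample_rate_hz
    nn = nn_intervals(peaks, sample_rate_hz, plausibility_s)
    s = cardiac_frequency(nn)
    harmonics = {i: harmonic_frequency(s, i) for i in range(6)}
    notes = []
    n_discarded = int(raw_nn.size - nn.size)
    if n_discarded:
        notes.append(f"discarded {n_discarded} implausible NN interval(s)")
    return CardiacResult(
        r_peak_indices=peaks,
        nn_intervals_s=nn,
        s_hz=s,
        harmonic_hz=harmonics,
        theoretical_iaf_hz=harmonics[3],
        n_discarded_nn=n_discarded,
        warnings=notes,
    )
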
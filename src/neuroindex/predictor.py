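"""Spectral-model fit and the neurophysiological aptitude index.

The central-channel PSD is modeled as a constant floor plus an aperiodic
power law plus one or two Gaussian probability-density peaks (alpha and,
optionally, beta):

    model(x) = k1 + A2 * x**k2 + A3 * N(x; mu, sigma) [+ A3b * N(x; mub, sigmab)]

where N is the unit-area Gaussian density, so each peak's maximum elevation
above the power law is A / (sigma * sqrt(2*pi)).

The index is the maximum difference between the fitted model and its
power-law component over the fit band. When the fit degenerates to the
power law (or fails to converge), the fallback takes the maximum difference
between the raw PSD and the power-law component instead; the method used is
always recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DataError, DomainError, GridError, ParameterError
from .spectral import PSDEstimate

__all__ = [
    "ModelParams",
    "SpectralModelFit",
    "PredictorResult",
    "Method",
    "model_psd",
    "power_law",
    "fit_psd_model",
    "compute_predictor",
    "combine_predictors",
]

SQRT_2PI = math.sqrt(2.0 * math.pi)

METHOD_MODEL = "model_minus_powerlaw"
METHOD_PSD = "psd_minus_powerlaw"
Method = str


@dataclass
class ModelParams:
    """Parameters of the spectral model.

    ``a3b``/``mub``/``sigmab`` describe the optional second (beta) peak and
    are ``None`` in single-peak mode.
    """

    k1: float
    a2: float
    k2: float
    a3: float
    mu: float
    sigma: float
    a3b: float | None = None
    mub: float | None = None
    sigmab: float | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise DomainError(f"sigma must be positive, got {self.sigma}")
        if min(self.k1, self.a2, self.a3) < 0:
            raise DomainError("k1, a2, a3 must be non-negative")
        if self.k2 > 0:
            raise DomainError(f"k2 must be <= 0, got {self.k2}")
        second = (self.a3b, self.mub, self.sigmab)
        if any(v is not None for v in second):
            if any(v is None for v in second):
                raise DomainError("a3b, mub, sigmab must be given together")
            if self.a3b < 0 or self.sigmab <= 0:
                raise DomainError("a3b must be >= 0 and sigmab > 0")
            if self.mub <= self.mu:
                raise DomainError("beta-peak center mub must exceed mu")

    @property
    def two_peaks(self) -> bool:
        return self.a3b is not None


@dataclass
class SpectralModelFit:
    """Fitted spectral model on a band of the PSD grid."""

    params: ModelParams
    freqs_hz: np.ndarray
    fitted: np.ndarray
    power_law: np.ndarray
    residual_rms: float
    converged: bool
    fit_band_hz: tuple[float, float]
    channel: str


@dataclass
class PredictorResult:
    """Per-channel aptitude indices with the method used for each."""

    index_per_channel: dict[str, float]
    method_per_channel: dict[str, Method]
    combined: float


def _gauss_density(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-((x - mu) ** 2) / (2.0 * sigma**2)) / (sigma * SQRT_2PI)


def power_law(freqs: np.ndarray, params: ModelParams) -> np.ndarray:
    """The aperiodic component ``k1 + a2 * x**k2``."""
    x = np.asarray(freqs, dtype=float)
    if np.any(x <= 0):
        raise DomainError("power law undefined at frequencies <= 0")
    return params.k1 + params.a2 * x**params.k2


def model_psd(freqs: np.ndarray, params: ModelParams) -> np.ndarray:
    """Evaluate the full spectral model pointwise on ``freqs`` (> 0)."""
    x = np.asarray(freqs, dtype=float)
    out = power_law(x, params) + params.a3 * _gauss_density(x, params.mu, params.sigma)
    if params.two_peaks:
        out = out + params.a3b * _gauss_density(x, params.mub, params.sigmab)
    return out


def _vector_to_params(theta: np.ndarray, two_peaks: bool) -> ModelParams:
    if two_peaks:
        k1, a2, k2, a3, mu, sigma, a3b, mub, sigmab = theta
        # optimizer bounds keep mub > mu; guard anyway for degenerate iterates
        mub = max(mub, mu + 1e-6)
        return ModelParams(k1, a2, k2, a3, mu, sigma, a3b, mub, sigmab)
    k1, a2, k2, a3, mu, sigma = theta
    return ModelParams(k1, a2, k2, a3, mu, sigma)


def _initial_mu(freqs: np.ndarray, power: np.ndarray, lo: float, hi: float) -> float:
    """Tallest local maximum of the PSD within [lo, hi], else band midpoint."""
    mask = (freqs >= lo) & (freqs <= hi)
    f, p = freqs[mask], power[mask]
    if f.size >= 3:
        interior = np.where((p[1:-1] >= p[:-2]) & (p[1:-1] >= p[2:]))[0] + 1
        if interior.size:
            return float(f[interior[np.argmax(p[interior])]])
    return float(0.5 * (lo + hi))


def fit_psd_model(
    psd: PSDEstimate,
    channel: str,
    iaf_hz: float | None = None,
    fit_band_hz: tuple[float, float] = (2.0, 35.0),
    two_peaks: bool = True,
    n_restarts: int = 3,
    scale: str = "linear",
    seed: int = 0,
) -> SpectralModelFit:
    """Fit the spectral model to one channel by bounded least squares.

    The alpha-peak center is initialized at ``iaf_hz`` when given (and
    bounded to IAF +- 2 Hz), otherwise at the tallest in-band local maximum.
    Up to ``n_restarts`` additional starts with jittered centers are tried;
    optimizer failure on every start yields ``converged=False``, never an
    exception.

    Parameters
    ----------
    scale
        ``"linear"`` fits raw power (the model's literal form); ``"db"``
        fits ``10*log10`` power.
    """
    lo, hi = fit_band_hz
    freqs_all = psd.freqs_hz
    mask = (freqs_all >= max(lo, psd.resolution_hz / 2)) & (freqs_all <= hi)
    mask &= freqs_all > 0
    freqs = freqs_all[mask]
    if freqs.size < 20:
        raise ParameterError(
            f"fit band {fit_band_hz} covers only {freqs.size} grid points (< 20)"
        )
    power = psd.channel_power(channel)[mask]
    pmax = float(np.max(power))
    if pmax <= 0:
        raise DataError(f"channel {channel}: PSD is identically zero in the fit band")
    if scale not in ("linear", "db"):
        raise ParameterError(f"scale must be 'linear' or 'db', got {scale!r}")

    # alpha-center bounds and starting point
    if iaf_hz is not None:
        mu0 = float(iaf_hz)
        mu_lo, mu_hi = mu0 - 2.0, mu0 + 2.0
    else:
        mu_lo, mu_hi = 7.0, 14.0
        mu0 = _initial_mu(freqs, power, mu_lo, mu_hi)
    mu_lo = max(mu_lo, float(freqs[0]))
    mu_hi = min(mu_hi, float(freqs[-1]))
    mu0 = float(np.clip(mu0, mu_lo, mu_hi))

    k1_0 = float(np.min(power))
    k2_0 = -1.0
    a2_0 = float(np.median(np.clip(power - k1_0, 1e-12 * pmax, None) * freqs))
    sigma0 = 1.0
    a3_0 = max(float(np.interp(mu0, freqs, power)) - k1_0, 1e-6 * pmax) * sigma0 * SQRT_2PI

    lower = [0.0, 0.0, -3.0, 0.0, mu_lo, 0.25]
    upper = [pmax, np.inf, 0.0, np.inf, mu_hi, 4.0]
    theta0 = [k1_0, a2_0, k2_0, a3_0, mu0, sigma0]
    if two_peaks:
        mub_lo, mub_hi = 15.0, min(30.0, float(freqs[-1]))
        mub0 = float(np.clip(2.0 * mu0, mub_lo, mub_hi))
        a3b_0 = max(float(np.interp(mub0, freqs, power)) - k1_0, 1e-6 * pmax) * SQRT_2PI
        lower += [0.0, mub_lo, 0.25]
        upper += [np.inf, mub_hi, 6.0]
        theta0 += [a3b_0, mub0, 1.5]

    if scale == "db":
        floor = 1e-12 * pmax
        target = 10.0 * np.log10(np.clip(power, floor, None))

        def residuals(theta: np.ndarray) -> np.ndarray:
            model = model_psd(freqs, _vector_to_params(theta, two_peaks))
            return 10.0 * np.log10(np.clip(model, floor, None)) - target

    else:

        def residuals(theta: np.ndarray) -> np.ndarray:
            return model_psd(freqs, _vector_to_params(theta, two_peaks)) - power

    rng = np.random.default_rng(seed)
    starts = [np.array(theta0, dtype=float)]
    for _ in range(max(n_restarts - 1, 0)):
        jittered = np.array(theta0, dtype=float)
        jittered[4] = rng.uniform(mu_lo, mu_hi)
        if two_peaks:
            jittered[6 + 1] = rng.uniform(lower[7], upper[7])
        starts.append(jittered)

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lower, upper)
        try:
            res = least_squares(
                residuals,
                x0,
                bounds=(lower, upper),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=10000,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        params = _vector_to_params(np.clip(theta0, lower, upper), two_peaks)
        fitted = model_psd(freqs, params)
        return SpectralModelFit(
            params=params,
            freqs_hz=freqs,
            fitted=fitted,
            power_law=power_law(freqs, params),
            residual_rms=float(np.sqrt(np.mean((fitted - power) ** 2))),
            converged=False,
            fit_band_hz=(float(lo), float(hi)),
            channel=channel,
        )

    params = _vector_to_params(best.x, two_peaks)
    fitted = model_psd(freqs, params)
    return SpectralModelFit(
        params=params,
        freqs_hz=freqs,
        fitted=fitted,
        power_law=power_law(freqs, params),
        residual_rms=float(np.sqrt(np.mean((fitted - power) ** 2))),
        converged=bool(best.success),
        fit_band_hz=(float(lo), float(hi)),
        channel=channel,
    )


def compute_predictor(
    fit: SpectralModelFit,
    psd: PSDEstimate,
    degenerate_tol: float = 0.01,
) -> tuple[float, Method]:
    """The aptitude index for one fitted channel.

    Primary index: max over the fit band of (fitted model - power law).
    Fallback (non-converged fit, or primary below ``degenerate_tol`` times
    the in-band PSD maximum): max of (raw PSD - power law), floored at 0.

    Returns ``(index, method)``.
    """
    band_power_full = psd.channel_power(fit.channel)
    mask = np.isin(psd.freqs_hz, fit.freqs_hz)
    if mask.sum() != fit.freqs_hz.size or not np.array_equal(
        psd.freqs_hz[mask], fit.freqs_hz
    ):
        raise GridError("fit grid is not a subset of the PSD grid")
    band_power = band_power_full[mask]

    primary = float(np.max(fit.fitted - fit.power_law))
    primary = max(primary, 0.0)
    if fit.converged and primary >= degenerate_tol * float(np.max(band_power)):
        return primary, METHOD_MODEL
    fallback = max(float(np.max(band_power - fit.power_law)), 0.0)
    return fallback, METHOD_PSD


def combine_predictors(
    entries: dict[str, tuple[float, Method]]
) -> PredictorResult:
    """Assemble per-channel (index, method) entries; combined = mean index."""
    if not entries:
        raise ParameterError("no predictor entries to combine")
    indices = {ch: v for ch, (v, _) in entries.items()}
    methods = {ch: m for ch, (_, m) in entries.items()}
    return PredictorResult(
        index_per_channel=indices,
        method_per_channel=methods,
        combined=float(np.mean(list(indices.values()))),
    )
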
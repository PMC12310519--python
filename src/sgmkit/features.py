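"""Spectral summary statistics: aperiodic 1/f fit, periodic peaks, band powers.

A global EEG power spectrum is reduced to the observation vector used for
inference: an aperiodic (1/f) component fitted as a line in log-log space, a
set of Gaussian periodic peaks riding on it (the strongest of which is the
posterior-dominant-rhythm candidate), and a coarse binned representation of
the full spectrum.  The parameterizer is a deliberately minimal, no-knee
variant of the standard oscillations-plus-one-over-f decomposition: iterative
robust line fit, Gaussian peak extraction on the residual, aperiodic refit on
the peak-subtracted spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .forward import FrequencyGrid

__all__ = [
    "AperiodicFit",
    "PeriodicPeak",
    "SummaryVector",
    "fit_spectral_model",
    "summary_vector",
    "umap_features",
    "normalize_to_distribution",
    "band_power",
    "relative_band_power",
]

#: Identifier of the summary-vector layout produced by :func:`summary_vector`.
#: "ap2" = (offset, exponent); "peak3" = (center Hz, log-power height, bandwidth
#: Hz), sentinel (0, 0, 0) when no peak clears the detection threshold;
#: "bins16" = mean log10 power in 16 equal-width bands over 0.5-50 Hz.
LAYOUT_VERSION = "ap2-peak3-bins16/v1"


@dataclass(frozen=True)
class AperiodicFit:
    """Line fit of log10 power against log10 frequency.

    ``offset`` is the intercept (log10 power at 1 Hz); ``exponent`` is the
    positive decay exponent chi of the 1/f^chi background (minus the slope).
    """

    offset: float
    exponent: float
    fit_range: tuple[float, float]


@dataclass(frozen=True)
class PeriodicPeak:
    """Gaussian peak above the aperiodic background."""

    center_freq: float  # Hz
    power: float  # height above the aperiodic fit, log10-power units
    bandwidth: float  # Hz, 2 * Gaussian sigma


@dataclass(frozen=True)
class SummaryVector:
    aperiodic: AperiodicFit
    first_peak: PeriodicPeak | None
    binned_psd: np.ndarray
    layout_version: str = LAYOUT_VERSION

    def to_array(self) -> np.ndarray:
        """Fixed-length flat vector: (offset, exponent, cf, power, bw, bins...)."""
        pk = self.first_peak
        peak3 = (0.0, 0.0, 0.0) if pk is None else (pk.center_freq, pk.power, pk.bandwidth)
        return np.concatenate(
            [[self.aperiodic.offset, self.aperiodic.exponent], peak3, self.binned_psd]
        )


def _gauss(f: np.ndarray, height: float, center: float, sigma: float) -> np.ndarray:
    return height * np.exp(-((f - center) ** 2) / (2.0 * sigma**2))


def _gauss_jac(f: np.ndarray, height: float, center: float, sigma: float) -> np.ndarray:
    d = f - center
    e = np.exp(-(d**2) / (2.0 * sigma**2))
    return np.column_stack([e, height * e * d / sigma**2, height * e * d**2 / sigma**3])


def _robust_line(logf: np.ndarray, logp: np.ndarray, n_iter: int = 2) -> np.ndarray:
    """Line fit that down-weights strong positive outliers (peaks).

    Fits OLS, then refits on the points whose residual lies below the 60th
    percentile, so narrowband bumps do not drag the aperiodic estimate up.
    """
    coef = np.polyfit(logf, logp, 1)
    for _ in range(n_iter):
        resid = logp - np.polyval(coef, logf)
        keep = resid <= np.percentile(resid, 60.0)
        if keep.sum() < 3:
            break
        coef = np.polyfit(logf[keep], logp[keep], 1)
    return coef


def fit_spectral_model(
    psd: np.ndarray,
    grid: FrequencyGrid,
    fit_range: tuple[float, float] = (1.0, 40.0),
    max_peaks: int = 4,
    peak_threshold_sd: float = 2.0,
    min_peak_height: float = 0.05,
) -> tuple[AperiodicFit, list[PeriodicPeak]]:
    """Decompose a power spectrum into aperiodic and periodic components.

    Procedure: (1) robust log-log line fit of the aperiodic background;
    (2) the largest positive residual exceeding both ``peak_threshold_sd``
    residual standard deviations and ``min_peak_height`` log10 units is fitted
    as a Gaussian (in linear frequency, log power) and subtracted; (3) repeat
    up to ``max_peaks``; (4) the aperiodic component is refitted on the
    peak-subtracted spectrum.  Peaks are returned sorted by height descending.
    """
    psd = np.asarray(psd, dtype=float)
    f = grid.freqs_hz
    lo, hi = fit_range
    mask = (f >= lo) & (f <= hi)
    if mask.sum() < 5:
        raise ValueError(f"fewer than 5 frequency bins in fit range {fit_range}")
    if np.any(psd[mask] <= 0):
        raise ValueError("power spectrum must be strictly positive over the fit range")
    ff = f[mask]
    logf = np.log10(ff)
    logp = np.log10(psd[mask])

    coef = _robust_line(logf, logp)
    resid = logp - np.polyval(coef, logf)

    peaks: list[PeriodicPeak] = []
    gauss_sum = np.zeros_like(resid)
    for _ in range(max_peaks):
        work = resid - gauss_sum
        k = int(np.argmax(work))
        height = float(work[k])
        if height < max(peak_threshold_sd * float(np.std(work)), min_peak_height):
            break
        # Initial width from the half-height extent around the maximum.
        half = height / 2.0
        right = k
        while right + 1 < work.size and work[right + 1] > half:
            right += 1
        left = k
        while left - 1 >= 0 and work[left - 1] > half:
            left -= 1
        fwhm = max(ff[right] - ff[left], ff[1] - ff[0])
        sigma0 = max(fwhm / 2.355, 0.3)
        # Unbounded Levenberg-Marquardt on a local window, sanitized after.
        win = np.abs(ff - ff[k]) <= max(5.0 * sigma0, 3.0)
        try:
            with warnings.catch_warnings(), np.errstate(over="ignore", invalid="ignore"):
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    _gauss,
                    ff[win],
                    work[win],
                    p0=(height, ff[k], sigma0),
                    jac=_gauss_jac,
                    method="lm",
                    maxfev=400,
                )
            popt = (float(popt[0]), float(popt[1]), abs(float(popt[2])))
            if not (0 < popt[0] < 3 * height + 1.0 and lo <= popt[1] <= hi and 0.1 <= popt[2] <= hi - lo):
                popt = (height, ff[k], sigma0)
        except RuntimeError:
            popt = (height, ff[k], sigma0)
        peaks.append(PeriodicPeak(center_freq=float(popt[1]), power=float(popt[0]), bandwidth=float(2 * popt[2])))
        gauss_sum = gauss_sum + _gauss(ff, *popt)

    # Final aperiodic fit on the peak-subtracted spectrum.
    coef = np.polyfit(logf, logp - gauss_sum, 1)
    ap = AperiodicFit(offset=float(coef[1]), exponent=float(-coef[0]), fit_range=(lo, hi))
    peaks.sort(key=lambda p: p.power, reverse=True)
    return ap, peaks


def first_peak_in_band(
    peaks: list[PeriodicPeak], band: tuple[float, float] = (3.0, 15.0)
) -> PeriodicPeak | None:
    """Highest-power peak with center frequency inside ``band`` (PDR search)."""
    cands = [p for p in peaks if band[0] <= p.center_freq <= band[1]]
    return cands[0] if cands else None


def binned_log_power(
    psd: np.ndarray,
    grid: FrequencyGrid,
    n_bands: int = 16,
    band_range: tuple[float, float] = (0.5, 50.0),
) -> np.ndarray:
    """Mean log10 power in contiguous equal-width bands."""
    psd = np.asarray(psd, dtype=float)
    if np.any(psd <= 0):
        raise ValueError("power spectrum must be strictly positive for log binning")
    edges = np.linspace(band_range[0], band_range[1], n_bands + 1)
    f = grid.freqs_hz
    out = np.empty(n_bands)
    logp = np.log10(psd)
    for i in range(n_bands):
        m = (f >= edges[i]) & (f <= edges[i + 1] if i == n_bands - 1 else f < edges[i + 1])
        if not m.any():
            raise ValueError(f"no frequency bins inside band [{edges[i]}, {edges[i+1]}] Hz")
        out[i] = logp[m].mean()
    return out


def summary_vector(
    psd: np.ndarray,
    grid: FrequencyGrid,
    fit_range: tuple[float, float] = (1.0, 40.0),
    n_bands: int = 16,
) -> SummaryVector:
    """The observation vector fed to inference.

    Concatenates the aperiodic fit (offset, exponent), the highest-power
    periodic peak (center frequency, height, bandwidth; sentinel zeros when no
    peak clears threshold) and the 16-band binned log-power spectrum.  The
    total length is fixed regardless of peak presence; deterministic for a
    fixed input.
    """
    ap, peaks = fit_spectral_model(psd, grid, fit_range=fit_range)
    first = peaks[0] if peaks else None
    bins = binned_log_power(psd, grid, n_bands=n_bands)
    return SummaryVector(aperiodic=ap, first_peak=first, binned_psd=bins)


def umap_features(psd: np.ndarray, grid: FrequencyGrid) -> np.ndarray:
    """26-element feature vector for manifold embedding of spectra.

    23 half-Hz bins of mean power over 0.5-12 Hz, then mean power in the high
    alpha (12-20 Hz), beta (20-40 Hz) and gamma (40 Hz to the grid maximum)
    bands, in that order.  The nominal gamma band extends to 55 Hz; it is
    truncated at the grid maximum when the grid stops short of that.
    """
    psd = np.asarray(psd, dtype=float)
    f = grid.freqs_hz
    if f[0] > 0.5 or f[-1] < 12.0:
        raise ValueError("grid must cover 0.5-12 Hz for half-Hz binned features")
    edges = np.arange(0.5, 12.01, 0.5)  # 24 edges -> 23 bins
    feats = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (f >= lo) & (f < hi)
        if not m.any():
            m = (f >= lo) & (f <= hi)
        feats.append(psd[m].mean())
    gamma_hi = min(55.0, float(f[-1]))
    for lo, hi in ((12.0, 20.0), (20.0, 40.0), (40.0, gamma_hi)):
        m = (f >= lo) & (f <= hi)
        feats.append(psd[m].mean())
    return np.array(feats)


def normalize_to_distribution(psd: np.ndarray) -> np.ndarray:
    """Normalize a non-negative spectrum to a probability vector (sum 1)."""
    psd = np.asarray(psd, dtype=float)
    if np.any(psd < 0):
        raise ValueError("spectrum must be non-negative")
    total = psd.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return psd / total


def band_power(psd: np.ndarray, grid: FrequencyGrid, band: tuple[float, float]) -> float:
    """Total linear power inside a frequency band (inclusive)."""
    m = (grid.freqs_hz >= band[0]) & (grid.freqs_hz <= band[1])
    return float(np.asarray(psd)[m].sum())


def relative_band_power(psd: np.ndarray, grid: FrequencyGrid, band: tuple[float, float]) -> float:
    """Band power as a fraction of total power on the grid."""
    psd = np.asarray(psd, dtype=float)
    return band_power(psd, grid, band) / float(psd.sum())
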
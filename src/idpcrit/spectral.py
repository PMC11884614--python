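"""Power spectra of conformational time series and 1/f exponent fitting.

The spectrum of a signal x(t) is computed as the one-sided periodogram
|DFT(x)|^2 * dt / n, which by the Wiener–Khinchin theorem equals the discrete
Fourier transform of the biased autocorrelation estimate — the classic
"Fourier transform of the autocorrelation" route.  A power-law spectrum
S(f) ∝ f^(-beta) is fitted by ordinary least squares in log10–log10
coordinates, usually after logarithmic binning; beta = 0 is white noise,
beta = 2 Brownian noise, and beta ≈ 1 the 1/f regime diagnostic of scale-free
temporal correlation.

Mean subtraction defaults to on: the DC offset of a distance series otherwise
leaks into the low-frequency bins and corrupts the exponent fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import TimeSeries

__all__ = [
    "PowerSpectrum",
    "SpectralFit",
    "autocorrelation",
    "power_spectrum",
    "average_spectra",
    "log_bin",
    "fit_exponent",
    "default_fit_window",
]


@dataclass
class PowerSpectrum:
    """One-sided spectrum: frequency grid (1/time units) and power density."""

    frequencies: np.ndarray
    power: np.ndarray
    n_averaged: int = 1

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if len(self.frequencies) != len(self.power):
            raise ValueError("frequency and power arrays must match in length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if not np.all(np.isfinite(self.power)) or np.any(self.power < 0):
            raise ValueError("power must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclass
class SpectralFit:
    """Least-squares power-law fit S(f) = 10^intercept * f^(-beta)."""

    beta: float
    intercept: float
    r_squared: float
    f_min: float
    f_max: float
    n_points: int = 0

    def __post_init__(self) -> None:
        if not self.f_min < self.f_max:
            raise ValueError("f_min must be below f_max")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


def autocorrelation(ts: TimeSeries, center: bool = True) -> TimeSeries:
    """Unbiased sample autocorrelation <x(t0+k) x(t0)> for lags 0..n-1.

    Lag-k value is (1/(n-k)) * sum_t0 x(t0+k) x(t0); x is mean-subtracted
    first when ``center`` is true.
    """
    x = np.asarray(ts.values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("autocorrelation requires length >= 2")
    if center:
        x = x - x.mean()
    # FFT-based full correlation, O(n log n)
    m = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.abs(np.fft.rfft(x, m)) ** 2
    full = np.fft.irfft(spec, m)[:n]
    return TimeSeries(values=full / (n - np.arange(n)), dt=ts.dt)


def power_spectrum(ts: TimeSeries, center: bool = True,
                   n_segments: int = 1) -> PowerSpectrum:
    """One-sided periodogram at frequencies k/(n*dt), k = 1..floor(n/2).

    ``n_segments > 1`` activates Welch-style averaging of the periodograms of
    non-overlapping segments (off by default).
    """
    x = np.asarray(ts.values, dtype=float)
    if len(x) < 4:
        raise ValueError("power_spectrum requires length >= 4")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if n_segments > 1:
        seg_len = len(x) // n_segments
        if seg_len < 4:
            raise ValueError("segments too short for n_segments")
        parts = [
            power_spectrum(TimeSeries(x[i * seg_len:(i + 1) * seg_len], ts.dt),
                           center=center)
            for i in range(n_segments)
        ]
        avg = average_spectra(parts)
        return PowerSpectrum(avg.frequencies, avg.power, n_averaged=1)
    if center:
        x = x - x.mean()
    n = len(x)
    X = np.fft.rfft(x)
    k = np.arange(1, n // 2 + 1)
    freqs = k / (n * ts.dt)
    power = (np.abs(X[k]) ** 2) * ts.dt / n
    return PowerSpectrum(frequencies=freqs, power=power, n_averaged=1)


def average_spectra(spectra: list[PowerSpectrum]) -> PowerSpectrum:
    """Bin-wise arithmetic mean of spectra sharing one frequency grid."""
    if not spectra:
        raise ValueError("need at least one spectrum")
    f0 = spectra[0].frequencies
    for s in spectra[1:]:
        if len(s.frequencies) != len(f0) or not np.allclose(
            s.frequencies, f0, rtol=1e-12, atol=0.0
        ):
            raise ValueError("all spectra must share an identical frequency grid")
    power = np.mean([s.power for s in spectra], axis=0)
    return PowerSpectrum(
        frequencies=f0.copy(),
        power=power,
        n_averaged=sum(s.n_averaged for s in spectra),
    )


def log_bin(spec: PowerSpectrum, bins_per_decade: int = 8) -> PowerSpectrum:
    """Average into logarithmic frequency bins; empty bins are dropped.

    Bin representative frequency is the geometric mean of member frequencies;
    bin power the arithmetic mean.
    """
    if bins_per_decade < 1:
        raise ValueError("bins_per_decade must be >= 1")
    f = spec.frequencies
    logf = np.log10(f)
    idx = np.floor(logf * bins_per_decade).astype(int)
    idx -= idx.min()
    n_bins = idx.max() + 1
    counts = np.bincount(idx, minlength=n_bins)
    sum_logf = np.bincount(idx, weights=logf, minlength=n_bins)
    sum_p = np.bincount(idx, weights=spec.power, minlength=n_bins)
    keep = counts > 0
    return PowerSpectrum(
        frequencies=10.0 ** (sum_logf[keep] / counts[keep]),
        power=sum_p[keep] / counts[keep],
        n_averaged=spec.n_averaged,
    )


def default_fit_window(spec: PowerSpectrum) -> tuple[float, float]:
    """Default window: skip the 3 lowest (poorly averaged) bins and the top
    half-decade (saving-interval aliasing)."""
    f = spec.frequencies
    if len(f) < 9:
        return float(f[0]), float(f[-1])
    return float(f[3]), float(f[-1] / 10 ** 0.5)


def fit_exponent(spec: PowerSpectrum, f_min: float | None = None,
                 f_max: float | None = None) -> SpectralFit:
    """OLS fit of log10 S on log10 f over [f_min, f_max]; beta = -slope."""
    if f_min is None or f_max is None:
        lo, hi = default_fit_window(spec)
        f_min = lo if f_min is None else f_min
        f_max = hi if f_max is None else f_max
    mask = (spec.frequencies >= f_min) & (spec.frequencies <= f_max)
    mask &= spec.power > 0
    if mask.sum() < 5:
        raise ValueError(
            f"need >= 5 usable bins in [{f_min:g}, {f_max:g}], found {mask.sum()}"
        )
    lf = np.log10(spec.frequencies[mask])
    lp = np.log10(spec.power[mask])
    res = stats.linregress(lf, lp)
    ss_tot = float(np.sum((lp - lp.mean()) ** 2))
    if ss_tot == 0.0:
        r_sq = 1.0  # constant log-power: a horizontal line fits exactly
    elif np.isfinite(res.rvalue):
        r_sq = min(float(res.rvalue) ** 2, 1.0)
    else:
        r_sq = 0.0
    return SpectralFit(
        beta=-float(res.slope),
        intercept=float(res.intercept),
        r_squared=r_sq,
        f_min=float(f_min),
        f_max=float(f_max),
        n_points=int(mask.sum()),
    )
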
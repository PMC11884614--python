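"""FRET efficiency <-> distance conversion and spectral analysis of traces.

Transfer efficiency and inter-dye distance are related by

    E = 1 / (1 + (R/R0)^6)

with Förster radius R0 (default 5 nm, typical of the Cy3/Alexa-647 pair).
Because the map is non-invertible at E = 0 and E = 1 and shot noise pushes
measured efficiencies past those bounds, E is clamped into (0.01, 0.99)
before inversion (configurable).  Distance series derived from traces are
analysed with the same periodogram/exponent machinery as simulated
end-to-end distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import ParseError, TimeSeries, Trajectory, residue_centers
from .spectral import (PowerSpectrum, SpectralFit, average_spectra,
                       fit_exponent, log_bin, power_spectrum)

__all__ = [
    "FretTrace",
    "FretSpectralResult",
    "read_fret_trace",
    "efficiency_from_intensities",
    "efficiency_from_distance",
    "distance_from_efficiency",
    "fret_power_spectrum",
    "mean_efficiency_from_trajectory",
]

DEFAULT_R0_NM = 5.0
DEFAULT_CLAMP = (0.01, 0.99)


@dataclass
class FretTrace:
    """Uniformly sampled transfer-efficiency trajectory."""

    time: np.ndarray          # s, strictly increasing, uniform within 1%
    efficiency: np.ndarray    # in [0, 1] after any clamping by the loader
    R0: float = DEFAULT_R0_NM

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        if len(self.time) != len(self.efficiency):
            raise ValueError("time and efficiency must have equal length")
        d = np.diff(self.time)
        if np.any(d <= 0):
            raise ValueError("time must be strictly increasing")
        if np.ptp(d) > 0.01 * d.mean():
            raise ValueError("time spacing must be uniform within 1%")
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")

    @property
    def dt(self) -> float:
        return float(np.diff(self.time).mean())

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class FretSpectralResult:
    """Spectral summary over one or more traces.

    ``averaged`` is False when trace lengths differ, in which case only the
    per-trace fits and their pooled mean +/- SD of beta are reported.
    """

    spectrum: PowerSpectrum | None
    fit: SpectralFit | None
    per_trace_fits: list
    beta_mean: float
    beta_sd: float
    averaged: bool


def read_fret_trace(path: str | Path, R0: float = DEFAULT_R0_NM,
                    gamma: float = 1.0) -> FretTrace:
    """Read a TSV trace: (time_s, efficiency) or (time_s, donor, acceptor)."""
    data = np.loadtxt(path, skiprows=1, ndmin=2)
    if data.shape[1] == 2:
        eff = data[:, 1]
    elif data.shape[1] >= 3:
        eff, _ = efficiency_from_intensities(data[:, 1], data[:, 2], gamma=gamma)
        if np.any(np.isnan(eff)):
            eff = np.where(np.isnan(eff), 0.0, eff)
    else:
        raise ParseError("FRET trace needs 2 or 3 columns")
    return FretTrace(time=data[:, 0], efficiency=eff, R0=R0)


def efficiency_from_intensities(donor: np.ndarray, acceptor: np.ndarray,
                                gamma: float = 1.0
                                ) -> tuple[np.ndarray, int]:
    """E = I_A / (I_A + gamma I_D); zero-total points become NaN (count returned)."""
    d = np.asarray(donor, dtype=float)
    a = np.asarray(acceptor, dtype=float)
    if d.shape != a.shape:
        raise ValueError("donor and acceptor series must have equal length")
    if np.any(d < 0) or np.any(a < 0):
        raise ValueError("intensities must be non-negative")
    tot = a + gamma * d
    masked = tot == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        eff = np.where(masked, np.nan, a / np.where(masked, 1.0, tot))
    return eff, int(np.count_nonzero(masked))


def efficiency_from_distance(R, R0: float = DEFAULT_R0_NM):
    """E = 1 / (1 + (R/R0)^6); strictly decreasing in R."""
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0) or R0 <= 0:
        raise ValueError("distances and R0 must be positive")
    out = 1.0 / (1.0 + (R / R0) ** 6)
    return float(out) if out.ndim == 0 else out


def distance_from_efficiency(E, R0: float = DEFAULT_R0_NM,
                             clamp: tuple = DEFAULT_CLAMP,
                             return_n_clamped: bool = False):
    """R = R0 ((1-E)/E)^(1/6) after clamping E into ``clamp``."""
    lo, hi = clamp
    if not (0 < lo < hi < 1):
        raise ValueError("clamp bounds must satisfy 0 < lo < hi < 1")
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    E = np.asarray(E, dtype=float)
    n_clamped = int(np.count_nonzero((E < lo) | (E > hi)))
    Ec = np.clip(E, lo, hi)
    R = R0 * ((1.0 - Ec) / Ec) ** (1.0 / 6.0)
    R = float(R) if R.ndim == 0 else R
    if return_n_clamped:
        return R, n_clamped
    return R


def fret_power_spectrum(traces, center: bool = True,
                        f_min: float | None = None,
                        f_max: float | None = None,
                        bins_per_decade: int | None = None,
                        clamp: tuple = DEFAULT_CLAMP) -> FretSpectralResult:
    """Convert trace(s) to distance series and fit the spectral exponent.

    Equal-length traces are bin-averaged before the headline fit; unequal
    lengths fall back to per-trace fits only (``averaged=False``).  The
    per-trace betas always feed the reported mean +/- SD.
    """
    if isinstance(traces, FretTrace):
        traces = [traces]
    if not traces:
        raise ValueError("need at least one trace")

    def one_spectrum(tr: FretTrace) -> PowerSpectrum:
        R = distance_from_efficiency(tr.efficiency, R0=tr.R0, clamp=clamp)
        spec = power_spectrum(TimeSeries(values=R, dt=tr.dt), center=center)
        if bins_per_decade:
            spec = log_bin(spec, bins_per_decade)
        return spec

    spectra = [one_spectrum(tr) for tr in traces]
    per_fits = [fit_exponent(s, f_min, f_max) for s in spectra]
    betas = np.array([f.beta for f in per_fits])
    lengths = {len(tr) for tr in traces}
    dts = {round(tr.dt, 12) for tr in traces}
    if len(lengths) == 1 and len(dts) == 1:
        avg = average_spectra(spectra)
        return FretSpectralResult(
            spectrum=avg, fit=fit_exponent(avg, f_min, f_max),
            per_trace_fits=per_fits,
            beta_mean=float(betas.mean()),
            beta_sd=float(betas.std(ddof=1)) if len(betas) > 1 else 0.0,
            averaged=True,
        )
    return FretSpectralResult(
        spectrum=None, fit=None, per_trace_fits=per_fits,
        beta_mean=float(betas.mean()),
        beta_sd=float(betas.std(ddof=1)) if len(betas) > 1 else 0.0,
        averaged=False,
    )


def mean_efficiency_from_trajectory(traj: Trajectory, i: int | None = None,
                                    j: int | None = None,
                                    R0: float = DEFAULT_R0_NM) -> float:
    """Frame-averaged E for the residue pair (i, j) (defaults: termini)."""
    n = traj.n_residues
    if i is None:
        i = 0
    if j is None:
        j = n - 1
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError(f"residue indices must be in [0, {n})")
    if i == j:
        raise ValueError("residue indices i and j must differ")
    effs = []
    for frame in traj.frames:
        centers = residue_centers(frame)
        r = float(np.linalg.norm(centers[i] - centers[j]))
        effs.append(efficiency_from_distance(r, R0))
    return float(np.mean(effs))
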
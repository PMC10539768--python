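"""Stejskal-Tanner fitting of measured decays and DOSY spectrum synthesis.

Each picked peak contributes a decay of amplitude versus gradient; fitting
``S_i = S0 exp(-b_i D)`` (with b-factors from the pulse-sequence physics,
including any gradient non-uniformity calibration) yields the diffusion
coefficient D, its standard error sigma_D, and the diffusion resolution
R_D = D/sigma_D.  The pseudo-2D DOSY spectrum then places, for every peak, a
2-D Gaussian at (chemical shift, D) whose diffusion-domain width is sigma_D:
the sharper the fit, the narrower the peak in the diffusion dimension.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .resolution import FitConvergenceError
from .st_model import PulseSequence, b_factor

__all__ = [
    "PeakDecay",
    "DiffusionPeak",
    "DosySpectrum",
    "fit_decay_to_D",
    "build_dosy_spectrum",
    "default_diffusion_grid",
]


@dataclass
class PeakDecay:
    """Measured signal amplitudes of one peak versus effective gradient."""

    peak_id: str
    gradients: np.ndarray  # effective gradient amplitudes, T m^-1
    amplitudes: np.ndarray
    seq: Optional[PulseSequence] = None
    frequency: Optional[float] = None  # chemical shift, ppm

    def __post_init__(self) -> None:
        order = np.argsort(np.asarray(self.gradients, dtype=float))
        self.gradients = np.asarray(self.gradients, dtype=float)[order]
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)[order]
        if self.gradients.size != self.amplitudes.size:
            raise ValueError(f"peak {self.peak_id}: gradient/amplitude length mismatch")
        if self.gradients.size < 3:
            raise ValueError(f"peak {self.peak_id}: need at least 3 points")
        if np.any(np.diff(self.gradients) <= 0):
            raise ValueError(f"peak {self.peak_id}: duplicate gradient values")


@dataclass(frozen=True)
class DiffusionPeak:
    """Fit result for one peak: position in both spectral dimensions."""

    peak_id: str
    s0: float
    D: float  # m^2 s^-1
    sigma_D: float  # m^2 s^-1
    r_d: float  # D/sigma_D
    frequency: Optional[float] = None  # ppm


@dataclass(frozen=True)
class DosySpectrum:
    """Pseudo-2D spectrum: intensity over (chemical shift, diffusion) grids."""

    frequencies: np.ndarray  # ppm, ascending
    diffusions: np.ndarray  # m^2 s^-1, ascending (typically log-spaced)
    intensity: np.ndarray  # shape (len(frequencies), len(diffusions))


def fit_decay_to_D(decay: PeakDecay, seq: Optional[PulseSequence] = None) -> DiffusionPeak:
    """Fit S_i = s0 exp(-b_i D) to one peak's decay.

    b-factors come from the pulse sequence (gradient non-uniformity series
    included when configured); sigma_D is the residual-scaled standard error
    at the optimum.
    """
    seq = seq or decay.seq
    if seq is None:
        raise ValueError(f"peak {decay.peak_id}: no pulse sequence given")
    b = np.atleast_1d(b_factor(seq, decay.gradients))
    S = decay.amplitudes
    # log-linear start on positive points
    pos = S > 0
    if pos.sum() >= 3:
        coef = np.polyfit(b[pos], np.log(S[pos]), 1, w=S[pos])
        p0 = (float(np.exp(coef[1])), max(float(-coef[0]), 1e-16))
    else:
        p0 = (float(np.max(S)), 1.0 / float(np.max(b)))
    model = lambda x, s0, D: s0 * np.exp(-x * D)
    try:
        popt, pcov = curve_fit(model, b, S, p0=p0, xtol=1e-12, maxfev=10000)
    except RuntimeError as exc:
        raise FitConvergenceError(
            f"Stejskal-Tanner fit failed for peak {decay.peak_id}: {exc}", p0=p0
        ) from exc
    s0, D = float(popt[0]), float(popt[1])
    if D <= 0:
        raise ValueError(f"peak {decay.peak_id}: fitted diffusion coefficient is non-positive")
    with np.errstate(invalid="ignore"):
        sigma_D = float(np.sqrt(pcov[1, 1]))
    if not math.isfinite(sigma_D):
        sigma_D = 0.0
    r_d = D / sigma_D if sigma_D > 0 else math.inf
    return DiffusionPeak(
        peak_id=decay.peak_id, s0=s0, D=D, sigma_D=sigma_D, r_d=r_d, frequency=decay.frequency
    )


def default_diffusion_grid(peaks: Sequence[DiffusionPeak], n: int = 256) -> np.ndarray:
    """Log-spaced diffusion axis covering [min D/10, max D*10]."""
    ds = np.array([p.D for p in peaks])
    return np.geomspace(ds.min() / 10.0, ds.max() * 10.0, n)


def build_dosy_spectrum(
    peaks: Sequence[DiffusionPeak],
    freq_grid: np.ndarray,
    d_grid: Optional[np.ndarray] = None,
    freq_linewidth: float = 0.02,
    normalization: str = "height",
) -> DosySpectrum:
    """Synthesize the pseudo-2D DOSY spectrum from fitted peaks.

    Each peak contributes ``s0 * g(freq; frequency, freq_linewidth) *
    g(D; D, sigma_D)`` with Gaussians in linear D.  With the default
    ``height`` normalization each Gaussian has unit apex, so the matrix
    maximum of an isolated peak equals its fitted s0; ``area`` normalizes
    the diffusion Gaussian to unit area instead.  ``freq_linewidth`` is the
    Gaussian standard deviation (ppm) of the display lineshape standing in
    for the processed 1-D spectrum.
    """
    if normalization not in ("height", "area"):
        raise ValueError("normalization must be 'height' or 'area'")
    freq_grid = np.asarray(freq_grid, dtype=float)
    d_grid = default_diffusion_grid(peaks) if d_grid is None else np.asarray(d_grid, float)
    intensity = np.zeros((freq_grid.size, d_grid.size))
    for p in peaks:
        if p.sigma_D <= 0:
            raise ValueError(f"peak {p.peak_id}: sigma_D must be positive")
        freq = p.frequency if p.frequency is not None else 0.0
        if not (freq_grid.min() <= freq <= freq_grid.max()) or not (
            d_grid.min() <= p.D <= d_grid.max()
        ):
            warnings.warn(
                f"peak {p.peak_id} at ({freq} ppm, {p.D:.3g} m^2/s) lies outside "
                "the spectrum grids and will be clipped"
            )
        gf = np.exp(-0.5 * ((freq_grid - freq) / freq_linewidth) ** 2)
        gd = np.exp(-0.5 * ((d_grid - p.D) / p.sigma_D) ** 2)
        if normalization == "area":
            gd = gd / (p.sigma_D * math.sqrt(2.0 * math.pi))
        intensity += p.s0 * np.outer(gf, gd)
    return DosySpectrum(frequencies=freq_grid, diffusions=d_grid, intensity=intensity)
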
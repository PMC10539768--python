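"""Cramér-Rao diffusion resolution and its analytical approximation.

The diffusion resolution R_D = D/sigma_D (inverse coefficient of variation of
the fitted diffusion coefficient) of a two-parameter exponential fit to a
sampled decay with Gaussian amplitude noise has the Cramér-Rao lower-bound
form

    R_D = 2 * SNR * sqrt((A C - B^2) / A)

with the weighted schedule sums

    A = sum exp(-2 eps_i),  B = sum eps_i exp(-2 eps_i),
    C = sum eps_i^2 exp(-2 eps_i)

over the Stejskal-Tanner exponents eps_i of the sampling scheme, and SNR the
peak signal-to-noise ratio S0/(2 sigma_S).  Pulling out the leading
dependence on SNR and on the number of gradient values N,

    R_D ~= SNR * sqrt(N - 1) * f(eps_max),

defines a relative resolution f that depends almost only on the deepest
sampled exponent eps_max.  f is well approximated by the three-parameter
shape

    f(eps_max) = a * eps_max * exp(-b * eps_max^c),

whose (a, b, c) are obtained by pooled nonlinear regression of exact CRLB
values across a grid of N and eps_max, per sampling mode.

Error sources other than spectral noise (pulse jitter, field-frequency
instability, temperature drift, convection) impose an effective
signal-to-noise ceiling SNR_lim:

    SNR_eff = SNR * SNR_lim / sqrt(SNR_lim^2 + SNR^2),

so the final predicted resolution is R_D ~= SNR_eff * sqrt(N-1) * f(eps_max).
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import curve_fit

from .sampling import EpsilonSchedule, SamplingMode, epsilon_schedule

__all__ = [
    "CrlbSums",
    "FShapeParams",
    "ResolutionPrediction",
    "FitConvergenceError",
    "crlb_sums",
    "crlb_resolution",
    "f_relative",
    "f_exact",
    "fit_f_params",
    "f_approx",
    "optimal_epsmax",
    "effective_snr",
    "predict_resolution",
    "shape_params",
    "DEFAULT_N_GRID",
    "DEFAULT_EPSMAX_GRID",
]

#: Numbers of gradient values used for the pooled shape-parameter regression.
DEFAULT_N_GRID = (10, 17, 37, 65, 101, 197)

#: eps_max grid for the pooled regression: 0.1-3.0 in steps of 0.05, covering
#: the range over which f rises to its maximum and turns over.  Deeper
#: sampling (eps_max >> 3) is outside the regime the approximation targets.
DEFAULT_EPSMAX_GRID = tuple(np.round(np.arange(0.1, 3.0 + 1e-9, 0.05), 10))


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, p0=None, residual=None):
        super().__init__(message)
        self.p0 = p0
        self.residual = residual


@dataclass(frozen=True)
class CrlbSums:
    """Weighted sums A, B, C over a schedule, with weights exp(-2 eps)."""

    A: float
    B: float
    C: float


@dataclass(frozen=True)
class FShapeParams:
    """Shape parameters (a, b, c) of f(eps_max) = a eps_max exp(-b eps_max^c)."""

    a: float
    b: float
    c: float
    mode: Optional[SamplingMode] = None

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("shape parameters must be positive")
        if self.mode is not None:
            object.__setattr__(self, "mode", SamplingMode(self.mode))


@dataclass(frozen=True)
class ResolutionPrediction:
    """Predicted diffusion resolution with its ingredients echoed back."""

    r_d: float
    snr_eff: float
    f: float
    snr: float
    N: int
    eps_max: float
    mode: Optional[SamplingMode]
    snr_lim: float


def _epsilons(schedule: Union[EpsilonSchedule, Sequence[float]]) -> np.ndarray:
    if isinstance(schedule, EpsilonSchedule):
        return schedule.epsilons
    return np.asarray(schedule, dtype=float)


def crlb_sums(schedule: Union[EpsilonSchedule, Sequence[float]]) -> CrlbSums:
    """The sums A, B, C entering the CRLB resolution expression."""
    eps = _epsilons(schedule)
    w = np.exp(-2.0 * eps)
    return CrlbSums(A=float(w.sum()), B=float((eps * w).sum()), C=float((eps**2 * w).sum()))


def crlb_resolution(
    schedule: Union[EpsilonSchedule, Sequence[float]], snr: float
) -> float:
    """Cramér-Rao lower-bound diffusion resolution R_D = D/sigma_D.

    ``R_D = 2 SNR sqrt((A C - B^2)/A)``; exactly linear in SNR.  A single
    measurement cannot determine two parameters, so N = 1 returns 0 with a
    warning.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    eps = _epsilons(schedule)
    if eps.size < 2:
        warnings.warn("two-parameter fit is underdetermined for N < 2; R_D = 0")
        return 0.0
    s = crlb_sums(eps)
    disc = max(s.A * s.C - s.B**2, 0.0)  # Cauchy-Schwarz; clip rounding
    return 2.0 * snr * math.sqrt(disc / s.A)


def f_relative(r_d: float, snr: float, N: int) -> float:
    """Relative resolution f = R_D / (SNR sqrt(N-1))."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    if N < 2:
        raise ValueError("need N >= 2")
    return r_d / (snr * math.sqrt(N - 1))


def f_exact(
    mode: Union[SamplingMode, str], N: int, kappa: float, eps_max: float
) -> float:
    """Exact CRLB relative resolution for a linear/quadratic schedule."""
    sched = epsilon_schedule(mode, N, kappa, eps_max)
    return f_relative(crlb_resolution(sched, 1.0), 1.0, N)


def _f_model(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * x * np.exp(-b * x**c)


def fit_f_params(
    mode: Union[SamplingMode, str],
    kappa: float = 0.05,
    n_grid: Sequence[int] = DEFAULT_N_GRID,
    epsmax_grid: Sequence[float] = DEFAULT_EPSMAX_GRID,
) -> FShapeParams:
    """Fit the shape f(eps_max) = a eps_max exp(-b eps_max^c) to exact values.

    Exact CRLB relative resolutions are pooled over ``n_grid`` x
    ``epsmax_grid`` and fitted by unweighted nonlinear least squares from the
    initial guess (0.7, 0.7, 0.8).
    """
    mode = SamplingMode(mode)
    n_grid = list(n_grid)
    epsmax_grid = np.asarray(epsmax_grid, dtype=float)
    if not n_grid or epsmax_grid.size == 0:
        raise ValueError("grids must be non-empty")
    xs = np.tile(epsmax_grid, len(n_grid))
    ys = np.concatenate(
        [[f_exact(mode, N, kappa, em) for em in epsmax_grid] for N in n_grid]
    )
    p0 = (0.7, 0.7, 0.8)
    try:
        popt, _ = curve_fit(_f_model, xs, ys, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        res = float(np.sum((_f_model(xs, *p0) - ys) ** 2))
        raise FitConvergenceError(
            f"shape-parameter fit did not converge: {exc}", p0=p0, residual=res
        ) from exc
    return FShapeParams(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]), mode=mode)


@functools.lru_cache(maxsize=None)
def shape_params(mode: str = "linear", kappa: float = 0.05) -> FShapeParams:
    """Cached default shape parameters for a sampling mode (regenerated, not
    hard-coded)."""
    return fit_f_params(mode, kappa=kappa)


def f_approx(eps_max: float, params: FShapeParams) -> float:
    """Analytical approximation a eps_max exp(-b eps_max^c)."""
    if eps_max < 0:
        raise ValueError("eps_max must be non-negative")
    return float(_f_model(np.asarray(eps_max, dtype=float), params.a, params.b, params.c))


def optimal_epsmax(params: FShapeParams) -> float:
    """eps_max maximizing f: closed form (1/(b c))^(1/c), grid cross-checked.

    Setting df/d(eps_max) = 0 for f = a x exp(-b x^c) gives
    1 - b c x^c = 0, i.e. x* = (1/(b c))^(1/c).
    """
    x_star = (1.0 / (params.b * params.c)) ** (1.0 / params.c)
    grid = np.linspace(max(x_star / 4.0, 1e-6), x_star * 4.0, 4001)
    x_grid = float(grid[np.argmax(_f_model(grid, params.a, params.b, params.c))])
    if abs(x_grid - x_star) > 2e-3 * x_star:
        warnings.warn(
            f"closed-form argmax {x_star:.4f} disagrees with grid search {x_grid:.4f}"
        )
    return x_star


def effective_snr(snr: float, snr_lim: float = math.inf) -> float:
    """Effective SNR under a non-noise error ceiling SNR_lim.

    ``SNR_eff = SNR SNR_lim / sqrt(SNR_lim^2 + SNR^2)``: equal to SNR when
    noise dominates, saturating at SNR_lim when other error sources do.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if snr_lim <= 0:
        raise ValueError("snr_lim must be positive (may be inf)")
    if math.isinf(snr_lim):
        return snr
    return snr * snr_lim / math.sqrt(snr_lim**2 + snr**2)


def predict_resolution(
    snr: float,
    eps_max: float,
    N: int,
    mode: Union[SamplingMode, str, None] = None,
    snr_lim: float = math.inf,
    params: Optional[FShapeParams] = None,
) -> ResolutionPrediction:
    """Predicted diffusion resolution R_D = SNR_eff sqrt(N-1) f(eps_max).

    Either ``params`` or ``mode`` must be given; with only ``mode`` the
    cached default shape parameters for that mode are used.  With
    ``snr_lim = inf`` this reduces to the plain noise-limited prediction.
    """
    if N < 2:
        raise ValueError("need N >= 2")
    if params is None:
        if mode is None:
            raise ValueError("give either shape params or a sampling mode")
        params = shape_params(SamplingMode(mode).value)
    elif mode is None:
        mode = params.mode
    snr_eff = effective_snr(snr, snr_lim)
    f = f_approx(eps_max, params)
    return ResolutionPrediction(
        r_d=snr_eff * math.sqrt(N - 1) * f,
        snr_eff=snr_eff,
        f=f,
        snr=snr,
        N=N,
        eps_max=eps_max,
        mode=SamplingMode(mode) if mode is not None else None,
        snr_lim=snr_lim,
    )
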
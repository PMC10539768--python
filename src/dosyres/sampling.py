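"""Gradient ramps and Stejskal-Tanner exponent schedules.

Diffusion experiments step the encoding gradient from ``Gmin = kappa * Gmax``
to ``Gmax`` in N increments, either linearly (equal steps in G) or
quadratically (equal steps in G^2).  A nonzero ``kappa`` is kept so that the
gradient pulses continue to assist coherence selection.  Because the
attenuation exponent is quadratic in G, the two ramps produce different
dimensionless exponent schedules

    linear:    eps_i = [kappa + (i-1)(1-kappa)/(N-1)]^2 * eps_max
    quadratic: eps_i = [kappa^2 + (i-1)(1-kappa^2)/(N-1)] * eps_max

both running from ``kappa^2 * eps_max`` to ``eps_max``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .st_model import PulseSequence, b_factor

__all__ = [
    "SamplingMode",
    "RampSpec",
    "EpsilonSchedule",
    "gradient_ramp",
    "epsilon_schedule",
    "schedule_from_ramp",
    "KAPPA_COMMON_PRACTICE",
]

#: Range of Gmin/Gmax ratios in common experimental practice.
KAPPA_COMMON_PRACTICE = (0.05, 0.25)


class SamplingMode(str, enum.Enum):
    LINEAR = "linear"
    QUADRATIC = "quadratic"


def _check_n_kappa(N: int, kappa: float) -> None:
    if N < 2:
        raise ValueError(f"need at least 2 gradient values, got N={N}")
    if not 0 < kappa < 1:
        raise ValueError(f"kappa must lie in (0, 1), got {kappa}")
    lo, hi = KAPPA_COMMON_PRACTICE
    if not lo <= kappa <= hi:
        warnings.warn(
            f"kappa={kappa} is outside the common-practice range [{lo}, {hi}]",
            stacklevel=3,
        )


@dataclass(frozen=True)
class RampSpec:
    """Specification of a gradient ramp.

    ``Gmax`` (maximum effective gradient, T m^-1) may be omitted when working
    purely in exponent space.
    """

    mode: SamplingMode
    N: int
    kappa: float
    Gmax: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", SamplingMode(self.mode))
        _check_n_kappa(self.N, self.kappa)
        if self.Gmax is not None and self.Gmax <= 0:
            raise ValueError("Gmax must be positive")


@dataclass(frozen=True)
class EpsilonSchedule:
    """Ordered Stejskal-Tanner exponents eps_1 < ... < eps_N = eps_max."""

    epsilons: np.ndarray
    eps_max: float
    mode: Optional[SamplingMode] = None
    kappa: Optional[float] = None

    def __post_init__(self) -> None:
        eps = np.asarray(self.epsilons, dtype=float)
        if eps.ndim != 1 or eps.size == 0:
            raise ValueError("epsilons must be a non-empty 1-D sequence")
        if eps.size > 1 and np.any(np.diff(eps) <= 0):
            raise ValueError("epsilons must be strictly increasing")
        if not np.isclose(eps[-1], self.eps_max, rtol=1e-12, atol=0):
            raise ValueError("last epsilon must equal eps_max")
        object.__setattr__(self, "epsilons", eps)
        if self.mode is not None:
            object.__setattr__(self, "mode", SamplingMode(self.mode))

    @property
    def N(self) -> int:
        return int(self.epsilons.size)


def gradient_ramp(spec: RampSpec) -> np.ndarray:
    """Gradient amplitudes from ``kappa*Gmax`` to ``Gmax`` (ascending).

    Linear mode spaces the values equally in G, quadratic mode equally in
    G^2.  ``spec.Gmax`` defaults to 1 (normalized units) when unset.
    """
    gmax = 1.0 if spec.Gmax is None else spec.Gmax
    gmin = spec.kappa * gmax
    if spec.mode is SamplingMode.LINEAR:
        return np.linspace(gmin, gmax, spec.N)
    return np.sqrt(np.linspace(gmin**2, gmax**2, spec.N))


def epsilon_schedule(
    mode: Union[SamplingMode, str], N: int, kappa: float, eps_max: float
) -> EpsilonSchedule:
    """Exponent schedule for a linear or quadratic gradient ramp."""
    mode = SamplingMode(mode)
    _check_n_kappa(N, kappa)
    if eps_max <= 0:
        raise ValueError("eps_max must be positive")
    i = np.arange(N, dtype=float)
    if mode is SamplingMode.LINEAR:
        eps = (kappa + i * (1.0 - kappa) / (N - 1)) ** 2 * eps_max
    else:
        eps = (kappa**2 + i * (1.0 - kappa**2) / (N - 1)) * eps_max
    eps[-1] = eps_max  # guard the endpoint against rounding
    return EpsilonSchedule(epsilons=eps, eps_max=eps_max, mode=mode, kappa=kappa)


def schedule_from_ramp(
    ramp: Sequence[float], seq: PulseSequence, D: float
) -> EpsilonSchedule:
    """Exponents ``eps_i = b_i * D`` for a ramp of effective gradients."""
    g = np.asarray(ramp, dtype=float)
    if np.any(g < 0):
        raise ValueError("gradients must be non-negative")
    if g.size > 1 and np.any(np.diff(g) <= 0):
        raise ValueError("gradients must be strictly increasing")
    if D <= 0:
        raise ValueError("diffusion coefficient must be positive")
    eps = np.atleast_1d(b_factor(seq, g)) * D
    kappa = float(g[0] / g[-1]) if g.size > 1 and g[-1] > 0 else None
    return EpsilonSchedule(epsilons=eps, eps_max=float(eps[-1]), kappa=kappa)
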
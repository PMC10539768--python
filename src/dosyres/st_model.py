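"""Pulse-sequence physics for pulsed field gradient diffusion NMR.

A pulsed field gradient spin (or stimulated) echo encodes molecular
displacement with a pair of gradient pulses of amplitude G and duration
``delta`` separated by a diffusion delay ``Delta``.  The signal of a species
with diffusion coefficient D decays as the Stejskal-Tanner single
exponential ``S/S0 = exp(-b D)``, where the b-factor collects the gradient
encoding strength.  For rectangular gradient pulses

    b = gamma^2 G^2 delta^2 (Delta - delta/3)

and for half-sine-shaped pulses

    b = gamma^2 G^2 delta^2 (Delta - delta/4)

with G the *effective* gradient (peak amplitude times 2/pi for half-sine
pulses).  All quantities are strictly SI internally: T m^-1, s, m^2 s^-1,
rad s^-1 T^-1.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "GAMMA_1H",
    "GAUSS_PER_CM",
    "GradientShape",
    "PulseSequence",
    "Attenuation",
    "effective_gradient",
    "b_factor",
    "attenuation",
]

#: Gyromagnetic ratio of the free proton, rad s^-1 T^-1 (CODATA 2018).
GAMMA_1H = 2.6752218744e8

#: 1 G cm^-1 expressed in T m^-1.
GAUSS_PER_CM = 0.01


class GradientShape(str, enum.Enum):
    """Temporal shape of the diffusion-encoding gradient pulses."""

    RECTANGULAR = "rectangular"
    HALF_SINE = "half_sine"


@dataclass(frozen=True)
class PulseSequence:
    """Gradient-encoding parameters defining the Stejskal-Tanner b-factor.

    Parameters
    ----------
    delta : float
        Encoding gradient pulse duration (s).
    Delta : float
        Diffusion delay (s); must exceed ``delta``.
    gamma : float, optional
        Gyromagnetic ratio (rad s^-1 T^-1).  Defaults to the 1H value; the
        b-factor expressions are nucleus-agnostic so any nucleus may be used.
    shape : GradientShape, optional
        Gradient pulse shape (default rectangular).
    nonuniformity_coeffs : sequence of float, optional
        Dimensionless power-series coefficients (c1, c2, ...) replacing the
        G^2 term by ``sum_k c_k (G^2)^k`` to compensate a spatially
        non-uniform gradient.  ``None`` means a uniform gradient (c1 = 1).
        Coefficients are probe-specific calibration data supplied by the
        user; none are shipped.
    """

    delta: float
    Delta: float
    gamma: float = GAMMA_1H
    shape: GradientShape = GradientShape.RECTANGULAR
    nonuniformity_coeffs: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if not 0 < self.delta < self.Delta:
            raise ValueError(
                f"require 0 < delta < Delta, got delta={self.delta}, Delta={self.Delta}"
            )
        object.__setattr__(self, "shape", GradientShape(self.shape))
        if self.nonuniformity_coeffs is not None:
            object.__setattr__(
                self, "nonuniformity_coeffs", tuple(float(c) for c in self.nonuniformity_coeffs)
            )

    def to_json(self) -> str:
        """Serialize to a JSON config block."""
        d = {
            "gamma": self.gamma,
            "delta": self.delta,
            "Delta": self.Delta,
            "shape": self.shape.value,
            "nonuniformity_coeffs": (
                None if self.nonuniformity_coeffs is None else list(self.nonuniformity_coeffs)
            ),
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "PulseSequence":
        """Deserialize from a JSON config block; unknown keys are rejected."""
        d = json.loads(text)
        allowed = {"gamma", "delta", "Delta", "shape", "nonuniformity_coeffs"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown PulseSequence keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class Attenuation:
    """Diffusional attenuation S/S0 with its Stejskal-Tanner exponent."""

    fraction: float  # S_i/S_0, in (0, 1] for non-negative exponent
    epsilon: float  # dimensionless exponent b*D


def effective_gradient(
    shape: Union[GradientShape, str], peak_G: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Effective gradient amplitude for a given pulse shape.

    Rectangular pulses deliver their peak amplitude; half-sine pulses deliver
    a time-averaged encoding equivalent to ``peak_G * 2/pi``.
    """
    peak = np.asarray(peak_G, dtype=float)
    if np.any(peak < 0):
        raise ValueError("peak gradient must be non-negative")
    shape = GradientShape(shape)
    if shape is GradientShape.HALF_SINE:
        peak = peak * (2.0 / math.pi)
    return peak if peak.ndim else float(peak)


def b_factor(
    seq: PulseSequence, G: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Stejskal-Tanner b-factor (s m^-2) for effective gradient ``G`` (T m^-1).

    ``G`` must already be the effective gradient (see
    :func:`effective_gradient`); the pulse shape only selects the timing
    correction ``Delta - delta/3`` (rectangular) or ``Delta - delta/4``
    (half-sine).  When ``seq.nonuniformity_coeffs`` is set, the G^2 term is
    replaced by the calibration power series in G^2.
    """
    g = np.asarray(G, dtype=float)
    if np.any(g < 0):
        raise ValueError("gradient must be non-negative")
    if seq.shape is GradientShape.HALF_SINE:
        timing = seq.Delta - seq.delta / 4.0
    else:
        timing = seq.Delta - seq.delta / 3.0
    g2 = g * g
    if seq.nonuniformity_coeffs is None:
        g2_term = g2
    else:
        g2_term = np.zeros_like(g2)
        for k, c in enumerate(seq.nonuniformity_coeffs, start=1):
            g2_term = g2_term + c * g2**k
    b = seq.gamma**2 * seq.delta**2 * timing * g2_term
    return b if np.ndim(b) else float(b)


def attenuation(b: float, D: float) -> Attenuation:
    """Ideal diffusional attenuation exp(-b D) for non-negative b and D."""
    if b < 0 or D < 0:
        raise ValueError("b-factor and diffusion coefficient must be non-negative")
    eps = b * D
    return Attenuation(fraction=math.exp(-eps), epsilon=eps)
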
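"""Model parameters and channel geometry.

The model describes steady peristaltic transport in the frame moving with the
wall wave.  The channel half-width oscillates sinusoidally, ``h(x) = 1 +
eps*sin(2*pi*x)``, with all lengths scaled on the mean half-width and the
axial coordinate on the wavelength.  A Jeffrey fluid (relaxation-to-
retardation ratio ``lambda1``) fills the channel, which is inclined at angle
``alpha`` to the horizontal and threaded by a uniform magnetic field inclined
at angle ``beta`` to the cross-stream axis.  Viscous heating (Brinkman number
``Br``) and a volumetric heat source/sink (``eta``) drive the temperature
field, which feeds back on the momentum balance through the buoyancy group
``c2``; ``c1`` is the gravity group.

Everything downstream of this module works with the dimensionless set
:class:`DimensionlessParams`; :func:`dimensionless_groups` builds it from
laboratory quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, fields as _dc_fields

import numpy as np

__all__ = [
    "DimensionlessParams",
    "DimensionalInputs",
    "dimensionless_groups",
    "wall_height",
    "InvalidParameterError",
    "ResonanceError",
    "DegenerateConfigurationError",
    "NumericalError",
]


class InvalidParameterError(ValueError):
    """A parameter violates its admissible range."""


class ResonanceError(InvalidParameterError):
    """The temperature closed form is singular: Br*h*sqrt(eta) has reached a
    multiple of pi, where csc(Br*h*sqrt(eta)) blows up."""


class DegenerateConfigurationError(ValueError):
    """The effective magnetic group a1 vanishes and the standard closed form
    (which contains cI/a1) does not apply; an explicit a1->0 limit path must
    be requested."""


class NumericalError(RuntimeError):
    """A numerical procedure (quadrature, fixed-point iteration) failed to
    converge within its budget."""


@dataclass(frozen=True)
class DimensionlessParams:
    """Complete dimensionless parameter set for one model configuration.

    Parameters
    ----------
    eps : float
        Amplitude ratio (wave amplitude / mean half-width), ``0 <= eps < 1``.
        ``eps = 1`` would pinch the channel shut at the wave trough.
    M : float
        Hartmann number ``B0 * a * sqrt(sigma/mu)``, >= 0.
    beta : float
        Inclination of the applied magnetic field, radians, ``|beta| < pi/2``.
        Enters only through ``cos(beta)**2``, so the model is even in beta.
    alpha : float
        Channel inclination angle, radians, ``0 <= alpha <= pi/2``.
    lambda1 : float
        Jeffrey ratio of relaxation to retardation times, >= 0 (0 recovers a
        Newtonian fluid).
    Br : float
        Brinkman number ``c**2 * mu / (K * T0)``, > 0.
    eta : float
        Heat source/sink parameter ``Q0 * a**2 / K``, >= 0.  The eta -> 0
        limit is handled by a dedicated small-argument path in the field
        evaluators.
    c1 : float
        Gravity group ``a**2 * rho * g / (c * mu)``, >= 0.
    c2 : float
        Buoyancy group ``a**2 * rho * g * beta1 * T0 / mu``, >= 0.
    """

    eps: float = 0.5
    M: float = 2.0
    beta: float = math.pi / 6
    alpha: float = math.pi / 4
    lambda1: float = 0.5
    Br: float = 2.0
    eta: float = 0.5
    c1: float = 1.0
    c2: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.eps < 1.0:
            raise InvalidParameterError(
                f"eps={self.eps}: amplitude ratio must satisfy 0 <= eps < 1 "
                "(the wall must never pinch shut; min h = 1 - eps > 0)"
            )
        if self.M < 0.0:
            raise InvalidParameterError(f"M={self.M}: Hartmann number must be >= 0")
        if self.lambda1 < 0.0:
            raise InvalidParameterError(
                f"lambda1={self.lambda1}: the Jeffrey ratio must be >= 0"
            )
        if self.Br <= 0.0:
            raise InvalidParameterError(
                f"Br={self.Br}: Brinkman number must be > 0"
            )
        if self.eta < 0.0:
            raise InvalidParameterError(
                f"eta={self.eta}: heat source/sink parameter must be >= 0 "
                "(the eta -> 0 limit is taken continuously)"
            )
        if not abs(self.beta) < math.pi / 2:
            raise InvalidParameterError(
                f"beta={self.beta}: field inclination must satisfy |beta| < pi/2 rad"
            )
        if not 0.0 <= self.alpha <= math.pi / 2:
            raise InvalidParameterError(
                f"alpha={self.alpha}: channel inclination must lie in [0, pi/2] rad"
            )
        if self.c1 < 0.0 or self.c2 < 0.0:
            raise InvalidParameterError(
                f"c1={self.c1}, c2={self.c2}: gravity and buoyancy groups must be >= 0"
            )
        # Temperature closed form ~ csc(Br*h*sqrt(eta)); it is singular when the
        # argument reaches pi anywhere along the channel (max h = 1 + eps).
        arg = self.Br * (1.0 + self.eps) * math.sqrt(self.eta)
        if arg >= math.pi:
            raise ResonanceError(
                f"resonance condition violated: Br*(1+eps)*sqrt(eta) = {arg:.6g} "
                ">= pi; the temperature closed form csc(Br*h*sqrt(eta)) is "
                "singular for this configuration"
            )

    # Derived groups -----------------------------------------------------

    @property
    def a1(self) -> float:
        """Effective magnetic group M^2 (1+lambda1) cos^2(beta)."""
        return self.M**2 * (1.0 + self.lambda1) * math.cos(self.beta) ** 2

    @property
    def a2(self) -> float:
        """Effective buoyancy group c2 (1+lambda1)."""
        return self.c2 * (1.0 + self.lambda1)

    @property
    def k_heat(self) -> float:
        """Temperature wavenumber Br*sqrt(eta) (the temperature profile is
        sin(k_heat*y)/sin(k_heat*h))."""
        return self.Br * math.sqrt(self.eta)

    def replace(self, **changes) -> "DimensionlessParams":
        """Return a validated copy with the given fields replaced."""
        return replace(self, **changes)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in _dc_fields(cls))


@dataclass(frozen=True)
class DimensionalInputs:
    """Laboratory-frame quantities from which the dimensionless groups are
    formed.  All strictly positive except ``Q0`` (heat source strength; a sink
    is negative) and ``beta1`` (thermal expansion coefficient, any sign)."""

    rho: float          # fluid density
    g: float            # gravitational acceleration
    a: float            # mean channel half-width
    b: float            # wave amplitude
    wave_speed: float   # peristaltic wave speed (the wave speed in laboratory units)
    mu: float           # dynamic viscosity
    sigma: float        # electrical conductivity
    B0: float           # applied magnetic-field magnitude
    K: float            # thermal conductivity
    T0: float           # reference temperature
    Q0: float = 0.0     # heat source strength (sign per source/sink)
    beta1: float = 0.0  # thermal expansion coefficient

    def __post_init__(self) -> None:
        positive = {
            "rho": self.rho, "g": self.g, "a": self.a, "b": self.b,
            "wave_speed": self.wave_speed, "mu": self.mu, "sigma": self.sigma,
            "B0": self.B0, "K": self.K, "T0": self.T0,
        }
        bad = [k for k, v in positive.items() if not v > 0.0]
        if bad:
            raise InvalidParameterError(
                f"dimensional inputs must be strictly positive: {', '.join(bad)}"
            )


def dimensionless_groups(
    dim: DimensionalInputs,
    alpha: float = 0.0,
    beta: float = 0.0,
    lambda1: float = 0.0,
) -> DimensionlessParams:
    """Form the dimensionless parameter set from laboratory quantities.

    The angles and the Jeffrey ratio are already dimensionless and are passed
    through.  Raises :class:`InvalidParameterError` if the resulting set is
    inadmissible (e.g. ``b >= a``, or ``Q0 < 0`` which would make ``eta``
    negative -- the implemented temperature solution covers sources, not
    sinks).
    """
    return DimensionlessParams(
        eps=dim.b / dim.a,
        M=dim.B0 * dim.a * math.sqrt(dim.sigma / dim.mu),
        beta=beta,
        alpha=alpha,
        lambda1=lambda1,
        Br=dim.wave_speed**2 * dim.mu / (dim.K * dim.T0),
        eta=dim.Q0 * dim.a**2 / dim.K,
        c1=dim.a**2 * dim.rho * dim.g / (dim.wave_speed * dim.mu),
        c2=dim.a**2 * dim.rho * dim.g * dim.beta1 * dim.T0 / dim.mu,
    )


def wall_height(x, params: DimensionlessParams):
    """Dimensionless channel half-width h(x) = 1 + eps*sin(2*pi*x).

    Accepts scalar or array ``x``; 1-periodic, bounded by 1 -+ eps.
    """
    x = np.asarray(x, dtype=float)
    h = 1.0 + params.eps * np.sin(2.0 * np.pi * x)
    return float(h) if h.ndim == 0 else h
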
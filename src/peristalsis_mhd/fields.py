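"""Closed-form field solutions at a fixed axial station.

Under the long-wavelength, low-Reynolds (lubrication) reduction the coupled
momentum/energy system at a station x collapses to two ODEs in the
cross-stream coordinate y on [0, h(x)]:

    theta'' + eta * Br^2 * theta = 0,            theta(0) = 0, theta(h) = 1
    u'' - a1 * u = a1 - cI - a2 * theta,         u(0) = 0,     u(h) = -1

with a1 = M^2 (1+lambda1) cos^2(beta), a2 = c2 (1+lambda1) and the momentum
forcing constant cI = (1+lambda1)(c1 sin(alpha) - dp/dx).  The temperature is

    theta = sin(k y) / sin(k h),   k = Br sqrt(eta),

and the velocity is the sum of a constant particular part, a buoyancy
particular part proportional to theta, and two exponential homogeneous modes
whose coefficients are fixed by the boundary values.  The homogeneous pair is
evaluated in a wall-anchored sinh form, sinh(m y)/sinh(m h) and
sinh(m (h-y))/sinh(m h) with m = sqrt(a1), so that nothing overflows at large
Hartmann number (all internal exponents are <= 0).

Two degenerate limits get dedicated paths:

* small k (k*h below 1e-5, covering eta -> 0): theta -> y/h, and the buoyancy
  particular solution takes its polynomial limit;
* small a1 (below 1e-8, e.g. M = 0): the closed form contains cI/a1, so the
  a1 -> 0 solution u'' = -cI - a2*theta is used instead.  This path must be
  requested explicitly (``a1_limit=True``); otherwise a
  :class:`~peristalsis_mhd.params.DegenerateConfigurationError` is raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import (
    DegenerateConfigurationError,
    DimensionlessParams,
    ResonanceError,
    wall_height,
)

__all__ = [
    "StationSolution",
    "SolutionConstants",
    "temperature",
    "velocity",
    "shear_stress",
    "solution_constants",
    "A1_MIN",
    "KH_MIN",
]

A1_MIN = 1e-8   # below this the cI/a1 closed form is abandoned
KH_MIN = 1e-5   # below this sin(k y)/sin(k h) is replaced by y/h


def _sinh_ratio(t, b):
    # sinh(t)/sinh(b) for 0 <= t, b > 0; exponents never positive.
    return np.exp(t - b) * np.expm1(-2.0 * t) / np.expm1(-2.0 * b)


def _cosh_over_sinh(t, b):
    # cosh(t)/sinh(b) for 0 <= t, b > 0.
    return np.exp(t - b) * (1.0 + np.exp(-2.0 * t)) / (-np.expm1(-2.0 * b))


def _maybe_scalar(out, y):
    out = np.asarray(out)
    return float(out) if np.ndim(y) == 0 else out


class StationSolution:
    """Exact solution of the reduced system at one axial station.

    Parameters
    ----------
    x : float
        Axial coordinate (the wall height h(x) is evaluated here).
    dpdx : float
        Imposed axial pressure gradient at this station.
    params : DimensionlessParams
    a1_limit : bool
        Permit the a1 -> 0 limit solution when a1 < 1e-8 instead of raising.
    """

    def __init__(self, x: float, dpdx: float, params: DimensionlessParams,
                 a1_limit: bool = False):
        self.params = params
        self.x = float(x)
        self.dpdx = float(dpdx)
        self.h = float(wall_height(self.x, params))
        lam = 1.0 + params.lambda1
        self.a1 = params.a1
        self.a2 = params.a2
        self.cI = lam * (params.c1 * math.sin(params.alpha) - self.dpdx)
        self.k = params.k_heat
        self.kh = self.k * self.h
        self.small_k = self.kh < KH_MIN
        if not self.small_k:
            s = math.sin(self.kh)
            if abs(s) < 1e-12:
                raise ResonanceError(
                    f"sin(Br*h*sqrt(eta)) = {s:.3g} at x={self.x}: temperature "
                    "closed form is singular (resonance)"
                )
            self._sin_kh = s
        self.D = self.a1 + self.k**2
        self.small_a1 = self.a1 < A1_MIN
        if self.small_a1:
            if not a1_limit:
                raise DegenerateConfigurationError(
                    f"a1 = M^2(1+lambda1)cos^2(beta) = {self.a1:.3g} < {A1_MIN}; "
                    "the closed form contains cI/a1. Pass a1_limit=True to use "
                    "the a1 -> 0 limit solution."
                )
            # u'' = -cI - a2*theta; integration constant from u(h) = -1.
            if self.small_k:
                self._A0 = (-1.0 + self.cI * self.h**2 / 2.0
                            + self.a2 * self.h**2 / 6.0) / self.h
            else:
                self._A0 = (-1.0 + self.cI * self.h**2 / 2.0
                            - self.a2 / self.k**2) / self.h
        else:
            self._m = math.sqrt(self.a1)
            self._mh = self._m * self.h
            bu = self.a2 / self.D
            self._bu = bu
            q = self.cI / self.a1
            self._up0 = -1.0 + q          # constant particular part
            self._B = 1.0 - q             # coefficient of sinh(m(h-y))/sinh(mh)
            self._A = -q - bu             # coefficient of sinh(m y)/sinh(m h)

    # Temperature ---------------------------------------------------------

    def theta(self, y):
        y = np.asarray(y, dtype=float)
        if self.small_k:
            out = y / self.h
        else:
            out = np.sin(self.k * y) / self._sin_kh
        return _maybe_scalar(out, y)

    def dtheta_dy(self, y):
        y = np.asarray(y, dtype=float)
        if self.small_k:
            out = np.full_like(y, 1.0 / self.h)
        else:
            out = self.k * np.cos(self.k * y) / self._sin_kh
        return _maybe_scalar(out, y)

    def theta_antiderivative(self, y):
        """J(y) = integral of theta from 0 to y."""
        return _maybe_scalar(self._J(np.asarray(y, dtype=float)), y)

    # Velocity ------------------------------------------------------------

    def u(self, y):
        y = np.asarray(y, dtype=float)
        if self.small_a1:
            out = -self.cI * y**2 / 2.0 + self._A0 * y + self._buoy_limit(y)
        else:
            S = _sinh_ratio(self._m * y, self._mh)
            Sb = _sinh_ratio(self._m * (self.h - y), self._mh)
            out = (self._up0 + self._bu * np.sin(self.k * y) / self._sin_kh
                   if not self.small_k else self._up0 + self._bu * y / self.h)
            out = out + self._A * S + self._B * Sb
        return _maybe_scalar(out, y)

    def _buoy_limit(self, y):
        # Buoyancy particular term of the a1 -> 0 solution.
        if self.small_k:
            return -self.a2 * y**3 / (6.0 * self.h)
        return (self.a2 / self.k**2) * np.sin(self.k * y) / self._sin_kh

    def du_dy(self, y):
        y = np.asarray(y, dtype=float)
        if self.small_a1:
            if self.small_k:
                buoy = -self.a2 * y**2 / (2.0 * self.h)
            else:
                buoy = (self.a2 / self.k**2) * self.k * np.cos(self.k * y) / self._sin_kh
            out = -self.cI * y + self._A0 + buoy
        else:
            C = _cosh_over_sinh(self._m * y, self._mh)
            Cb = _cosh_over_sinh(self._m * (self.h - y), self._mh)
            out = (self._bu * np.asarray(self.dtheta_dy(y))
                   + self._m * (self._A * C - self._B * Cb))
        return _maybe_scalar(out, y)

    def shear(self, y):
        """Jeffrey shear stress S_xy = u'(y) / (1 + lambda1)."""
        return self.du_dy(y) / (1.0 + self.params.lambda1)

    # Stream function and flux --------------------------------------------

    def psi(self, y):
        """Psi(y) = integral of u from 0 to y (Psi(0) = 0 convention)."""
        y = np.asarray(y, dtype=float)
        if self.small_a1:
            if self.small_k:
                buoy = -self.a2 * y**4 / (24.0 * self.h)
            else:
                buoy = (self.a2 / self.k**2) * self._J(y)
            out = -self.cI * y**3 / 6.0 + self._A0 * y**2 / 2.0 + buoy
        else:
            m, mh = self._m, self._mh
            # (cosh(m y) - 1)/(m sinh(m h)) and
            # (cosh(m h) - cosh(m (h-y)))/(m sinh(m h)), both zero at y = 0.
            c0 = _cosh_over_sinh(0.0, mh)
            termA = (_cosh_over_sinh(m * y, mh) - c0) / m
            termB = (_cosh_over_sinh(mh, mh) - _cosh_over_sinh(m * (self.h - y), mh)) / m
            out = (self._up0 * y + self._bu * self._J(y)
                   + self._A * termA + self._B * termB)
        return _maybe_scalar(out, y)

    def _J(self, y):
        if self.small_k:
            return np.asarray(y, dtype=float) ** 2 / (2.0 * self.h)
        return (1.0 - np.cos(self.k * y)) / (self.k * self._sin_kh)

    def flux(self) -> float:
        """Wave-frame volumetric flow rate F = integral of u over [0, h]."""
        return float(self.psi(self.h))


# Functional wrappers ------------------------------------------------------

def temperature(x, y, params: DimensionlessParams):
    """Dimensionless temperature theta(x, y) = sin(k y)/sin(k h(x)).

    Independent of the pressure gradient.  For Br^2*eta*h^2 below the
    small-argument threshold the conduction limit theta = y/h is returned.
    Broadcasts over array ``x`` and ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    h = 1.0 + params.eps * np.sin(2.0 * np.pi * x)
    k = params.k_heat
    kh = k * h
    small = kh < KH_MIN
    if np.all(small):
        out = y / h
    else:
        s = np.sin(kh)
        if np.any(np.abs(np.where(small, 1.0, s)) < 1e-12):
            raise ResonanceError(
                "sin(Br*h*sqrt(eta)) vanished: singular temperature configuration"
            )
        out = np.where(small, y / h, np.sin(k * y) / np.where(small, 1.0, s))
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def velocity(x, y, dpdx, params: DimensionlessParams, a1_limit: bool = False):
    """Wave-frame axial velocity u(x, y) at imposed pressure gradient."""
    return StationSolution(x, dpdx, params, a1_limit=a1_limit).u(y)


def shear_stress(x, y, dpdx, params: DimensionlessParams, a1_limit: bool = False):
    """Jeffrey shear stress S_xy(x, y) = (du/dy)/(1+lambda1), from the
    analytic derivative of the closed-form velocity."""
    return StationSolution(x, dpdx, params, a1_limit=a1_limit).shear(y)


@dataclass(frozen=True)
class SolutionConstants:
    """Per-station constants of the closed-form velocity written in the
    exponential basis u = -1 + cI/a1 + c3*exp(m y) + c4*exp(-m y) + buoyancy."""

    a1: float
    a2: float
    cI: float
    c3: float
    c4: float
    h: float
    dpdx: float


def solution_constants(x, dpdx, params: DimensionlessParams) -> SolutionConstants:
    """Exponential-basis constants, obtained by solving the 2x2 boundary
    system directly (not by transcribing a printed formula).

    For moderate m*h the 2x2 linear system is solved literally; for large m*h
    the algebraically identical overflow-safe expressions are used.  Raises
    :class:`DegenerateConfigurationError` when a1 < 1e-8.
    """
    st = StationSolution(x, dpdx, params, a1_limit=False)
    m, mh = st._m, st._mh
    # Boundary conditions on the homogeneous part:
    #   c3 + c4                      = -u_p(0) = B
    #   c3 exp(mh) + c4 exp(-mh)     = -1 - u_p(h) = A
    B = st._B
    A = st._A
    if mh < 30.0:
        mat = np.array([[1.0, 1.0], [math.exp(mh), math.exp(-mh)]])
        c3, c4 = np.linalg.solve(mat, np.array([B, A]))
    else:
        den = -math.expm1(-2.0 * mh)          # 1 - exp(-2 mh)
        c3 = (A - B * math.exp(-mh)) * math.exp(-mh) / den
        c4 = (B - A * math.exp(-mh)) / den
    return SolutionConstants(a1=st.a1, a2=st.a2, cI=st.cI, c3=float(c3),
                             c4=float(c4), h=st.h, dpdx=st.dpdx)
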
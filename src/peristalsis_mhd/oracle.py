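"""Independent finite-difference verifier for the closed-form fields.

At a fixed station x the reduced system is a pair of one-way-coupled linear
two-point boundary-value problems (temperature does not see the velocity, the
velocity sees the temperature as a source).  Both are discretised with
second-order central differences on a uniform grid over [0, h(x)] and solved
directly as tridiagonal systems -- no piece of the closed-form algebra is
reused, so agreement is a genuine cross-check.

The discrete equations are assembled in the dy^2-scaled form

    theta_{i-1} - (2 - dy^2 k^2) theta_i + theta_{i+1} = 0
    u_{i-1} - (2 + dy^2 a1) u_i + u_{i+1} = dy^2 (a1 - cI - a2 theta_i)

so that matrix rows are O(1) and the reported residual_norm is a clean
backward-error measure.  Near the temperature resonance the theta matrix
becomes ill-conditioned; a 1-norm condition estimate (sparse LU +
Hager/Higham estimator) guards against silently returning garbage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded
from scipy.sparse import diags
from scipy.sparse.linalg import LinearOperator, onenormest, splu

from .fields import StationSolution
from .params import DimensionlessParams, ResonanceError, wall_height

__all__ = ["OracleSolution", "VerificationReport", "fd_solve", "verify_closed_form"]

COND_LIMIT = 1e12


@dataclass(frozen=True)
class OracleSolution:
    """Finite-difference solution at one station."""

    y_nodes: np.ndarray
    u_fd: np.ndarray
    theta_fd: np.ndarray
    n: int
    residual_norm: float  # max |scaled stencil residual| over both systems
    x: float
    dpdx: float


def _tridiag_solve(lower, diag, upper, rhs):
    n = len(diag)
    ab = np.zeros((3, n))
    ab[0, 1:] = upper
    ab[1, :] = diag
    ab[2, :-1] = lower
    return solve_banded((1, 1), ab, rhs, check_finite=False)


def _condition_estimate(lower, diag, upper) -> float:
    n = len(diag)
    A = diags([lower, diag, upper], offsets=[-1, 0, 1], format="csc")
    lu = splu(A)
    inv_op = LinearOperator(
        (n, n),
        matvec=lambda v: lu.solve(v),
        rmatvec=lambda v: lu.solve(v, trans="T"),
    )
    norm_a = max(abs(diag).max() + abs(lower).max() + abs(upper).max(), 1.0)
    return float(onenormest(inv_op)) * norm_a


def fd_solve(x, dpdx, params: DimensionlessParams, n: int = 4001,
             check_conditioning: bool = True) -> OracleSolution:
    """Solve the reduced boundary-value system by central differences.

    theta is solved first (it is decoupled), then the velocity with the
    discrete theta as source.  ``n`` is the total node count including the
    two boundary nodes (n >= 11).
    """
    if n < 11:
        raise ValueError(f"n={n}: need at least 11 nodes")
    h = float(wall_height(x, params))
    y = np.linspace(0.0, h, n)
    dy = h / (n - 1)
    lam = 1.0 + params.lambda1
    a1 = params.a1
    a2 = params.a2
    cI = lam * (params.c1 * math.sin(params.alpha) - float(dpdx))
    k2 = params.Br**2 * params.eta

    m = n - 2  # interior unknowns
    ones = np.ones(m - 1)

    # Temperature: theta'' + k^2 theta = 0, theta(0)=0, theta(h)=1.
    diag_t = np.full(m, -2.0 + dy * dy * k2)
    if check_conditioning:
        cond = _condition_estimate(ones, diag_t, ones)
        if cond > COND_LIMIT:
            raise ResonanceError(
                f"discrete temperature system is near-singular "
                f"(1-norm condition estimate {cond:.3g} > {COND_LIMIT:.0e}); "
                "the configuration is too close to the resonance"
            )
    rhs_t = np.zeros(m)
    rhs_t[-1] -= 1.0  # theta(h) = 1 boundary column
    theta_int = _tridiag_solve(ones, diag_t, ones, rhs_t)
    theta = np.concatenate(([0.0], theta_int, [1.0]))

    # Velocity: u'' - a1 u = a1 - cI - a2 theta, u(0)=0, u(h)=-1.
    diag_u = np.full(m, -2.0 - dy * dy * a1)
    rhs_u = dy * dy * (a1 - cI - a2 * theta[1:-1])
    rhs_u[-1] -= -1.0  # u(h) = -1 boundary column
    u_int = _tridiag_solve(ones, diag_u, ones, rhs_u)
    u = np.concatenate(([0.0], u_int, [-1.0]))

    # Residuals of the scaled stencil equations, from the full nodal arrays.
    res_t = (theta[:-2] - (2.0 - dy * dy * k2) * theta[1:-1] + theta[2:])
    res_u = (u[:-2] - (2.0 + dy * dy * a1) * u[1:-1] + u[2:]
             - dy * dy * (a1 - cI - a2 * theta[1:-1]))
    residual = max(np.abs(res_t).max(), np.abs(res_u).max())

    return OracleSolution(y_nodes=y, u_fd=u, theta_fd=theta, n=n,
                          residual_norm=float(residual), x=float(x),
                          dpdx=float(dpdx))


@dataclass(frozen=True)
class VerificationReport:
    """Max-abs discrepancies of the closed forms against the FD oracle."""

    x: float
    dpdx: float
    n: int
    tol: float
    max_err: dict = field(default_factory=dict)
    passed: bool = True

    def as_text(self) -> str:
        lines = [
            f"x: {self.x!r}",
            f"dpdx: {self.dpdx!r}",
            f"n: {self.n}",
            f"tol: {self.tol!r}",
        ]
        for key, val in self.max_err.items():
            lines.append(f"max_abs_err_{key}: {val:.6e}")
        lines.append(f"passed: {str(self.passed).lower()}")
        return "\n".join(lines)


def verify_closed_form(params: DimensionlessParams, dpdx: float = 1.0,
                       x: float = 0.0, tol: float = 1e-6, n: int = 4001,
                       a1_limit: bool = False,
                       velocity_fn=None) -> VerificationReport:
    """Compare closed-form u, theta, S_xy and flux against the FD oracle.

    ``velocity_fn(y) -> u`` may override the closed-form velocity (used by
    fault-injection audits); by default the package's own closed form is
    checked.  Failures are report entries, never exceptions.
    """
    sol = fd_solve(x, dpdx, params, n=n)
    st = StationSolution(x, dpdx, params, a1_limit=a1_limit)
    y = sol.y_nodes
    lam = 1.0 + params.lambda1

    u_closed = np.asarray(velocity_fn(y) if velocity_fn is not None else st.u(y))
    theta_closed = np.asarray(st.theta(y))

    err_u = float(np.abs(u_closed - sol.u_fd).max())
    err_theta = float(np.abs(theta_closed - sol.theta_fd).max())

    # Shear: 4th-order central differences of the FD velocity, interior only.
    dy = y[1] - y[0]
    i = slice(2, -2)
    du_fd = (-sol.u_fd[4:] + 8.0 * sol.u_fd[3:-1]
             - 8.0 * sol.u_fd[1:-3] + sol.u_fd[:-4]) / (12.0 * dy)
    if velocity_fn is not None:
        shear_closed = np.gradient(u_closed, y)[i] / lam
    else:
        shear_closed = np.asarray(st.shear(y[i]))
    err_shear = float(np.abs(shear_closed - du_fd / lam).max())

    flux_fd = float(np.trapezoid(sol.u_fd, y))
    flux_closed = float(np.trapezoid(u_closed, y)) if velocity_fn is not None \
        else st.flux()
    err_flux = abs(flux_closed - flux_fd)

    max_err = {"u": err_u, "theta": err_theta, "S_xy": err_shear, "flux": err_flux}
    passed = all(v < tol for v in max_err.values())
    return VerificationReport(x=float(x), dpdx=float(dpdx), n=n, tol=tol,
                              max_err=max_err, passed=passed)
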
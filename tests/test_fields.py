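import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_

from peristalsis_mhd import (
    DegenerateConfigurationError,
    DimensionlessParams,
    StationSolution,
    shear_stress,
    solution_constants,
    temperature,
    velocity,
    wall_height,
)
from conftest import DEFAULTS, draw_params


def second_derivative(f, y, d):
    # 5-point central stencil, O(d^4)
    return (-f(y + 2 * d) + 16 * f(y + d) - 30 * f(y)
            + 16 * f(y - d) - f(y - 2 * d)) / (12 * d * d)


def test_temperature_boundary_values():
    for x in (0.0, 0.17, 0.25, 0.75):
        h = wall_height(x, DEFAULTS)
        assert temperature(x, 0.0, DEFAULTS) == pytest.approx(0.0, abs=1e-14)
        assert temperature(x, h, DEFAULTS) == pytest.approx(1.0, abs=1e-14)


def test_temperature_small_eta_limit():
    p = DimensionlessParams(Br=1.0, eta=1e-12)
    h = wall_height(0.3, p)
    assert temperature(0.3, h / 2, p) == pytest.approx(0.5, abs=1e-6)
    # conduction limit is linear in y
    y = np.linspace(0, h, 11)
    assert np.allclose(temperature(0.3, y, p), y / h, atol=1e-6)


def test_temperature_satisfies_energy_ode():
    p = DEFAULTS
    h = wall_height(0.1, p)
    k2 = p.Br**2 * p.eta
    y = np.linspace(0.1 * h, 0.9 * h, 7)
    res = second_derivative(lambda t: temperature(0.1, t, p), y, 1e-3) \
        + k2 * temperature(0.1, y, p)
    assert np.abs(res).max() < 1e-7


def test_velocity_boundary_conditions_random(rng):
    for _ in range(200):
        p = draw_params(rng)
        x = float(rng.uniform(0, 1))
        dpdx = float(rng.uniform(-3, 3))
        st = StationSolution(x, dpdx, p, a1_limit=True)
        assert abs(st.u(0.0)) < 1e-10
        assert abs(st.u(st.h) + 1.0) < 1e-10
        assert abs(st.theta(0.0)) < 1e-10
        assert abs(st.theta(st.h) - 1.0) < 1e-10


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    eps=st_.floats(0.0, 0.8),
    M=st_.floats(0.05, 8.0),
    beta=st_.floats(-1.3, 1.3),
    lambda1=st_.floats(0.0, 2.0),
    Br=st_.floats(0.3, 2.0),
    eta=st_.floats(0.0, 0.5),
    dpdx=st_.floats(-3.0, 3.0),
    x=st_.floats(0.0, 1.0),
)
def test_boundary_conditions_hold_for_any_valid_configuration(
        eps, M, beta, lambda1, Br, eta, dpdx, x):
    # cap eta so the draw stays clear of the temperature resonance
    eta = min(eta, (2.9 / (Br * (1.0 + eps))) ** 2)
    p = DimensionlessParams(eps=eps, M=M, beta=beta, lambda1=lambda1,
                            Br=Br, eta=eta)
    st = StationSolution(x, dpdx, p, a1_limit=True)
    assert abs(st.u(0.0)) < 1e-10
    assert abs(st.u(st.h) + 1.0) < 1e-10
    assert abs(st.theta(0.0)) < 1e-10
    assert abs(st.theta(st.h) - 1.0) < 1e-10
    assert abs(st.psi(0.0)) < 1e-14
    assert abs(st.psi(st.h) - st.flux()) < 1e-12


def test_velocity_satisfies_momentum_ode(rng):
    # u'' - a1 u = a1 - cI - a2 theta, pointwise
    for _ in range(10):
        p = draw_params(rng, fd_safe=True)
        x = float(rng.uniform(0, 1))
        dpdx = float(rng.uniform(-2, 2))
        st = StationSolution(x, dpdx, p)
        y = np.linspace(0.15 * st.h, 0.85 * st.h, 9)
        upp = second_derivative(st.u, y, 1e-3)
        res = upp - st.a1 * st.u(y) - (st.a1 - st.cI - st.a2 * st.theta(y))
        assert np.abs(res).max() < 1e-7


def test_solution_constants_closure_and_printed_c4(rng):
    # c3, c4 from the boundary solve reproduce both BCs, and agree with the
    # published c4 expression:
    # c4 = a2/(2 D sinh(mh)) + cI (1-e^{mh})/(2 a1 sinh(mh)) + e^{mh}/(2 sinh(mh))
    for _ in range(25):
        p = draw_params(rng, fd_safe=True)
        x, dpdx = float(rng.uniform(0, 1)), float(rng.uniform(-2, 2))
        cst = solution_constants(x, dpdx, p)
        m = math.sqrt(cst.a1)
        k2 = p.Br**2 * p.eta
        D = cst.a1 + k2
        bu_h = cst.a2 / D  # theta(h) = 1
        u0 = -1 + cst.cI / cst.a1 + cst.c3 + cst.c4
        uh = (-1 + cst.cI / cst.a1 + cst.c3 * math.exp(m * cst.h)
              + cst.c4 * math.exp(-m * cst.h) + bu_h)
        assert abs(u0) < 1e-10 and abs(uh + 1) < 1e-10
        sinh_mh = math.sinh(m * cst.h)
        c4_printed = (cst.a2 / (2 * D * sinh_mh)
                      + cst.cI * (1 - math.exp(m * cst.h)) / (2 * cst.a1 * sinh_mh)
                      + math.exp(m * cst.h) / (2 * sinh_mh))
        assert cst.c4 == pytest.approx(c4_printed, rel=1e-10, abs=1e-12)


def test_exponential_and_wall_anchored_forms_agree(rng):
    for _ in range(10):
        p = draw_params(rng, fd_safe=True)
        x, dpdx = float(rng.uniform(0, 1)), float(rng.uniform(-2, 2))
        st = StationSolution(x, dpdx, p)
        cst = solution_constants(x, dpdx, p)
        m = math.sqrt(cst.a1)
        y = np.linspace(0, st.h, 21)
        bu = cst.a2 / (cst.a1 + p.Br**2 * p.eta)
        u_exp = (-1 + cst.cI / cst.a1 + cst.c3 * np.exp(m * y)
                 + cst.c4 * np.exp(-m * y) + bu * st.theta(y))
        assert np.allclose(st.u(y), u_exp, atol=1e-11)


def test_fields_even_in_beta(rng):
    p = draw_params(rng, fd_safe=True)
    y = np.linspace(0, wall_height(0.2, p), 15)
    up = velocity(0.2, y, 0.7, p.replace(beta=0.9))
    um = velocity(0.2, y, 0.7, p.replace(beta=-0.9))
    assert np.allclose(up, um, atol=1e-14)


def test_overflow_safe_at_large_hartmann():
    p = DimensionlessParams(M=50.0, eps=0.5)
    st = StationSolution(0.25, 1.0, p)  # h = 1.5, sqrt(a1)*h ~ 80
    y = np.linspace(0, st.h, 101)
    for arr in (st.u(y), st.du_dy(y), st.psi(y), np.atleast_1d(st.flux())):
        assert np.all(np.isfinite(arr))
    assert abs(st.u(0.0)) < 1e-10 and abs(st.u(st.h) + 1.0) < 1e-10
    # and an extreme case that would overflow exp(sqrt(a1)*h) naively
    p = DimensionlessParams(M=1000.0)
    st = StationSolution(0.25, 1.0, p)
    assert np.isfinite(st.u(st.h / 2)) and abs(st.u(st.h) + 1.0) < 1e-10


def test_shear_is_scaled_velocity_gradient(rng):
    for _ in range(10):
        p = draw_params(rng, fd_safe=True)
        x, dpdx = float(rng.uniform(0, 1)), float(rng.uniform(-2, 2))
        st = StationSolution(x, dpdx, p)
        y = np.linspace(0.1 * st.h, 0.9 * st.h, 9)
        d = 1e-5 * st.h
        du_num = (st.u(y + d) - st.u(y - d)) / (2 * d)
        assert np.allclose(st.shear(y), du_num / (1 + p.lambda1), atol=1e-8)


def test_shear_vanishes_at_large_lambda1_with_fixed_profile():
    # Fix a1, cI and drop buoyancy so the velocity profile is lambda1-free;
    # S_xy = u'/(1+lambda1) must then scale as 1/(1+lambda1).
    a1_target, cI_target = 3.0, 1.2
    vals = []
    for lam1 in (1.0, 10.0, 100.0):
        M = math.sqrt(a1_target / (1 + lam1))
        dpdx = -cI_target / (1 + lam1)  # with c1 = 0: cI = -(1+lam1) dpdx
        p = DimensionlessParams(M=M, lambda1=lam1, beta=0.0, c1=0.0, c2=0.0)
        vals.append(float(shear_stress(0.0, 0.5, dpdx, p)))
    assert vals[0] / vals[1] == pytest.approx(11.0 / 2.0, rel=1e-10)
    assert vals[1] / vals[2] == pytest.approx(101.0 / 11.0, rel=1e-10)
    assert abs(vals[2]) < abs(vals[0])


def test_signed_shear_increases_with_hartmann_at_fixed_gradient():
    vals = [float(shear_stress(0.0, 0.5, 0.0, DEFAULTS.replace(M=m)))
            for m in (0.5, 1.0, 2.0, 3.0)]
    assert np.all(np.diff(vals) > 0)


def test_velocity_monotonic_in_hartmann_alpha_gravity():
    # midpoint velocity at fixed dp/dx = 0, x = 0
    u = lambda **kw: float(velocity(0.0, 0.5, 0.0, DEFAULTS.replace(**kw)))
    assert np.all(np.diff([u(M=m) for m in (0.5, 1, 2, 3)]) < 0)
    assert np.all(np.diff([u(alpha=a) for a in (0, math.pi / 6, math.pi / 4,
                                                math.pi / 3)]) > 0)
    assert np.all(np.diff([u(c1=c) for c in (0, 0.5, 1, 2)]) > 0)


def test_temperature_monotonic_in_brinkman_and_source():
    th = lambda **kw: float(temperature(0.0, 0.5, DEFAULTS.replace(**kw)))
    assert np.all(np.diff([th(Br=b) for b in (0.5, 1, 1.5, 2)]) > 0)
    assert np.all(np.diff([th(eta=e) for e in (0.1, 0.3, 0.5, 0.7)]) > 0)


def test_degenerate_a1_requires_explicit_flag():
    p = DimensionlessParams(M=0.0)
    with pytest.raises(DegenerateConfigurationError):
        velocity(0.0, 0.5, 1.0, p)
    with pytest.raises(DegenerateConfigurationError):
        solution_constants(0.0, 1.0, p)
    assert np.isfinite(velocity(0.0, 0.5, 1.0, p, a1_limit=True))


def test_a1_limit_path_is_continuous_with_main_branch():
    # M tiny (main branch) vs M = 0 (limit branch) agree to O(a1)
    p_small = DimensionlessParams(M=1e-4)
    p_zero = DimensionlessParams(M=0.0)
    y = np.linspace(0, 1, 11)
    u_small = velocity(0.0, y, 1.0, p_small)
    u_zero = velocity(0.0, y, 1.0, p_zero, a1_limit=True)
    assert np.abs(u_small - u_zero).max() < 1e-6


def test_a1_limit_quadratic_lubrication_profile():
    # no magnetic damping, no buoyancy, conduction-limit temperature:
    # u'' = -cI with u(0)=0, u(h)=-1 (a plain Poiseuille-type parabola)
    p = DimensionlessParams(M=0.0, c2=0.0, eta=1e-12)
    x, dpdx = 0.0, 1.0
    st = StationSolution(x, dpdx, p, a1_limit=True)
    cI = (1 + p.lambda1) * (p.c1 * math.sin(p.alpha) - dpdx)
    h = st.h
    y = np.linspace(0, h, 33)
    u_quad = -cI * y**2 / 2 + (-1 + cI * h**2 / 2) * y / h
    assert np.abs(st.u(y) - u_quad).max() < 1e-10
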
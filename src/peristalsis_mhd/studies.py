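"""Parameter-study drivers: the standard sweeps a user plots from this model.

Each driver returns a ``(columns, metadata)`` pair ready for
:func:`~peristalsis_mhd.tables.write_table`.  Profile studies (velocity,
temperature) are evaluated at a fixed imposed pressure gradient, default
dp/dx = 0, so that the parameter effect on the body-force-driven motion is
isolated; along-channel studies (pressure gradient, wall shear) and the
pumping/friction curves are evaluated at prescribed flow rate F.
"""

from __future__ import annotations

import numpy as np

from .fields import StationSolution
from .params import DimensionlessParams, wall_height
from .pumping import pumping_curve, solve_dpdx
from .streamlines import bolus_sweep

__all__ = [
    "velocity_profiles",
    "temperature_profiles",
    "dpdx_along_channel",
    "wall_shear_along_channel",
    "pumping_curves",
    "bolus_table",
]


def velocity_profiles(param_name: str, values, params: DimensionlessParams,
                      dpdx: float = 0.0, x: float = 0.0, ny: int = 101,
                      a1_limit: bool = False):
    """u(y) at station x and fixed dp/dx, one column per parameter value."""
    h0 = wall_height(x, params)
    cols: dict = {}
    for v in values:
        p = params.replace(**{param_name: float(v)})
        st = StationSolution(x, dpdx, p, a1_limit=a1_limit)
        y = np.linspace(0.0, st.h, ny)
        cols.setdefault("y_frac", y / st.h)
        cols[f"u[{param_name}={v:g}]"] = st.u(y)
    return cols, {"x": x, "dpdx": dpdx, "h(x)": h0, "study": "velocity-profiles"}


def temperature_profiles(param_name: str, values, params: DimensionlessParams,
                         x: float = 0.0, ny: int = 101):
    """theta(y) at station x, one column per parameter value."""
    cols: dict = {}
    for v in values:
        p = params.replace(**{param_name: float(v)})
        st = StationSolution(x, 0.0, p, a1_limit=True)
        y = np.linspace(0.0, st.h, ny)
        cols.setdefault("y_frac", y / st.h)
        cols[f"theta[{param_name}={v:g}]"] = st.theta(y)
    return cols, {"x": x, "study": "temperature-profiles"}


def dpdx_along_channel(param_name: str, values, F: float,
                       params: DimensionlessParams, nx: int = 101,
                       a1_limit: bool = False):
    """dp/dx(x) over one wavelength at prescribed flow rate F."""
    x = np.linspace(0.0, 1.0, nx)
    cols: dict = {"x": x}
    for v in values:
        p = params.replace(**{param_name: float(v)})
        cols[f"dpdx[{param_name}={v:g}]"] = np.array(
            [solve_dpdx(F, xi, p, a1_limit=a1_limit) for xi in x])
    return cols, {"F": F, "study": "dpdx-along-channel"}


def wall_shear_along_channel(param_name: str, values, F: float,
                             params: DimensionlessParams, nx: int = 101,
                             a1_limit: bool = False):
    """Wall shear stress S_xy(x, h(x)) over one wavelength at flow rate F."""
    x = np.linspace(0.0, 1.0, nx)
    cols: dict = {"x": x}
    for v in values:
        p = params.replace(**{param_name: float(v)})
        vals = []
        for xi in x:
            dpdx = solve_dpdx(F, xi, p, a1_limit=a1_limit)
            st = StationSolution(xi, dpdx, p, a1_limit=a1_limit)
            vals.append(st.shear(st.h))
        cols[f"S_xy[{param_name}={v:g}]"] = np.array(vals)
    return cols, {"F": F, "study": "wall-shear-along-channel"}


def pumping_curves(param_name: str, values, F_values,
                   params: DimensionlessParams, window: str = "2pi",
                   a1_limit: bool = False):
    """Pressure rise and friction force vs flow rate, per parameter value."""
    F_values = np.atleast_1d(np.asarray(F_values, dtype=float))
    cols: dict = {"F": F_values}
    for v in values:
        p = params.replace(**{param_name: float(v)})
        pts = pumping_curve(F_values, p, window=window, a1_limit=a1_limit)
        cols[f"delta_p[{param_name}={v:g}]"] = np.array([pt.dp_rise for pt in pts])
        cols[f"friction[{param_name}={v:g}]"] = np.array([pt.friction for pt in pts])
    return cols, {"window": window, "study": "pumping-curves"}


def bolus_table(param_name: str, values, F: float,
                params: DimensionlessParams, nx: int = 129, ny: int = 129,
                n_levels: int = 41):
    """Total trapped-bolus area and count per parameter value."""
    rows = bolus_sweep(param_name, values, F, params, nx=nx, ny=ny,
                       n_levels=n_levels)
    cols = {
        param_name: np.array([r["value"] for r in rows]),
        "total_area": np.array([r["total_area"] for r in rows]),
        "n_boluses": np.array([r["n_boluses"] for r in rows]),
        "error": np.array([r["error"] or "-" for r in rows], dtype=object),
    }
    return cols, {"F": F, "nx": nx, "ny": ny, "n_levels": n_levels,
                  "study": "bolus-sweep"}
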
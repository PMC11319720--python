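"""Stream function, streamline topology, and trapped-bolus quantification.

In the wave frame the flow is steady and the stream function Psi (with
u = dPsi/dy and the convention Psi = 0 on the centreline y = 0) makes the
moving wall a streamline: Psi(x, h(x)) equals the prescribed flow rate F at
every station.  When the wall wave is strong enough, some streamlines close
up and enclose a recirculating fluid mass -- a trapped bolus -- that travels
with the wave.

Boluses are quantified operationally: Psi is sampled on a body-fitted grid
(uniform x over one period, uniform sigma = y/h(x) per column), marching
squares extracts iso-Psi contours at a fixed ladder of levels between min Psi
and max Psi, closed contours away from both walls are grouped into nested
families, and the outermost contour of each family defines one
:class:`BolusRegion` with its shoelace area, centroid and interior Psi
extremum.  Because h has period 1 in x, the field is tiled over two periods
before contouring so that boluses straddling the x = 0 seam are captured
whole; each bolus is then counted once via a one-period centroid window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon
from skimage.measure import find_contours

from .fields import StationSolution
from .params import DimensionlessParams, wall_height
from .pumping import solve_dpdx

__all__ = [
    "FieldGrid",
    "BolusRegion",
    "make_field_grid",
    "stream_function",
    "detect_boluses",
    "bolus_sweep",
    "shoelace_area",
]


@dataclass(frozen=True)
class FieldGrid:
    """Sampled fields over one wavelength on a body-fitted grid.

    ``x`` has shape (nx,) covering [0, 1) uniformly; ``sigma`` has shape
    (ny,) covering [0, 1]; physical heights are ``y[i, j] = sigma[j] * h[i]``.
    """

    x: np.ndarray
    sigma: np.ndarray
    y: np.ndarray
    h: np.ndarray
    dpdx: np.ndarray
    u: np.ndarray
    theta: np.ndarray
    S_xy: np.ndarray
    psi: np.ndarray
    F: float
    params: DimensionlessParams


@dataclass(frozen=True)
class BolusRegion:
    """One trapped-bolus region: the outermost closed iso-Psi contour of a
    nested family."""

    contour: np.ndarray       # (N, 2) closed polyline in (x, y)
    area: float               # enclosed area (shoelace)
    centroid: tuple           # (x, y), x reduced to [0, 1)
    psi_extremum: float       # Psi at the interior extremum
    level: float              # contour level


def make_field_grid(params: DimensionlessParams, F: float = -0.4,
                    nx: int = 129, ny: int = 129,
                    a1_limit: bool = False) -> FieldGrid:
    """Sample u, theta, S_xy and Psi over one wavelength at prescribed flow
    rate F; the pressure gradient is solved per column."""
    if nx < 4 or ny < 4:
        raise ValueError("degenerate grid resolution")
    x = np.linspace(0.0, 1.0, nx, endpoint=False)
    sigma = np.linspace(0.0, 1.0, ny)
    h = np.asarray(wall_height(x, params))
    y = np.empty((nx, ny))
    dpdx = np.empty(nx)
    u = np.empty((nx, ny))
    theta = np.empty((nx, ny))
    S_xy = np.empty((nx, ny))
    psi = np.empty((nx, ny))
    for i, xi in enumerate(x):
        dpdx[i] = solve_dpdx(F, xi, params, a1_limit=a1_limit)
        st = StationSolution(xi, dpdx[i], params, a1_limit=a1_limit)
        yi = sigma * h[i]
        y[i] = yi
        u[i] = st.u(yi)
        theta[i] = st.theta(yi)
        S_xy[i] = st.shear(yi)
        psi[i] = st.psi(yi)
    return FieldGrid(x=x, sigma=sigma, y=y, h=h, dpdx=dpdx, u=u, theta=theta,
                     S_xy=S_xy, psi=psi, F=float(F), params=params)


def stream_function(x, y, F, params: DimensionlessParams,
                    a1_limit: bool = False):
    """Psi(x, y) at prescribed flow rate F (dp/dx solved internally).

    ``x`` is scalar; ``y`` may be an array.  Psi(x, 0) = 0 and
    Psi(x, h(x)) = F by construction.
    """
    dpdx = solve_dpdx(F, x, params, a1_limit=a1_limit)
    return StationSolution(x, dpdx, params, a1_limit=a1_limit).psi(y)


def shoelace_area(vertices: np.ndarray) -> float:
    """Absolute polygon area by the shoelace formula (first vertex need not
    be repeated at the end)."""
    v = np.asarray(vertices, dtype=float)
    xs, ys = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1)))


def _closed_contours(grid: FieldGrid, levels) -> list[dict]:
    """Closed iso-Psi contours over the two-period tiling, in physical
    coordinates, excluding any touching the centreline or the wall."""
    nx, ny = grid.psi.shape
    dx = 1.0 / nx
    psi2 = np.vstack([grid.psi, grid.psi, grid.psi[:1]])  # x in [0, 2]
    eps_edge = 1e-9
    out = []
    for lev in levels:
        for c in find_contours(psi2, lev):
            if not np.allclose(c[0], c[-1]):
                continue
            sg = c[:, 1] / (ny - 1)
            if sg.min() < eps_edge or sg.max() > 1.0 - eps_edge:
                continue
            xs = c[:, 0] * dx
            ys = sg * np.asarray(wall_height(xs, grid.params))
            verts = np.column_stack([xs, ys])
            area = shoelace_area(verts[:-1])
            if area < 1e-9:
                continue
            poly = Polygon(verts)
            if not poly.is_valid:
                poly = poly.buffer(0)
                if poly.is_empty:
                    continue
            out.append({"level": float(lev), "verts": verts, "area": area,
                        "poly": poly})
    return out


def detect_boluses(grid: FieldGrid, n_levels: int = 41,
                   levels=None) -> list[BolusRegion]:
    """Detect trapped boluses on a sampled field grid.

    Contours of Psi are taken at ``n_levels`` evenly spaced levels strictly
    between min Psi and max Psi (or at the explicit ``levels`` if given).
    Closed contours not touching either wall are grouped into nested
    families; the outermost contour of each family becomes one
    :class:`BolusRegion`.
    """
    nx, ny = grid.psi.shape
    if nx < 64 or ny < 64:
        raise ValueError(
            f"grid resolution {nx}x{ny} too coarse for bolus detection; "
            "need at least 64x64 per period"
        )
    if levels is None:
        lo, hi = float(grid.psi.min()), float(grid.psi.max())
        if not hi > lo:
            return []
        levels = np.linspace(lo, hi, n_levels + 2)[1:-1]
    contours = _closed_contours(grid, np.atleast_1d(levels))
    # Outermost-first: a contour contained in an already accepted region
    # belongs to that region's nested family.
    contours.sort(key=lambda c: c["area"], reverse=True)
    accepted = []
    for c in contours:
        rep = c["poly"].representative_point()
        if any(a["poly"].contains(rep) for a in accepted):
            continue
        accepted.append(c)

    # One-period centroid window on the two-period tiling: keep centroids in
    # [0.5, 1.5) so each bolus (including seam-straddlers) is counted once.
    dxg = 1.0 / nx
    x2 = np.arange(2 * nx + 1) * dxg
    X2 = np.repeat(x2[:, None], ny, axis=1)
    Y2 = grid.sigma[None, :] * np.asarray(wall_height(x2, grid.params))[:, None]
    psi2 = np.vstack([grid.psi, grid.psi, grid.psi[:1]])

    regions = []
    for c in accepted:
        cen = c["poly"].centroid
        if not 0.5 <= cen.x < 1.5:
            continue
        inside = shapely.contains_xy(c["poly"], X2.ravel(), Y2.ravel())
        vals = psi2.ravel()[inside]
        if vals.size:
            ext = float(vals.max() if vals.mean() > c["level"] else vals.min())
        else:
            ext = c["level"]
        shift = -1.0 if cen.x >= 1.0 else 0.0
        verts = c["verts"].copy()
        verts[:, 0] += shift
        regions.append(BolusRegion(
            contour=verts,
            area=float(c["area"]),
            centroid=(float(cen.x + shift), float(cen.y)),
            psi_extremum=ext,
            level=c["level"],
        ))
    regions.sort(key=lambda r: r.centroid[0])
    return regions


def bolus_sweep(param_name: str, values, F: float,
                params: DimensionlessParams, nx: int = 129, ny: int = 129,
                n_levels: int = 41, a1_limit: bool = True) -> list[dict]:
    """Sweep one parameter and tabulate total bolus area and bolus count.

    Grid resolution and level count are identical across rows.  Per-row
    failures (e.g. a value violating the resonance guard) are recorded in the
    row's ``error`` field and the sweep continues.  The a1 -> 0 limit path is
    enabled by default so that M = 0 rows are computable.
    """
    rows = []
    for v in values:
        row = {"value": float(v), "total_area": math.nan, "n_boluses": 0,
               "error": ""}
        try:
            p = params.replace(**{param_name: float(v)})
            grid = make_field_grid(p, F=F, nx=nx, ny=ny, a1_limit=a1_limit)
            regions = detect_boluses(grid, n_levels=n_levels)
            row["total_area"] = float(sum(r.area for r in regions))
            row["n_boluses"] = len(regions)
        except Exception as exc:  # per-row errors reported, sweep continues
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return rows
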
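"""Depth-averaged steady transport in a two-chamber microgroove device.

The device is two parallel culture chambers joined through a wall pierced by
shallow microgrooves (defaults: 13 grooves, 100 μm long × 10 μm wide ×
5 μm deep).  Media flows along each chamber (plug flow, u = Q/(width·depth));
no pressure-driven flow crosses the grooves, so grooves transport solute by
diffusion only.  The solver treats the vertical dimension by depth
averaging: it solves

    ∇·(h D ∇c) − h u·∇c = 0

on a 2D grid whose local depth h is the chamber depth in the chambers, the
groove depth inside grooves and zero in the solid wall, with Dirichlet
concentrations at the chamber inlets, advective outflow at the outlets and
no-flux walls elsewhere.  Advection is upwinded (finite volumes), which is
stable at the large chamber Péclet numbers of these devices at the cost of
some numerical diffusion along the flow; the grid default of 2.5 μm keeps
the cell Péclet number moderate.

Units: lengths μm, time s, concentration mM.  ``TransportParams`` accepts
the conventional lab units (cm² s⁻¹, μl min⁻¹) and converts internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve


@dataclass
class DeviceGeometry:
    """Two-chamber + microgroove layout, all lengths in μm.

    The chamber depth is not a molded-groove dimension and is rarely
    reported; 100 μm (a typical thick-resist device layer) is the default
    and should be listed with any run report.  ``cell_site_offset`` is the
    distance of the cell-attachment sites from the wall on the
    low-concentration side.
    """

    chamber_length: float = 750.0    # along the flow
    chamber_width: float = 300.0     # across the flow
    chamber_depth: float = 100.0
    n_grooves: int = 13
    groove_length: float = 100.0     # wall thickness
    groove_width: float = 10.0
    groove_depth: float = 5.0
    groove_pitch: float = 50.0
    cell_site_offset: float = 175.0

    def __post_init__(self) -> None:
        for name in ("chamber_length", "chamber_width", "chamber_depth",
                     "groove_length", "groove_width", "groove_depth",
                     "groove_pitch", "cell_site_offset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_grooves < 0:
            raise ValueError("n_grooves must be ≥ 0")
        span = (self.n_grooves - 1) * self.groove_pitch + self.groove_width
        if self.n_grooves and span > self.chamber_length:
            raise ValueError("grooves do not fit within the shared wall")

    def groove_centers(self) -> np.ndarray:
        """y positions (μm) of groove centrelines, centred on the wall."""
        k = np.arange(self.n_grooves)
        return (self.chamber_length / 2.0
                + (k - (self.n_grooves - 1) / 2.0) * self.groove_pitch)


@dataclass
class TransportParams:
    """Physics and discretization parameters.

    D — solute diffusion coefficient in cm² s⁻¹ (default 5×10⁻⁷, typical of
    proteins in water); Q — volumetric flow per chamber in μl min⁻¹ (default
    0.03, the steady culture flow); boundary concentrations in mM.
    """

    D: float = 5e-7          # cm² s⁻¹
    Q: float = 0.03          # μl min⁻¹
    c_left: float = 1.0      # mM
    c_right: float = 0.0     # mM
    grid: float = 2.5        # μm

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("D must be > 0")
        if self.Q < 0:
            raise ValueError("Q must be ≥ 0")
        if self.grid <= 0:
            raise ValueError("grid spacing must be > 0")

    @property
    def D_um2_s(self) -> float:
        return self.D * 1e8

    @property
    def Q_um3_s(self) -> float:
        return self.Q * 1e9 / 60.0


@dataclass
class ConcentrationField:
    """Steady depth-averaged concentration on the device grid.

    ``c[j, i]`` is the concentration at cell centre
    (x, y) = ((i+½)·grid, (j+½)·grid); blocked (solid-wall) cells are NaN.
    """

    c: np.ndarray
    depth: np.ndarray
    grid: float
    inlet_segments: list = field(default_factory=list)  # (x_lo, x_hi, value)
    residual: float = 0.0

    @property
    def extent(self) -> tuple[float, float]:
        ny, nx = self.c.shape
        return nx * self.grid, ny * self.grid

    def probe(self, points) -> np.ndarray:
        """Bilinear interpolation of c at (x, y) points in μm.

        Points exactly on a Dirichlet inlet segment return the boundary
        value; near blocked cells the bilinear weights are renormalized over
        the open neighbours.  Points outside the domain are rejected.
        """
        Lx, Ly = self.extent
        out = np.empty(len(points))
        for n, (x, y) in enumerate(points):
            if not (0 <= x <= Lx and 0 <= y <= Ly):
                raise ValueError(f"probe point ({x}, {y}) outside domain "
                                 f"[0,{Lx}]×[0,{Ly}]")
            if y == 0.0:
                hit = [v for (lo, hi, v) in self.inlet_segments if lo <= x <= hi]
                if hit:
                    out[n] = hit[0]
                    continue
            gi = np.clip(x / self.grid - 0.5, 0, self.c.shape[1] - 1)
            gj = np.clip(y / self.grid - 0.5, 0, self.c.shape[0] - 1)
            i0, j0 = int(np.floor(gi)), int(np.floor(gj))
            i1, j1 = min(i0 + 1, self.c.shape[1] - 1), min(j0 + 1, self.c.shape[0] - 1)
            fx, fy = gi - i0, gj - j0
            vals = np.array([self.c[j0, i0], self.c[j0, i1],
                             self.c[j1, i0], self.c[j1, i1]])
            wts = np.array([(1 - fx) * (1 - fy), fx * (1 - fy),
                            (1 - fx) * fy, fx * fy])
            ok = np.isfinite(vals)
            if not ok.any():
                raise ValueError(f"probe point ({x}, {y}) lies inside the solid wall")
            out[n] = float((vals[ok] * wts[ok]).sum() / wts[ok].sum())
        return out


# ---------------------------------------------------------------------------
# Core finite-volume solver
# ---------------------------------------------------------------------------

def solve_on_maps(h: np.ndarray, u: np.ndarray, dx: float, D: float,
                  inlet_value: np.ndarray, outlet_value: np.ndarray | None = None,
                  ) -> tuple[np.ndarray, float]:
    """Solve ∇·(hD∇c) − h u ∂c/∂y = 0 on arbitrary depth/velocity maps.

    ``h`` is the (ny, nx) depth map (0 = blocked); ``u`` the per-column plug
    velocity along +y (μm s⁻¹); ``inlet_value[i]`` the Dirichlet value at
    the j = 0 edge of column i (NaN = no-flux); ``outlet_value`` optionally
    imposes Dirichlet values at j = ny−1 (NaN = advective outflow).  Face
    diffusivities use the harmonic mean of h; advection is first-order
    upwind.  Returns (c, relative residual); blocked cells are NaN.
    """
    ny, nx = h.shape
    active = h > 0
    idx = -np.ones(h.shape, dtype=np.int64)
    idx[active] = np.arange(active.sum())
    N = int(active.sum())
    if N == 0:
        raise ValueError("no open cells in the domain")

    rows, cols, vals = [], [], []
    b = np.zeros(N)

    def add(r, c_, v):
        rows.append(r)
        cols.append(c_)
        vals.append(v)

    def harm(h1, h2):
        return 2.0 * h1 * h2 / (h1 + h2)

    for j in range(ny):
        for i in range(nx):
            if not active[j, i]:
                continue
            p = idx[j, i]
            # x-faces: diffusion only
            for i2 in (i - 1, i + 1):
                if 0 <= i2 < nx and active[j, i2]:
                    T = D * harm(h[j, i], h[j, i2])
                    add(p, p, T)
                    add(p, idx[j, i2], -T)
            # y-faces: diffusion + upwind advection (u ≥ 0 assumed)
            q = u[i] * h[j, i] * dx
            for j2 in (j - 1, j + 1):
                if 0 <= j2 < ny and active[j2, i]:
                    T = D * harm(h[j, i], h[j2, i])
                    add(p, p, T)
                    add(p, idx[j2, i], -T)
                    if q > 0:
                        if j2 == j + 1:          # outflow face: carries c_p
                            add(p, p, q)
                        else:                    # inflow face: brings c_neighbour
                            add(p, idx[j2, i], -q)
            if j == 0 and np.isfinite(inlet_value[i]):
                T = 2.0 * D * h[j, i]
                add(p, p, T)
                b[p] += T * inlet_value[i] + q * inlet_value[i]
            if j == ny - 1:
                if outlet_value is not None and np.isfinite(outlet_value[i]):
                    T = 2.0 * D * h[j, i]
                    add(p, p, T + 0.0)
                    b[p] += T * outlet_value[i]
                    if q > 0:
                        add(p, p, q)  # advective outflow at c_p
                elif q > 0:
                    add(p, p, q)

    A = sparse.csr_matrix((vals, (rows, cols)), shape=(N, N))
    x = spsolve(A, b)
    resid = float(np.linalg.norm(A @ x - b)
                  / max(np.linalg.norm(b), np.finfo(float).tiny))
    c = np.full(h.shape, np.nan)
    c[active] = x
    return c, resid


def build_maps(geometry: DeviceGeometry, grid: float,
               ) -> tuple[np.ndarray, np.ndarray, slice]:
    """Rasterize the device: returns (depth map, per-column u mask columns of
    the wall as a slice).  Velocity is filled in by the caller."""
    g = geometry
    nxc = int(round(g.chamber_width / grid))
    nxw = int(round(g.groove_length / grid))
    ny = int(round(g.chamber_length / grid))
    nx = 2 * nxc + nxw
    h = np.zeros((ny, nx))
    h[:, :nxc] = g.chamber_depth
    h[:, nxc + nxw:] = g.chamber_depth
    y = (np.arange(ny) + 0.5) * grid
    for yc in g.groove_centers():
        rows = np.abs(y - yc) <= g.groove_width / 2.0
        h[rows, nxc:nxc + nxw] = g.groove_depth
    return h, y, slice(nxc, nxc + nxw)


def solve_steady(geometry: DeviceGeometry, params: TransportParams,
                 ) -> ConcentrationField:
    """Steady concentration field for the device under culture flow."""
    if params.grid > geometry.groove_width / 2.0:
        raise ValueError("grid too coarse: spacing must be ≤ groove_width/2 "
                         "(≥ 4 cells across each groove is recommended)")
    h, _, wall = build_maps(geometry, params.grid)
    ny, nx = h.shape
    u = np.zeros(nx)
    u_ch = params.Q_um3_s / (geometry.chamber_width * geometry.chamber_depth)
    u[:wall.start] = u_ch
    u[wall.stop:] = u_ch
    inlet = np.full(nx, np.nan)
    inlet[:wall.start] = params.c_left
    inlet[wall.stop:] = params.c_right
    c, resid = solve_on_maps(h, u, params.grid, params.D_um2_s, inlet)
    segs = [(0.0, wall.start * params.grid, params.c_left),
            (wall.stop * params.grid, nx * params.grid, params.c_right)]
    return ConcentrationField(c, h, params.grid, segs, resid)


def groove_concentrations(field: ConcentrationField, geometry: DeviceGeometry,
                          ) -> pd.DataFrame:
    """Concentration in the first and last interior cell of each groove.

    "Entrance" is the groove cell column adjacent to the high-concentration
    chamber, "end" the column adjacent to the low-concentration chamber;
    values are averaged over each groove's rows.
    """
    grid = field.grid
    nxc = int(round(geometry.chamber_width / grid))
    nxw = int(round(geometry.groove_length / grid))
    y = (np.arange(field.c.shape[0]) + 0.5) * grid
    rows_out = []
    for k, yc in enumerate(geometry.groove_centers()):
        rows = np.abs(y - yc) <= geometry.groove_width / 2.0
        entrance = float(np.nanmean(field.c[rows, nxc]))
        end = float(np.nanmean(field.c[rows, nxc + nxw - 1]))
        rows_out.append({"groove": k, "y_um": yc,
                         "entrance_mM": entrance, "end_mM": end})
    return pd.DataFrame(rows_out, columns=["groove", "y_um",
                                           "entrance_mM", "end_mM"])


def cell_site_points(geometry: DeviceGeometry, n: int = 5) -> list:
    """(x, y) probe points at the cell-attachment sites: ``cell_site_offset``
    μm into the low-concentration chamber from the wall, spread along the
    groove span."""
    x = geometry.chamber_width + geometry.groove_length + geometry.cell_site_offset
    centers = geometry.groove_centers()
    ys = np.linspace(centers.min(), centers.max(), n) if len(centers) else \
        np.linspace(0.25, 0.75, n) * geometry.chamber_length
    return [(x, float(yy)) for yy in ys]


# ---------------------------------------------------------------------------
# Arithmetic helpers
# ---------------------------------------------------------------------------

def chamber_turnover(volume_ul: float, flow_ul_min: float) -> float:
    """Minutes to replace one chamber volume of media: volume / flow."""
    if flow_ul_min <= 0:
        raise ValueError("flow must be > 0")
    if volume_ul <= 0:
        raise ValueError("volume must be > 0")
    return volume_ul / flow_ul_min


def dilution(volumes_ul, concentrations_um) -> float:
    """Concentration after mixing: Σ(v·c)/Σv (volumes μl, concentrations μM)."""
    v = np.asarray(volumes_ul, dtype=float)
    c = np.asarray(concentrations_um, dtype=float)
    if v.size == 0 or c.size == 0:
        raise ValueError("volumes and concentrations must be non-empty")
    if v.size != c.size:
        raise ValueError("volumes and concentrations must have equal length")
    if (v <= 0).any():
        raise ValueError("volumes must be positive")
    return float((v * c).sum() / v.sum())


def peclet(geometry: DeviceGeometry, params: TransportParams) -> dict[str, float]:
    """Péclet numbers Pe = u·L/D per region.  Grooves carry no flow in this
    model, so their Pe is 0 by construction."""
    u_ch = params.Q_um3_s / (geometry.chamber_width * geometry.chamber_depth)
    pe_ch = u_ch * geometry.chamber_length / params.D_um2_s
    return {"chamber_left": pe_ch, "chamber_right": pe_ch, "groove": 0.0}
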
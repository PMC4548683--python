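"""Steady groundwater flow and 3-D reactive plume transport on a site grid.

The flow problem is div(K grad h) = 0 on a regular cell-centred grid with
constant-head (Dirichlet) cells and no-flow outer faces, solved by finite
differences with harmonic-mean interface conductivities.  The transport
problem advects a dissolved plume through the resulting Darcy field with
explicit upwind advection, explicit velocity-dependent dispersion
(longitudinal/transverse dispersivities), equilibrium linear retardation R
and first-order aqueous decay k, with no persistent source.  Under
equilibrium sorption the total (aqueous + sorbed) plume mass therefore
decays as M0 exp(-k t / R) in a closed domain.

Concentrations are in mg/L (== g/m^3), lengths in metres, times in days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import spsolve

from .exceptions import InvalidSpecError, NumericsError

__all__ = [
    "SiteModel",
    "FlowSolution",
    "PlumeState",
    "WellRecord",
    "PlumeMetrics",
    "solve_steady_flow",
    "simulate_plume",
    "plume_metrics",
    "compare_wells",
    "total_mass",
]


@dataclass
class SiteModel:
    """Gridded site description.

    Arrays are indexed ``[layer, row, col]`` with layer 0 at the top.
    ``conductivity`` is the horizontal hydraulic conductivity (m/d);
    vertical conductivity is ``conductivity / vertical_anisotropy``.
    ``fixed_head`` marks constant-head cells whose head is read from
    ``fixed_head_values``; all outer faces are otherwise no-flow.
    """

    nx: int
    ny: int
    nlayers: int
    dx: float
    dy: float
    layer_thickness: np.ndarray          # (nlayers,), m
    conductivity: np.ndarray             # (nlayers, ny, nx), m/d
    porosity: np.ndarray                 # (nlayers, ny, nx)
    fixed_head: np.ndarray               # bool (nlayers, ny, nx)
    fixed_head_values: np.ndarray        # (nlayers, ny, nx), m
    vertical_anisotropy: float = 10.0

    def __post_init__(self) -> None:
        shape = (self.nlayers, self.ny, self.nx)
        self.layer_thickness = np.broadcast_to(
            np.asarray(self.layer_thickness, dtype=float), (self.nlayers,)
        ).copy()
        self.conductivity = np.broadcast_to(
            np.asarray(self.conductivity, dtype=float), shape
        ).copy()
        self.porosity = np.broadcast_to(np.asarray(self.porosity, dtype=float), shape).copy()
        self.fixed_head = np.broadcast_to(np.asarray(self.fixed_head, dtype=bool), shape).copy()
        self.fixed_head_values = np.broadcast_to(
            np.asarray(self.fixed_head_values, dtype=float), shape
        ).copy()
        if self.nx < 2 or self.ny < 2 or self.nlayers < 1:
            raise InvalidSpecError("grid must be at least 2 x 2 x 1")
        if np.any(self.conductivity <= 0):
            raise InvalidSpecError("conductivities must be positive")
        if np.any((self.porosity <= 0) | (self.porosity >= 1)):
            raise InvalidSpecError("porosities must lie in (0, 1)")
        if np.any(self.layer_thickness <= 0):
            raise InvalidSpecError("layer thicknesses must be positive")
        if not np.any(self.fixed_head):
            raise InvalidSpecError("at least one constant-head cell is required")
        if self.vertical_anisotropy <= 0:
            raise InvalidSpecError("vertical anisotropy must be positive")

    @classmethod
    def uniform(
        cls,
        *,
        nx: int = 100,
        ny: int = 100,
        nlayers: int = 4,
        dx: float = 1.0,
        dy: float = 1.0,
        layer_thickness: float = 2.0,
        conductivity: float = 0.1944,
        porosity: float = 0.296,
        head_west: float = 10.0,
        head_east: float = 9.8,
        vertical_anisotropy: float = 10.0,
    ) -> "SiteModel":
        """Homogeneous site with constant heads on the west and east faces."""
        shape = (nlayers, ny, nx)
        fixed = np.zeros(shape, dtype=bool)
        fixed[:, :, 0] = True
        fixed[:, :, -1] = True
        values = np.zeros(shape)
        values[:, :, 0] = head_west
        values[:, :, -1] = head_east
        return cls(
            nx=nx,
            ny=ny,
            nlayers=nlayers,
            dx=dx,
            dy=dy,
            layer_thickness=np.full(nlayers, layer_thickness),
            conductivity=np.full(shape, conductivity),
            porosity=np.full(shape, porosity),
            fixed_head=fixed,
            fixed_head_values=values,
            vertical_anisotropy=vertical_anisotropy,
        )

    @property
    def cell_volume(self) -> np.ndarray:
        """Bulk volume per cell, (nlayers, ny, nx), m^3."""
        dz = self.layer_thickness[:, None, None]
        return np.broadcast_to(self.dx * self.dy * dz, (self.nlayers, self.ny, self.nx))


@dataclass
class FlowSolution:
    """Steady heads and Darcy fluxes on the site grid.

    ``qx/qy/qz`` are specific discharges (m/d) on cell faces, shapes
    (nl, ny, nx+1), (nl, ny+1, nx) and (nl+1, ny, nx); positive toward
    increasing index.  Outer faces are zero (no-flow).
    """

    heads: np.ndarray
    qx: np.ndarray
    qy: np.ndarray
    qz: np.ndarray
    residual_norm: float
    site: SiteModel

    def volumetric_face_fluxes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Water fluxes through faces, m^3/d."""
        s = self.site
        dz = s.layer_thickness[:, None, None]
        fx = self.qx * (s.dy * dz)
        fy = self.qy * (s.dx * dz)
        fz = self.qz * (s.dx * s.dy)
        return fx, fy, fz

    def cell_divergence(self) -> np.ndarray:
        """Net volumetric outflow per cell, m^3/d (zero for interior cells)."""
        fx, fy, fz = self.volumetric_face_fluxes()
        return (
            fx[:, :, 1:] - fx[:, :, :-1]
            + fy[:, 1:, :] - fy[:, :-1, :]
            + fz[1:, :, :] - fz[:-1, :, :]
        )

    def pore_velocity(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cell-centred pore velocities (m/d) from face-averaged fluxes."""
        theta = self.site.porosity
        vx = 0.5 * (self.qx[:, :, :-1] + self.qx[:, :, 1:]) / theta
        vy = 0.5 * (self.qy[:, :-1, :] + self.qy[:, 1:, :]) / theta
        vz = 0.5 * (self.qz[:-1, :, :] + self.qz[1:, :, :]) / theta
        return vx, vy, vz


@dataclass
class PlumeState:
    """Concentration field at one time."""

    concentration: np.ndarray  # (nlayers, ny, nx), mg/L
    time: float                # d
    retardation: float = 1.0
    decay: float = 0.0

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.time < 0:
            raise InvalidSpecError("time must be non-negative")
        if np.any(self.concentration < 0):
            raise InvalidSpecError("concentrations must be non-negative")


@dataclass
class WellRecord:
    """Observed concentration series at one monitoring-well cell."""

    well_id: str
    layer: int
    row: int
    col: int
    times: np.ndarray
    concentrations: np.ndarray
    screen_label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.size != self.concentrations.size:
            raise InvalidSpecError("well series lengths differ")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise InvalidSpecError("well sample times must be increasing")


# ---------------------------------------------------------------------------
# flow
# ---------------------------------------------------------------------------


def _face_transmissibilities(site: SiteModel):
    """Harmonic-mean interface conductances, m^2/d (flux = T * dh)."""
    k = site.conductivity
    kv = k / site.vertical_anisotropy
    dz = site.layer_thickness[:, None, None]

    def harmonic(a, b):
        return 2.0 * a * b / (a + b)

    # x faces between (.., c-1) and (.., c): area dy*dz over distance dx
    tx = harmonic(k[:, :, :-1], k[:, :, 1:]) * (site.dy * dz) / site.dx
    ty = harmonic(k[:, :-1, :], k[:, 1:, :]) * (site.dx * dz) / site.dy
    dz_pair = 0.5 * (site.layer_thickness[:-1] + site.layer_thickness[1:])[:, None, None]
    tz = harmonic(kv[:-1], kv[1:]) * (site.dx * site.dy) / dz_pair
    return tx, ty, tz


def solve_steady_flow(site: SiteModel) -> FlowSolution:
    """Solve div(K grad h) = 0 with constant-head cells by finite differences."""
    nl, ny, nx = site.nlayers, site.ny, site.nx
    n = nl * ny * nx
    tx, ty, tz = _face_transmissibilities(site)

    def idx(l, r, c):
        return (l * ny + r) * nx + c

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag = np.zeros(n)

    def add_pairs(t, offset_idx):
        i, j = offset_idx
        t_flat = t.ravel()
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([t_flat, t_flat])
        np.add.at(diag, i, -t_flat)
        np.add.at(diag, j, -t_flat)

    ll, rr, cc = np.meshgrid(np.arange(nl), np.arange(ny), np.arange(nx - 1), indexing="ij")
    add_pairs(tx, (idx(ll, rr, cc).ravel(), idx(ll, rr, cc + 1).ravel()))
    ll, rr, cc = np.meshgrid(np.arange(nl), np.arange(ny - 1), np.arange(nx), indexing="ij")
    add_pairs(ty, (idx(ll, rr, cc).ravel(), idx(ll, rr + 1, cc).ravel()))
    ll, rr, cc = np.meshgrid(np.arange(nl - 1), np.arange(ny), np.arange(nx), indexing="ij")
    add_pairs(tz, (idx(ll, rr, cc).ravel(), idx(ll + 1, rr, cc).ravel()))

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    a = csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tolil()

    fixed = site.fixed_head.ravel()
    b = np.zeros(n)
    fixed_idx = np.flatnonzero(fixed)
    a[fixed_idx, :] = 0.0
    a[fixed_idx, fixed_idx] = 1.0
    b[fixed_idx] = site.fixed_head_values.ravel()[fixed_idx]
    a = a.tocsr()

    h = spsolve(a, b)
    if not np.all(np.isfinite(h)):
        raise NumericsError("flow solve produced non-finite heads")
    heads = h.reshape(nl, ny, nx)

    dz = site.layer_thickness[:, None, None]
    qx = np.zeros((nl, ny, nx + 1))
    qy = np.zeros((nl, ny + 1, nx))
    qz = np.zeros((nl + 1, ny, nx))
    qx[:, :, 1:-1] = tx * (heads[:, :, :-1] - heads[:, :, 1:]) / (site.dy * dz)
    qy[:, 1:-1, :] = ty * (heads[:, :-1, :] - heads[:, 1:, :]) / (site.dx * dz)
    qz[1:-1, :, :] = tz * (heads[:-1, :, :] - heads[1:, :, :]) / (site.dx * site.dy)

    sol = FlowSolution(heads=heads, qx=qx, qy=qy, qz=qz, residual_norm=0.0, site=site)
    fx, fy, fz = sol.volumetric_face_fluxes()
    div = (
        fx[:, :, 1:] - fx[:, :, :-1]
        + fy[:, 1:, :] - fy[:, :-1, :]
        + fz[1:, :, :] - fz[:-1, :, :]
    )
    free = ~site.fixed_head
    scale = max(np.abs(np.concatenate([fx.ravel(), fy.ravel(), fz.ravel()])).max(), 1e-30)
    sol.residual_norm = float(np.abs(div[free]).max() / scale) if np.any(free) else 0.0
    return sol


# ---------------------------------------------------------------------------
# transport
# ---------------------------------------------------------------------------


def simulate_plume(
    flow: FlowSolution,
    initial: PlumeState,
    *,
    retardation: float = 1.0,
    decay: float = 0.0,
    dispersivities: tuple[float, float] = (1.0, 0.1),
    molecular_diffusion: float = 0.0,
    times=(1.0, 183.0, 365.0, 730.0, 1825.0),
    courant: float = 0.9,
) -> list[PlumeState]:
    """Forward plume transport with no persistent source.

    Explicit upwind advection and explicit velocity-dependent dispersion
    with internal sub-stepping to the stability limits; first-order aqueous
    decay applied analytically per sub-step (total-mass rate k/R under
    equilibrium sorption).  Returns one :class:`PlumeState` per requested
    output time.
    """
    site = flow.site
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0) or np.any(times < 0):
        raise InvalidSpecError("output times must be non-negative and increasing")
    if retardation < 1.0:
        raise InvalidSpecError("retardation factor must be >= 1")
    if decay < 0:
        raise InvalidSpecError("decay must be non-negative")
    alpha_l, alpha_t = dispersivities
    if alpha_l < 0 or alpha_t < 0:
        raise InvalidSpecError("dispersivities must be non-negative")

    c = initial.concentration.astype(float).copy()
    if c.shape != (site.nlayers, site.ny, site.nx):
        raise InvalidSpecError("initial concentration shape does not match the grid")

    theta = site.porosity
    vol = site.cell_volume
    water = theta * vol * retardation  # storage volume per cell, m^3
    fx, fy, fz = flow.volumetric_face_fluxes()
    dz = site.layer_thickness[:, None, None]

    # net boundary (constant-head) water source per cell, m^3/d
    div = (
        fx[:, :, 1:] - fx[:, :, :-1]
        + fy[:, 1:, :] - fy[:, :-1, :]
        + fz[1:, :, :] - fz[:-1, :, :]
    )
    src = np.where(site.fixed_head, div, 0.0)  # >0: cell exports water to the domain? no:
    # div > 0 means more leaves through faces than enters, so the fixed cell
    # injects water (at zero concentration); div < 0 means it extracts water
    # at its own concentration.

    vx, vy, vz = flow.pore_velocity()
    d_x = alpha_l * np.abs(vx) + alpha_t * (np.abs(vy) + np.abs(vz)) + molecular_diffusion
    d_y = alpha_l * np.abs(vy) + alpha_t * (np.abs(vx) + np.abs(vz)) + molecular_diffusion
    d_z = alpha_l * np.abs(vz) + alpha_t * (np.abs(vx) + np.abs(vy)) + molecular_diffusion

    # face diffusive conductances theta*D*A/d, m^3/d (arithmetic means)
    def face_mean(a, axis):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        return 0.5 * (a[tuple(sl_lo)] + a[tuple(sl_hi)])

    gx = face_mean(theta * d_x, 2) * (site.dy * dz) / site.dx
    gy = face_mean(theta * d_y, 1) * (site.dx * dz) / site.dy
    dz_pair = 0.5 * (site.layer_thickness[:-1] + site.layer_thickness[1:])[:, None, None]
    gz = face_mean(theta * d_z, 0) * (site.dx * site.dy) / dz_pair

    # stability limits
    outflux = (
        np.maximum(fx[:, :, 1:], 0) + np.maximum(-fx[:, :, :-1], 0)
        + np.maximum(fy[:, 1:, :], 0) + np.maximum(-fy[:, :-1, :], 0)
        + np.maximum(fz[1:, :, :], 0) + np.maximum(-fz[:-1, :, :], 0)
        + np.maximum(-src, 0)
    )
    with np.errstate(divide="ignore"):
        dt_adv = courant * np.min(np.where(outflux > 0, water / np.maximum(outflux, 1e-300), np.inf))
        g_sum = np.zeros_like(c)
        g_sum[:, :, :-1] += gx
        g_sum[:, :, 1:] += gx
        g_sum[:, :-1, :] += gy
        g_sum[:, 1:, :] += gy
        g_sum[:-1, :, :] += gz
        g_sum[1:, :, :] += gz
        dt_disp = courant * 0.5 * np.min(
            np.where(g_sum > 0, water / np.maximum(g_sum, 1e-300), np.inf)
        )
    dt_max = min(dt_adv, dt_disp)
    if not math.isfinite(dt_max):
        dt_max = math.inf

    out: list[PlumeState] = []
    t_now = 0.0
    for t_target in times:
        span = t_target - t_now
        if span > 0:
            n_sub = max(1, int(math.ceil(span / dt_max))) if math.isfinite(dt_max) else 1
            dt = span / n_sub
            for _ in range(n_sub):
                # upwind advective face loads, g/d
                adv_x = np.where(fx[:, :, 1:-1] > 0, c[:, :, :-1], c[:, :, 1:]) * fx[:, :, 1:-1]
                adv_y = np.where(fy[:, 1:-1, :] > 0, c[:, :-1, :], c[:, 1:, :]) * fy[:, 1:-1, :]
                adv_z = np.where(fz[1:-1, :, :] > 0, c[:-1, :, :], c[1:, :, :]) * fz[1:-1, :, :]
                dif_x = gx * (c[:, :, 1:] - c[:, :, :-1])
                dif_y = gy * (c[:, 1:, :] - c[:, :-1, :])
                dif_z = gz * (c[1:, :, :] - c[:-1, :, :])

                rate = np.zeros_like(c)
                rate[:, :, :-1] -= adv_x
                rate[:, :, 1:] += adv_x
                rate[:, :-1, :] -= adv_y
                rate[:, 1:, :] += adv_y
                rate[:-1, :, :] -= adv_z
                rate[1:, :, :] += adv_z
                rate[:, :, :-1] += dif_x
                rate[:, :, 1:] -= dif_x
                rate[:, :-1, :] += dif_y
                rate[:, 1:, :] -= dif_y
                rate[:-1, :, :] += dif_z
                rate[1:, :, :] -= dif_z
                # constant-head water exchange: extraction (src < 0) removes
                # mass at the cell concentration; injection enters clean
                rate += np.where(src < 0, src * c, 0.0)

                c = c + dt * rate / water
                if decay > 0:
                    c *= math.exp(-decay * dt / retardation)
                if not np.all(np.isfinite(c)):
                    raise NumericsError(f"transport produced non-finite values near t={t_now}")
            c = np.clip(c, 0.0, None)
        t_now = t_target
        out.append(PlumeState(c.copy(), time=t_target, retardation=retardation, decay=decay))
    return out


def total_mass(state: PlumeState, site: SiteModel, retardation: float | None = None) -> float:
    """Total aqueous + sorbed plume mass, g (equilibrium sorption)."""
    r = state.retardation if retardation is None else retardation
    return float(np.sum(state.concentration * site.porosity * site.cell_volume) * r)


@dataclass
class PlumeMetrics:
    """Summary metrics of one plume state."""

    max_concentration: float                   # mg/L
    centroid: tuple[float, float]              # (x, y), m, mass-weighted
    cell_counts: dict                          # threshold -> 3-D cell count
    areas: dict                                # threshold -> plan-view area, m^2


def plume_metrics(state: PlumeState, thresholds, site: SiteModel) -> PlumeMetrics:
    """Maximum, mass centroid, and threshold exceedance counts/areas.

    The area for a threshold is the plan-view footprint: the number of map
    columns whose maximum over layers meets the threshold (inclusive),
    times dx * dy.
    """
    c = state.concentration
    if c.size == 0:
        raise InvalidSpecError("empty grid")
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    counts = {}
    areas = {}
    plan_max = c.max(axis=0)
    for thr in thresholds:
        counts[float(thr)] = int(np.count_nonzero(c >= thr))
        areas[float(thr)] = float(np.count_nonzero(plan_max >= thr) * site.dx * site.dy)
    mass = c * site.porosity * site.cell_volume
    m_tot = mass.sum()
    if m_tot > 0:
        xs = (np.arange(site.nx) + 0.5) * site.dx
        ys = (np.arange(site.ny) + 0.5) * site.dy
        cx = float(np.sum(mass.sum(axis=(0, 1)) * xs) / m_tot)
        cy = float(np.sum(mass.sum(axis=(0, 2)) * ys) / m_tot)
    else:
        cx = cy = float("nan")
    return PlumeMetrics(
        max_concentration=float(c.max()),
        centroid=(cx, cy),
        cell_counts=counts,
        areas=areas,
    )


def compare_wells(wells, states) -> dict:
    """Per-well mean squared error between observed and simulated series.

    Simulated concentrations are linearly interpolated in time at the
    observation instants; observation times must lie within the simulated
    range.  Returns ``{well_id: MSE}`` in (mg/L)^2.
    """
    if not states:
        raise InvalidSpecError("no simulated states supplied")
    shape = states[0].concentration.shape
    sim_times = np.array([st.time for st in states])
    result = {}
    for well in wells:
        if not (
            0 <= well.layer < shape[0]
            and 0 <= well.row < shape[1]
            and 0 <= well.col < shape[2]
        ):
            raise IndexError(f"well {well.well_id} lies outside the grid")
        if well.times.size == 0:
            raise InvalidSpecError(f"well {well.well_id} has no observations")
        if well.times.min() < sim_times.min() or well.times.max() > sim_times.max():
            raise InvalidSpecError(
                f"well {well.well_id} observation times fall outside the simulated range"
            )
        series = np.array([st.concentration[well.layer, well.row, well.col] for st in states])
        sim = np.interp(well.times, sim_times, series)
        result[well.well_id] = float(np.mean((well.concentrations - sim) ** 2))
    return result
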
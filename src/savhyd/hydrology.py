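"""Daily surface-water and two-layer soil-moisture dynamics.

Each grid cell carries a surface-water store (mm) and two soil buckets
(volumetric moisture in an upper and a lower layer).  The daily sequence is
fixed: precipitation -> infiltration -> lateral runoff routing -> percolation
-> upper-to-lower diffusion -> soil evaporation (upper layer) -> plant
transpiration (both layers, per strategy type).

Vegetation feeds back on every loss pathway: cover raises effective
infiltrability (root macropores), slows runoff (surface roughness), shades
the soil (less evaporation) and withdraws water through roots (more
transpiration).  Annual grasses root only in the upper layer; perennial
grasses and shrubs split their roots across both layers.

Potential evapotranspiration is a temperature-driven Hargreaves-type
simplification ``PET = 0.0023 * Ra(d) * (T + 17.8)`` where ``Ra(d)`` is a
fixed seasonal radiation proxy (units folded in, peaking at the austral
summer solstice); temperature is the only atmospheric forcing available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .climate import DAYS_PER_YEAR
from .terrain import SoilParams, TerrainGrid

#: fraction of saturated conductivity retained by bare soil
DEFAULT_C0 = 0.4
#: roughness coefficient: runoff transfer scales with (1 - r * cover)
DEFAULT_ROUGHNESS = 0.8
#: shading coefficient: evaporation scales with (1 - s * cover)
DEFAULT_SHADING = 0.8

_RA_MEAN = 50.0
_RA_AMP = 0.18
_RA_PEAK_DOY = 354  # austral summer solstice


def pet(temp: float | np.ndarray, doy: int | np.ndarray) -> float | np.ndarray:
    """Potential evapotranspiration, mm/day."""
    ra = _RA_MEAN * (1.0 + _RA_AMP * np.cos(2 * np.pi * (np.asarray(doy) - _RA_PEAK_DOY) / DAYS_PER_YEAR))
    return np.maximum(0.0, 0.0023 * ra * (np.asarray(temp) + 17.8))


@dataclass
class CellHydroState:
    """Grid hydrological state: surface water (mm) and layer moistures."""

    surface_water: np.ndarray  # mm, shape (n,)
    theta_upper: np.ndarray    # vol fraction, shape (n,)
    theta_lower: np.ndarray    # vol fraction, shape (n,)

    @classmethod
    def initial(cls, n_cells: int, soil: SoilParams) -> "CellHydroState":
        return cls(
            surface_water=np.zeros(n_cells),
            theta_upper=np.full(n_cells, soil.field_capacity * 0.6),
            theta_lower=np.full(n_cells, soil.field_capacity * 0.8),
        )

    def validate(self, soil: SoilParams) -> None:
        for arr in (self.surface_water, self.theta_upper, self.theta_lower):
            if not np.all(np.isfinite(arr)):
                raise ValueError("NaN/inf in hydrological state")
        if np.any(self.surface_water < -1e-12):
            raise ValueError("negative surface water")
        for th in (self.theta_upper, self.theta_lower):
            if np.any(th < soil.residual_water_content - 1e-9) or np.any(
                th > soil.porosity + 1e-9
            ):
                raise ValueError("theta outside [residual, porosity]")


def infiltrate(
    surface_water: np.ndarray,
    total_cover: np.ndarray,
    soil: SoilParams,
    theta_upper: np.ndarray,
    c0: float = DEFAULT_C0,
) -> np.ndarray:
    """Daily infiltration into the upper layer, mm.

    Limited by supply, by remaining pore space, and by a cover-enhanced
    saturated conductivity ``Ksat * (c0 + (1-c0)*cover)``.
    """
    total_cover = np.asarray(total_cover, float)
    if np.any(total_cover < 0) or np.any(total_cover > 1 + 1e-9):
        raise ValueError("total_cover must be in [0,1]")
    du = soil.layer_depths[0]
    capacity = np.maximum(0.0, (soil.porosity - np.asarray(theta_upper)) * du)
    ksat_eff = soil.sat_conductivity * (c0 + (1.0 - c0) * total_cover)
    return np.minimum(np.minimum(np.asarray(surface_water, float), capacity), ksat_eff)


def compute_receivers(dem: TerrainGrid) -> np.ndarray:
    """Steepest-descent receiver cell index per cell; -1 for flat/pit cells.

    Lateral boundaries are closed: water never leaves the grid edge, so grid
    totals are conserved by routing.
    """
    rows, cols = dem.shape
    elev = dem.elevation
    n = rows * cols
    receivers = np.full(n, -1, dtype=np.int64)
    idx = np.arange(n).reshape(rows, cols)
    best_drop = np.zeros((rows, cols))
    best_recv = np.full((rows, cols), -1, dtype=np.int64)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            dist = np.hypot(dr, dc)
            r0, r1 = max(0, -dr), rows - max(0, dr)
            c0_, c1 = max(0, -dc), cols - max(0, dc)
            src = (slice(r0, r1), slice(c0_, c1))
            dst = (slice(r0 + dr, r1 + dr), slice(c0_ + dc, c1 + dc))
            drop = (elev[src] - elev[dst]) / dist
            better = drop > best_drop[src]
            best_drop[src] = np.where(better, drop, best_drop[src])
            best_recv[src] = np.where(better, idx[dst], best_recv[src])
    receivers = best_recv.ravel()
    return receivers


def route_runoff(
    surface_water_grid: np.ndarray,
    dem: TerrainGrid,
    cover_grid: np.ndarray,
    receivers: np.ndarray | None = None,
    roughness: float = DEFAULT_ROUGHNESS,
) -> tuple[np.ndarray, np.ndarray]:
    """Move excess surface water one cell downslope.

    Returns ``(runoff_out, runon_in)`` in mm per cell.  The transferred
    amount is the cell's surface water scaled by ``(1 - roughness*cover)``;
    flat or pit cells retain their water.  Total water is conserved.
    """
    sw = np.asarray(surface_water_grid, float).ravel()
    cov = np.asarray(cover_grid, float).ravel()
    if sw.size != dem.elevation.size or cov.size != sw.size:
        raise ValueError("grid shape mismatch")
    if receivers is None:
        receivers = compute_receivers(dem)
    moving = receivers >= 0
    runoff_out = np.zeros_like(sw)
    runoff_out[moving] = sw[moving] * np.clip(1.0 - roughness * cov[moving], 0.0, 1.0)
    runon_in = np.zeros_like(sw)
    np.add.at(runon_in, receivers[moving], runoff_out[moving])
    return runoff_out, runon_in


def evaporate(
    theta_upper: np.ndarray,
    total_cover: np.ndarray,
    temp: float,
    soil: SoilParams,
    doy: int = 0,
    shading: float = DEFAULT_SHADING,
    pet_today: float | None = None,
) -> np.ndarray:
    """Bare-soil evaporation from the upper layer, mm/day."""
    th = np.asarray(theta_upper, float)
    wetness = np.clip(
        (th - soil.residual_water_content)
        / (soil.field_capacity - soil.residual_water_content),
        0.0,
        1.0,
    )
    if pet_today is None:
        pet_today = pet(temp, doy)
    e = (
        pet_today
        * soil.evaporation_constant
        * wetness
        * np.clip(1.0 - shading * np.asarray(total_cover, float), 0.0, 1.0)
    )
    avail = np.maximum(0.0, (th - soil.residual_water_content) * soil.layer_depths[0])
    return np.minimum(e, avail)


def uptake_response(theta: np.ndarray, wilting_point: np.ndarray, field_capacity: float) -> np.ndarray:
    """Water-stress response g: 0 at the plant wilting point, 1 at field capacity."""
    return np.clip(
        (theta[..., None] - wilting_point) / (field_capacity - wilting_point), 0.0, 1.0
    )


def transpire(
    theta_upper: np.ndarray,
    theta_lower: np.ndarray,
    cover_by_type: np.ndarray,
    uptake_rate: np.ndarray,
    wilting_point: np.ndarray,
    root_frac_upper: np.ndarray,
    root_frac_lower: np.ndarray,
    soil: SoilParams,
    temp: float,
    doy: int = 0,
    pet_today: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-type transpiration from each layer, mm/day; shapes (n, T).

    Demand per type and layer is PET * cover * uptake_rate * root_frac * g(theta);
    when summed demand exceeds the water available above the least demanding
    wilting point, all withdrawals are rationed proportionally.
    """
    cover = np.asarray(cover_by_type, float)
    if pet_today is None:
        pet_today = pet(temp, doy)
    wilt_floor = float(np.min(wilting_point))

    out = []
    for theta, depth, rf in (
        (np.asarray(theta_upper, float), soil.layer_depths[0], root_frac_upper),
        (np.asarray(theta_lower, float), soil.layer_depths[1], root_frac_lower),
    ):
        g = uptake_response(theta, wilting_point, soil.field_capacity)
        demand = pet_today * cover * (uptake_rate * rf) * g
        total = demand.sum(axis=-1)
        avail = np.maximum(0.0, (theta - wilt_floor) * depth)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(total > avail, np.where(total > 0, avail / np.maximum(total, 1e-300), 1.0), 1.0)
        out.append(demand * scale[..., None])
    return out[0], out[1]


def step_day(
    state: CellHydroState,
    precip: float,
    temp: float,
    doy: int,
    cover_by_type: np.ndarray,
    strat,
    soil: SoilParams,
    dem: TerrainGrid | None = None,
    receivers: np.ndarray | None = None,
    c0: float = DEFAULT_C0,
    roughness: float = DEFAULT_ROUGHNESS,
    shading: float = DEFAULT_SHADING,
) -> dict:
    """Advance the grid one day in place; returns the day's fluxes.

    ``strat`` is any object exposing per-type arrays ``uptake_rate``,
    ``wilting_point``, ``root_frac_upper``, ``root_frac_lower`` (see
    :class:`savhyd.strategies.StrategySet`).
    """
    du, dl = soil.layer_depths
    sw = state.surface_water
    cover = np.asarray(cover_by_type, float)
    total_cover = cover.sum(axis=-1)
    if not np.isfinite(precip):
        raise ValueError("NaN in forcing")

    sw += precip

    infil = infiltrate(sw, total_cover, soil, state.theta_upper, c0=c0)
    sw -= infil
    state.theta_upper += infil / du

    runoff = np.zeros_like(sw)
    runon = np.zeros_like(sw)
    if dem is not None and not dem.is_flat and np.any(sw > 0):
        runoff, runon = route_runoff(sw, dem, total_cover, receivers, roughness)
        sw += runon - runoff
        # routed water gets a second infiltration opportunity downslope
        infil2 = infiltrate(sw, total_cover, soil, state.theta_upper, c0=c0)
        sw -= infil2
        state.theta_upper += infil2 / du
        infil = infil + infil2

    perc = np.minimum(
        np.maximum(0.0, (state.theta_upper - soil.field_capacity) * du),
        soil.sat_conductivity,
    )
    room_lower = np.maximum(0.0, (soil.porosity - state.theta_lower) * dl)
    perc = np.minimum(perc, room_lower)
    state.theta_upper -= perc / du
    state.theta_lower += perc / dl

    deep = np.minimum(
        np.maximum(0.0, (state.theta_lower - soil.field_capacity) * dl),
        soil.sat_conductivity,
    )
    state.theta_lower -= deep / dl

    diff = np.where(state.theta_upper > state.theta_lower, soil.diffusion_coeff, 0.0)
    diff = np.minimum(
        diff, np.maximum(0.0, (state.theta_upper - soil.residual_water_content) * du)
    )
    diff = np.minimum(diff, np.maximum(0.0, (soil.porosity - state.theta_lower) * dl))
    state.theta_upper -= diff / du
    state.theta_lower += diff / dl

    pet_today = float(pet(temp, doy))
    evap = evaporate(
        state.theta_upper, total_cover, temp, soil, doy, shading, pet_today=pet_today
    )
    state.theta_upper -= evap / du

    t_up, t_low = transpire(
        state.theta_upper,
        state.theta_lower,
        cover,
        strat.uptake_rate,
        strat.wilting_point,
        strat.root_frac_upper,
        strat.root_frac_lower,
        soil,
        temp,
        doy,
        pet_today=pet_today,
    )
    state.theta_upper -= t_up.sum(axis=-1) / du
    state.theta_lower -= t_low.sum(axis=-1) / dl

    return {
        "infiltration": infil,
        "runoff": runoff,
        "runon": runon,
        "percolation": perc,
        "deep_drainage": deep,
        "diffusion": diff,
        "evaporation": evap,
        "transp_upper": t_up,
        "transp_lower": t_low,
    }


def simulate_column(soil: SoilParams, climate) -> tuple[np.ndarray, np.ndarray]:
    """Bare-soil single-cell run; returns daily (theta_upper, theta_lower).

    Used by the soil-calibration harness, where observed station moisture is
    compared against simulated moisture under the recorded weather.
    """
    from .strategies import StrategySet

    n_days = climate.n_days
    state = CellHydroState.initial(1, soil)
    cover = np.zeros((1, 1))
    strat = StrategySet.empty()
    theta_u = np.empty(n_days)
    theta_l = np.empty(n_days)
    for d in range(n_days):
        step_day(
            state,
            float(climate.precip[d]),
            float(climate.temp[d]),
            d % DAYS_PER_YEAR,
            cover,
            strat,
            soil,
        )
        theta_u[d] = state.theta_upper[0]
        theta_l[d] = state.theta_lower[0]
    return theta_u, theta_l
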
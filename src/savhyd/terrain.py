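"""Terrain grids and soil parameterisation.

The landscape is a rectangular grid of square cells.  Digital elevation data
arrive at coarse resolution and are bilinearly interpolated to the model
resolution.  Soil hydraulic parameters follow pedotransfer presets for the
site texture class (loamy sand) and can be refined against an observed
soil-moisture series by a deterministic grid-search calibration that minimises
RMSE between observed and simulated moisture.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import itertools

import numpy as np
from scipy.interpolate import RegularGridInterpolator


@dataclass
class TerrainGrid:
    """Elevation field (m) on square cells of side ``cell_size`` (m)."""

    elevation: np.ndarray
    cell_size: float = 5.0

    def __post_init__(self):
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.ndim != 2:
            raise ValueError("elevation must be a 2-D grid")
        if not np.all(np.isfinite(self.elevation)):
            raise ValueError("elevation must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    @property
    def is_flat(self) -> bool:
        return bool(np.ptp(self.elevation) == 0.0)


def flat_terrain(rows: int = 30, cols: int = 30, elevation: float = 1195.0,
                 cell_size: float = 5.0) -> TerrainGrid:
    """Level plain at the site's altitude; the default synthetic DEM."""
    return TerrainGrid(np.full((rows, cols), float(elevation)), cell_size)


def interpolate_dem(coarse: TerrainGrid, target_cell: float) -> TerrainGrid:
    """Bilinearly refine a DEM to a finer cell size.

    The coarse cell size must be an integer multiple of ``target_cell``
    (e.g. 30 m -> 5 m).  Corner node values are preserved.
    """
    ratio = coarse.cell_size / target_cell
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"target cell {target_cell} must divide coarse cell {coarse.cell_size}"
        )
    ratio = int(round(ratio))
    rows, cols = coarse.shape
    y = np.arange(rows) * coarse.cell_size
    x = np.arange(cols) * coarse.cell_size
    interp = RegularGridInterpolator((y, x), coarse.elevation, method="linear")
    fy = np.arange((rows - 1) * ratio + 1) * target_cell
    fx = np.arange((cols - 1) * ratio + 1) * target_cell
    yy, xx = np.meshgrid(fy, fx, indexing="ij")
    fine = interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(yy.shape)
    return TerrainGrid(fine, target_cell)


@dataclass(frozen=True)
class SoilParams:
    """Two-layer bucket soil.

    Volumetric fractions; depths in mm; conductivity in mm/day.  The
    evaporation constant folds soil-crust suppression of bare-soil
    evaporation into a single multiplier.
    """

    layer_depths: tuple[float, float] = (300.0, 700.0)  # upper, lower, mm
    porosity: float = 0.437
    field_capacity: float = 0.125
    residual_water_content: float = 0.035
    soil_wilting_point: float = 0.055
    sat_conductivity: float = 1500.0  # mm/day
    evaporation_constant: float = 0.10
    diffusion_coeff: float = 0.02     # mm/day, upper->lower only
    texture_label: str = "loamy sand"

    def __post_init__(self):
        if not (
            self.residual_water_content
            < self.soil_wilting_point
            < self.field_capacity
            < self.porosity
        ):
            raise ValueError(
                "require residual < soil wilting < field capacity < porosity"
            )
        if self.diffusion_coeff < 0:
            raise ValueError("diffusion_coeff must be >= 0")
        if min(self.layer_depths) <= 0:
            raise ValueError("layer depths must be positive")
        if not (0.0 <= self.evaporation_constant <= 1.0):
            raise ValueError("evaporation_constant must be in [0,1]")


LOAMY_SAND = SoilParams()


def rmse(observed: np.ndarray, simulated: np.ndarray) -> float:
    observed = np.asarray(observed, float)
    simulated = np.asarray(simulated, float)
    if observed.shape != simulated.shape:
        raise ValueError("length mismatch between observed and simulated series")
    return float(np.sqrt(np.mean((observed - simulated) ** 2)))


def calibrate_soil(
    observed: np.ndarray,
    candidate_grid: dict[str, list[float]],
    climate,
    base: SoilParams = LOAMY_SAND,
    simulate=None,
    observed_layer: str = "upper",
) -> tuple[SoilParams, float]:
    """Grid-search soil parameters minimising RMSE against observed moisture.

    ``candidate_grid`` maps SoilParams field names to candidate values; the
    full Cartesian product is scanned in deterministic order and ties keep the
    first-encountered candidate.  ``simulate(params, climate) -> series``
    defaults to the single-cell bare-soil column model from
    :mod:`savhyd.hydrology`.
    """
    observed = np.asarray(observed, float)
    if observed.size == 0:
        raise ValueError("empty observed series")
    if not candidate_grid or any(len(v) == 0 for v in candidate_grid.values()):
        raise ValueError("empty candidate set")
    if simulate is None:
        from .hydrology import simulate_column

        def simulate(params, clim):
            theta_u, theta_l = simulate_column(params, clim)
            return theta_u if observed_layer == "upper" else theta_l

    names = list(candidate_grid)
    best: tuple[SoilParams, float] | None = None
    for combo in itertools.product(*(candidate_grid[n] for n in names)):
        params = replace(base, **dict(zip(names, combo)))
        sim = np.asarray(simulate(params, climate), float)
        err = rmse(observed, sim)
        if best is None or err < best[1]:
            best = (params, err)
    return best


# ---------------------------------------------------------------------------
# DEM I/O: ESRI ASCII grid and plain CSV matrix

def write_esri_ascii(grid: TerrainGrid, path) -> None:
    rows, cols = grid.shape
    header = (
        f"ncols {cols}\nnrows {rows}\nxllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize {grid.cell_size}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.elevation, fmt="%.6g")


def read_esri_ascii(path) -> TerrainGrid:
    meta: dict[str, float] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                meta[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    elev = np.array(rows)
    if "nrows" in meta and elev.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise ValueError("ESRI ASCII header does not match data shape")
    return TerrainGrid(elev, meta.get("cellsize", 5.0))


def write_dem_csv(grid: TerrainGrid, path) -> None:
    np.savetxt(path, grid.elevation, delimiter=",", fmt="%.6g")


def read_dem_csv(path, cell_size: float = 5.0) -> TerrainGrid:
    return TerrainGrid(np.loadtxt(path, delimiter=",", ndmin=2), cell_size)
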
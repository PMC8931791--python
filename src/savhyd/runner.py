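"""Scenario orchestration: daily hydrology, biweekly vegetation, annual
herbivory over 100-year runs with replicated stochastic climate.

Timing conventions
------------------
* The *fixed growing season* runs 1 October - 30 April; mortality, herbivory
  and drought-stress accounting follow it.
* The *variable wet season* of each hydrological year (1 July - 30 June) is
  the span between the first and last daily rain event >= 5 mm; biweekly
  vegetation updates and wet-season soil-moisture averaging follow it.
* Annual outputs are recorded at the growing-season end (30 April): standing
  cover just before herbivory, water-flux sums over the preceding 365 days,
  and the season's herbivory ledger.

Randomness is keyed by (master seed, replicate, year, process) so replicates
are order-independent and adding diagnostics never perturbs trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from . import hydrology as hyd
from . import vegetation as veg_mod
from .climate import ClimateConfig, ClimateSeries, DAYS_PER_YEAR, wet_season_bounds
from .herbivory import (
    BROWSING_FEEDING,
    GRAZING_FEEDING,
    FeedingSettings,
    apply_herbivory,
    rain_correction,
)
from .strategies import StrategySet, assemble_strategy_types
from .terrain import LOAMY_SAND, SoilParams, TerrainGrid, flat_terrain
from .vegetation import VegState, initial_veg_state

SEASON_END_DOY = 119    # 30 April (0-based, 365-day year)
SEASON_START_DOY = 273  # 1 October
GROWING_SEASON_DAYS = DAYS_PER_YEAR - SEASON_START_DOY + SEASON_END_DOY + 1
ANNUAL_SEED_FACTOR = 3.0  # seeds set per unit annual cover at season end
ANNUAL_SEED_RETENTION = 0.90  # annual seed-bank carryover between years
STOCKING_LEVELS = {"very_low": 50, "low": 40, "medium": 30, "high": 20, "very_high": 10}


@dataclass
class ScenarioConfig:
    """Land-use scenario and run settings."""

    land_use: str = "grazing"            # grazing | browsing
    stocking_rate: float = 40.0          # ha/LSU
    years: int = 100
    replicates: int = 30
    rows: int = 30
    cols: int = 30
    cell_size: float = 5.0               # m
    seed: int = 0
    feeding: FeedingSettings | None = None
    soil: SoilParams = field(default_factory=lambda: LOAMY_SAND)
    climate_config: ClimateConfig = field(default_factory=ClimateConfig)
    init_meta_cover: dict = field(
        default_factory=lambda: {"shrub": 0.20, "perennial": 0.20, "annual": 0.05}
    )
    wue: float = veg_mod.DEFAULT_WUE
    b0: float = veg_mod.DEFAULT_B0
    est_margin: float = veg_mod.DEFAULT_EST_MARGIN
    ld_rate: float = veg_mod.DEFAULT_LD_RATE
    stress_margin: float = veg_mod.DEFAULT_STRESS_MARGIN
    p_est: dict = field(default_factory=lambda: dict(veg_mod.DEFAULT_P_EST))

    def __post_init__(self):
        if self.stocking_rate <= 0:
            raise ValueError("stocking_rate must be positive")
        if self.land_use not in ("grazing", "browsing"):
            raise ValueError(f"unknown land use {self.land_use!r}")
        if self.feeding is None:
            self.feeding = (
                GRAZING_FEEDING if self.land_use == "grazing" else BROWSING_FEEDING
            )

    @property
    def area_ha(self) -> float:
        return self.rows * self.cols * self.cell_size**2 / 1e4


@dataclass
class RunSummary:
    """Per-replicate, per-year outputs of one scenario."""

    config: ScenarioConfig
    type_ids: list[str]
    cover: pd.DataFrame      # replicate, year, one column per type (%, grid mean)
    water: pd.DataFrame      # replicate, year, total_cover_pct, t_mm, et_mm, ...
    herbivory: pd.DataFrame  # replicate, year, demand_kg, removed_kg, ...


def _stream(seed: int, replicate: int, year: int, process: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(replicate, year, process))
    return np.random.default_rng(ss)


def _wet_season_table(series: ClimateSeries, threshold: float = 5.0) -> dict[int, tuple[int, int]]:
    """Absolute-day wet-season bounds per hydrological year (keyed by the
    calendar year in which the hydro year starts)."""
    from .climate import HYDRO_YEAR_START

    bounds: dict[int, tuple[int, int]] = {}
    n = series.n_days
    for k in range(-1, series.years):
        a = k * DAYS_PER_YEAR + HYDRO_YEAR_START
        b = a + DAYS_PER_YEAR
        a_eff, b_eff = max(a, 0), min(b, n)
        if b_eff <= a_eff:
            continue
        res = wet_season_bounds(series.precip[a_eff:b_eff], threshold)
        if res is not None:
            bounds[k] = (res[0] + a_eff, res[1] + a_eff)
    return bounds


def run_replicate(
    config: ScenarioConfig,
    climate: ClimateSeries,
    strat: StrategySet,
    replicate: int,
    dem: TerrainGrid | None = None,
    dynamic_mask: np.ndarray | None = None,
    static_cover: np.ndarray | None = None,
) -> dict:
    """Simulate one climate replicate; returns per-year record arrays."""
    if climate.years < config.years:
        raise ValueError("climate series shorter than the requested run")
    n_types = len(strat)
    rows, cols = config.rows, config.cols
    n_cells = rows * cols
    if dem is None:
        dem = flat_terrain(rows, cols, cell_size=config.cell_size)
    receivers = None if dem.is_flat else hyd.compute_receivers(dem)
    soil = config.soil
    state = hyd.CellHydroState.initial(n_cells, soil)
    veg = initial_veg_state(strat, rows, cols, config.init_meta_cover)
    if static_cover is not None:
        veg.cover[..., ~dynamic_mask] = static_cover[~dynamic_mask]
    p_est = np.array([config.p_est[m] for m in strat.meta_labels])

    ws_table = _wet_season_table(climate)
    n_days = config.years * DAYS_PER_YEAR

    # season accumulators
    stress_days = np.zeros((n_cells, n_types))
    season_days = 0
    t_upper_sum = 0.0
    t_lower_sum = 0.0
    evap_sum = 0.0
    precip_sum = 0.0
    # biweek accumulators
    bw_transp = np.zeros((n_cells, n_types))
    bw_theta = 0.0
    bw_days = 0
    # wet-season soil moisture
    ws_theta_sum = 0.0
    ws_theta_days = 0
    effective_sr = config.stocking_rate

    years_out: list[dict] = []
    cover_out = np.zeros((config.years, n_types))
    rf_u = strat.root_frac_upper
    rf_l = strat.root_frac_lower
    wilt = strat.wilting_point

    use_kernel = dem.is_flat
    if use_kernel:
        from ._kernel import multi_day_flat

        scratch_u = np.empty(n_types)
        scratch_l = np.empty(n_types)
    doys = np.arange(n_days) % DAYS_PER_YEAR
    pet_series = hyd.pet(climate.temp[:n_days], doys)

    def do_biweek(year: int, doy: int, bw_theta: float, bw_days: int) -> None:
        nonlocal veg
        rng = _stream(config.seed, replicate, year, 1000 + doy)
        veg_mod.step_biweek(
            veg,
            bw_transp.reshape(rows, cols, n_types),
            np.full((rows, cols), bw_theta / bw_days),
            strat,
            effective_sr,
            rng,
            wue=config.wue,
            p_est=p_est,
            est_margin=config.est_margin,
            ld_rate=config.ld_rate,
            dynamic_mask=dynamic_mask,
        )
        if static_cover is not None:
            veg.cover[..., ~dynamic_mask] = static_cover[~dynamic_mask]
        bw_transp[:] = 0.0

    def do_season_end(year: int) -> None:
        nonlocal veg, effective_sr, season_days
        nonlocal t_upper_sum, t_lower_sum, evap_sum, precip_sum
        nonlocal ws_theta_sum, ws_theta_days
        # annuals shed seed before herbivores consume the standing crop
        ann = strat.is_annual
        veg.seed_bank[..., ann] = np.maximum(
            ANNUAL_SEED_RETENTION * veg.seed_bank[..., ann],
            ANNUAL_SEED_FACTOR * veg.cover[..., ann],
        )
        cf = rain_correction(precip_sum, config.climate_config.map_target)
        rng_h = _stream(config.seed, replicate, year, 1)
        outcome = apply_herbivory(
            veg, strat, config.feeding, config.stocking_rate,
            config.area_ha, cf, rng_h,
        )
        if static_cover is not None:
            veg.cover[..., ~dynamic_mask] = static_cover[~dynamic_mask]
        effective_sr = outcome.effective_sr
        # standing cover at season end, net of herbivore offtake
        cover_out[year] = veg.cover.reshape(n_cells, n_types).mean(axis=0) * 100.0
        stress_frac = stress_days / max(season_days, 1)
        new_cover = veg_mod.end_season_mortality(
            veg.cover.reshape(n_cells, n_types),
            stress_frac,
            strat.mrd,
            strat.is_annual,
            b0=config.b0,
        )
        veg.cover = new_cover.reshape(rows, cols, n_types)
        if static_cover is not None:
            veg.cover[..., ~dynamic_mask] = static_cover[~dynamic_mask]

        years_out.append(
            {
                "replicate": replicate,
                "year": year,
                "total_cover_pct": float(cover_out[year].sum()),
                "t_mm": t_upper_sum,
                "t_lower_mm": t_lower_sum,
                "et_mm": t_upper_sum + evap_sum,
                "precip_mm": precip_sum,
                "wet_season_theta_pct": (
                    100.0 * ws_theta_sum / ws_theta_days if ws_theta_days else np.nan
                ),
                "demand_kg": outcome.demand,
                "removed_kg": outcome.removed_total,
                "deficit_kg": outcome.deficit,
                "effective_sr": outcome.effective_sr,
            }
        )
        stress_days[:] = 0.0
        season_days = 0
        t_upper_sum = t_lower_sum = evap_sum = precip_sum = 0.0
        ws_theta_sum = 0.0
        ws_theta_days = 0

    if use_kernel:
        # segment the timeline so the compiled kernel runs uninterrupted
        # between vegetation/bookkeeping events
        cum_precip = np.concatenate([[0.0], np.cumsum(climate.precip[:n_days])])
        bps: set[int] = {n_days}
        for y in range(config.years):
            bps.add(y * DAYS_PER_YEAR + SEASON_END_DOY + 1)
            bps.add(y * DAYS_PER_YEAR + SEASON_START_DOY)
        for s, e in ws_table.values():
            bps.add(min(s, n_days))
            k = s + 14
            while k <= min(e, n_days - 1):
                bps.add(k)
                k += 14
            bps.add(min(e + 1, n_days))
        breakpoints = sorted(b for b in bps if 0 < b <= n_days)
        du_, dl_ = soil.layer_depths
        start = 0
        for end in breakpoints:
            if end <= start:
                continue
            year0, doy0 = divmod(start, DAYS_PER_YEAR)
            hydro_year = year0 if doy0 >= 181 else year0 - 1
            ws = ws_table.get(hydro_year)
            in_wet = ws is not None and ws[0] <= start <= ws[1]
            in_grow = doy0 >= SEASON_START_DOY or doy0 <= SEASON_END_DOY
            cover_flat = veg.cover.reshape(n_cells, n_types)
            t_up_s, t_low_s, ev_s, th_sum = multi_day_flat(
                state.surface_water, state.theta_upper, state.theta_lower,
                cover_flat, strat.uptake_rate, wilt, rf_u, rf_l,
                du_, dl_, soil.porosity, soil.field_capacity,
                soil.residual_water_content, soil.sat_conductivity,
                soil.evaporation_constant, soil.diffusion_coeff,
                hyd.DEFAULT_C0, hyd.DEFAULT_SHADING,
                climate.precip[start:end], pet_series[start:end],
                bw_transp, in_wet,
                stress_days, in_grow,
                scratch_u, scratch_l,
                config.stress_margin,
            )
            nseg = end - start
            t_upper_sum += t_up_s / n_cells
            t_lower_sum += t_low_s / n_cells
            evap_sum += ev_s / n_cells
            precip_sum += float(cum_precip[end] - cum_precip[start])
            if in_grow:
                season_days += nseg
            if in_wet:
                bw_theta += th_sum
                bw_days += nseg
                ws_theta_sum += th_sum
                ws_theta_days += nseg
            last = end - 1
            year_l, doy_l = divmod(last, DAYS_PER_YEAR)
            if in_wet and (last == ws[1] or bw_days >= 14):
                do_biweek(year_l, doy_l, bw_theta, bw_days)
                bw_theta = 0.0
                bw_days = 0
            if doy_l == SEASON_END_DOY:
                do_season_end(year_l)
            start = end
        return {"years": years_out, "cover": cover_out}

    for d in range(n_days):
        year, doy = divmod(d, DAYS_PER_YEAR)
        precip = float(climate.precip[d])
        temp = float(climate.temp[d])
        cover_flat = veg.cover.reshape(n_cells, n_types)

        hydro_year = year if doy >= 181 else year - 1  # hydro year starts 1 July
        ws = ws_table.get(hydro_year)
        in_wet_season = ws is not None and ws[0] <= d <= ws[1]
        in_growing_season = doy >= SEASON_START_DOY or doy <= SEASON_END_DOY

        fluxes = hyd.step_day(
            state, precip, temp, doy, cover_flat, strat, soil, dem, receivers
        )
        t_up = fluxes["transp_upper"]
        t_low = fluxes["transp_lower"]
        t_upper_sum += float(t_up.sum()) / n_cells
        t_lower_sum += float(t_low.sum()) / n_cells
        evap_sum += float(fluxes["evaporation"].sum()) / n_cells
        mean_thu = float(state.theta_upper.mean())
        if in_wet_season:
            bw_transp += t_up + t_low
        if in_growing_season:
            theta_eff = np.outer(state.theta_upper, rf_u) + np.outer(
                state.theta_lower, rf_l
            )
            stress_days += theta_eff < wilt + config.stress_margin
            season_days += 1
        precip_sum += precip

        if in_wet_season:
            bw_theta += mean_thu
            bw_days += 1
            ws_theta_sum += mean_thu
            ws_theta_days += 1
            if bw_days == 14 or d == ws[1]:
                do_biweek(year, doy, bw_theta, bw_days)
                bw_theta = 0.0
                bw_days = 0

        if doy == SEASON_END_DOY:
            do_season_end(year)

    return {"years": years_out, "cover": cover_out}


def scenario_label(config: ScenarioConfig) -> str:
    return f"{config.land_use}_{config.stocking_rate:g}"


def run_scenario(
    config: ScenarioConfig,
    climate_set: list[ClimateSeries],
    strat: StrategySet | None = None,
) -> RunSummary:
    """Run all climate replicates of one land-use scenario."""
    if len(climate_set) != config.replicates:
        raise ValueError(
            f"need {config.replicates} climate replicates, got {len(climate_set)}"
        )
    if strat is None:
        strat = assemble_strategy_types(land_use=config.land_use)
    water_rows: list[dict] = []
    cover_rows: list[dict] = []
    for rep, clim in enumerate(climate_set):
        rec = run_replicate(config, clim, strat, rep)
        water_rows.extend(rec["years"])
        for y in range(config.years):
            row = {"replicate": rep, "year": y}
            row.update(
                {tid: rec["cover"][y, j] for j, tid in enumerate(strat.ids)}
            )
            cover_rows.append(row)
    label = scenario_label(config)
    water = pd.DataFrame(water_rows)
    cover = pd.DataFrame(cover_rows)
    water.insert(0, "scenario", label)
    cover.insert(0, "scenario", label)
    herb_cols = ["scenario", "replicate", "year", "demand_kg", "removed_kg", "deficit_kg", "effective_sr"]
    return RunSummary(
        config=config,
        type_ids=list(strat.ids),
        cover=cover,
        water=water.drop(columns=["demand_kg", "removed_kg", "deficit_kg", "effective_sr"]),
        herbivory=water[herb_cols].copy(),
    )


def summarize_last20(summary: RunSummary, window: int = 20) -> dict:
    """Means +/- SD over the last ``window`` years x replicates.

    Returns per-variable overall mean/sd, the per-replicate means (for
    downstream statistics), and per-type mean cover.
    """
    years = summary.config.years
    if years < window:
        raise ValueError(f"need at least {window} simulated years, got {years}")
    sel_w = summary.water[summary.water["year"] >= years - window]
    sel_c = summary.cover[summary.cover["year"] >= years - window]
    num_w = sel_w.select_dtypes("number").drop(columns=["replicate", "year"])
    stats = pd.DataFrame({"mean": num_w.mean(), "sd": num_w.std(ddof=1)})
    per_rep = sel_w.groupby("replicate").mean(numeric_only=True).drop(columns=["year"])
    type_cover = sel_c.select_dtypes("number").drop(columns=["replicate", "year"]).mean()
    type_cover_per_rep = (
        sel_c.groupby("replicate").mean(numeric_only=True).drop(columns=["year"])
    )
    return {
        "stats": stats,
        "per_replicate": per_rep,
        "type_cover": type_cover,
        "type_cover_per_replicate": type_cover_per_rep,
        "annual": sel_w.reset_index(drop=True),
        "annual_cover": sel_c.reset_index(drop=True),
    }


# ---------------------------------------------------------------------------
# Trait-calibration community

def make_scan_evaluator(
    meta_label: str,
    parameter: str,
    land_use: str,
    seed: int,
    years: int = 100,
    replicates: int = 30,
    window: int = 20,
    stocking_rate: float = 40.0,
    rows: int = 30,
    cols: int = 30,
    climate_set: list[ClimateSeries] | None = None,
    config_kwargs: dict | None = None,
):
    """Evaluator for :func:`savhyd.strategies.scan_parameter`.

    Builds the four-type sensitivity community - altered type and same-meta
    base type dynamic, the other two meta base types static - and returns a
    callable mapping a trait value to the altered type's mean cover (%) over
    the last ``window`` years, averaged across climate replicates, at medium
    animal density.
    """
    from .climate import generate_replicates
    from .strategies import META_DEFAULTS, StrategyType

    if climate_set is None:
        climate_set = generate_replicates(ClimateConfig(), years, replicates, seed)
    feeding = GRAZING_FEEDING if land_use == "grazing" else BROWSING_FEEDING

    def evaluate(value: float) -> float:
        metas = META_DEFAULTS
        types = []
        dynamic = []
        for lbl in ("perennial", "shrub", "annual"):
            m = metas[lbl]
            types.append(
                StrategyType("base", m, m.t_veg, m.mrd, None, None,
                             m.uptake_rate, m.wilting_point)
            )
            dynamic.append(lbl == meta_label)
        m = metas[meta_label]
        kwargs = dict(t_veg=m.t_veg, mrd=m.mrd, herbivore_pref=None, defense=None,
                      uptake_rate=m.uptake_rate, wilting_point=m.wilting_point)
        kwargs[parameter] = value
        types.append(StrategyType("alt", m, **kwargs))
        dynamic.append(True)
        strat = StrategySet(types)
        dyn = np.array(dynamic)

        init = {"shrub": 0.20, "perennial": 0.20, "annual": 0.05}
        cfg = ScenarioConfig(
            land_use=land_use, stocking_rate=stocking_rate, years=years,
            replicates=len(climate_set), rows=rows, cols=cols, seed=seed,
            feeding=feeding, init_meta_cover=init, **(config_kwargs or {}),
        )
        static_cover = np.array(
            [init[t.meta.label] / (2 if t.meta.label == meta_label else 1)
             for t in types]
        )
        alt_idx = len(types) - 1
        covers = []
        for rep, clim in enumerate(climate_set):
            rec = run_replicate(
                cfg, clim, strat, rep, dynamic_mask=dyn, static_cover=static_cover
            )
            covers.append(rec["cover"][years - window :, alt_idx].mean())
        return float(np.mean(covers))

    return evaluate
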
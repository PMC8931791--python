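"""Stochastic daily weather generation for a semi-arid summer-rainfall savanna.

Rainfall is a two-state (wet/dry day) occurrence process restricted to the
wet-season months (October-April by default) with gamma-distributed event
depths.  Inter-annual variability far exceeds what a stationary daily process
can produce in drylands, so each rain year additionally carries a gamma
multiplier (mean 1) on event depths; its shape parameter sets the coefficient
of variation of annual sums.  Temperature is an annual sinusoid pinned through
the coolest (June) and warmest (October) monthly means plus i.i.d. Gaussian
daily noise.

All series are daily, 365-day years (no leap days).  The simulation's
"day 0" is 1 January.
"""

from __future__ import annotations

from dataclasses import dataclass
import io

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365

#: first day-of-year (0-based) of each calendar month in a 365-day year
_MONTH_STARTS = np.array([0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334])
_MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

#: 1 July, start of the hydrological year (wet season never straddles it)
HYDRO_YEAR_START = int(_MONTH_STARTS[6])


def month_of_day(doy: np.ndarray | int) -> np.ndarray | int:
    """Calendar month (1-12) for a 0-based day-of-year."""
    return np.searchsorted(_MONTH_STARTS, np.asarray(doy) % DAYS_PER_YEAR, side="right")


@dataclass(frozen=True)
class ClimateConfig:
    """Parameters of the stochastic weather generator.

    The default configuration reproduces the study climate: mean annual
    precipitation ~291.3 mm falling October-April, annual sums spanning
    roughly 50-840 mm, MAT 26 degC with June mean 19 and October mean 29.
    """

    map_target: float = 291.3          # mm/yr
    wet_season_months: frozenset[int] = frozenset({10, 11, 12, 1, 2, 3, 4})
    p_wet_day: float = 0.18            # per wet-season day
    event_mean: float | None = None    # mm; derived from map_target if None
    event_shape: float = 0.85          # gamma shape of event depths
    annual_cv_shape: float = 5.0       # gamma shape of the per-year multiplier
    dry_season_p_wet: float = 0.0      # negligible drizzle by default
    mat: float = 26.0                  # degC
    daily_sd: float = 2.0              # degC
    coolest_month_mean: float = 19.0   # June
    warmest_month_mean: float = 29.0   # October

    def __post_init__(self):
        if not (0.0 <= self.p_wet_day <= 1.0):
            raise ValueError(f"p_wet_day must be in [0,1], got {self.p_wet_day}")
        if not (0.0 <= self.dry_season_p_wet <= 1.0):
            raise ValueError("dry_season_p_wet must be in [0,1]")
        if self.daily_sd < 0:
            raise ValueError("daily_sd must be non-negative")
        if self.event_mean is None:
            n_wet = self.n_wet_season_days
            if self.p_wet_day > 0 and n_wet > 0:
                object.__setattr__(
                    self, "event_mean", self.map_target / (self.p_wet_day * n_wet)
                )
            else:
                object.__setattr__(self, "event_mean", 1.0)
        if self.event_mean <= 0:
            raise ValueError("event_mean must be positive")

    @property
    def n_wet_season_days(self) -> int:
        return int(sum(_MONTH_LENGTHS[m - 1] for m in self.wet_season_months))

    @property
    def expected_annual_sum(self) -> float:
        return self.p_wet_day * self.n_wet_season_days * self.event_mean


@dataclass
class ClimateSeries:
    """Daily precipitation (mm) and mean temperature (degC) series."""

    precip: np.ndarray
    temp: np.ndarray
    years: int

    def __post_init__(self):
        self.precip = np.asarray(self.precip, dtype=float)
        self.temp = np.asarray(self.temp, dtype=float)
        if self.precip.shape != self.temp.shape:
            raise ValueError("precip and temp must have equal length")
        if np.any(self.precip < 0):
            raise ValueError("precipitation must be non-negative")

    @property
    def n_days(self) -> int:
        return self.precip.size

    def annual_sums(self) -> np.ndarray:
        """Calendar-year precipitation totals, mm."""
        return self.precip.reshape(self.years, DAYS_PER_YEAR).sum(axis=1)


def _wet_season_day_mask(config: ClimateConfig) -> np.ndarray:
    months = month_of_day(np.arange(DAYS_PER_YEAR))
    return np.isin(months, list(config.wet_season_months))


def generate_precipitation(
    config: ClimateConfig, years: int, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Generate a daily precipitation series of length 365*years (mm/day)."""
    if years < 1:
        raise ValueError(f"years must be >= 1, got {years}")
    rng = np.random.default_rng(seed)
    n = years * DAYS_PER_YEAR
    in_season = np.tile(_wet_season_day_mask(config), years)

    p = np.where(in_season, config.p_wet_day, config.dry_season_p_wet)
    wet = rng.random(n) < p
    depths = np.zeros(n)
    k = config.event_shape
    nwet = int(wet.sum())
    if nwet:
        depths[wet] = rng.gamma(k, config.event_mean / k, size=nwet)
    # per rain-year (Jul-Jun) wetness multiplier, mean 1
    a = config.annual_cv_shape
    year_mult = rng.gamma(a, 1.0 / a, size=years + 1)
    doy_all = np.arange(n)
    rain_year = (doy_all + (DAYS_PER_YEAR - HYDRO_YEAR_START)) // DAYS_PER_YEAR
    return depths * year_mult[rain_year]


def _temperature_harmonic(config: ClimateConfig) -> tuple[float, float]:
    """Solve T(d) = mat + a cos(w d) + b sin(w d) through the June and
    October monthly means (mid-month days 166 and 288)."""
    w = 2 * np.pi / DAYS_PER_YEAR
    d_jun, d_oct = 166.0, 288.0
    A = np.array(
        [[np.cos(w * d_jun), np.sin(w * d_jun)], [np.cos(w * d_oct), np.sin(w * d_oct)]]
    )
    rhs = np.array(
        [config.coolest_month_mean - config.mat, config.warmest_month_mean - config.mat]
    )
    a, b = np.linalg.solve(A, rhs)
    return float(a), float(b)


def temperature_climatology(config: ClimateConfig) -> np.ndarray:
    """Noise-free 365-day mean temperature cycle."""
    a, b = _temperature_harmonic(config)
    w = 2 * np.pi / DAYS_PER_YEAR
    d = np.arange(DAYS_PER_YEAR)
    return config.mat + a * np.cos(w * d) + b * np.sin(w * d)


def generate_temperature(
    config: ClimateConfig, years: int, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Daily mean temperature: sinusoid through the June/October pins + noise."""
    if years < 1:
        raise ValueError(f"years must be >= 1, got {years}")
    rng = np.random.default_rng(seed)
    base = np.tile(temperature_climatology(config), years)
    if config.daily_sd > 0:
        base = base + rng.normal(0.0, config.daily_sd, size=base.size)
    return base


def generate_climate(
    config: ClimateConfig, years: int, seed: int | np.random.SeedSequence
) -> ClimateSeries:
    """Generate coupled precipitation and temperature series."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_precip, s_temp = ss.spawn(2)
    return ClimateSeries(
        precip=generate_precipitation(config, years, s_precip),
        temp=generate_temperature(config, years, s_temp),
        years=years,
    )


def generate_replicates(
    config: ClimateConfig, years: int, replicates: int, seed: int
) -> list[ClimateSeries]:
    """Independent climate replicates from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [generate_climate(config, years, child) for child in ss.spawn(replicates)]


def wet_season_bounds(
    precip_year: np.ndarray, threshold: float = 5.0
) -> tuple[int, int] | None:
    """First and last day index with a rain event >= threshold (inclusive).

    ``precip_year`` should cover one hydrological year (Jul-Jun) so a single
    wet season is never split.  Returns None when no day qualifies.
    """
    precip_year = np.asarray(precip_year, dtype=float)
    if precip_year.size == 0:
        raise ValueError("empty precipitation series")
    qualifying = np.flatnonzero(precip_year >= threshold)
    if qualifying.size == 0:
        return None
    return int(qualifying[0]), int(qualifying[-1])


def apply_calibration_factor(series: np.ndarray, factor: float = 1.16) -> np.ndarray:
    """Scale a daily series by a gauge-calibration factor (satellite rainfall
    products systematically underestimate station totals)."""
    if factor <= 0:
        raise ValueError(f"calibration factor must be positive, got {factor}")
    return np.asarray(series, dtype=float) * factor


# ---------------------------------------------------------------------------
# CSV round-trip

def _iso_dates(years: int) -> list[str]:
    # 365-day model calendar: Feb 29 never occurs, whatever the nominal year
    month_day = [
        (m + 1, d + 1) for m in range(12) for d in range(int(_MONTH_LENGTHS[m]))
    ]
    return [
        f"{2001 + y:04d}-{mm:02d}-{dd:02d}" for y in range(years) for mm, dd in month_day
    ]


def write_climate_csv(series: ClimateSeries, path, replicate: int = 0, seed: int | None = None) -> None:
    """Write one replicate: header comment + columns date, precip_mm, temp_c."""
    df = pd.DataFrame(
        {"date": _iso_dates(series.years), "precip_mm": series.precip, "temp_c": series.temp}
    )
    with open(path, "w") as fh:
        fh.write(f"# replicate={replicate} seed={seed}\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def read_climate_csv(path) -> ClimateSeries:
    with open(path) as fh:
        first = fh.readline()
        body = fh.read()
    if not first.startswith("#"):
        body = first + body
    df = pd.read_csv(io.StringIO(body))
    years = len(df) // DAYS_PER_YEAR
    return ClimateSeries(df["precip_mm"].to_numpy(), df["temp_c"].to_numpy(), years)
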
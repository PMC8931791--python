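"""Plant strategy types: trait trade-offs within three meta-PFTs.

Three broad plant functional types (meta-PFTs) share process equations:
shrubs, perennial grasses and annual grasses.  Shrubs and perennials are
subdivided into strategy types, each specialised in one trait (capital
letter: the value that raises equilibrium cover by 10%) and handicapped in
another (lowercase letter: the value that lowers it by 10%).  Six traits
trade off:

====== ======================== =====================
letter trait                    parameter
====== ======================== =====================
B      biomass production       ``t_veg``
M      mortality                ``mrd``
P      palatability             ``herbivore_pref``
D      defense                  ``defense``
C      water competitiveness    ``uptake_rate``
R      drought resistance       ``wilting_point``
====== ======================== =====================

``defense`` is the *defended* (non-removable) biomass fraction: herbivores
can eat at most ``1 - defense`` of a type's standing biomass.  A reference
+/-10% trait table (separately calibrated for grazer- and browser-dominated
land use) ships with the package, so scenario runs do not require re-running
the calibration scan.

The calibration harness itself is also here: a trait is scanned over +/-30%
of its default in a four-type community, a linear regression of resulting
cover on trait value is fitted, and the +/-10%-cover trait values are read
off the fitted line (only when the slope is significant at p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

TRAIT_NAMES = ("defense", "herbivore_pref", "mrd", "t_veg", "uptake_rate", "wilting_point")
TRAIT_LETTERS = {
    "B": "t_veg",
    "M": "mrd",
    "P": "herbivore_pref",
    "D": "defense",
    "C": "uptake_rate",
    "R": "wilting_point",
}

PERENNIAL_CODES = ("Bd", "Bp", "Cb", "Cp", "Pb", "Pr", "Rb", "Rp")
SHRUB_CODES = ("Bd", "Bp", "Bc", "Cb", "Db", "Dc", "Dr", "Mb", "Rc", "Rd")

#: reference trait table: {land_use: {meta: {trait: (default, minus10, plus10)}}}
REFERENCE_TRAIT_TABLE: dict[str, dict[str, dict[str, tuple[float, float, float]]]] = {
    "grazing": {
        "perennial": {
            "defense": (0.15, 0.125, 0.175),
            "herbivore_pref": (1.0, 1.030, 0.970),
            "mrd": (0.54, 0.557, 0.523),
            "t_veg": (0.5, 0.484, 0.516),
            "uptake_rate": (0.9, 0.879, 0.921),
            "wilting_point": (0.077, 0.0774, 0.0766),
        },
        "shrub": {
            "defense": (0.95, 0.924, 0.976),
            "herbivore_pref": (0.2, 0.243, 0.157),
            "mrd": (0.12, 0.137, 0.103),
            "t_veg": (0.15, 0.143, 0.157),
            "uptake_rate": (0.5, 0.479, 0.521),
            "wilting_point": (0.076, 0.077, 0.075),
        },
    },
    "browsing": {
        "perennial": {
            "defense": (0.95, 0.944, 0.956),
            "herbivore_pref": (0.2, 0.898, 0.000),
            "mrd": (0.54, 0.556, 0.524),
            "t_veg": (0.5, 0.482, 0.518),
            "uptake_rate": (0.9, 0.876, 0.924),
            "wilting_point": (0.077, 0.0774, 0.0766),
        },
        "shrub": {
            "defense": (0.7, 0.614, 0.786),
            "herbivore_pref": (1.0, 1.291, 0.709),
            "mrd": (0.12, 0.136, 0.104),
            "t_veg": (0.15, 0.142, 0.158),
            "uptake_rate": (0.5, 0.471, 0.529),
            "wilting_point": (0.076, 0.083, 0.069),
        },
    },
}


@dataclass(frozen=True)
class MetaPFT:
    """Shared parameters of a broad plant functional type."""

    label: str                      # shrub | perennial | annual
    biomass_conversion: float       # kg per unit cover per 25 m2 cell
    root_fractions: tuple[float, float]  # upper, lower
    max_biweekly_growth: float      # cover fraction per biweek
    t_veg: float
    mrd: float
    uptake_rate: float
    wilting_point: float

    def __post_init__(self):
        if abs(sum(self.root_fractions) - 1.0) > 1e-9:
            raise ValueError("root fractions must sum to 1")
        if self.biomass_conversion <= 0:
            raise ValueError("biomass_conversion must be positive")


#: meta-PFT defaults.  Trait values for shrubs/perennials follow the
#: reference table; annuals are not subdivided and carry their own defaults
#: (obligate annual life cycle: mrd = 1).
META_DEFAULTS: dict[str, MetaPFT] = {
    "perennial": MetaPFT("perennial", biomass_conversion=14.0, root_fractions=(0.8, 0.2),
                         max_biweekly_growth=0.10, t_veg=0.5, mrd=0.54,
                         uptake_rate=0.9, wilting_point=0.077),
    "shrub": MetaPFT("shrub", biomass_conversion=150.0, root_fractions=(0.3, 0.7),
                     max_biweekly_growth=0.003, t_veg=0.15, mrd=0.12,
                     uptake_rate=0.5, wilting_point=0.076),
    "annual": MetaPFT("annual", biomass_conversion=3.0, root_fractions=(1.0, 0.0),
                      max_biweekly_growth=0.15, t_veg=0.6, mrd=1.0,
                      uptake_rate=0.45, wilting_point=0.0775),
}


@dataclass(frozen=True)
class StrategyType:
    """One plant life strategy: meta-PFT membership plus six traits."""

    id: str                  # e.g. "Rp" or "base"
    meta: MetaPFT
    t_veg: float
    mrd: float
    herbivore_pref: float | None  # None: inherit the scenario feeding setting
    defense: float | None
    uptake_rate: float
    wilting_point: float

    def __post_init__(self):
        if not (0.0 <= self.mrd <= 1.0):
            raise ValueError("mrd must be in [0,1]")
        if self.defense is not None and not (0.0 <= self.defense <= 1.0):
            raise ValueError("defense must be in [0,1]")
        if self.herbivore_pref is not None and self.herbivore_pref < 0:
            raise ValueError("herbivore_pref must be >= 0")


@dataclass
class StrategySet:
    """Vectorised view of a strategy-type community.

    Per-type arrays align with cover-array columns everywhere in the model.
    ``herbivore_pref``/``defense`` hold NaN for types that inherit the
    scenario-level feeding settings of their meta-PFT; resolve with
    :meth:`resolved_feeding`.
    """

    types: list[StrategyType]
    ids: list[str] = field(init=False)
    meta_labels: np.ndarray = field(init=False)
    t_veg: np.ndarray = field(init=False)
    mrd: np.ndarray = field(init=False)
    herbivore_pref: np.ndarray = field(init=False)
    defense: np.ndarray = field(init=False)
    uptake_rate: np.ndarray = field(init=False)
    wilting_point: np.ndarray = field(init=False)
    root_frac_upper: np.ndarray = field(init=False)
    root_frac_lower: np.ndarray = field(init=False)
    biomass_conversion: np.ndarray = field(init=False)
    max_growth: np.ndarray = field(init=False)
    is_annual: np.ndarray = field(init=False)
    is_shrub: np.ndarray = field(init=False)
    is_perennial: np.ndarray = field(init=False)

    def __post_init__(self):
        ts = self.types
        self.ids = [f"{t.meta.label}_{t.id}" for t in ts]
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate strategy-type codes")
        self.meta_labels = np.array([t.meta.label for t in ts])
        self.t_veg = np.array([t.t_veg for t in ts])
        self.mrd = np.array([t.mrd for t in ts])
        self.herbivore_pref = np.array(
            [np.nan if t.herbivore_pref is None else t.herbivore_pref for t in ts]
        )
        self.defense = np.array(
            [np.nan if t.defense is None else t.defense for t in ts]
        )
        self.uptake_rate = np.array([t.uptake_rate for t in ts])
        self.wilting_point = np.array([t.wilting_point for t in ts])
        self.root_frac_upper = np.array([t.meta.root_fractions[0] for t in ts])
        self.root_frac_lower = np.array([t.meta.root_fractions[1] for t in ts])
        self.biomass_conversion = np.array([t.meta.biomass_conversion for t in ts])
        self.max_growth = np.array([t.meta.max_biweekly_growth for t in ts])
        self.is_annual = self.meta_labels == "annual"
        self.is_shrub = self.meta_labels == "shrub"
        self.is_perennial = self.meta_labels == "perennial"

    def __len__(self) -> int:
        return len(self.types)

    @classmethod
    def empty(cls) -> "StrategySet":
        """Single inert placeholder type (zero uptake); for bare-soil runs."""
        meta = MetaPFT("annual", 1.0, (1.0, 0.0), 0.0, 0.0, 1.0, 0.0, 0.0775)
        t = StrategyType("base", meta, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0775)
        return cls([t])

    def resolved_feeding(self, feeding: dict[str, dict[str, float]]) -> tuple[np.ndarray, np.ndarray]:
        """Per-type (pref, defense) with scenario defaults filled in.

        ``feeding`` maps meta label -> {"herbivore_pref": x, "defense": y}
        (the land-use scenario's Table-3 settings).  Types specialised in P
        or D override the scenario default with their own calibrated value.
        """
        pref = self.herbivore_pref.copy()
        dfns = self.defense.copy()
        for i, lbl in enumerate(self.meta_labels):
            if np.isnan(pref[i]):
                pref[i] = feeding[lbl]["herbivore_pref"]
            if np.isnan(dfns[i]):
                dfns[i] = feeding[lbl]["defense"]
        if not np.any(pref > 0):
            raise ValueError("at least one herbivore preference must be positive")
        return pref, dfns


def _build_type(meta_label: str, code: str, table_meta: dict, land_use: str,
                meta: MetaPFT) -> StrategyType:
    vals = {
        "t_veg": meta.t_veg,
        "mrd": meta.mrd,
        "uptake_rate": meta.uptake_rate,
        "wilting_point": meta.wilting_point,
        "herbivore_pref": None,
        "defense": None,
    }
    if code != "base":
        spec_letter, trade_letter = code[0], code[1].upper()
        for letter, col in ((spec_letter, 2), (trade_letter, 1)):
            trait = TRAIT_LETTERS[letter]
            vals[trait] = table_meta[trait][col]
    return StrategyType(id=code, meta=meta, **vals)


def assemble_strategy_types(
    table: dict | None = None,
    land_use: str = "grazing",
    metas: dict[str, MetaPFT] | None = None,
) -> StrategySet:
    """Build the 21-type community for one land-use type.

    8 perennial and 10 shrub two-letter strategies plus the three meta-PFT
    base types.  The capital letter takes the +10% (specialisation) value,
    the lowercase letter the -10% (trade-off) value; every other trait keeps
    the meta default.  Pure function of the table: no randomness.
    """
    if land_use not in ("grazing", "browsing"):
        raise ValueError(f"unknown land use {land_use!r}")
    table = REFERENCE_TRAIT_TABLE if table is None else table
    metas = META_DEFAULTS if metas is None else metas
    lu = table[land_use]
    types: list[StrategyType] = []
    for meta_label, codes in (("perennial", PERENNIAL_CODES), ("shrub", SHRUB_CODES)):
        meta = metas[meta_label]
        types.append(_build_type(meta_label, "base", lu[meta_label], land_use, meta))
        for code in codes:
            types.append(_build_type(meta_label, code, lu[meta_label], land_use, meta))
    am = metas["annual"]
    types.append(StrategyType("base", am, am.t_veg, am.mrd, None, None,
                              am.uptake_rate, am.wilting_point))
    return StrategySet(types)


# ---------------------------------------------------------------------------
# Trait-calibration harness

@dataclass
class ScanResult:
    """Outcome of scanning one trait over a range of settings."""

    parameter: str
    values: np.ndarray
    mean_cover: np.ndarray     # per setting: last-20-year mean cover, %
    slope: float = field(init=False)
    intercept: float = field(init=False)
    slope_p: float = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.mean_cover = np.asarray(self.mean_cover, float)
        if self.values.size != self.mean_cover.size:
            raise ValueError("values and mean_cover length mismatch")
        if self.values.size < 2 or np.any(np.diff(self.values) == 0):
            raise ValueError("need >= 2 strictly monotone parameter values")
        fit = stats.linregress(self.values, self.mean_cover)
        self.slope = float(fit.slope)
        self.intercept = float(fit.intercept)
        self.slope_p = float(fit.pvalue)


EXCLUDED = "excluded"


def scan_parameter(
    meta_label: str,
    parameter: str,
    evaluate: Callable[[float], float],
    default_value: float | None = None,
    rel_range: float = 0.30,
    n_points: int = 7,
) -> ScanResult:
    """Scan one trait over ``default*(1 +/- rel_range)``.

    ``evaluate(value) -> mean cover (%)`` must run the community simulation
    with the altered type (the default full-model evaluator is
    :func:`savhyd.runner.make_scan_evaluator`).  Deterministic given the
    evaluator's seeding.
    """
    if parameter not in TRAIT_NAMES:
        raise ValueError(f"unknown parameter {parameter!r}")
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    if default_value is None:
        default_value = getattr(META_DEFAULTS[meta_label], parameter)
    values = default_value * (1.0 + np.linspace(-rel_range, rel_range, n_points))
    if np.any(np.diff(values) == 0):
        raise ValueError("parameter range degenerate: need >= 2 distinct values")
    covers = np.array([evaluate(float(v)) for v in values])
    return ScanResult(parameter, values, covers)


def solve_target_deviation(
    scan: ScanResult, base_cover: float, target: float, alpha: float = 0.05
) -> float | str:
    """Trait value giving a ``target`` relative cover deviation, via the
    fitted line; ``EXCLUDED`` when the slope is not significant."""
    if scan.slope_p >= alpha:
        return EXCLUDED
    if scan.slope == 0.0:
        raise ZeroDivisionError("significant regression with zero slope")
    return float((base_cover * (1.0 + target) - scan.intercept) / scan.slope)


# ---------------------------------------------------------------------------
# Table I/O

def trait_table_to_frame(table: dict | None = None) -> pd.DataFrame:
    table = REFERENCE_TRAIT_TABLE if table is None else table
    rows = []
    for land_use, metas in table.items():
        for meta, traits in metas.items():
            for trait, (d, m10, p10) in traits.items():
                rows.append(
                    {"land_use": land_use, "meta": meta, "trait": trait,
                     "default": d, "minus10": m10, "plus10": p10}
                )
    return pd.DataFrame(rows)


def frame_to_trait_table(df: pd.DataFrame) -> dict:
    table: dict = {}
    for row in df.itertuples(index=False):
        table.setdefault(row.land_use, {}).setdefault(row.meta, {})[row.trait] = (
            float(row.default), float(row.minus10), float(row.plus10)
        )
    return table
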
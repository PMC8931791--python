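"""End-of-season biomass removal by grazer- or browser-dominated herds.

Once per growing season, standing cover is converted to biomass with a
rain-corrected conversion constant, the herd's annual fodder demand is
computed from the stocking rate (one livestock unit = a 450 kg herbivore
eating 2% of its body weight daily), and demand is filled by visiting grid
cells in random order.  A visited cell either loses all of its edible
biomass (when remaining demand exceeds it) or, in the final cell, demand is
split across strategy types in proportion to palatability x edible mass.
The ``defense`` trait is the defended (non-removable) biomass fraction, so
at most ``1 - defense`` of a type's biomass can ever be eaten.  Deficits do
not starve the herd (supplemental feeding is assumed) but reduce the
effective animal density used for seed dispersal the following season.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .strategies import StrategySet
from .vegetation import VegState

BODY_WEIGHT_KG = 450.0
INTAKE_FRAC_PER_DAY = 0.02


@dataclass
class FeedingSettings:
    """Scenario-level palatability/defense per meta-PFT (the land-use table)."""

    settings: dict[str, dict[str, float]]

    def __post_init__(self):
        prefs = [v["herbivore_pref"] for v in self.settings.values()]
        if not any(p > 0 for p in prefs):
            raise ValueError("at least one herbivore preference must be positive")
        for v in self.settings.values():
            if not (0.0 <= v["defense"] <= 1.0):
                raise ValueError("defense must be in [0,1]")


GRAZING_FEEDING = FeedingSettings(
    {
        "shrub": {"herbivore_pref": 0.2, "defense": 0.95},
        "perennial": {"herbivore_pref": 1.0, "defense": 0.15},
        "annual": {"herbivore_pref": 0.6, "defense": 0.05},
    }
)
BROWSING_FEEDING = FeedingSettings(
    {
        "shrub": {"herbivore_pref": 1.0, "defense": 0.7},
        "perennial": {"herbivore_pref": 0.2, "defense": 0.95},
        "annual": {"herbivore_pref": 0.1, "defense": 0.95},
    }
)


@dataclass
class HerbivoryOutcome:
    """Bookkeeping of one season's biomass removal."""

    removed_bm: np.ndarray   # (cells, T) kg
    demand: float            # kg
    deficit: float           # kg
    effective_sr: float      # ha/LSU (inf when nothing was removed)

    @property
    def removed_total(self) -> float:
        return float(self.removed_bm.sum())


def rain_correction(annual_precip: float, map_ref: float,
                    lo: float = 0.2, hi: float = 2.0) -> float:
    """Rainfall correction factor on the cover-to-biomass conversion."""
    if map_ref <= 0:
        raise ValueError("map_ref must be positive")
    return float(np.clip(annual_precip / map_ref, lo, hi))


def cover_to_biomass(cover: np.ndarray, conversion: np.ndarray | float,
                     cf_rain: float) -> np.ndarray:
    """kg of standing biomass from cover fraction (exact inverse exists)."""
    return np.asarray(cover, float) * conversion * cf_rain


def biomass_to_cover(bm: np.ndarray, conversion: np.ndarray | float,
                     cf_rain: float) -> np.ndarray:
    if cf_rain <= 0:
        raise ValueError("cf_rain must be positive to invert")
    return np.asarray(bm, float) / (np.asarray(conversion, float) * cf_rain)


def needed_biomass(sr: float, area_ha: float, body_weight: float = BODY_WEIGHT_KG,
                   intake_frac: float = INTAKE_FRAC_PER_DAY) -> float:
    """Annual herd fodder demand, kg/yr, for a stocking rate in ha/LSU."""
    if sr <= 0:
        raise ValueError("stocking rate must be positive")
    if area_ha < 0:
        raise ValueError("area must be non-negative")
    return body_weight * 365.0 * intake_frac * (1.0 / sr) * area_ha


def edible_biomass(bm: np.ndarray, defense: np.ndarray | float) -> np.ndarray:
    """Removable biomass: the undefended fraction ``bm * (1 - defense)``."""
    defense = np.asarray(defense, float)
    if np.any(defense < 0) or np.any(defense > 1):
        raise ValueError("defense must be in [0,1]")
    return np.asarray(bm, float) * (1.0 - defense)


def _allocate_within_cell(
    edible_row: np.ndarray, prefs: np.ndarray, remaining: float
) -> np.ndarray:
    """Split remaining demand across a cell's types, weights pref * edible.

    When a preferred type cannot absorb its share, the overflow re-spreads
    over the types with edible mass left (and positive preference).
    """
    share = np.zeros_like(edible_row)
    if remaining >= edible_row.sum():
        return edible_row.copy()
    for _ in range(edible_row.size):
        weights = prefs * (edible_row - share)
        wsum = weights.sum()
        gap = remaining - share.sum()
        if wsum <= 0 or gap <= 1e-12:
            break
        share = np.minimum(share + gap * weights / wsum, edible_row)
    return share


def remove_biomass(
    edible: np.ndarray,
    demand: float,
    prefs: np.ndarray,
    rng: np.random.Generator,
) -> HerbivoryOutcome:
    """Fill ``demand`` kg from ``edible`` (cells x types) biomass.

    Cells are visited in a random permutation; each visited cell is emptied
    of edible biomass unless it is the last one needed, in which case the
    remaining demand is split within the cell proportionally to
    ``pref * edible``.  Equivalent to drawing random cells without
    replacement until demand is met or nothing edible remains.
    """
    edible = np.asarray(edible, float)
    if demand < 0 or np.any(edible < 0) or np.any(np.asarray(prefs) < 0):
        raise ValueError("negative inputs")
    n_cells = edible.shape[0]
    removed = np.zeros_like(edible)
    cell_tot = edible.sum(axis=-1)
    if demand > 0 and cell_tot.sum() > 0:
        order = rng.permutation(n_cells)
        csum = np.cumsum(cell_tot[order])
        # cells whose cumulative edible total fits inside demand are emptied
        cut = int(np.searchsorted(csum, demand, side="right"))
        full = order[:cut]
        removed[full] = edible[full]
        remaining = demand - (csum[cut - 1] if cut > 0 else 0.0)
        # selective removal in the remaining cells until demand is met;
        # normally a single cell, more only when zero-preference types
        # block part of a cell's edible biomass
        for cell in order[cut:]:
            if remaining <= 1e-12:
                break
            share = _allocate_within_cell(edible[cell], prefs, remaining)
            removed[cell] = share
            remaining -= share.sum()
    total_removed = float(removed.sum())
    deficit = max(0.0, demand - total_removed)
    return HerbivoryOutcome(removed_bm=removed, demand=float(demand),
                            deficit=deficit, effective_sr=np.nan)


def effective_stocking(sr: float, demand: float, removed: float) -> float:
    """Stocking rate felt by seed dispersal after a fodder deficit.

    Fewer fed animals means a larger area per livestock unit; with nothing
    removed, no herbivore-mediated dispersal occurs (+inf sentinel).
    """
    if not (demand >= removed >= 0):
        raise ValueError("require demand >= removed >= 0")
    if removed == 0:
        return float("inf")
    return float(sr * demand / removed)


def apply_herbivory(
    veg: VegState,
    strat: StrategySet,
    feeding: FeedingSettings,
    sr: float,
    area_ha: float,
    cf_rain: float,
    rng: np.random.Generator,
) -> HerbivoryOutcome:
    """One season's selective biomass removal, updating cover in place."""
    pref, defense = strat.resolved_feeding(feeding.settings)
    shape = veg.cover.shape
    cover_flat = veg.cover.reshape(-1, shape[-1])
    bm = cover_to_biomass(cover_flat, strat.biomass_conversion, cf_rain)
    edible = edible_biomass(bm, defense)
    demand = needed_biomass(sr, area_ha)
    outcome = remove_biomass(edible, demand, pref, rng)
    new_bm = bm - outcome.removed_bm
    veg.cover = biomass_to_cover(new_bm, strat.biomass_conversion, cf_rain).reshape(shape)
    outcome.effective_sr = effective_stocking(
        sr, demand, min(demand, outcome.removed_total)
    )
    return outcome
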
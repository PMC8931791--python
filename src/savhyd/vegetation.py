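"""Biweekly vegetation dynamics within the wet season.

Cover of each strategy type grows in proportion to the water it transpired
during the fortnight (growth is water-use driven), subject to free space in
the cell and a meta-PFT growth-rate cap.  Seeds disperse every biweek -
grasses uniformly within a 150 m^2 neighbourhood, shrubs via a short
exponential kernel plus rare herbivore-mediated long-distance events whose
rate scales with animal density (1/effective stocking rate).  Establishment
converts seed availability into new cover only in fortnights whose mean
upper-layer moisture clears the type's wilting point by a margin, with
stochastic rounding so rare types are not deterministically truncated to
extinction.  Mortality acts once per year at the end of the fixed growing
season (October-April): a senescence share plus a drought share proportional
to the fraction of the season the root zone spent below the type's wilting
point.  Annual grasses die back completely and regrow from their seed bank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .strategies import StrategySet

#: global water-use efficiency: new cover fraction per mm transpired
DEFAULT_WUE = 0.005
#: establishment probability per biweek per unit seed availability
DEFAULT_P_EST = {"perennial": 0.03, "shrub": 0.022, "annual": 0.075}
#: required moisture clearance above the wilting point for establishment
DEFAULT_EST_MARGIN = 0.005
#: background-senescence share of the annual mortality rate
DEFAULT_B0 = 0.2
#: drought stress accrues when root-zone moisture is within this margin of
#: the wilting point (incipient stomatal closure)
DEFAULT_STRESS_MARGIN = 0.0
#: cover quantum for stochastic rounding of establishment
EST_QUANTUM = 0.001
#: shrub long-distance dispersal: expected events per cell-biweek per (LSU/ha)
DEFAULT_LD_RATE = 2.5
#: mean of the shrub exponential dispersal kernel, in cells
SHRUB_KERNEL_MEAN = 1.0
SHRUB_KERNEL_RADIUS = 2


@dataclass
class VegState:
    """Per-cell cover and seed availability for every strategy type."""

    cover: np.ndarray      # (rows, cols, T) fractions
    seed_bank: np.ndarray  # (rows, cols, T) dimensionless

    def __post_init__(self):
        self.cover = np.asarray(self.cover, float)
        self.seed_bank = np.asarray(self.seed_bank, float)
        if self.cover.shape != self.seed_bank.shape:
            raise ValueError("cover and seed_bank shapes differ")

    def validate(self) -> None:
        if np.any(self.cover < -1e-12) or np.any(self.seed_bank < -1e-12):
            raise ValueError("negative cover or seed bank")
        if np.any(self.cover.sum(axis=-1) > 1.0 + 1e-9):
            raise ValueError("per-cell total cover exceeds 1")

    @property
    def total_cover(self) -> np.ndarray:
        return self.cover.sum(axis=-1)


def initial_veg_state(
    strat: StrategySet,
    rows: int = 30,
    cols: int = 30,
    init_meta_cover: dict[str, float] | None = None,
) -> VegState:
    """Uniform start: each meta-PFT's initial cover split equally among its
    strategy types (shrubs and perennials 20%, annuals 5% by default)."""
    init_meta_cover = init_meta_cover or {"shrub": 0.20, "perennial": 0.20, "annual": 0.05}
    cover = np.zeros((rows, cols, len(strat)))
    for meta, total in init_meta_cover.items():
        mask = strat.meta_labels == meta
        n = int(mask.sum())
        if n:
            cover[:, :, mask] = total / n
    return VegState(cover=cover, seed_bank=cover.copy())


def grow(
    cover: np.ndarray,
    transp_biweek: np.ndarray,
    t_veg: np.ndarray,
    max_growth: np.ndarray,
    free_space: np.ndarray,
    wue: float = DEFAULT_WUE,
) -> np.ndarray:
    """Cover increment from a fortnight's transpiration.

    ``delta = t_veg * wue * transpiration * free_space`` capped by the
    meta-PFT biweekly growth limit and by the free space itself.
    """
    delta = t_veg * wue * np.asarray(transp_biweek, float) * free_space[..., None]
    delta = np.minimum(delta, max_growth)
    return np.minimum(delta, free_space[..., None])


def end_season_mortality(
    cover: np.ndarray,
    stress_frac: np.ndarray,
    mrd: np.ndarray,
    is_annual: np.ndarray,
    b0: float = DEFAULT_B0,
) -> np.ndarray:
    """Annual mortality at the end of the growing season.

    Survival = 1 - mrd*(b0 + (1-b0)*stress_frac); annuals always die back
    completely (they persist via the seed bank).
    """
    stress = np.clip(np.asarray(stress_frac, float), 0.0, 1.0)
    loss = mrd * b0 + mrd * (1.0 - b0) * stress
    new_cover = np.maximum(0.0, cover * (1.0 - loss))
    new_cover[..., is_annual] = 0.0
    return new_cover


#: grass-dispersal weights: focal + 4 orthogonal cells fully, diagonals a
#: quarter each -- six cells' worth of 25 m^2 area, orientation-free
_GRASS_K = np.array([[0.25, 1.0, 0.25], [1.0, 1.0, 1.0], [0.25, 1.0, 0.25]])


def _shrub_kernel() -> np.ndarray:
    r = SHRUB_KERNEL_RADIUS
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    dist = np.hypot(dy, dx)
    k = np.exp(-dist / SHRUB_KERNEL_MEAN)
    return k / k.sum()


_SHRUB_K = _shrub_kernel()
_DEN_CACHE: dict[tuple, np.ndarray] = {}


def _kernel_smooth(field: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Normalised kernel smoothing with edge re-normalisation (weights of
    off-grid cells are redistributed onto the grid)."""
    from scipy import ndimage

    key = (field.shape[0], field.shape[1], kernel.tobytes())
    den = _DEN_CACHE.get(key)
    if den is None:
        den = ndimage.correlate(
            np.ones(field.shape[:2]), kernel, mode="constant", cval=0.0
        )
        _DEN_CACHE[key] = den
    num = ndimage.correlate(field, kernel[:, :, None], mode="constant", cval=0.0)
    return num / den[..., None]


def _neighborhood_mean(field: np.ndarray) -> np.ndarray:
    """Mean cover over the ~150 m^2 grass-dispersal neighbourhood."""
    return _kernel_smooth(field, _GRASS_K / _GRASS_K.sum())


def disperse(
    veg: VegState,
    strat: StrategySet,
    effective_sr: float,
    rng: np.random.Generator,
    ld_rate: float = DEFAULT_LD_RATE,
) -> np.ndarray:
    """Seed input per cell and type for one fortnight.

    Grasses (perennial and annual): spatially uniform within the 150 m^2
    neighbourhood - each cell receives the local mean cover.  Shrubs: short
    exponential kernel plus Poisson long-distance events seeded by herbivores;
    the event rate scales with animal density, i.e. with 1/effective_sr.
    """
    if effective_sr <= 0:
        raise ValueError("effective stocking rate must be positive")
    cover = veg.cover
    seed_input = np.zeros_like(cover)
    grass = ~strat.is_shrub
    if np.any(grass):
        seed_input[..., grass] = _neighborhood_mean(cover[..., grass])
    if np.any(strat.is_shrub):
        shr = _kernel_smooth(cover[..., strat.is_shrub], _SHRUB_K)
        rows, cols = cover.shape[:2]
        n_cells = rows * cols
        mean_cover = cover[..., strat.is_shrub].mean(axis=(0, 1))
        if np.isfinite(effective_sr):
            lam = ld_rate * n_cells / effective_sr
            shrub_cols = np.flatnonzero(strat.is_shrub)
            for j, col in enumerate(shrub_cols):
                if mean_cover[j] <= 0:
                    continue
                n_events = rng.poisson(lam * mean_cover[j] / max(mean_cover.sum(), 1e-12))
                if n_events:
                    cells = rng.integers(0, n_cells, size=n_events)
                    np.add.at(shr[..., j].reshape(-1), cells, mean_cover[j])
        seed_input[..., strat.is_shrub] = shr
    return seed_input


def establish(
    seed_bank: np.ndarray,
    theta_upper_biweek: np.ndarray,
    free_space: np.ndarray,
    strat: StrategySet,
    rng: np.random.Generator,
    p_est: np.ndarray | None = None,
    est_margin: float = DEFAULT_EST_MARGIN,
    grass_cover: np.ndarray | None = None,
) -> np.ndarray:
    """New cover from seeds, with stochastic rounding.

    Establishment requires the fortnight's mean upper-layer moisture to
    exceed the type's wilting point by ``est_margin``; the expected increment
    is ``p_est * seed_bank * free_space``.
    """
    if p_est is None:
        p_est = np.array([DEFAULT_P_EST[m] for m in strat.meta_labels])
    wet_enough = theta_upper_biweek[..., None] > (strat.wilting_point + est_margin)
    expected = p_est * np.asarray(seed_bank, float) * free_space[..., None] * wet_enough
    # woody seedlings need open microsites: recruitment is quadratic in free
    # space, so a closed sward suppresses shrub invasion
    expected[..., strat.is_shrub] *= free_space[..., None]
    # the annual flush fills ground not held by grasses (shrub canopies leave
    # the ground layer open); a dense perennial sward suppresses it
    if grass_cover is not None and np.any(strat.is_annual):
        open_ground = np.clip(1.0 - grass_cover, 0.0, 1.0)
        expected[..., strat.is_annual] = (
            p_est[strat.is_annual]
            * np.asarray(seed_bank, float)[..., strat.is_annual]
            * open_ground[..., None] ** 2
            * wet_enough[..., strat.is_annual]
        )
    quanta = expected / EST_QUANTUM
    whole = np.floor(quanta)
    frac = quanta - whole
    inc = (whole + (rng.random(frac.shape) < frac)) * EST_QUANTUM
    return np.minimum(inc, free_space[..., None])


def _cap_increments(cover: np.ndarray, increments: np.ndarray) -> np.ndarray:
    """Scale competing increments so per-cell total cover stays <= 1."""
    free = np.maximum(0.0, 1.0 - cover.sum(axis=-1))
    tot_inc = increments.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(tot_inc > free, free / np.maximum(tot_inc, 1e-300), 1.0)
    return increments * scale[..., None]


def step_biweek(
    veg: VegState,
    transp_biweek: np.ndarray,
    theta_upper_biweek: np.ndarray,
    strat: StrategySet,
    effective_sr: float,
    rng: np.random.Generator,
    wue: float = DEFAULT_WUE,
    p_est: np.ndarray | None = None,
    est_margin: float = DEFAULT_EST_MARGIN,
    ld_rate: float = DEFAULT_LD_RATE,
    dynamic_mask: np.ndarray | None = None,
) -> None:
    """One vegetation update inside the wet season: grow, disperse, establish.

    ``transp_biweek``: (rows, cols, T) mm transpired by each type over the
    fortnight; ``theta_upper_biweek``: (rows, cols) mean upper moisture.
    ``dynamic_mask`` freezes the cover of unmasked types (their seeds still
    disperse and they keep occupying space) - used by the calibration scan.
    """
    veg.validate()
    free = np.maximum(0.0, 1.0 - veg.cover.sum(axis=-1))
    growth = grow(veg.cover, transp_biweek, strat.t_veg, strat.max_growth, free, wue)
    seed_input = disperse(veg, strat, effective_sr, rng, ld_rate)
    # annual-grass seed banks are durable; grass/shrub seed pools turn over
    # within a season
    decay = np.where(strat.is_annual, 1.0, 0.5)
    veg.seed_bank = np.minimum(decay * veg.seed_bank + seed_input, 1.0)
    grass_cover = veg.cover[..., ~strat.is_shrub].sum(axis=-1)
    recruits = establish(
        veg.seed_bank, theta_upper_biweek, free, strat, rng, p_est, est_margin,
        grass_cover=grass_cover,
    )
    increments = growth + recruits
    if dynamic_mask is not None:
        increments[..., ~dynamic_mask] = 0.0
    increments = _cap_increments(veg.cover, increments)
    veg.cover = veg.cover + increments
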
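"""Headline analyses over scenario runs.

Everything here consumes the tidy per-year tables produced by the runner
(either in memory as :class:`savhyd.runner.RunSummary` or re-read from the
CSV files written by ``savhyd run``) and produces the study-level summaries:
diversity per replicate, functional dispersion in two-factor trait space,
pooled clustering of type loadings, the cover -> T/ET regression, and the
grass-richness contrast between browser- and grazer-dominated land use.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import (
    TraitSpace,
    cluster_wcss,
    factor_structure,
    functional_dispersion,
    richness,
    scenario_diversity,
    tet_regression,
    water_use,
)


def meta_of_type(type_id: str) -> str:
    """Meta-PFT label from a column id like ``perennial_Rp``."""
    return type_id.split("_")[0]


def last20_cover(cover: pd.DataFrame, window: int = 20) -> pd.DataFrame:
    years = cover["year"].max() + 1
    return cover[cover["year"] >= years - window]


def annual_water_table(water: pd.DataFrame, window: int = 20) -> pd.DataFrame:
    years = water["year"].max() + 1
    df = water[water["year"] >= years - window].copy()
    df["tet_pct"] = water_use(df["t_mm"].to_numpy(), df["et_mm"].to_numpy())
    return df


def type_columns(cover: pd.DataFrame) -> list[str]:
    return [c for c in cover.columns if c not in ("scenario", "replicate", "year")]


def diversity_table(cover: pd.DataFrame, window: int = 20) -> pd.DataFrame:
    """Per-scenario, per-replicate richness/H/J from last-window mean covers."""
    cols = type_columns(cover)
    meta = {c: meta_of_type(c) for c in cols}
    out = []
    for scen, grp in last20_cover(cover, window).groupby("scenario"):
        per_rep = grp.groupby("replicate")[cols].mean()
        tab = scenario_diversity(per_rep, meta)
        tab.insert(0, "scenario", scen)
        out.append(tab)
    return pd.concat(out, ignore_index=True)


def scenario_fdis(cover: pd.DataFrame, scenario: str, window: int = 20,
                  seed: int = 0) -> dict:
    """FDis of one scenario's community in its two-factor loading space.

    The factor structure is extracted from that scenario's last-window
    annual cover observations (replicates x years as rows); abundance
    weights are the last-window mean cover of each retained type.
    """
    cols = type_columns(cover)
    sel = last20_cover(cover[cover["scenario"] == scenario], window)
    if sel.empty:
        raise ValueError(f"no rows for scenario {scenario!r}")
    X = sel[cols].to_numpy(float)
    orient = np.array([meta_of_type(c) in ("shrub", "annual") for c in cols])
    loadings, eigvals, retained, kept = factor_structure(X, orient_positive=orient)
    weights = X.mean(axis=0)[kept]
    space = TraitSpace(coordinates=loadings[:, :2], abundances=weights)
    return {
        "fdis": functional_dispersion(space),
        "loadings": loadings,
        "kept_types": [cols[i] for i in kept],
        "eigenvalues": eigvals,
        "retained": retained,
        "weights": weights,
    }


def pooled_cluster_wcss(cover: pd.DataFrame, window: int = 20, seed: int = 0) -> dict:
    """Two-factor extraction on cover pooled over all scenarios, k=2
    clustering of type loadings, and per-cluster WCSS.

    Returns the WCSS of the cluster holding the majority of shrub types
    (annuals group with shrubs in loading space) and of the perennial
    cluster.
    """
    cols = type_columns(cover)
    sel = last20_cover(cover, window)
    X = sel[cols].to_numpy(float)
    orient = np.array([meta_of_type(c) in ("shrub", "annual") for c in cols])
    loadings, eigvals, retained, kept = factor_structure(X, orient_positive=orient)
    kept_types = [cols[i] for i in kept]
    labels, wcss = cluster_wcss(loadings[:, :2], k=2, seed=seed)
    is_shrub = np.array([meta_of_type(t) == "shrub" for t in kept_types])
    shrub_cluster = int(np.round(labels[is_shrub].mean())) if is_shrub.any() else 0
    return {
        "labels": labels,
        "wcss": wcss,
        "shrub_wcss": float(wcss[shrub_cluster]),
        "perennial_wcss": float(wcss[1 - shrub_cluster]),
        "kept_types": kept_types,
        "loadings": loadings,
    }


def grass_richness_ratio(diversity: pd.DataFrame) -> float:
    """Mean perennial-grass richness, browsing runs over grazing runs."""
    browsing = diversity[diversity["scenario"].str.startswith("browsing")]
    grazing = diversity[diversity["scenario"].str.startswith("grazing")]
    if browsing.empty or grazing.empty:
        raise ValueError("need both browsing and grazing scenarios")
    g = grazing["S_perennial"].mean()
    if g == 0:
        return float("inf")
    return float(browsing["S_perennial"].mean() / g)


def water_summary(water: pd.DataFrame, window: int = 20) -> pd.DataFrame:
    """Per-scenario mean +/- SD of total cover, T/ET and wet-season moisture."""
    df = annual_water_table(water, window)
    agg = df.groupby("scenario").agg(
        total_cover_mean=("total_cover_pct", "mean"),
        total_cover_sd=("total_cover_pct", "std"),
        tet_mean=("tet_pct", "mean"),
        tet_sd=("tet_pct", "std"),
        moisture_mean=("wet_season_theta_pct", "mean"),
        moisture_sd=("wet_season_theta_pct", "std"),
    )
    return agg.reset_index()


def cover_tet_r2(water: pd.DataFrame, window: int = 20) -> float:
    """R^2 (%) of T/ET on total cover + scenario across pooled annual obs."""
    df = annual_water_table(water, window)
    res = tet_regression(df[["scenario", "total_cover_pct", "t_mm", "et_mm"]])
    return res["r2_pct"]


# ---------------------------------------------------------------------------
# CLI support: re-read run directories

def load_run_dir(path: Path) -> dict[str, pd.DataFrame]:
    return {
        "cover": pd.read_csv(path / "cover.csv"),
        "water": pd.read_csv(path / "water.csv"),
        "herbivory": pd.read_csv(path / "herbivory.csv"),
    }


def analyze_runs(run_dirs: list[Path], window: int = 20) -> dict[str, pd.DataFrame]:
    """The `analyze` subcommand: diversity, trait-space and water tables."""
    covers, waters = [], []
    for d in run_dirs:
        tabs = load_run_dir(Path(d))
        covers.append(tabs["cover"])
        waters.append(tabs["water"])
    cover = pd.concat(covers, ignore_index=True)
    water = pd.concat(waters, ignore_index=True)

    diversity = diversity_table(cover, window)
    rows = []
    for scen in sorted(cover["scenario"].unique()):
        f = scenario_fdis(cover, scen, window)
        rows.append({"scenario": scen, "fdis": f["fdis"], "retained": f["retained"]})
    pooled = pooled_cluster_wcss(cover, window)
    traitspace = pd.DataFrame(rows)
    traitspace["shrub_wcss_pooled"] = pooled["shrub_wcss"]
    traitspace["perennial_wcss_pooled"] = pooled["perennial_wcss"]
    return {
        "diversity": diversity,
        "traitspace": traitspace,
        "water": water_summary(water, window),
        "water_annual": annual_water_table(water, window),
    }
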
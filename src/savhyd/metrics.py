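"""Community diversity, trait-space and water-use analytics.

Richness applies a 2.5% total-cover threshold so residual biomass of
near-extinct types is not counted.  Shannon diversity and Pielou evenness
use natural logarithms.  Community structure in trait space is summarised
by an exploratory two-factor extraction from the cover matrix
(eigendecomposition of the correlation matrix), k-means clustering of the
type loadings with within-cluster sums of squares, and functional
dispersion (FDis): the abundance-weighted mean distance of types to the
abundance-weighted community centroid.  Water use is summarised as the
transpired share of evapotranspiration (T/ET).

Inferential machinery (mixed models, rank tests, post hoc corrections) is
deliberately not reimplemented; the run outputs are tidy tables any stats
package can consume.  Effect sizes that headline results depend on -
epsilon squared and Cohen's d - are provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

RICHNESS_THRESHOLD_PCT = 2.5


@dataclass
class DiversitySummary:
    """Richness, Shannon diversity (nats) and Pielou evenness."""

    S: int
    H: float
    J: float
    p: np.ndarray


def richness(cover_by_type: dict[str, float] | np.ndarray,
             threshold_pct: float = RICHNESS_THRESHOLD_PCT) -> int:
    """Number of types whose total cover strictly exceeds the threshold."""
    values = np.asarray(
        list(cover_by_type.values()) if isinstance(cover_by_type, dict) else cover_by_type,
        float,
    )
    if np.any(values < 0):
        raise ValueError("covers must be non-negative")
    return int(np.sum(values > threshold_pct))


def shannon_pielou(abundances: np.ndarray,
                   threshold_pct: float = RICHNESS_THRESHOLD_PCT) -> DiversitySummary:
    """Shannon H = -sum p ln p and Pielou J = H / ln S.

    Richness S applies the cover threshold before normalisation; J of a
    single-type community is defined as 0.
    """
    a = np.asarray(abundances, float)
    if a.sum() <= 0:
        raise ValueError("all-zero abundances")
    keep = a > threshold_pct
    S = int(keep.sum())
    if S == 0:
        return DiversitySummary(0, 0.0, 0.0, np.array([]))
    p = a[keep] / a[keep].sum()
    nz = p > 0
    H = float(-(p[nz] * np.log(p[nz])).sum())
    J = float(H / np.log(S)) if S > 1 else 0.0
    return DiversitySummary(S, H, J, p)


def epsilon_squared(kruskal_H: float, n: int) -> tuple[float, str]:
    """Nonparametric effect size e2 = H / ((n^2-1)/(n+1)) with size label."""
    if n < 2:
        raise ValueError("need at least 2 observations")
    e2 = kruskal_H / ((n**2 - 1) / (n + 1))
    label = "small" if e2 < 0.08 else ("medium" if e2 <= 0.26 else "large")
    return float(e2), label


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardised mean difference with df-pooled standard deviation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need >= 2 values")
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        raise ZeroDivisionError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


@dataclass
class TraitSpace:
    """Type coordinates plus abundance weights in a (trait or factor) space."""

    coordinates: np.ndarray  # (T, axes)
    abundances: np.ndarray   # (T,)

    def __post_init__(self):
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, float))
        self.abundances = np.asarray(self.abundances, float)
        if self.coordinates.shape[0] != self.abundances.size:
            raise ValueError("coordinates/abundances length mismatch")
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be >= 0")

    @property
    def centroid(self) -> np.ndarray:
        w = self.abundances
        if w.sum() <= 0:
            raise ValueError("no positive abundance")
        return (w[:, None] * self.coordinates).sum(axis=0) / w.sum()


def functional_dispersion(space: TraitSpace) -> float:
    """FDis: abundance-weighted mean Euclidean distance to the weighted
    centroid of the community."""
    c = space.centroid
    d = np.linalg.norm(space.coordinates - c, axis=1)
    w = space.abundances
    return float((w * d).sum() / w.sum())


def factor_structure(
    cover_matrix: np.ndarray | pd.DataFrame,
    max_factors: int = 2,
    orient_positive: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """Two-factor structure of a (observations x types) cover matrix.

    Eigendecomposition of the correlation matrix (principal-axis style,
    unrotated); factors with eigenvalue > 1 are retained, capped at
    ``max_factors``.  Constant columns are dropped with a warning.  Factor
    signs are fixed so the mean loading of ``orient_positive`` columns
    (e.g. shrub + annual types) is positive on factor 1.

    Returns (loadings (kept_types x max_factors), eigenvalues, n_retained,
    kept column indices).
    """
    X = np.asarray(cover_matrix, float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D matrix with >= 3 observations")
    sd = X.std(axis=0)
    keep = sd > 1e-12
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-constant columns")
    if not np.all(keep):
        import warnings

        warnings.warn(
            f"dropping {int((~keep).sum())} constant column(s) from factor analysis"
        )
    Xk = X[:, keep]
    R = np.corrcoef(Xk, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    retained = int(min(max_factors, max(1, np.sum(eigvals > 1.0))))
    loadings = eigvecs[:, :max_factors] * np.sqrt(np.maximum(eigvals[:max_factors], 0.0))
    if orient_positive is not None:
        mask = np.asarray(orient_positive)[keep]
        for j in range(loadings.shape[1]):
            ref = loadings[mask, j].mean() if mask.any() else loadings[:, j].mean()
            if ref < 0:
                loadings[:, j] = -loadings[:, j]
    else:
        for j in range(loadings.shape[1]):
            if loadings[:, j].mean() < 0:
                loadings[:, j] = -loadings[:, j]
    return loadings, eigvals, retained, np.flatnonzero(keep)


def cluster_wcss(
    loadings: np.ndarray, k: int = 2, seed: int = 0, n_init: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """k-means on type loadings; per-cluster within-cluster sum of squares."""
    pts = np.atleast_2d(np.asarray(loadings, float))
    if k > pts.shape[0]:
        raise ValueError("k exceeds number of points")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(pts)
    wcss = np.array(
        [((pts[labels == j] - km.cluster_centers_[j]) ** 2).sum() for j in range(k)]
    )
    return labels, wcss


def water_use(T: float | np.ndarray, ET: float | np.ndarray) -> float | np.ndarray:
    """Relative plant water use 100 * T/ET (%); 0 where ET is 0."""
    T = np.asarray(T, float)
    ET = np.asarray(ET, float)
    if np.any(T < 0) or np.any(ET + 1e-12 < T):
        raise ValueError("require ET >= T >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(ET > 0, 100.0 * T / np.maximum(ET, 1e-300), 0.0)
    return float(out) if out.ndim == 0 else out


def wet_season_moisture(
    theta_series: np.ndarray, bounds: tuple[int, int] | None
) -> float | None:
    """Mean volumetric moisture (vol %) over the variable wet season."""
    if bounds is None:
        return None
    start, end = bounds
    window = np.asarray(theta_series, float)[start : end + 1]
    if window.size == 0:
        raise ValueError("empty wet-season window")
    return float(window.mean())


# ---------------------------------------------------------------------------
# Higher-level analytics over RunSummary tables

def scenario_diversity(type_cover_per_rep: pd.DataFrame,
                       meta_of: dict[str, str]) -> pd.DataFrame:
    """Per-replicate richness/H/J, total and per meta-PFT."""
    rows = []
    for rep, series in type_cover_per_rep.iterrows():
        vals = series.to_numpy(float)
        names = list(series.index)
        total = shannon_pielou(vals)
        row = {"replicate": rep, "S": total.S, "H": total.H, "J": total.J}
        for meta in ("shrub", "perennial", "annual"):
            idx = [i for i, n in enumerate(names) if meta_of[n] == meta]
            row[f"S_{meta}"] = richness(vals[idx])
        rows.append(row)
    return pd.DataFrame(rows)


def tet_regression(annual: pd.DataFrame) -> dict:
    """OLS of T/ET on total cover + scenario indicator; returns R2 etc.

    ``annual`` needs columns total_cover_pct, t_mm, et_mm, scenario.
    """
    import statsmodels.formula.api as smf

    df = annual.copy()
    df["tet"] = water_use(df["t_mm"].to_numpy(), df["et_mm"].to_numpy())
    model = smf.ols("tet ~ total_cover_pct + C(scenario)", data=df).fit()
    return {
        "r2": float(model.rsquared),
        "r2_pct": float(100.0 * model.rsquared),
        "params": model.params,
        "model": model,
    }
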
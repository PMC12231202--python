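"""Home ranges (kernel utilization distributions), spatial clustering and
Global Moran's I on survival times.

Home range = 95% isopleth of a Gaussian kernel density estimate of an
individual's pre-migration locations; core area = 50% isopleth. Densities
are evaluated on a regular grid in a local azimuthal-equidistant plane via
binning + Gaussian convolution, with Silverman's per-axis bandwidth by
default. Clustering of individuals uses complete-linkage agglomeration on
great-circle distances between median locations. Global Moran's I on
survival times uses row-standardized inverse-distance weights between 50%-KDE
centroids, with both a normal (randomization) p-value and a permutation
p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import norm
from sklearn.metrics import silhouette_score

from ._geo import LocalProjection, haversine_m

# ---------------------------------------------------------------------------
# kernel density surface and isopleths
# ---------------------------------------------------------------------------


@dataclass
class KDEGrid:
    mass: np.ndarray            # cell probability mass (sums to ~1)
    x_min: float
    y_min: float
    cell_m: float
    bandwidth_m: tuple[float, float]
    projection: LocalProjection

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_m / 1000.0) ** 2

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())


@dataclass
class HomeRange:
    individual_id: str
    kde95_area_km2: float
    kde50_area_km2: float
    kde50_centroid: tuple[float, float]   # lon, lat
    grid_spec: dict = field(default_factory=dict)


def silverman_bandwidth(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Per-axis Silverman rule for a 2-D Gaussian KDE: h_i = sigma_i * n^(-1/6)."""
    n = len(x)
    return float(np.std(x, ddof=1) * n ** (-1 / 6)), float(np.std(y, ddof=1) * n ** (-1 / 6))


def kde_surface(
    lons,
    lats,
    bandwidth="silverman",
    cell_m: float | None = None,
    margin_bandwidths: float = 3.0,
    max_cells: int = 4_000_000,
) -> KDEGrid:
    """Gaussian-kernel density of a point set on a regular metric grid.

    Points are projected to a local azimuthal-equidistant plane; the grid
    covers them plus ``margin_bandwidths`` bandwidths on each side; the cell
    size defaults to a quarter of the smaller bandwidth. The returned cell
    masses sum to 1 within 1%.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if len(lons) < 3 or len(np.unique(np.column_stack([lons, lats]), axis=0)) < 3:
        raise ValueError("need >= 3 distinct points for a kernel surface")
    proj = LocalProjection(float(lons.mean()), float(lats.mean()))
    x, y = proj.forward(lons, lats)
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("all points identical; jitter the input or skip the individual")
    if bandwidth == "silverman":
        hx, hy = silverman_bandwidth(x, y)
    else:
        hx = hy = float(bandwidth)
    hx = max(hx, 1.0)
    hy = max(hy, 1.0)
    if cell_m is None:
        cell_m = max(min(hx, hy) / 4.0, 1.0)
    x0 = x.min() - margin_bandwidths * hx
    x1 = x.max() + margin_bandwidths * hx
    y0 = y.min() - margin_bandwidths * hy
    y1 = y.max() + margin_bandwidths * hy
    nx = int(np.ceil((x1 - x0) / cell_m))
    ny = int(np.ceil((y1 - y0) / cell_m))
    while nx * ny > max_cells:
        cell_m *= 1.5
        nx = int(np.ceil((x1 - x0) / cell_m))
        ny = int(np.ceil((y1 - y0) / cell_m))
    hist, _, _ = np.histogram2d(
        x, y, bins=[nx, ny], range=[[x0, x0 + nx * cell_m], [y0, y0 + ny * cell_m]]
    )
    mass = ndimage.gaussian_filter(
        hist / len(x), sigma=(hx / cell_m, hy / cell_m), mode="constant", truncate=6.0
    )
    return KDEGrid(mass=mass, x_min=x0, y_min=y0, cell_m=cell_m, bandwidth_m=(hx, hy), projection=proj)


def isopleth(grid: KDEGrid, p: float) -> tuple[float, np.ndarray]:
    """Area (km^2) and cell mask of the smallest highest-density region with
    probability mass >= p."""
    if not (0.0 < p < 1.0):
        raise ValueError("isopleth probability must be in (0, 1)")
    flat = grid.mass.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order]) / grid.total_mass
    k = int(np.searchsorted(csum, p)) + 1
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    mask = mask.reshape(grid.mass.shape)
    return float(k * grid.cell_area_km2), mask


def home_range(individual_id: str, fixes: pd.DataFrame, bandwidth="silverman", **kde_kwargs) -> HomeRange:
    """95% / 50% KDE areas and the mass-weighted 50%-core centroid."""
    grid = kde_surface(fixes["longitude"].to_numpy(), fixes["latitude"].to_numpy(), bandwidth, **kde_kwargs)
    a95, _ = isopleth(grid, 0.95)
    a50, m50 = isopleth(grid, 0.50)
    ii, jj = np.nonzero(m50)
    w = grid.mass[ii, jj]
    cx = grid.x_min + (ii + 0.5) * grid.cell_m
    cy = grid.y_min + (jj + 0.5) * grid.cell_m
    lon_c, lat_c = grid.projection.inverse(np.average(cx, weights=w), np.average(cy, weights=w))
    return HomeRange(
        individual_id=str(individual_id),
        kde95_area_km2=a95,
        kde50_area_km2=a50,
        kde50_centroid=(float(lon_c), float(lat_c)),
        grid_spec={
            "cell_m": grid.cell_m,
            "bandwidth_m": grid.bandwidth_m,
            "shape": list(grid.mass.shape),
        },
    )


# ---------------------------------------------------------------------------
# clustering of individuals by site use
# ---------------------------------------------------------------------------

def individual_distance_matrix(site_fixes: dict[str, pd.DataFrame]) -> tuple[list[str], np.ndarray]:
    """Pairwise great-circle distances (km) between individuals' median
    locations (component-wise median lon/lat); empty individuals excluded."""
    ids, lons, lats = [], [], []
    for ind, f in site_fixes.items():
        if f is None or len(f) == 0:
            continue
        ids.append(str(ind))
        lons.append(float(f["longitude"].median()))
        lats.append(float(f["latitude"].median()))
    lons = np.asarray(lons)
    lats = np.asarray(lats)
    dist = haversine_m(lons[:, None], lats[:, None], lons[None, :], lats[None, :]) / 1000.0
    np.fill_diagonal(dist, 0.0)
    return ids, dist


def hierarchical_clusters(
    distance_matrix: np.ndarray,
    linkage: str = "complete",
    k: int | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Agglomerative clustering on a precomputed distance matrix.

    Returns (labels at a cut of k, dendrogram leaf order, k). When k is None
    it is chosen by silhouette over 2..min(8, n-1).
    """
    n = distance_matrix.shape[0]
    if n < 2:
        raise ValueError("need >= 2 individuals to cluster")
    Z = hierarchy.linkage(squareform(distance_matrix, checks=False), method=linkage)
    order = hierarchy.leaves_list(Z)
    if k is not None:
        if k > n:
            raise ValueError(f"k={k} exceeds n={n}")
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        return labels, order, k
    best_k, best_s = 2, -np.inf
    for kk in range(2, min(8, n - 1) + 1):
        labels = hierarchy.fcluster(Z, t=kk, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(distance_matrix, labels, metric="precomputed")
        if s > best_s:
            best_k, best_s = kk, s
    labels = hierarchy.fcluster(Z, t=best_k, criterion="maxclust")
    return labels, order, best_k


# ---------------------------------------------------------------------------
# Global Moran's I
# ---------------------------------------------------------------------------


@dataclass
class SpatialWeights:
    w: np.ndarray
    scheme: str = "inverse_distance"
    row_standardized: bool = True


@dataclass
class MoranResult:
    I: float
    expected_I: float
    z: float
    p_norm: float
    p_perm: float
    n: int
    permutations: int


def inverse_distance_weights(lonlats, row_standardize: bool = True) -> SpatialWeights:
    """Inverse great-circle-distance weights between points (zero diagonal)."""
    pts = np.asarray(lonlats, dtype=float)
    d = haversine_m(pts[:, 0][:, None], pts[:, 1][:, None], pts[:, 0][None, :], pts[:, 1][None, :])
    with np.errstate(divide="ignore"):
        w = np.where(d > 0, 1.0 / np.maximum(d, 1e-9), 0.0)
    np.fill_diagonal(w, 0.0)
    if row_standardize:
        rs = w.sum(axis=1, keepdims=True)
        w = np.divide(w, rs, out=np.zeros_like(w), where=rs > 0)
    return SpatialWeights(w=w, scheme="inverse_distance", row_standardized=row_standardize)


def morans_I(
    values,
    weights: SpatialWeights | np.ndarray,
    permutations: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I with normal-approximation (randomization) and
    permutation p-values (two-sided).

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    with E[I] = -1/(n-1) under no spatial autocorrelation.
    """
    x = np.asarray(values, dtype=float)
    w = weights.w if isinstance(weights, SpatialWeights) else np.asarray(weights, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("Moran's I needs n >= 4")
    if np.ptp(x) == 0:
        raise ValueError("Moran's I is undefined for constant values")
    z = x - x.mean()
    s0 = w.sum()
    denom = float(z @ z)
    I = float(n / s0 * (z @ w @ z) / denom)
    e_i = -1.0 / (n - 1)

    # randomization variance (Cliff & Ord)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    b2 = n * (z**4).sum() / denom**2
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    var = num / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
    zscore = (I - e_i) / np.sqrt(var)
    p_norm = 2.0 * norm.sf(abs(zscore))

    rng = np.random.default_rng(seed)
    exceed = 0
    obs = abs(I - e_i)
    for _ in range(permutations):
        zp = rng.permutation(z)
        I_p = n / s0 * (zp @ w @ zp) / denom
        if abs(I_p - e_i) >= obs - 1e-15:
            exceed += 1
    p_perm = (exceed + 1) / (permutations + 1)
    return MoranResult(I=I, expected_I=e_i, z=float(zscore), p_norm=float(p_norm),
                       p_perm=float(p_perm), n=n, permutations=permutations)
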
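"""Density maps, 50%-of-maximum contours, gating, and rare-cell ratios.

Populations are summarized in the (area, deformability) plane by a density
estimate — a normalized 2-D histogram or a binned Gaussian KDE with per-axis
Scott bandwidths.  The "50% density contour" of the scatterplots is the
iso-contour at half the maximum density value (a level on the linear density
scale, not a 50%-probability-mass region).  A gate is the largest-area such
contour of a reference population; applying it is point-in-polygon counting
with the boundary counted as inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage, stats
from shapely.geometry import Polygon as ShapelyPolygon
from skimage import measure as skmeasure

__all__ = [
    "DensityGrid",
    "GateRegion",
    "density_map",
    "half_max_contour",
    "derive_gate",
    "apply_gate",
    "rare_cell_ratio",
]

AXIS_NAMES = ("area", "deformability")


@dataclass
class DensityGrid:
    """Normalized density on a rectangular (area, deformability) grid.

    ``density[i, j]`` is the density at ``x_centers[i]``, ``y_centers[j]``;
    when normalized it integrates to ~1 over the grid.
    """

    density: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    method: str
    n_points: int
    bandwidth: tuple[float, float] | None = None

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def integral(self) -> float:
        dx = np.diff(self.x_edges)[:, None]
        dy = np.diff(self.y_edges)[None, :]
        return float((self.density * dx * dy).sum())


@dataclass
class GateRegion:
    """A closed polygonal gate in (area μm², deformability) space."""

    polygon: np.ndarray
    level: float
    provenance: dict = field(default_factory=dict)

    def as_shapely(self) -> ShapelyPolygon:
        return ShapelyPolygon(self.polygon)

    @property
    def area(self) -> float:
        return float(self.as_shapely().area)


def _scott_bandwidths(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # Scott's rule for a 2-D Gaussian product kernel: h_i = sigma_i * n^(-1/6)
    n = len(x)
    return float(np.std(x, ddof=1) * n ** (-1 / 6)), float(np.std(y, ddof=1) * n ** (-1 / 6))


def density_map(
    points: np.ndarray,
    method: str = "histogram",
    bins: int = 64,
    bandwidth: tuple[float, float] | None = None,
    ranges: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> DensityGrid:
    """Estimate the 2-D density of (area, deformability) points.

    ``histogram``: bin counts normalized to a density.  ``kde``: a Gaussian
    product kernel with per-axis bandwidths (Scott's rule by default),
    evaluated by binning on a fine grid and Gaussian filtering — the standard
    fast binned-KDE approximation.  Axis ranges default to the 1st-99th
    percentile span (expanded by 3 bandwidths for the KDE so kernel mass is
    retained on the grid).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (area, deformability)")
    if len(pts) < 10:
        raise ValueError("need at least 10 points for a density map")
    if method not in ("histogram", "kde"):
        raise ValueError("method must be 'histogram' or 'kde'")
    x, y = pts[:, 0], pts[:, 1]
    for name, v in zip(AXIS_NAMES, (x, y)):
        if np.ptp(v) == 0 and method == "kde":
            raise ValueError(f"degenerate {name} axis: zero variance")

    if ranges is None:
        xr = np.percentile(x, [1, 99])
        yr = np.percentile(y, [1, 99])
        if xr[0] == xr[1]:
            xr = (xr[0] - 0.5, xr[1] + 0.5)
        if yr[0] == yr[1]:
            yr = (yr[0] - 0.5, yr[1] + 0.5)
    else:
        xr, yr = ranges[0], ranges[1]

    if method == "histogram":
        h, xe, ye = np.histogram2d(x, y, bins=bins, range=(tuple(xr), tuple(yr)))
        area_per_bin = np.diff(xe)[:, None] * np.diff(ye)[None, :]
        inside = int(h.sum())
        dens = h / (inside * area_per_bin) if inside else h
        return DensityGrid(dens, xe, ye, "histogram", len(pts))

    hx, hy = bandwidth if bandwidth is not None else _scott_bandwidths(x, y)
    if hx <= 0 or hy <= 0:
        raise ValueError("KDE bandwidths must be positive")
    # pad by 6 bandwidths so kernel mass stays on the grid (integral ~ 1)
    xr = (xr[0] - 6 * hx, xr[1] + 6 * hx)
    yr = (yr[0] - 6 * hy, yr[1] + 6 * hy)
    h, xe, ye = np.histogram2d(x, y, bins=bins, range=(tuple(xr), tuple(yr)))
    dx, dy = xe[1] - xe[0], ye[1] - ye[0]
    smoothed = ndimage.gaussian_filter(h, sigma=(hx / dx, hy / dy), mode="constant")
    dens = smoothed / (h.sum() * dx * dy)
    return DensityGrid(dens, xe, ye, "kde", len(pts), bandwidth=(hx, hy))


def half_max_contour(grid: DensityGrid, level: float = 0.5) -> list[GateRegion]:
    """Iso-contours of the density at ``level`` x max(density).

    Contours are traced marching-squares style with linear interpolation on a
    zero-padded copy of the grid, so every region closes even when it touches
    the grid edge.  Multiple disjoint regions are returned separately, sorted
    by descending enclosed area.
    """
    if not 0.0 < level <= 1.0:
        raise ValueError("level must lie in (0, 1]")
    dmax = float(grid.density.max())
    if dmax <= 0:
        raise ValueError("density grid has no positive maximum")
    padded = np.pad(grid.density, 1, mode="constant")
    iso = level * dmax
    xc, yc = grid.x_centers, grid.y_centers
    dx = grid.x_edges[1] - grid.x_edges[0]
    dy = grid.y_edges[1] - grid.y_edges[0]
    regions: list[GateRegion] = []
    for cont in skmeasure.find_contours(padded, iso):
        if len(cont) < 3 or not np.allclose(cont[0], cont[-1]):
            continue
        # padded index -> data coordinates (index 1 maps to first center)
        xs = xc[0] + (cont[:, 0] - 1.0) * dx
        ys = yc[0] + (cont[:, 1] - 1.0) * dy
        poly = np.column_stack([xs, ys])[:-1]
        if len(poly) < 3:
            continue
        sp = ShapelyPolygon(poly)
        if not sp.is_valid or sp.area == 0:
            sp = sp.buffer(0)
            if sp.is_empty:
                continue
        regions.append(
            GateRegion(
                polygon=poly,
                level=level,
                provenance={"method": grid.method, "n_points": grid.n_points},
            )
        )
    regions.sort(key=lambda r: r.area, reverse=True)
    return regions


def derive_gate(
    reference_points: np.ndarray,
    method: str = "kde",
    level: float = 0.5,
    bins: int = 64,
    min_points: int = 100,
) -> GateRegion:
    """Gate from a pure reference population: its largest 50%-density contour.

    The returned region records its provenance (density method, level, number
    of reference points); two derivations from identical inputs yield
    identical polygons.
    """
    pts = np.asarray(reference_points, dtype=float)
    if len(pts) < min_points:
        raise ValueError(
            f"reference population too small ({len(pts)} < {min_points} points)"
        )
    grid = density_map(pts, method=method, bins=bins)
    regions = half_max_contour(grid, level=level)
    if not regions:
        raise ValueError("no closed density contour found at the requested level")
    gate = regions[0]
    gate.provenance.update({"level": level, "reference_n": len(pts), "density_method": method})
    return gate


def apply_gate(points: np.ndarray, gate: GateRegion) -> np.ndarray:
    """Boolean in-gate flags for (area, deformability) points.

    Points exactly on the gate boundary count as inside.  The bounding box is
    checked first so that gating millions of points against a compact gate is
    cheap.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    poly = gate.as_shapely()
    minx, miny, maxx, maxy = poly.bounds
    inside = np.zeros(len(pts), dtype=bool)
    bbox = (
        (pts[:, 0] >= minx)
        & (pts[:, 0] <= maxx)
        & (pts[:, 1] >= miny)
        & (pts[:, 1] <= maxy)
    )
    if bbox.any():
        cand = pts[bbox]
        geoms = shapely.points(cand[:, 0], cand[:, 1])
        inside[bbox] = shapely.covers(poly, geoms)
    return inside


def rare_cell_ratio(
    gated_count: int, total_count: int, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Rare-cell fraction with a Clopper-Pearson (exact binomial) interval."""
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    if gated_count < 0 or gated_count > total_count:
        raise ValueError("gated_count must lie in [0, total_count]")
    k, n = gated_count, total_count
    alpha = 1.0 - confidence
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return k / n, (lo, hi)
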
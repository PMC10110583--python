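"""Spatial infiltration and co-exclusion analysis of marker-labeled cells.

Inputs are already-classified cell centroids: x/y coordinates in µm plus one
boolean column per marker (e.g. VHL, Ki67, POSTN).  The analysis mirrors the
standard digital-pathology infiltration workflow:

1. grid the marker-positive cells into a density heatmap (Gaussian-smoothed
   counts on a regular grid);
2. infer the marker-positive region boundary as an iso-contour of the
   smoothed density at a fraction of its maximum;
3. measure every cell's signed Euclidean distance to the boundary
   (negative = inside the region);
4. bin target-marker-positive cells into distance bands, normalize counts by
   the geometric band area (polygon buffering clipped to the analysis
   window), and report area-normalized densities;
5. for two mutually exclusive phenotypes, compare their band-density curves
   with a Spearman rank correlation — strongly negative values indicate
   spatial co-exclusion.

All areas are clipped to an analysis window: the bounding box of all cells
expanded by the outer band extent, which makes the area normalization
computable without an external tissue mask.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections.abc import Mapping

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from scipy.stats import spearmanr
from shapely.geometry import MultiPolygon, Polygon, box
from shapely.ops import unary_union
from skimage.measure import find_contours
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Density grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DensityGrid:
    """Gridded cell counts (``counts``) and their Gaussian smoothing (``density``).

    ``counts[i, j]`` is the number of positive cells whose x falls in bin i
    and y in bin j; ``x_centers`` / ``y_centers`` are bin centers in µm.
    """
    x_centers: np.ndarray
    y_centers: np.ndarray
    counts: np.ndarray
    density: np.ndarray
    cell_size: float
    bandwidth: float

    def argmax_xy(self) -> tuple[float, float]:
        i, j = np.unravel_index(int(np.argmax(self.density)), self.density.shape)
        return float(self.x_centers[i]), float(self.y_centers[j])

    def to_frame(self) -> pd.DataFrame:
        xi, yi = np.meshgrid(np.arange(len(self.x_centers)),
                             np.arange(len(self.y_centers)), indexing="ij")
        return pd.DataFrame({
            "x_um": self.x_centers[xi.ravel()],
            "y_um": self.y_centers[yi.ravel()],
            "count": self.counts.ravel(),
            "density": self.density.ravel(),
        })


def _marker_mask(cells: pd.DataFrame, marker) -> np.ndarray:
    """Boolean mask for a marker name or a {marker: bool} phenotype conjunction."""
    if isinstance(marker, Mapping):
        mask = np.ones(len(cells), dtype=bool)
        for name, wanted in marker.items():
            mask &= cells[name].astype(bool).to_numpy() == bool(wanted)
        return mask
    return cells[marker].astype(bool).to_numpy()


def density_grid(
    cells: pd.DataFrame,
    marker,
    cell_size: float = 100.0,
    bandwidth: float = 200.0,
    bounds: tuple[float, float, float, float] | None = None,
) -> DensityGrid:
    """Gaussian-smoothed density grid of marker-positive cells.

    The raw per-cell counts sum to the number of positive cells; smoothing
    uses a Gaussian with sigma = ``bandwidth`` µm (zero-padded beyond the
    grid).  ``bounds`` defaults to the bounding box of *all* cells so grids
    of different markers on one tissue align.
    """
    pos = cells[_marker_mask(cells, marker)]
    if len(pos) == 0:
        raise ValueError(f"no cells positive for marker {marker!r}")
    if bounds is None:
        x0, y0 = cells["x_um"].min(), cells["y_um"].min()
        x1, y1 = cells["x_um"].max(), cells["y_um"].max()
    else:
        x0, y0, x1, y1 = bounds
    x_edges = np.arange(x0, x1 + cell_size, cell_size)
    y_edges = np.arange(y0, y1 + cell_size, cell_size)
    if len(x_edges) < 2:
        x_edges = np.array([x0, x0 + cell_size])
    if len(y_edges) < 2:
        y_edges = np.array([y0, y0 + cell_size])
    counts, _, _ = np.histogram2d(
        pos["x_um"], pos["y_um"], bins=(x_edges, y_edges)
    )
    smooth = gaussian_filter(counts, sigma=bandwidth / cell_size, mode="constant")
    return DensityGrid(
        x_centers=(x_edges[:-1] + x_edges[1:]) / 2,
        y_centers=(y_edges[:-1] + y_edges[1:]) / 2,
        counts=counts,
        density=smooth,
        cell_size=cell_size,
        bandwidth=bandwidth,
    )


# ---------------------------------------------------------------------------
# Region boundary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionBoundary:
    """Marker-positive region as one or more simple polygons (µm coordinates)."""
    polygons: MultiPolygon
    grid_resolution: float = field(default=float("nan"))

    def __post_init__(self):
        if self.polygons.area <= 0:
            raise ValueError("region boundary must have positive area")

    @classmethod
    def from_geometry(cls, geom, grid_resolution: float = float("nan")) -> "RegionBoundary":
        if isinstance(geom, Polygon):
            geom = MultiPolygon([geom])
        elif not isinstance(geom, MultiPolygon):
            geom = MultiPolygon(
                [g for g in getattr(geom, "geoms", [geom]) if isinstance(g, Polygon)]
            )
        return cls(polygons=geom, grid_resolution=grid_resolution)

    @property
    def area(self) -> float:
        return float(self.polygons.area)

    @property
    def n_polygons(self) -> int:
        return len(self.polygons.geoms)

    def to_wkt(self) -> str:
        return self.polygons.wkt


def infer_region_boundary(
    cells: pd.DataFrame,
    marker,
    density_threshold: float = 0.2,
    cell_size: float = 100.0,
    bandwidth: float = 200.0,
    min_area: float | None = None,
) -> RegionBoundary:
    """Region polygons as the iso-contour of the smoothed density at
    ``density_threshold`` x max.

    Polygons below ``min_area`` (default: one grid cell) are discarded and
    logged.  Raises when no grid value exceeds the threshold level.
    """
    if not 0 < density_threshold < 1:
        raise ValueError("density_threshold must lie in (0, 1)")
    grid = density_grid(cells, marker, cell_size=cell_size, bandwidth=bandwidth)
    level = density_threshold * grid.density.max()
    # zero-pad so every contour closes inside the array
    padded = np.pad(grid.density, 1, mode="constant")
    if padded.max() <= level or level <= 0:
        raise ValueError(
            f"no smoothed density above threshold level {level:.3g}; "
            "region boundary is undefined for this marker/threshold"
        )
    contours = find_contours(padded, level)
    x0 = grid.x_centers[0] - cell_size  # padded index 0 center
    y0 = grid.y_centers[0] - cell_size
    polys = []
    min_area = cell_size ** 2 if min_area is None else min_area
    dropped = 0
    for c in contours:
        xy = np.column_stack([x0 + c[:, 0] * cell_size, y0 + c[:, 1] * cell_size])
        if len(xy) < 4:
            continue
        p = Polygon(xy).buffer(0)
        if p.area < min_area:
            dropped += 1
            continue
        polys.append(p)
    if dropped:
        logger.info("discarded %d sub-minimum-area contour polygon(s)", dropped)
    if not polys:
        raise ValueError("all contour polygons fell below min_area")
    merged = unary_union(polys)
    return RegionBoundary.from_geometry(merged, grid_resolution=cell_size)


def signed_distance_to_boundary(points, boundary: RegionBoundary) -> np.ndarray:
    """Signed Euclidean distance (µm) to the nearest boundary edge.

    Negative inside any region polygon, positive outside, zero on the
    boundary.  ``points`` is an (n, 2) array or a cells DataFrame.
    """
    if isinstance(points, pd.DataFrame):
        xy = points[["x_um", "y_um"]].to_numpy(dtype=float)
    else:
        xy = np.atleast_2d(np.asarray(points, dtype=float))
    pts = shapely.points(xy[:, 0], xy[:, 1])
    edges = boundary.polygons.boundary
    d = shapely.distance(pts, edges)
    inside = shapely.contains(boundary.polygons, pts)
    return np.where(inside, -d, d)


class RegionBoundaryEstimator(BaseEstimator):
    """Fit a marker-positive region boundary; transform cells to signed distances.

    A fit/transform wrapper over :func:`infer_region_boundary` and
    :func:`signed_distance_to_boundary` so the boundary step composes with
    sklearn pipelines.

    Attributes
    ----------
    boundary_ : the inferred :class:`RegionBoundary`.
    density_grid_ : the smoothed density grid used for the contour.
    """

    def __init__(self, marker="VHL", density_threshold: float = 0.2,
                 cell_size: float = 100.0, bandwidth: float = 200.0,
                 min_area: float | None = None):
        self.marker = marker
        self.density_threshold = density_threshold
        self.cell_size = cell_size
        self.bandwidth = bandwidth
        self.min_area = min_area

    def fit(self, cells: pd.DataFrame, y=None):
        self.density_grid_ = density_grid(
            cells, self.marker, cell_size=self.cell_size, bandwidth=self.bandwidth
        )
        self.boundary_ = infer_region_boundary(
            cells, self.marker, density_threshold=self.density_threshold,
            cell_size=self.cell_size, bandwidth=self.bandwidth, min_area=self.min_area,
        )
        return self

    def transform(self, cells: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "boundary_"):
            raise RuntimeError("RegionBoundaryEstimator is not fitted")
        return signed_distance_to_boundary(cells, self.boundary_)


# ---------------------------------------------------------------------------
# Infiltration profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InfiltrationProfile:
    """Area-normalized counts of target cells in signed-distance bands.

    ``bins`` are contiguous (d_lo, d_hi] ranges in µm (negative = inside the
    region); ``density`` is count / band area (µm^-2), NaN where the band has
    zero area inside the analysis window.  ``n_out_of_band`` counts the
    target-positive cells beyond the band span.
    """
    bins: list[tuple[float, float]]
    counts: np.ndarray
    areas: np.ndarray
    n_out_of_band: int

    @property
    def densities(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(self.areas > 0, self.counts / self.areas, np.nan)
        return d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "band": np.arange(len(self.bins)),
            "d_lo": [b[0] for b in self.bins],
            "d_hi": [b[1] for b in self.bins],
            "count": self.counts.astype(int),
            "area_um2": self.areas,
            "density": self.densities,
        })


def analysis_window(cells: pd.DataFrame, margin: float) -> Polygon:
    """Bounding box of all cells expanded by ``margin`` µm on each side."""
    return box(
        cells["x_um"].min() - margin, cells["y_um"].min() - margin,
        cells["x_um"].max() + margin, cells["y_um"].max() + margin,
    )


def _band_edges(inner_extent: float, outer_extent: float, band_width: float) -> np.ndarray:
    if inner_extent <= 0 or outer_extent <= 0 or band_width <= 0:
        raise ValueError("extents and band width must be positive")
    lo = -np.arange(0, inner_extent + band_width, band_width)[::-1]
    hi = np.arange(band_width, outer_extent + band_width, band_width)
    edges = np.concatenate([lo, hi])
    edges = edges[(edges >= -inner_extent - 1e-9) & (edges <= outer_extent + 1e-9)]
    if not np.isclose(edges[0], -inner_extent) or not np.isclose(edges[-1], outer_extent):
        logger.info("band width does not divide the extents; edge bands truncated")
        edges = np.unique(np.concatenate([[-inner_extent], edges, [outer_extent]]))
    return edges


def band_areas(boundary: RegionBoundary, window: Polygon, edges: np.ndarray) -> np.ndarray:
    """Geometric area (µm²) of each signed-distance band, clipped to the window.

    The band (d_lo, d_hi] is the set-difference of the region dilated by d_hi
    and by d_lo (negative offsets erode), so areas follow polygon buffering
    exactly rather than any grid approximation.
    """
    region = boundary.polygons
    cum = []
    for d in edges:
        g = region.buffer(d) if d != 0 else region
        cum.append(g.intersection(window).area)
    return np.diff(np.asarray(cum))


def infiltration_profile(
    cells: pd.DataFrame,
    target_marker,
    boundary: RegionBoundary,
    inner_extent: float = 2000.0,
    outer_extent: float = 4000.0,
    band_width: float = 500.0,
    window: Polygon | None = None,
) -> InfiltrationProfile:
    """Band-wise area-normalized density of target-positive cells around a region.

    Bands span signed distances from ``-inner_extent`` (deep inside the
    region) to ``+outer_extent`` (far outside); target cells beyond that span
    are excluded and counted in ``n_out_of_band``.
    """
    edges = _band_edges(inner_extent, outer_extent, band_width)
    pos = cells[_marker_mask(cells, target_marker)]
    d = signed_distance_to_boundary(pos, boundary)
    counts, _ = np.histogram(d, bins=edges)
    n_out = int(len(pos) - counts.sum())
    if window is None:
        window = analysis_window(cells, margin=outer_extent)
    areas = band_areas(boundary, window, edges)
    zero = areas <= 0
    if zero.any():
        logger.info("%d band(s) have zero area inside the window; density undefined",
                    int(zero.sum()))
    return InfiltrationProfile(
        bins=list(zip(edges[:-1].tolist(), edges[1:].tolist())),
        counts=counts.astype(float),
        areas=areas,
        n_out_of_band=n_out,
    )


def fit_exponential_decay(profile: InfiltrationProfile) -> tuple[float, float]:
    """Least-squares exponential fit lambda0 * exp(-d / tau) to the outside bands.

    Linear regression of log density on band midpoints over outside bands
    with positive density.  Returns ``(lambda0, tau)``.
    """
    df = profile.to_frame()
    mid = (df["d_lo"] + df["d_hi"]) / 2
    use = (df["d_lo"] >= 0) & (df["density"] > 0)
    if use.sum() < 3:
        raise ValueError("need >= 3 outside bands with positive density")
    slope, intercept = np.polyfit(mid[use], np.log(df.loc[use, "density"]), 1)
    if slope >= 0:
        raise ValueError("band densities do not decay with distance")
    return float(np.exp(intercept)), float(-1.0 / slope)


# ---------------------------------------------------------------------------
# Region-wise positivity
# ---------------------------------------------------------------------------

def positivity_fraction_by_region(
    cells: pd.DataFrame,
    target_marker,
    regions: Mapping[str, RegionBoundary],
) -> pd.DataFrame:
    """Fraction of target-positive cells among all cells within each labeled region.

    Cells outside every region are tallied under ``neither``.  Cells falling
    in several regions are assigned to the first matching label (declaration
    order) and logged.  Regions without cells get a NaN fraction, flagged.
    """
    pts = shapely.points(cells["x_um"].to_numpy(float), cells["y_um"].to_numpy(float))
    assigned = np.full(len(cells), "neither", dtype=object)
    claimed = np.zeros(len(cells), dtype=bool)
    multi = 0
    for label, region in regions.items():
        inside = shapely.covers(region.polygons, pts)
        multi += int((inside & claimed).sum())
        take = inside & ~claimed
        assigned[take] = label
        claimed |= inside
    if multi:
        logger.info("%d cell(s) inside multiple regions; first label kept", multi)
    target = _marker_mask(cells, target_marker)
    rows = []
    for label in list(regions) + ["neither"]:
        in_reg = assigned == label
        n = int(in_reg.sum())
        frac = float(target[in_reg].sum() / n) if n else np.nan
        if n == 0:
            logger.info("region %r contains no cells; fraction undefined", label)
        rows.append({"region": label, "n_cells": n,
                     "n_positive": int(target[in_reg].sum()), "fraction": frac})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Co-exclusion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoExclusionResult:
    profile_a: InfiltrationProfile
    profile_b: InfiltrationProfile
    spearman: float
    n_bands_used: int


def co_exclusion_profile(
    cells: pd.DataFrame,
    phenotype_a: Mapping[str, bool],
    phenotype_b: Mapping[str, bool],
    boundary: RegionBoundary,
    inner_extent: float = 2000.0,
    outer_extent: float = 4000.0,
    band_width: float = 500.0,
) -> CoExclusionResult:
    """Band-density curves of two phenotypes plus their Spearman overlap statistic.

    Phenotypes are conjunctions of marker booleans (e.g. ``{"VHL": True,
    "POSTN": False}``).  Bands are the signed-distance bands of
    :func:`infiltration_profile` relative to the A-region boundary; the
    overlap statistic is the Spearman rank correlation of the two per-band
    density vectors over bands where both densities are defined.  A strong
    negative value indicates the phenotypes occupy disjoint distance ranges
    (co-exclusion); NaN when fewer than 3 usable bands remain.
    """
    window = analysis_window(cells, margin=outer_extent)
    kwargs = dict(inner_extent=inner_extent, outer_extent=outer_extent,
                  band_width=band_width, window=window)
    pa = infiltration_profile(cells, phenotype_a, boundary, **kwargs)
    pb = infiltration_profile(cells, phenotype_b, boundary, **kwargs)
    da, db = pa.densities, pb.densities
    usable = ~np.isnan(da) & ~np.isnan(db)
    if usable.sum() < 3:
        rho = float("nan")
    else:
        rho = float(spearmanr(da[usable], db[usable]).statistic)
    return CoExclusionResult(pa, pb, rho, int(usable.sum()))


def co_exclusion_permutation_null(
    cells: pd.DataFrame,
    phenotype_a: Mapping[str, bool],
    phenotype_b: Mapping[str, bool],
    boundary: RegionBoundary,
    n_permutations: int = 999,
    seed: int | None = None,
    **kwargs,
) -> tuple[float, np.ndarray]:
    """Permutation null for the co-exclusion statistic.

    Phenotype labels are shuffled among the cells belonging to either
    phenotype (positions fixed), the Spearman statistic recomputed each time.
    Returns ``(observed, null_distribution)``.
    """
    rng = np.random.default_rng(seed)
    obs = co_exclusion_profile(cells, phenotype_a, phenotype_b, boundary, **kwargs)

    mask_a = _marker_mask(cells, phenotype_a)
    mask_b = _marker_mask(cells, phenotype_b)
    pool = cells[mask_a | mask_b].reset_index(drop=True)
    labels = np.where(mask_a[mask_a | mask_b], "A", "B")
    window = analysis_window(cells, margin=kwargs.get("outer_extent", 4000.0))
    edges = _band_edges(kwargs.get("inner_extent", 2000.0),
                        kwargs.get("outer_extent", 4000.0),
                        kwargs.get("band_width", 500.0))
    areas = band_areas(boundary, window, edges)
    d = signed_distance_to_boundary(pool, boundary)

    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(labels)
        ca, _ = np.histogram(d[perm == "A"], bins=edges)
        cb, _ = np.histogram(d[perm == "B"], bins=edges)
        with np.errstate(invalid="ignore", divide="ignore"):
            da = np.where(areas > 0, ca / areas, np.nan)
            db = np.where(areas > 0, cb / areas, np.nan)
        usable = ~np.isnan(da) & ~np.isnan(db)
        null[i] = (spearmanr(da[usable], db[usable]).statistic
                   if usable.sum() >= 3 else np.nan)
    return obs.spearman, null
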
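"""Synthetic landscapes with controlled heterogeneity for pipeline testing.

The generator emulates the structure of a global categorical land-cover
product at desk scale: a patchy multi-class mosaic raster, known-SEPL
sites (polygon or center-point form), and rectangular protected-area/KBA
layers.  Patches are Voronoi cells of random seed points, which gives the
mosaic spatial autocorrelation at a controllable patch scale — essential
because the index is patch-sensitive; independent per-pixel noise would
make every land unit maximally diverse and erase all contrast.

Two dials shape the statistical structure:

* ``agricultural_fraction`` — the target share of agricultural pixels,
  enforced by assigning whole patches until the realized share is within
  +/-0.05 of the target (patch structure is preserved).
* ``delta`` — the heterogeneity contrast: patches inside the declared SEPL
  zones draw their class from a pool ``delta`` classes richer than the
  background pool.  ``delta = 0`` makes zones statistically identical to
  background (the null); large ``delta`` gives zone land units visibly
  higher class richness and hence higher index values.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import box

from .index_core import IndexParams, LandUnitIndexGrid, satoyama_index
from .landcover_raster import (
    ClassCountTable,
    ClassLegend,
    LandCoverGrid,
    LandUnitGridSpec,
    aggregate_counts,
)
from .overlay import PolygonLayer
from .sites_validation import SiteRecord

__all__ = [
    "MosaicParams",
    "generate_mosaic",
    "generate_sites",
    "generate_conservation_layers",
    "mosaic_index_grid",
    "default_zones",
]

#: Natural (non-agricultural, non-urban) class pool, ordered by how commonly
#: each cover type borders agriculture in mosaic landscapes.
NATURAL_POOL = (2, 8, 6, 7, 1, 3, 5, 9, 15, 20)

#: Agricultural classes used for agricultural patches (cropland, paddy, mosaic).
AG_CODES = (11, 12, 13)


def default_zones(west: float, south: float, width: float, height: float
                  ) -> tuple[tuple[float, float, float, float], ...]:
    """Three well-separated rectangular SEPL zones covering ~16% of the extent."""
    rel = ((0.08, 0.08, 0.33, 0.33), (0.55, 0.15, 0.80, 0.40), (0.20, 0.60, 0.45, 0.85))
    return tuple(
        (west + rx0 * width, south + ry0 * height,
         west + rx1 * width, south + ry1 * height)
        for rx0, ry0, rx1, ry1 in rel
    )


@dataclass(frozen=True)
class MosaicParams:
    """Parameters of a synthetic land-cover mosaic.

    Defaults describe a 1-degree by 1-degree landscape of 240x240 pixels at
    the 15-arc-second resolution of the target product, i.e. a 20x20 grid
    of land units at aggregation factor 12, with a mean patch of ~24 pixels
    (several patches per land unit) and 30% agricultural cover.
    """

    shape: tuple[int, int] = (240, 240)
    west: float = 30.0
    north: float = 10.0
    pixel_size: float = 1.0 / 240.0
    seed: int = 0
    n_patches: int | None = None
    agricultural_fraction: float = 0.3
    ag_tolerance: float = 0.05
    background_richness: int = 2
    delta: int = 0
    sepl_zones: tuple[tuple[float, float, float, float], ...] | None = None
    natural_pool: tuple[int, ...] = NATURAL_POOL
    ag_codes: tuple[int, ...] = AG_CODES
    nodata_code: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.agricultural_fraction <= 1.0:
            raise ValueError("agricultural_fraction must be in [0, 1]")
        if self.background_richness < 1:
            raise ValueError("background_richness must be >= 1")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.background_richness + self.delta > len(self.natural_pool):
            raise ValueError(
                "background_richness + delta exceeds the natural class pool"
            )
        if self.agricultural_fraction > 0 and not self.ag_codes:
            raise ValueError("agricultural fraction requested but no agricultural code in palette")

    @property
    def resolved_n_patches(self) -> int:
        if self.n_patches is not None:
            return self.n_patches
        return max(1, self.shape[0] * self.shape[1] // 24)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) of the raster."""
        rows, cols = self.shape
        return (
            self.west,
            self.north - rows * self.pixel_size,
            self.west + cols * self.pixel_size,
            self.north,
        )

    @property
    def zones(self) -> tuple[tuple[float, float, float, float], ...]:
        if self.sepl_zones is not None:
            return self.sepl_zones
        west, south, east, north = self.extent
        return default_zones(west, south, east - west, north - south)


def _zone_membership(x: np.ndarray, y: np.ndarray,
                     zones: Sequence[tuple[float, float, float, float]]) -> np.ndarray:
    inside = np.zeros(x.shape, dtype=bool)
    for w, s, e, n in zones:
        inside |= (x >= w) & (x < e) & (y >= s) & (y < n)
    return inside


def generate_mosaic(params: MosaicParams) -> LandCoverGrid:
    """Generate a seeded Voronoi-patch mosaic raster.

    Patches are assigned to agriculture greedily (in random order) until the
    realized agricultural pixel fraction is within ``ag_tolerance`` of the
    target; the remaining patches draw a natural class uniformly from the
    background pool, or from the ``delta``-enriched pool when the patch's
    Voronoi seed lies inside a SEPL zone.
    """
    rng = np.random.default_rng(params.seed)
    rows, cols = params.shape
    n_patches = params.resolved_n_patches

    seeds = rng.uniform(size=(n_patches, 2)) * (cols, rows)
    py, px = np.mgrid[0:rows, 0:cols]
    pixel_xy = np.column_stack([px.ravel() + 0.5, py.ravel() + 0.5])
    _, patch_of_pixel = cKDTree(seeds).query(pixel_xy)
    patch_of_pixel = patch_of_pixel.reshape(rows, cols)
    patch_area = np.bincount(patch_of_pixel.ravel(), minlength=n_patches)

    # seed coordinates in lon/lat to decide zone membership per patch
    seed_lon = params.west + seeds[:, 0] * params.pixel_size
    seed_lat = params.north - seeds[:, 1] * params.pixel_size
    in_zone = _zone_membership(seed_lon, seed_lat, params.zones)

    total = rows * cols
    a = params.agricultural_fraction
    is_ag = np.zeros(n_patches, dtype=bool)
    if a > 0:
        frac = 0.0
        for idx in rng.permutation(n_patches):
            if frac >= a:
                break
            if frac + patch_area[idx] / total <= a + params.ag_tolerance:
                is_ag[idx] = True
                frac += patch_area[idx] / total
        if abs(frac - a) > params.ag_tolerance:
            raise ValueError(
                f"could not hit agricultural fraction {a} within "
                f"+/-{params.ag_tolerance} (realized {frac:.3f})"
            )

    bg_pool = np.asarray(params.natural_pool[: params.background_richness])
    zone_pool = np.asarray(
        params.natural_pool[: params.background_richness + params.delta]
    )
    patch_class = np.empty(n_patches, dtype=np.int64)
    ag_pick = rng.integers(0, len(params.ag_codes), size=n_patches)
    bg_pick = rng.integers(0, len(bg_pool), size=n_patches)
    zone_pick = rng.integers(0, len(zone_pool), size=n_patches)
    patch_class[:] = bg_pool[bg_pick]
    patch_class[in_zone] = zone_pool[zone_pick[in_zone]]
    patch_class[is_ag] = np.asarray(params.ag_codes)[ag_pick[is_ag]]

    values = patch_class[patch_of_pixel]
    return LandCoverGrid(
        values=values,
        west=params.west,
        north=params.north,
        pixel_size=params.pixel_size,
        nodata_code=params.nodata_code,
    )


def mosaic_index_grid(
    params: MosaicParams,
    legend: ClassLegend | None = None,
    factor: int = 12,
) -> tuple[LandCoverGrid, ClassCountTable, LandUnitIndexGrid]:
    """Convenience: mosaic -> aggregate -> score, returning all three stages."""
    legend = legend or ClassLegend.default()
    grid = generate_mosaic(params)
    table = aggregate_counts(grid, legend=legend, factor=factor)
    index = satoyama_index(table, IndexParams.from_legend(legend))
    return grid, table, index


def generate_sites(
    params: MosaicParams,
    n_sepl: int,
    n_random_like: int = 0,
    polygon_fraction: float = 0.0,
    seed: int = 0,
    site_size: float | None = None,
) -> list[SiteRecord]:
    """Place known-SEPL sites in the declared zones plus background-uniform decoys.

    ``polygon_fraction`` of the SEPL sites are emitted as rectangular
    boundary polygons (side ~3 land units by default) centered on the drawn
    point, the rest as bare center points; decoy sites are always points,
    drawn uniformly over the whole extent.
    """
    if n_sepl > 0 and not params.zones:
        raise ValueError("n_sepl > 0 requires at least one SEPL zone")
    rng = np.random.default_rng(seed)
    west, south, east, north = params.extent
    half = (site_size if site_size is not None else 36 * params.pixel_size) / 2.0
    sites: list[SiteRecord] = []
    zones = params.zones
    for k in range(n_sepl):
        w, s, e, n = zones[rng.integers(0, len(zones))]
        lon = rng.uniform(w, e)
        lat = rng.uniform(s, n)
        if rng.uniform() < polygon_fraction:
            sites.append(
                SiteRecord(
                    id=f"sepl_{k:03d}", region="sepl",
                    polygon=box(lon - half, lat - half, lon + half, lat + half),
                )
            )
        else:
            sites.append(SiteRecord(id=f"sepl_{k:03d}", region="sepl", point=(lon, lat)))
    for k in range(n_random_like):
        lon = rng.uniform(west, east)
        lat = rng.uniform(south, north)
        sites.append(
            SiteRecord(id=f"decoy_{k:03d}", region="background", point=(lon, lat))
        )
    return sites


def generate_conservation_layers(
    params: MosaicParams,
    coverage_fraction: float,
    overlap_fraction: float = 0.3,
    seed: int = 0,
    rect_size: float | None = None,
    max_rects: int = 4000,
) -> tuple[PolygonLayer, PolygonLayer]:
    """Random rectangular protected-area and KBA layers.

    Rectangles are added until the measured areal coverage (on a lattice of
    probe points) reaches ``coverage_fraction``; a KBA rectangle is centered
    inside a random protected-area rectangle with probability
    ``overlap_fraction``, producing the requested pairwise overlap.
    """
    if not 0.0 <= coverage_fraction <= 1.0 or not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    west, south, east, north = params.extent
    width, height = east - west, north - south
    size = rect_size if rect_size is not None else 0.15 * min(width, height)

    nx = ny = 48
    probe_x = west + (np.arange(nx) + 0.5) * width / nx
    probe_y = south + (np.arange(ny) + 0.5) * height / ny
    gx, gy = np.meshgrid(probe_x, probe_y)
    gx, gy = gx.ravel(), gy.ravel()

    def fill(target: float, centers_from: list[tuple[float, float, float, float]] | None):
        if target >= 1.0:
            return [(west, south, east, north)]
        rects: list[tuple[float, float, float, float]] = []
        covered = np.zeros(gx.size, dtype=bool)
        while covered.mean() < target and len(rects) < max_rects:
            if centers_from and rng.uniform() < overlap_fraction:
                w0, s0, e0, n0 = centers_from[rng.integers(0, len(centers_from))]
                cx = rng.uniform(w0, e0)
                cy = rng.uniform(s0, n0)
            else:
                cx = rng.uniform(west, east)
                cy = rng.uniform(south, north)
            rect = (cx - size / 2, cy - size / 2, cx + size / 2, cy + size / 2)
            rects.append(rect)
            covered |= (gx >= rect[0]) & (gx < rect[2]) & (gy >= rect[1]) & (gy < rect[3])
        return rects

    pa_rects = fill(coverage_fraction, None) if coverage_fraction > 0 else []
    kba_rects = fill(coverage_fraction, pa_rects or None) if coverage_fraction > 0 else []
    pa = PolygonLayer(geoms=tuple(box(*r) for r in pa_rects), label="protected_area")
    kba = PolygonLayer(geoms=tuple(box(*r) for r in kba_rects), label="kba")
    return pa, kba
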
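"""Overlap of SEPL-candidate land units with protected areas and KBAs.

A land unit is "inside" a conservation layer when its center point lies in
any of the layer's polygons; points exactly on a polygon boundary count as
inside (closed polygons).  Above-threshold units are cross-tabulated into
four exclusive categories — inside both layers, protected area only, KBA
only, or neither — and the share outside any recognized priority area is
reported.  Layers are plain polygon collections (GeoJSON); a layer covered
by several overlapping designations still counts each unit once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry

from .index_core import LandUnitIndexGrid, threshold_map

__all__ = [
    "PolygonLayer",
    "OverlapTable",
    "Histogram",
    "point_in_layer",
    "categorize_units",
    "subset_histogram",
]

CATEGORIES = ("both", "pa_only", "kba_only", "neither")


def _validate_rings(geom: BaseGeometry) -> None:
    polys = getattr(geom, "geoms", [geom]) if geom.geom_type == "MultiPolygon" else [geom]
    for poly in polys:
        if poly.geom_type != "Polygon":
            continue
        for ring in (poly.exterior, *poly.interiors):
            # a closed ring repeats its first vertex, so 4 coords = triangle
            if len(ring.coords) < 4:
                raise ValueError("degenerate ring with fewer than 3 distinct vertices")


@dataclass
class PolygonLayer:
    """A named collection of (multi)polygons in lon/lat coordinates.

    May be empty (e.g. a region with no protected areas), in which case no
    point is covered.
    """

    geoms: tuple[BaseGeometry, ...]
    label: str = ""

    def __post_init__(self) -> None:
        self.geoms = tuple(self.geoms)
        for geom in self.geoms:
            _validate_rings(geom)
        self._union = shapely.union_all(self.geoms) if self.geoms else None

    def covers_points(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Boundary-inclusive containment for arrays of points."""
        lon = np.asarray(lon, dtype=float)
        if self._union is None:
            return np.zeros(lon.shape, dtype=bool)
        return shapely.covers(self._union, shapely.points(lon, lat))

    @classmethod
    def from_geojson(cls, path: str | Path, label: str = "") -> "PolygonLayer":
        with open(path) as fh:
            collection = json.load(fh)
        if collection.get("type") == "FeatureCollection":
            geoms = [geom_shape(f["geometry"]) for f in collection.get("features", [])]
        else:
            geoms = [geom_shape(collection)]
        return cls(geoms=tuple(geoms), label=label or Path(path).stem)

    def to_geojson(self, path: str | Path) -> None:
        features = [
            {"type": "Feature", "properties": {"layer": self.label},
             "geometry": geom_mapping(g)}
            for g in self.geoms
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


def point_in_layer(point: tuple[float, float], layer: PolygonLayer) -> bool:
    """True if the point lies inside (or on the boundary of) any layer polygon.

    Containment honors holes with the even-odd rule: a point inside a
    polygon's interior ring is outside the polygon.
    """
    lon, lat = point
    if not (np.isfinite(lon) and np.isfinite(lat)):
        raise ValueError("point coordinates must be finite")
    return bool(layer.covers_points(np.asarray([lon]), np.asarray([lat]))[0])


@dataclass
class OverlapTable:
    """Counts of above-threshold land units by conservation category."""

    both: int
    pa_only: int
    kba_only: int
    neither: int

    @property
    def total(self) -> int:
        return self.both + self.pa_only + self.kba_only + self.neither

    @property
    def counts(self) -> dict[str, int]:
        return {c: getattr(self, c) for c in CATEGORIES}

    @property
    def percentages(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {c: 0.0 for c in CATEGORIES}
        return {c: 100.0 * getattr(self, c) / total for c in CATEGORIES}

    @property
    def percent_outside(self) -> float:
        """Share of candidate units outside both layers, in percent."""
        return self.percentages["neither"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(CATEGORIES),
                "count": [getattr(self, c) for c in CATEGORIES],
                "percent": [self.percentages[c] for c in CATEGORIES],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


def categorize_units(
    grid: LandUnitIndexGrid,
    pa: PolygonLayer,
    kba: PolygonLayer,
    threshold: float,
) -> OverlapTable:
    """Cross-tabulate above-threshold units by center containment in PA/KBA layers."""
    candidates = threshold_map(grid, threshold)
    lon, lat = grid.spec.unit_centers()
    in_pa = pa.covers_points(lon, lat) & candidates
    in_kba = kba.covers_points(lon, lat) & candidates
    return OverlapTable(
        both=int((in_pa & in_kba).sum()),
        pa_only=int((in_pa & ~in_kba).sum()),
        kba_only=int((~in_pa & in_kba).sum()),
        neither=int((candidates & ~in_pa & ~in_kba).sum()),
    )


@dataclass
class Histogram:
    """Index-value histogram over half-open bins ``(lower, upper]``.

    The first bin additionally includes exact zeros, so every defined score
    in [0, 1) lands in exactly one bin.
    """

    edges: np.ndarray
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lower": self.edges[:-1],
                "bin_upper": self.edges[1:],
                "count": self.counts,
            }
        )


def subset_histogram(
    grid: LandUnitIndexGrid,
    layer: PolygonLayer | None = None,
    bin_width: float = 0.05,
) -> Histogram:
    """Histogram of defined index values in units whose centers fall in ``layer``.

    With ``layer=None`` the whole grid is binned.  Bins are upper-bound
    inclusive: a score of exactly 0.05 falls in the (0, 0.05] bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    subset = grid.defined.copy()
    if layer is not None:
        lon, lat = grid.spec.unit_centers()
        subset &= layer.covers_points(lon, lat)
    values = grid.si[subset]
    n_bins = int(np.ceil(round(1.0 / bin_width, 9)))
    edges = np.arange(n_bins + 1) * bin_width
    if values.size:
        # upper-inclusive binning: index = ceil(v / w) - 1, zeros into bin 0
        idx = np.ceil(np.round(values / bin_width, 9)).astype(int) - 1
        idx = np.clip(idx, 0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
    else:
        counts = np.zeros(n_bins, dtype=int)
    return Histogram(edges=edges, counts=counts)
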
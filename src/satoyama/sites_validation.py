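"""Site-based validation of the index against random null sites.

Known SEPL sites come in two forms: digitized boundary polygons
(project-style sites) and bare center points (case-study-style sites).  A
polygon site's member land units are those whose centers fall inside the
polygon; a point site's members are the "nine neighbors" — the 3x3 block of
land units centered on the unit containing the point.  Each site is
summarized by the median and maximum index value over its members with a
defined score; sites with none are retained but flagged non-evaluable and
excluded from tests.

Validation draws random nine-neighbor sites from the terrestrial mask and
compares site medians and maxima against them with a one-sided Wilcoxon
rank-sum (Mann-Whitney) test, alternative "sites score higher than random".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry

from .index_core import LandUnitIndexGrid
from .landcover_raster import LandUnitGridSpec

__all__ = [
    "SiteRecord",
    "SiteSummary",
    "RankSumResult",
    "nine_neighbors",
    "site_summary",
    "generate_random_sites",
    "rank_sum_test",
    "validation_report",
    "read_point_sites",
    "write_point_sites",
    "read_polygon_sites",
    "write_polygon_sites",
]

#: Largest sample-size product for which the exact rank-sum null is enumerated.
EXACT_LIMIT = 10_000


@dataclass
class SiteRecord:
    """A known or candidate SEPL site: either a boundary polygon or a center point."""

    id: str
    region: str = ""
    point: tuple[float, float] | None = None
    polygon: BaseGeometry | None = None

    def __post_init__(self) -> None:
        if (self.point is None) == (self.polygon is None):
            raise ValueError(
                f"site {self.id!r}: exactly one of point or polygon must be given"
            )


@dataclass
class SiteSummary:
    """Median and maximum index value over a site's member land units."""

    id: str
    region: str
    members: tuple[tuple[int, int], ...]
    n_defined: int
    median_si: float | None
    max_si: float | None

    @property
    def evaluable(self) -> bool:
        return self.n_defined >= 1


@dataclass
class RankSumResult:
    """One-sided Wilcoxon rank-sum (Mann-Whitney) outcome.

    ``statistic`` is the Mann-Whitney count W = #{(i, j): t_i > r_j}
    (+1/2 per tie), matching the W printed by R's ``wilcox.test``.
    """

    statistic: float
    pvalue: float
    n_treatment: int
    n_random: int
    method: str


def nine_neighbors(center: tuple[float, float],
                   spec: LandUnitGridSpec) -> list[tuple[int, int]]:
    """The 3x3 block of land units around the unit containing ``center``.

    Truncated at grid edges, so corner centers yield 4 units.  Containment
    uses the half-open cell convention of :class:`LandUnitGridSpec`.
    """
    lon, lat = center
    row, col = spec.unit_of_point(lon, lat)
    keys = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            r, c = row + dr, col + dc
            if 0 <= r < spec.unit_rows and 0 <= c < spec.unit_cols:
                keys.append((r, c))
    return keys


def _polygon_members(polygon: BaseGeometry,
                     spec: LandUnitGridSpec) -> list[tuple[int, int]]:
    import shapely

    lon, lat = spec.unit_centers()
    inside = shapely.covers(polygon, shapely.points(lon, lat))
    rows, cols = np.nonzero(inside)
    return [(int(r), int(c)) for r, c in zip(rows, cols)]


def site_summary(site: SiteRecord, grid: LandUnitIndexGrid) -> SiteSummary:
    """Summarize a site's defined index values (median and maximum).

    Polygon sites use unit-center-in-polygon membership (boundary
    inclusive); point sites use the nine neighbors.
    """
    spec = grid.spec
    if site.polygon is not None:
        members = _polygon_members(site.polygon, spec)
    else:
        members = nine_neighbors(site.point, spec)
    values = [grid.si[r, c] for r, c in members if grid.defined[r, c]]
    if values:
        median = float(np.median(values))
        maximum = float(np.max(values))
    else:
        median = maximum = None
    return SiteSummary(
        id=site.id,
        region=site.region,
        members=tuple(members),
        n_defined=len(values),
        median_si=median,
        max_si=maximum,
    )


def generate_random_sites(
    n: int,
    mask: np.ndarray,
    spec: LandUnitGridSpec,
    lat_bounds: tuple[float, float] = (-60.0, 75.0),
    seed: int = 0,
    id_prefix: str = "random",
    region: str = "random",
) -> list[SiteRecord]:
    """Draw ``n`` random point sites on mask-true land units within a latitude band.

    Centers are placed at unit centers, drawn uniformly over eligible cells
    (cell-uniform, not cosine-latitude area-weighted) with replacement, so
    random nine-neighbor clusters may overlap each other or known sites.
    Deterministic under ``seed``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (spec.unit_rows, spec.unit_cols):
        raise ValueError("mask shape does not match the land-unit grid")
    lat_lo, lat_hi = min(lat_bounds), max(lat_bounds)
    _, lat = spec.unit_centers()
    eligible = mask & (lat >= lat_lo) & (lat <= lat_hi)
    rows, cols = np.nonzero(eligible)
    if rows.size == 0:
        raise ValueError("no eligible land unit in the mask/latitude bounds")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, rows.size, size=n)
    sites = []
    for k, i in enumerate(picks):
        lon_c, lat_c = spec.unit_center(int(rows[i]), int(cols[i]))
        sites.append(SiteRecord(id=f"{id_prefix}_{k:04d}", region=region,
                                point=(lon_c, lat_c)))
    return sites


def rank_sum_test(
    treatment: Sequence[float],
    random: Sequence[float],
    alternative: str = "greater",
) -> RankSumResult:
    """One-sided Wilcoxon rank-sum test that treatment values exceed random ones.

    The p-value is exact (full enumeration of the null distribution) when
    both samples are tie-free and ``n_t * n_r <= 10000``, and otherwise a
    normal approximation with tie and continuity corrections — the same
    switch R's ``wilcox.test`` applies.
    """
    t = np.asarray(treatment, dtype=float)
    r = np.asarray(random, dtype=float)
    if t.size == 0 or r.size == 0:
        raise ValueError("both samples must be nonempty")
    w = float((t[:, None] > r[None, :]).sum() + 0.5 * (t[:, None] == r[None, :]).sum())
    has_ties = np.unique(np.concatenate([t, r])).size < t.size + r.size
    if not has_ties and t.size * r.size <= EXACT_LIMIT:
        method = "exact"
    else:
        method = "normal-approx"
    res = stats.mannwhitneyu(
        t, r, alternative=alternative,
        method="exact" if method == "exact" else "asymptotic",
        use_continuity=True,
    )
    return RankSumResult(
        statistic=w,
        pvalue=float(res.pvalue),
        n_treatment=int(t.size),
        n_random=int(r.size),
        method=method,
    )


def validation_report(
    site_groups: Mapping[str, Sequence[SiteSummary]],
    random_groups: Mapping[str, Sequence[SiteSummary]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-group rank-sum comparison of site medians and maxima against random.

    Returns one row per (group, statistic) with sample sizes, means, the W
    statistic, the one-sided p-value, and a significance flag at ``alpha``.
    Non-evaluable sites are dropped from both samples.
    """
    records = []
    for group, summaries in site_groups.items():
        if group not in random_groups:
            raise KeyError(f"no random site set provided for group {group!r}")
        sites = [s for s in summaries if s.evaluable]
        if not sites:
            raise ValueError(f"group {group!r} has no evaluable site")
        rand = [s for s in random_groups[group] if s.evaluable]
        if not rand:
            raise ValueError(f"random set for group {group!r} has no evaluable site")
        for stat_name, attr in (("median", "median_si"), ("max", "max_si")):
            t_vals = [getattr(s, attr) for s in sites]
            r_vals = [getattr(s, attr) for s in rand]
            res = rank_sum_test(t_vals, r_vals)
            records.append(
                {
                    "group": group,
                    "statistic": stat_name,
                    "n_treatment": res.n_treatment,
                    "n_random": res.n_random,
                    "treatment_mean": float(np.mean(t_vals)),
                    "random_mean": float(np.mean(r_vals)),
                    "W": res.statistic,
                    "p": res.pvalue,
                    "significant": res.pvalue < alpha,
                }
            )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Site I/O: CSV center points and GeoJSON polygons

def read_point_sites(path: str | Path) -> list[SiteRecord]:
    """Read center-point sites from a CSV with columns id, lon, lat[, region]."""
    sites = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            sites.append(
                SiteRecord(
                    id=row["id"],
                    region=row.get("region", "") or "",
                    point=(float(row["lon"]), float(row["lat"])),
                )
            )
    return sites


def write_point_sites(sites: Iterable[SiteRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "lon", "lat", "region"])
        for s in sites:
            if s.point is None:
                raise ValueError(f"site {s.id!r} has no center point")
            writer.writerow([s.id, repr(s.point[0]), repr(s.point[1]), s.region])


def read_polygon_sites(path: str | Path) -> list[SiteRecord]:
    """Read polygon sites from a GeoJSON FeatureCollection (id/region properties)."""
    import json

    with open(path) as fh:
        collection = json.load(fh)
    sites = []
    for i, feature in enumerate(collection.get("features", [])):
        props = feature.get("properties") or {}
        sites.append(
            SiteRecord(
                id=str(props.get("id", f"site_{i:04d}")),
                region=str(props.get("region", "")),
                polygon=geom_shape(feature["geometry"]),
            )
        )
    return sites


def write_polygon_sites(sites: Iterable[SiteRecord], path: str | Path) -> None:
    import json

    features = []
    for s in sites:
        if s.polygon is None:
            raise ValueError(f"site {s.id!r} has no polygon")
        features.append(
            {
                "type": "Feature",
                "properties": {"id": s.id, "region": s.region},
                "geometry": geom_mapping(s.polygon),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
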
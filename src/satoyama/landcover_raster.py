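"""Categorical land-cover rasters, legends, and coarse land-unit aggregation.

The analysis operates on two nested grids: a fine categorical raster of
land-cover class codes (~15 arc-second / 500 m pixels in the global product
this package targets) and a coarse grid of *land units* (~180 arc-second /
6 km cells), each spanning ``aggregation_factor`` fine pixels per side
(default 12, so a full land unit holds 144 pixels).  Everything downstream —
diversity indices, site summaries, conservation overlays — consumes the
per-unit class-count table produced here.

Rasters are read and written in the ESRI ASCII grid format (plain text,
north-up, row-major), with geographic coordinates in decimal degrees.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "ClassLegend",
    "LandCoverGrid",
    "LandUnitGridSpec",
    "ClassCountTable",
    "read_landcover",
    "write_landcover",
    "aggregate_counts",
    "select_agricultural_units",
    "write_index_raster",
    "read_index_raster",
    "write_index_table",
]

#: Role-flag tokens understood in legend CSV files.
ROLE_FLAGS = ("agricultural_strict", "agricultural_selection", "urban")


@dataclass(frozen=True)
class ClassLegend:
    """A land-cover class legend with role annotations.

    Parameters
    ----------
    entries
        ``(code, name)`` pairs; codes must be unique positive integers.
    agricultural_strict
        Codes counted as agriculture in the natural-proportion exclusion
        (cropland and paddy in the default 20-class legend).
    agricultural_selection
        Codes whose presence makes a land unit eligible for scoring
        (cropland, paddy, and cropland/other-vegetation mosaic by default).
        Must be a superset of ``agricultural_strict``.
    urban
        Urban codes, excluded from the natural proportion.
    nodata
        Sentinel for missing pixels; must not collide with a legend code.
    """

    entries: tuple[tuple[int, str], ...]
    agricultural_strict: frozenset[int]
    agricultural_selection: frozenset[int]
    urban: frozenset[int]
    nodata: int = 0

    def __post_init__(self) -> None:
        codes = [c for c, _ in self.entries]
        if len(codes) != len(set(codes)):
            raise ValueError("legend codes must be unique")
        code_set = set(codes)
        if not self.agricultural_strict <= self.agricultural_selection:
            raise ValueError("agricultural_strict must be a subset of agricultural_selection")
        if self.urban & self.agricultural_strict:
            raise ValueError("urban codes must be disjoint from agricultural_strict")
        for role, members in (
            ("agricultural_strict", self.agricultural_strict),
            ("agricultural_selection", self.agricultural_selection),
            ("urban", self.urban),
        ):
            missing = set(members) - code_set
            if missing:
                raise ValueError(f"{role} codes {sorted(missing)} not present in legend entries")
        if self.nodata in code_set:
            raise ValueError(f"nodata sentinel {self.nodata} collides with a legend code")

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(c for c, _ in self.entries)

    @property
    def names(self) -> dict[int, str]:
        return dict(self.entries)

    @classmethod
    def from_csv(cls, path: str | Path, nodata: int = 0) -> "ClassLegend":
        """Read a legend from a CSV with columns ``code,name,role_flags``.

        ``role_flags`` is a semicolon-separated list of tokens from
        ``ROLE_FLAGS`` (empty for classes with no special role).
        """
        entries: list[tuple[int, str]] = []
        roles: dict[str, set[int]] = {flag: set() for flag in ROLE_FLAGS}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "code" not in reader.fieldnames:
                raise ValueError(f"legend file {path} lacks a 'code' column")
            for row in reader:
                code = int(row["code"])
                entries.append((code, row.get("name", "").strip()))
                for token in (row.get("role_flags") or "").split(";"):
                    token = token.strip()
                    if not token:
                        continue
                    if token not in roles:
                        raise ValueError(f"unknown role flag {token!r} in {path}")
                    roles[token].add(code)
        return cls(
            entries=tuple(entries),
            agricultural_strict=frozenset(roles["agricultural_strict"]),
            agricultural_selection=frozenset(roles["agricultural_selection"]),
            urban=frozenset(roles["urban"]),
            nodata=nodata,
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["code", "name", "role_flags"])
            for code, name in self.entries:
                flags = []
                if code in self.agricultural_strict:
                    flags.append("agricultural_strict")
                if code in self.agricultural_selection:
                    flags.append("agricultural_selection")
                if code in self.urban:
                    flags.append("urban")
                writer.writerow([code, name, ";".join(flags)])

    @classmethod
    def default(cls) -> "ClassLegend":
        """The packaged 20-class global land-cover legend."""
        ref = resources.files("satoyama.data").joinpath("glcnmo_20class_legend.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


@dataclass
class LandCoverGrid:
    """A north-up categorical raster in geographic coordinates.

    ``values`` holds integer class codes, row 0 being the northernmost row.
    ``west``/``north`` locate the outer corner of the top-left pixel and
    ``pixel_size`` is the square pixel edge in degrees.
    """

    values: np.ndarray
    west: float
    north: float
    pixel_size: float
    nodata_code: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("land-cover raster must have an integer dtype")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def east(self) -> float:
        return self.west + self.shape[1] * self.pixel_size

    @property
    def south(self) -> float:
        return self.north - self.shape[0] * self.pixel_size

    def validate_codes(self, legend: ClassLegend) -> None:
        present = np.unique(self.values)
        legal = set(legend.codes) | {self.nodata_code}
        unknown = sorted(int(c) for c in present if int(c) not in legal)
        if unknown:
            raise ValueError(
                f"raster contains codes not in the legend: {unknown}"
            )


@dataclass(frozen=True)
class LandUnitGridSpec:
    """Geometry of the coarse land-unit grid.

    The coarse grid is anchored at the fine raster's top-left corner; edge
    units on the south/east may be partial.  Point containment uses the
    half-open convention ``[west, east) x (south, north]`` per cell, so a
    point exactly on a shared boundary belongs to the cell to its south-east.
    """

    aggregation_factor: int
    unit_rows: int
    unit_cols: int
    west: float
    north: float
    unit_size: float

    def __post_init__(self) -> None:
        if self.aggregation_factor < 1:
            raise ValueError("aggregation factor must be >= 1")

    @classmethod
    def from_grid(cls, grid: LandCoverGrid, factor: int = 12) -> "LandUnitGridSpec":
        if factor < 1:
            raise ValueError("aggregation factor must be >= 1")
        rows, cols = grid.shape
        return cls(
            aggregation_factor=factor,
            unit_rows=math.ceil(rows / factor),
            unit_cols=math.ceil(cols / factor),
            west=grid.west,
            north=grid.north,
            unit_size=grid.pixel_size * factor,
        )

    def unit_center(self, row: int, col: int) -> tuple[float, float]:
        """Longitude/latitude of the (full-size) cell center."""
        lon = self.west + (col + 0.5) * self.unit_size
        lat = self.north - (row + 0.5) * self.unit_size
        return lon, lat

    def unit_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays of unit-center lon/lat, shape (unit_rows, unit_cols)."""
        lon = self.west + (np.arange(self.unit_cols) + 0.5) * self.unit_size
        lat = self.north - (np.arange(self.unit_rows) + 0.5) * self.unit_size
        return np.meshgrid(lon, lat)

    def contains_point(self, lon: float, lat: float) -> bool:
        col = math.floor((lon - self.west) / self.unit_size)
        row = math.floor((self.north - lat) / self.unit_size)
        return 0 <= row < self.unit_rows and 0 <= col < self.unit_cols

    def unit_of_point(self, lon: float, lat: float) -> tuple[int, int]:
        """Land-unit key containing a point (half-open cell convention)."""
        col = math.floor((lon - self.west) / self.unit_size)
        row = math.floor((self.north - lat) / self.unit_size)
        if not (0 <= row < self.unit_rows and 0 <= col < self.unit_cols):
            raise ValueError(f"point ({lon}, {lat}) is outside the land-unit grid")
        return row, col


@dataclass
class ClassCountTable:
    """Per-land-unit pixel counts per class code.

    This is the sufficient statistic for all index arithmetic: ``counts``
    has shape ``(unit_rows, unit_cols, n_codes)`` aligned with ``codes``,
    and ``n_valid`` counts non-nodata pixels per unit (<= factor**2; equal
    for full interior units, smaller on partial edge units or where nodata
    pixels such as ocean occur).
    """

    codes: np.ndarray
    counts: np.ndarray
    n_valid: np.ndarray
    spec: LandUnitGridSpec

    def unit_counts(self, row: int, col: int) -> dict[int, int]:
        """Nonzero class counts of one unit, as a ``{code: count}`` dict."""
        vec = self.counts[row, col]
        return {int(c): int(n) for c, n in zip(self.codes, vec) if n > 0}

    def keys(self) -> Iterator[tuple[int, int]]:
        for r in range(self.spec.unit_rows):
            for c in range(self.spec.unit_cols):
                yield r, c


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, float, float, float]:
    """Parse an ESRI ASCII grid; returns (values, west, north, cellsize, nodata)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header: dict[str, float] = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            header[parts[0].lower()] = float(parts[1])
            data_start = i + 1
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ValueError(f"{path}: ASCII grid header missing {missing}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    values = np.loadtxt(lines[data_start:], ndmin=2)
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: data block is {values.shape}, header says ({nrows}, {ncols})"
        )
    cellsize = header["cellsize"]
    west = header["xllcorner"]
    north = header["yllcorner"] + nrows * cellsize
    nodata = header.get("nodata_value", -9999.0)
    return values, west, north, cellsize, nodata


def _write_ascii_grid(
    values: np.ndarray,
    west: float,
    north: float,
    cellsize: float,
    nodata: float,
    path: str | Path,
    fmt: str,
) -> None:
    nrows, ncols = values.shape
    yll = north - nrows * cellsize
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {west!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {cellsize!r}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        np.savetxt(fh, values, fmt=fmt)


def read_landcover(path: str | Path, legend: ClassLegend) -> LandCoverGrid:
    """Read a categorical single-band raster, validating codes against the legend."""
    values, west, north, cellsize, nodata = _read_ascii_grid(path)
    if not np.all(values == np.round(values)):
        raise ValueError(f"{path}: land-cover band contains non-integer values")
    grid = LandCoverGrid(
        values=values.astype(np.int64),
        west=west,
        north=north,
        pixel_size=cellsize,
        nodata_code=int(nodata),
    )
    grid.validate_codes(legend)
    return grid


def write_landcover(grid: LandCoverGrid, path: str | Path) -> None:
    _write_ascii_grid(
        grid.values, grid.west, grid.north, grid.pixel_size,
        float(grid.nodata_code), path, fmt="%d",
    )


# ---------------------------------------------------------------------------
# Aggregation

def aggregate_counts(
    grid: LandCoverGrid,
    spec: LandUnitGridSpec | None = None,
    legend: ClassLegend | None = None,
    factor: int = 12,
) -> ClassCountTable:
    """Count fine pixels per class within each coarse land unit.

    Partial edge units (when raster dimensions are not multiples of the
    aggregation factor) are padded with nodata, so their ``n_valid`` simply
    reflects the pixels they actually contain.  Pixel totals are conserved:
    the table sums to the number of non-nodata fine pixels.
    """
    if spec is None:
        spec = LandUnitGridSpec.from_grid(grid, factor=factor)
    f = spec.aggregation_factor
    rows, cols = grid.shape
    pad_r = spec.unit_rows * f - rows
    pad_c = spec.unit_cols * f - cols
    values = grid.values
    if pad_r or pad_c:
        values = np.pad(values, ((0, pad_r), (0, pad_c)),
                        constant_values=grid.nodata_code)
    blocks = values.reshape(spec.unit_rows, f, spec.unit_cols, f)

    if legend is not None:
        codes = np.asarray(sorted(legend.codes), dtype=np.int64)
    else:
        present = np.unique(grid.values)
        codes = np.asarray(
            [c for c in present if c != grid.nodata_code], dtype=np.int64
        )
    counts = np.empty((spec.unit_rows, spec.unit_cols, len(codes)), dtype=np.int64)
    for k, code in enumerate(codes):
        counts[:, :, k] = (blocks == code).sum(axis=(1, 3))
    n_valid = (blocks != grid.nodata_code).sum(axis=(1, 3))
    if not np.array_equal(counts.sum(axis=2), n_valid):
        stray = np.setdiff1d(np.unique(values), np.append(codes, grid.nodata_code))
        raise ValueError(f"raster contains codes missing from the legend: {stray.tolist()}")
    return ClassCountTable(codes=codes, counts=counts, n_valid=n_valid, spec=spec)


def select_agricultural_units(
    table: ClassCountTable, legend: ClassLegend
) -> set[tuple[int, int]]:
    """Land units containing at least one pixel of an agricultural class.

    Selection uses the legend's ``agricultural_selection`` role (cropland,
    paddy, and cropland/other-vegetation mosaic in the default legend).
    """
    mask = selection_mask(table, legend)
    rows, cols = np.nonzero(mask)
    return {(int(r), int(c)) for r, c in zip(rows, cols)}


def selection_mask(table: ClassCountTable, legend: ClassLegend) -> np.ndarray:
    """Boolean (unit_rows, unit_cols) array of agricultural-selection units."""
    sel = np.isin(table.codes, sorted(legend.agricultural_selection))
    return table.counts[:, :, sel].sum(axis=2) >= 1


# ---------------------------------------------------------------------------
# Index-grid output

INDEX_NODATA = -9999.0


def write_index_raster(index_grid, path: str | Path) -> None:
    """Write the per-unit index values as a float ASCII grid (nodata where undefined)."""
    si = np.where(index_grid.defined, index_grid.si, INDEX_NODATA)
    spec = index_grid.spec
    _write_ascii_grid(
        si, spec.west, spec.north, spec.unit_size, INDEX_NODATA, path, fmt="%.9g"
    )


def read_index_raster(path: str | Path):
    """Reload a written index raster as a minimal index grid.

    Only the score band and its footprint are recoverable from the raster;
    the diversity and natural-proportion components are not stored and come
    back as NaN.  Sufficient for thresholding, site summaries, and overlays.
    """
    from .index_core import LandUnitIndexGrid  # deferred: avoids an import cycle

    values, west, north, cellsize, nodata = _read_ascii_grid(path)
    defined = values != nodata
    si = np.where(defined, values, np.nan)
    nrows, ncols = values.shape
    spec = LandUnitGridSpec(
        aggregation_factor=1,
        unit_rows=nrows,
        unit_cols=ncols,
        west=west,
        north=north,
        unit_size=cellsize,
    )
    nan = np.full_like(si, np.nan)
    return LandUnitIndexGrid(
        sdi=nan.copy(), p=nan.copy(), p_raw=nan.copy(), si=si,
        n_valid=np.zeros_like(values, dtype=np.int64),
        defined=defined, spec=spec,
    )


def write_index_table(index_grid, path: str | Path) -> None:
    """Write one CSV row per land unit: key, center lon/lat, components, score."""
    import pandas as pd

    spec = index_grid.spec
    rows, cols = np.meshgrid(
        np.arange(spec.unit_rows), np.arange(spec.unit_cols), indexing="ij"
    )
    lon, lat = spec.unit_centers()
    frame = pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "center_lon": lon.ravel(),
            "center_lat": lat.ravel(),
            "n_valid": index_grid.n_valid.ravel(),
            "sdi": index_grid.sdi.ravel(),
            "p": index_grid.p.ravel(),
            "p_raw": index_grid.p_raw.ravel(),
            "si": index_grid.si.ravel(),
        }
    )
    frame.to_csv(path, index=False, float_format="%.9g")
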
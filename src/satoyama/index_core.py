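"""The Satoyama Index: Simpson diversity times the proportion of natural cover.

For each land unit of ``N`` valid pixels with ``n_i`` pixels in land-cover
class ``i``, the score is

    SI = SDI * P,
    SDI = 1 - sum_i (n_i / N)**2,
    P   = (sum of n_i over natural classes) / (N - 1),

where "natural" means every class except urban and strict agriculture
(cropland and paddy).  The ``N - 1`` denominator makes ``P`` reach 1 in
eligible units, because eligibility requires at least one agricultural
pixel.  The score is defined only on units that (a) contain at least one
pixel of an agricultural-selection class and (b) have ``N >= 2``; other
units carry NaN.

High SI marks heterogeneous mosaics of agriculture interleaved with many
natural cover types — the land-cover signature of socio-ecological
production landscapes (SEPL) such as Japanese satoyama, shifting
cultivation, or traditional agro-pastoral systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .landcover_raster import (
    ClassCountTable,
    ClassLegend,
    LandUnitGridSpec,
    selection_mask,
)

__all__ = [
    "IndexParams",
    "LandUnitIndexGrid",
    "ThresholdRule",
    "simpson_diversity",
    "natural_proportion",
    "satoyama_index",
    "theoretical_max_si",
    "resolve_threshold",
    "threshold_map",
]


@dataclass(frozen=True)
class IndexParams:
    """Parameters of the index computation.

    ``p_excluded_codes`` are removed from the natural-proportion numerator
    (urban + strict agriculture; the cropland/vegetation-mosaic class is used
    for unit *selection* but still counts as natural cover).  ``clip_p``
    caps P at 1: a unit whose only agricultural pixels are of the mosaic
    class has a raw P of N/(N-1), slightly above 1, which the index's
    intended [0, 1] range forbids.  The raw value is kept for diagnostics.
    """

    selection_codes: frozenset[int] = frozenset({11, 12, 13})
    p_excluded_codes: frozenset[int] = frozenset({18, 11, 12})
    clip_p: bool = True

    def __post_init__(self) -> None:
        if not self.p_excluded_codes:
            raise ValueError("p_excluded_codes must be nonempty")

    @classmethod
    def from_legend(cls, legend: ClassLegend, clip_p: bool = True) -> "IndexParams":
        return cls(
            selection_codes=frozenset(legend.agricultural_selection),
            p_excluded_codes=frozenset(legend.urban | legend.agricultural_strict),
            clip_p=clip_p,
        )


@dataclass
class LandUnitIndexGrid:
    """Per-land-unit index surfaces on the coarse grid.

    All float arrays have shape ``(unit_rows, unit_cols)`` and are NaN
    where the score is undefined; ``defined`` is the corresponding boolean
    mask.  ``p_raw`` is the natural proportion before clipping at 1.
    """

    sdi: np.ndarray
    p: np.ndarray
    p_raw: np.ndarray
    si: np.ndarray
    n_valid: np.ndarray
    defined: np.ndarray
    spec: LandUnitGridSpec

    @property
    def n_defined(self) -> int:
        return int(self.defined.sum())

    @property
    def n_clipped(self) -> int:
        """Units whose natural proportion was clipped from above 1."""
        with np.errstate(invalid="ignore"):
            return int(np.nansum((self.p_raw > 1.0) & self.defined))

    def defined_values(self) -> np.ndarray:
        """1-D array of the defined scores."""
        return self.si[self.defined]


def _as_count_vector(counts: Mapping[int, int] | Sequence[int]) -> np.ndarray:
    if isinstance(counts, Mapping):
        return np.asarray(list(counts.values()), dtype=float)
    return np.asarray(counts, dtype=float)


def simpson_diversity(counts: Mapping[int, int] | Sequence[int],
                      n_valid: int | None = None) -> float:
    """Simpson diversity 1 - sum p_i**2 of one unit's class counts.

    ``counts`` maps class code to pixel count (or is a bare count vector);
    ``n_valid`` defaults to the counts' sum.  Ranges over [0, 1 - 1/k] for
    k occupied classes.
    """
    vec = _as_count_vector(counts)
    if np.any(vec < 0):
        raise ValueError("class counts must be non-negative")
    total = float(vec.sum()) if n_valid is None else float(n_valid)
    if total < 1:
        raise ValueError("simpson_diversity requires at least one valid pixel")
    return float(1.0 - np.sum((vec / total) ** 2))


def natural_proportion(counts: Mapping[int, int], n_valid: int | None = None,
                       params: IndexParams | None = None) -> float:
    """Proportion of natural cover, (sum of natural n_i) / (N - 1).

    Excludes urban and strict-agriculture codes from the numerator and uses
    the ``N - 1`` denominator so that a unit with a single agricultural
    pixel and otherwise natural cover scores exactly 1.
    """
    params = params or IndexParams()
    if n_valid is None:
        n_valid = int(sum(counts.values()))
    if n_valid < 2:
        raise ValueError("natural_proportion requires at least two valid pixels")
    natural = sum(n for code, n in counts.items()
                  if code not in params.p_excluded_codes)
    p = natural / (n_valid - 1)
    if params.clip_p:
        p = min(p, 1.0)
    return float(p)


def satoyama_index(table: ClassCountTable, params: IndexParams | None = None,
                   legend: ClassLegend | None = None) -> LandUnitIndexGrid:
    """Compute SDI, P, and SI for every eligible land unit of a count table.

    Eligibility follows the selection rule (>= 1 agricultural-selection
    pixel) and requires ``n_valid >= 2`` for the ``N - 1`` denominator;
    every other unit is NaN.  Partial units (coasts, raster edges) use
    their own ``n_valid`` as ``N``.
    """
    if params is None:
        params = IndexParams.from_legend(legend) if legend else IndexParams()

    codes = table.codes
    counts = table.counts.astype(float)
    n_valid = table.n_valid.astype(float)

    sel = np.isin(codes, sorted(params.selection_codes))
    selected = counts[:, :, sel].sum(axis=2) >= 1
    defined = selected & (table.n_valid >= 2)

    with np.errstate(divide="ignore", invalid="ignore"):
        sdi = 1.0 - (counts ** 2).sum(axis=2) / n_valid ** 2
        excluded = np.isin(codes, sorted(params.p_excluded_codes))
        natural = counts[:, :, ~excluded].sum(axis=2)
        p_raw = natural / (n_valid - 1.0)
    p = np.minimum(p_raw, 1.0) if params.clip_p else p_raw.copy()
    si = sdi * p

    nan = np.nan
    for arr in (sdi, p, p_raw, si):
        arr[~defined] = nan
    return LandUnitIndexGrid(
        sdi=sdi, p=p, p_raw=p_raw, si=si,
        n_valid=table.n_valid.copy(), defined=defined, spec=table.spec,
    )


def theoretical_max_si(k: int, a: float, n_pixels: int = 144) -> float:
    """Upper bound of SI for k cover classes and agricultural fraction a.

    The bound is attained when the non-agricultural fraction ``1 - a`` is
    split equally among the ``k - 1`` remaining classes:

        SDI_max = 1 - a**2 - (1 - a)**2 / (k - 1)
        P_max   = min(1, (1 - a) * N / (N - 1))

    Urban cover is not discounted (every non-agricultural class counts as
    natural), so the bound is conservative for landscapes with towns.
    Continuous in ``a``; integer pixel allocations fall short by at most
    the 1/N discretization gap.
    """
    if k < 2:
        raise ValueError("at least two cover classes are required")
    if not 0.0 < a <= 1.0:
        raise ValueError("agricultural fraction must be in (0, 1]")
    if n_pixels < 2:
        raise ValueError("n_pixels must be >= 2")
    sdi_max = 1.0 - a ** 2 - (1.0 - a) ** 2 / (k - 1)
    p_max = min(1.0, (1.0 - a) * n_pixels / (n_pixels - 1))
    return float(sdi_max * p_max)


@dataclass
class ThresholdRule:
    """How the SEPL threshold is derived from reference-site summaries.

    The per-site statistic defaults to the maximum because maxima are what
    discriminate known SEPL sites from random ones (site boundaries often
    wrap extensive non-SEPL area, deflating medians).  The percentile uses
    linear interpolation.
    """

    percentile: float = 50.0
    statistic: str = "max"
    value: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.percentile <= 100.0:
            raise ValueError("percentile must be in [0, 100]")
        if self.statistic not in ("max", "median"):
            raise ValueError("statistic must be 'max' or 'median'")


def resolve_threshold(summaries: Iterable, rule: ThresholdRule | None = None) -> float:
    """Percentile of a per-site statistic over evaluable reference sites."""
    rule = rule or ThresholdRule()
    attr = "max_si" if rule.statistic == "max" else "median_si"
    values = [getattr(s, attr) for s in summaries if getattr(s, "evaluable", True)]
    values = [v for v in values if v is not None and np.isfinite(v)]
    if not values:
        raise ValueError("no evaluable site statistic to derive a threshold from")
    threshold = float(np.percentile(values, rule.percentile))
    rule.value = threshold
    return threshold


def threshold_map(grid: LandUnitIndexGrid, threshold: float) -> np.ndarray:
    """Boolean mask of SEPL-candidate units: defined and SI >= threshold."""
    with np.errstate(invalid="ignore"):
        return grid.defined & (np.nan_to_num(grid.si, nan=-np.inf) >= threshold)
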
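"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written the slow, obvious way (per-pixel
Python loops, full enumeration) and shares no code with the package paths
it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

AG_SELECTION = {11, 12, 13}
P_EXCLUDED = {18, 11, 12}


def pixel_scan_counts(values, nodata, factor):
    """Per-unit class counts by looping over every fine pixel."""
    rows = len(values)
    cols = len(values[0])
    units = {}
    for i in range(rows):
        for j in range(cols):
            v = int(values[i][j])
            if v == nodata:
                continue
            key = (i // factor, j // factor)
            units.setdefault(key, {})
            units[key][v] = units[key].get(v, 0) + 1
    return units


def scalar_index(counts: dict[int, int]) -> tuple[float, float, float] | None:
    """(sdi, p, si) from one unit's counts, or None when undefined."""
    n_valid = sum(counts.values())
    if n_valid < 2:
        return None
    if not any(code in AG_SELECTION for code in counts):
        return None
    sdi = 1.0 - sum(n * n for n in counts.values()) / n_valid**2
    natural = sum(n for code, n in counts.items() if code not in P_EXCLUDED)
    p = min(1.0, natural / (n_valid - 1))
    return sdi, p, sdi * p


def enumerate_rank_sum(treatment, random):
    """Exact one-sided rank-sum test by full enumeration (tie-free samples).

    Returns (W, p) where W counts pairs with treatment > random and p is the
    probability, under random assignment of the pooled values to the two
    groups, of a W at least as large as observed.
    """
    t = list(treatment)
    r = list(random)
    pooled = t + r
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free samples"

    def w_of(group):
        rest = [v for v in pooled if v not in group]
        return sum(1 for a in group for b in rest if a > b)

    w_obs = w_of(t)
    n_t = len(t)
    hits = 0
    total = 0
    for combo in combinations(pooled, n_t):
        total += 1
        if w_of(list(combo)) >= w_obs:
            hits += 1
    return w_obs, hits / total


def enumerate_allocations(n_pixels: int, k: int, ag_count: int):
    """All allocations of n_pixels into 1 agricultural + (k-1) occupied natural classes."""
    remaining = n_pixels - ag_count
    if k == 2:
        if remaining >= 1:
            yield (ag_count, remaining)
        return
    # compositions of `remaining` into k-1 positive parts
    for cuts in combinations(range(1, remaining), k - 2):
        parts = []
        prev = 0
        for c in cuts:
            parts.append(c - prev)
            prev = c
        parts.append(remaining - prev)
        yield (ag_count, *parts)


def allocation_si(allocation, n_pixels: int) -> float:
    """SI of an integer allocation (first entry agricultural, rest natural)."""
    sdi = 1.0 - sum(n * n for n in allocation) / n_pixels**2
    p = min(1.0, (n_pixels - allocation[0]) / (n_pixels - 1))
    return sdi * p


def ray_cast_inside(lon, lat, rings):
    """Even-odd ray casting over a polygon's rings (exterior + holes).

    Points exactly on an edge are reported as inside, matching the
    boundary-inclusive convention of the overlay module.
    """
    crossings = 0
    for ring in rings:
        n = len(ring)
        for i in range(n):
            x1, y1 = ring[i]
            x2, y2 = ring[(i + 1) % n]
            # on-edge check
            cross = (x2 - x1) * (lat - y1) - (y2 - y1) * (lon - x1)
            if (
                abs(cross) < 1e-12
                and min(x1, x2) - 1e-12 <= lon <= max(x1, x2) + 1e-12
                and min(y1, y2) - 1e-12 <= lat <= max(y1, y2) + 1e-12
            ):
                return True
            if (y1 > lat) != (y2 > lat):
                x_at = x1 + (lat - y1) * (x2 - x1) / (y2 - y1)
                if x_at > lon:
                    crossings += 1
    return crossings % 2 == 1
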
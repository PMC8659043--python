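"""m/z x retention-time zone partition of markers and condition comparison.

Used to localize the effect of a treatment (e.g. performic-acid
disinfection of wastewater effluent) on the detected chemical space:
consensus features are binned into rectangular zones of the m/z x RT plane
(default 2x2: m/z split at 500 Th, RT split at 10 min, bounded at 25 min)
and per-zone marker counts and summed areas are compared before/after.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .feature_io import ConsensusFeature

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ZoneDefinition:
    """Strictly increasing zone edges on each axis.

    Zones are numbered row-major by (rt band, mz band): zone 1 = low mz/low
    rt, zone 2 = high mz/low rt, zone 3 = low mz/high rt, zone 4 = high
    mz/high rt for the default 2x2 grid.  Intervals are half-open [lo, hi),
    the top interval closed at the global maximum.
    """

    mz_edges: tuple[float, ...] = (0.0, 500.0, 1000.0)
    rt_edges: tuple[float, ...] = (0.0, 10.0, 25.0)

    def __post_init__(self) -> None:
        for name, edges in (("mz_edges", self.mz_edges), ("rt_edges", self.rt_edges)):
            e = tuple(float(v) for v in edges)
            if len(e) < 2:
                raise ValueError(f"{name} needs at least two edges")
            if any(b <= a for a, b in zip(e, e[1:])):
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, e)

    @property
    def n_zones(self) -> int:
        return (len(self.mz_edges) - 1) * (len(self.rt_edges) - 1)

    def zone_id(self, mz: float, rt: float) -> int | None:
        """1-based zone id, or None when outside the global bounds."""
        i = _band(mz, self.mz_edges)
        j = _band(rt, self.rt_edges)
        if i is None or j is None:
            return None
        return j * (len(self.mz_edges) - 1) + i + 1


def _band(value: float, edges: tuple[float, ...]) -> int | None:
    if value < edges[0] or value > edges[-1]:
        return None
    if value == edges[-1]:  # top edge closed at the global maximum
        return len(edges) - 2
    return int(np.searchsorted(edges, value, side="right")) - 1


@dataclass
class ZoneStats:
    """Per-zone marker count and summed area, plus the out-of-bounds remainder."""

    zones: ZoneDefinition
    counts: dict[int, int]
    areas: dict[int, float]
    n_excluded: int = 0

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


def partition_zones(
    features: Sequence[ConsensusFeature], zones: ZoneDefinition
) -> tuple[dict[int, int], int]:
    """Assign each feature to a zone id; returns (assignment by position, excluded count).

    Features outside the global mz/rt bounds are excluded and counted in a
    logged remainder.
    """
    assignment: dict[int, int] = {}
    excluded = 0
    for idx, f in enumerate(features):
        z = zones.zone_id(f.mz, f.rt)
        if z is None:
            excluded += 1
        else:
            assignment[idx] = z
    if excluded:
        logger.info("%d features outside zone bounds (excluded)", excluded)
    return assignment, excluded


def zone_summary(features: Sequence[ConsensusFeature], zones: ZoneDefinition) -> ZoneStats:
    """Per-zone marker counts and summed mean areas."""
    assignment, excluded = partition_zones(features, zones)
    counts = {z: 0 for z in range(1, zones.n_zones + 1)}
    areas = {z: 0.0 for z in range(1, zones.n_zones + 1)}
    for idx, z in assignment.items():
        counts[z] += 1
        areas[z] += features[idx].mean_area
    return ZoneStats(zones=zones, counts=counts, areas=areas, n_excluded=excluded)


def compare_conditions(before: ZoneStats, after: ZoneStats) -> pd.DataFrame:
    """Per-zone deltas and after/before ratios of counts and areas.

    Ratios over a zero before-value are None (logged); the two stats must
    share a zone definition.
    """
    if before.zones != after.zones:
        raise ValueError("before/after use different zone definitions")
    rows = {}
    for z in range(1, before.zones.n_zones + 1):
        cb, ca = before.counts[z], after.counts[z]
        ab, aa = before.areas[z], after.areas[z]
        count_ratio = ca / cb if cb else None
        area_ratio = aa / ab if ab else None
        if cb == 0 or ab == 0:
            logger.warning("zone %d has zero before-value; ratio undefined", z)
        rows[z] = {
            "count_before": cb,
            "count_after": ca,
            "delta_count": ca - cb,
            "count_ratio": count_ratio,
            "area_before": ab,
            "area_after": aa,
            "delta_area": aa - ab,
            "area_ratio": area_ratio,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "zone"
    return out
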
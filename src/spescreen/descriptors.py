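"""Per-sample feature descriptors and percentage comparisons.

Summarizes a cartridge's consensus feature set by the indicators used to
rank SPE phases: feature count, total area, plain and area-weighted average
m/z, and plain and area-weighted average retention expressed as the % of
acetonitrile (%ACN) in the mobile phase at the feature's elution time —
a polarity proxy obtained from the gradient program.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .feature_io import ConsensusFeature


@dataclass(frozen=True)
class GradientProgram:
    """Piecewise-linear mobile-phase gradient: (time min, % organic) breakpoints.

    Times must be strictly increasing and start at 0; percentages lie in
    [0, 100].  %ACN is identified with %B (mobile phase B is acetonitrile);
    no dwell-volume or dead-time correction is applied.
    """

    breakpoints: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        bp = tuple((float(t), float(p)) for t, p in self.breakpoints)
        if len(bp) < 2:
            raise ValueError("gradient needs at least two breakpoints")
        times = [t for t, _ in bp]
        if times[0] != 0:
            raise ValueError("gradient must start at time 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("gradient times must be strictly increasing")
        if any(not 0 <= p <= 100 for _, p in bp):
            raise ValueError("percent organic must lie in [0, 100]")
        object.__setattr__(self, "breakpoints", bp)

    @classmethod
    def default(cls, run_length: float = 34.0) -> "GradientProgram":
        """Linear 5 -> 95 %B over the run (documented default, not an instrument program)."""
        return cls(((0.0, 5.0), (float(run_length), 95.0)))

    @classmethod
    def from_csv(cls, path) -> "GradientProgram":
        df = pd.read_csv(path)
        if not {"time_min", "percent_b"} <= set(df.columns):
            raise ValueError("gradient CSV needs columns time_min, percent_b")
        return cls(tuple(zip(df["time_min"], df["percent_b"])))


@dataclass
class SampleDescriptors:
    """Feature-set indicators for one sample/cartridge.

    Averages are None when the sample has no features.  Retention values are
    in %ACN; weighted variants use each feature's mean area as weight.
    """

    n_features: int
    total_area: float
    avg_mz: float | None
    wavg_mz: float | None
    avg_retention: float | None
    wavg_retention: float | None


def rt_to_percent_organic(rt: float, gradient: GradientProgram) -> float:
    """%ACN at elution time ``rt`` by piecewise-linear interpolation.

    Times beyond the last breakpoint clamp to the final percentage.
    """
    if rt < 0:
        raise ValueError("retention time must be non-negative")
    times = np.array([t for t, _ in gradient.breakpoints])
    percents = np.array([p for _, p in gradient.breakpoints])
    return float(np.interp(rt, times, percents))


def compute_descriptors(
    features: Sequence[ConsensusFeature], gradient: GradientProgram
) -> SampleDescriptors:
    """Compute count, total area and (weighted) average m/z and %ACN retention."""
    n = len(features)
    if n == 0:
        return SampleDescriptors(0, 0.0, None, None, None, None)
    mz = np.array([f.mz for f in features])
    area = np.array([f.mean_area for f in features])
    acn = np.array([rt_to_percent_organic(f.rt, gradient) for f in features])
    wsum = area.sum()
    return SampleDescriptors(
        n_features=n,
        total_area=float(wsum),
        avg_mz=float(mz.mean()),
        wavg_mz=float((mz * area).sum() / wsum),
        avg_retention=float(acn.mean()),
        wavg_retention=float((acn * area).sum() / wsum),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def percent_fewer(count_a: int, count_ref: int) -> int:
    """Whole-percent deficit of ``count_a`` relative to ``count_ref``.

    ``round((count_ref - count_a) / count_ref * 100)``, ties away from zero.
    """
    if count_ref <= 0:
        raise ValueError("reference count must be positive")
    return _round_half_away((count_ref - count_a) / count_ref * 100)


def percent_more(count_a: int, count_ref: int) -> int:
    """Whole-percent excess of ``count_a`` relative to ``count_ref``."""
    if count_ref <= 0:
        raise ValueError("reference count must be positive")
    return _round_half_away((count_a - count_ref) / count_ref * 100)


def mz_distribution(
    features: Sequence[ConsensusFeature], bin_width: float = 100.0
) -> dict[float, int]:
    """Histogram of feature m/z in half-open bins [k*w, (k+1)*w) -> count."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    out: dict[float, int] = {}
    for f in features:
        edge = math.floor(f.mz / bin_width) * bin_width
        out[edge] = out.get(edge, 0) + 1
    return dict(sorted(out.items()))


def descriptor_table(
    consensus_sets: dict[str, Sequence[ConsensusFeature]], gradient: GradientProgram
) -> pd.DataFrame:
    """Descriptors for several samples as one DataFrame (rows = samples)."""
    rows = {}
    for sample, feats in consensus_sets.items():
        d = compute_descriptors(feats, gradient)
        rows[sample] = {
            "n_features": d.n_features,
            "total_area": d.total_area,
            "avg_mz": d.avg_mz,
            "wavg_mz": d.wavg_mz,
            "avg_retention": d.avg_retention,
            "wavg_retention": d.wavg_retention,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
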
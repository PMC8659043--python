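"""Excitation-emission matrix handling and fluorescence regional integration.

An EEM is a fluorescence intensity landscape over excitation (default
240-450 nm every 5 nm) and emission (250-600 nm every 2 nm) wavelengths.
Fluorescence regional integration (FRI) partitions the ex-em plane into
five literature regions — I/II (aromatic proteins), III (fulvic-like),
IV (microbial byproducts), V (humic-like) — integrates the intensity volume
in each, normalizes by inverse fractional projected area (multiplication
factor MF), and reports the percent distribution.  Comparing regional
volumes before and after SPE loading gives a per-region DOM retention.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_GRID_ATOL = 1e-9


class EEMParseError(ValueError):
    """Malformed EEM text grid."""


def default_ex_grid() -> np.ndarray:
    """Excitation 240-450 nm every 5 nm (43 wavelengths)."""
    return np.linspace(240.0, 450.0, 43)


def default_em_grid() -> np.ndarray:
    """Emission 250-600 nm every 2 nm (176 wavelengths)."""
    return np.linspace(250.0, 600.0, 176)


@dataclass
class EEMSpectrum:
    """Fluorescence intensity grid with A254 and the applied dilution factor.

    ``intensity[i, j]`` is the signal at excitation ``ex[i]`` and emission
    ``em[j]`` of the (possibly diluted) measured sample; ``dilution_factor``
    is re-multiplied during integration so volumes refer to the undiluted
    sample.
    """

    ex: np.ndarray
    em: np.ndarray
    intensity: np.ndarray
    a254: float = 0.0
    dilution_factor: int = 1

    def __post_init__(self) -> None:
        self.ex = np.asarray(self.ex, dtype=float)
        self.em = np.asarray(self.em, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        for name, grid in (("ex", self.ex), ("em", self.em)):
            if grid.ndim != 1 or grid.size < 2:
                raise ValueError(f"{name} grid must be 1-D with at least two points")
            if not np.all(np.diff(grid) > 0):
                raise ValueError(f"{name} grid must be strictly increasing")
        if self.intensity.shape != (self.ex.size, self.em.size):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match grids "
                f"({self.ex.size}, {self.em.size})"
            )
        if (self.intensity < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.a254 < 0:
            raise ValueError("a254 must be non-negative")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class FriRegion:
    """Rectangular FRI region: half-open [lo, hi) ranges on both axes.

    The upper edge is closed at the measured grid maximum, so top regions
    may use ``inf`` upper bounds.
    """

    label: str
    ex_range: tuple[float, float]
    em_range: tuple[float, float]


@dataclass
class FriResult:
    """Regional volumes and percent distribution.

    ``raw_volume`` is the dilution-corrected rectangle-rule volume per
    region (intensity x nm^2); ``mf`` the inverse fractional projected area;
    ``normalized_volume = mf x raw_volume``; ``percent`` the normalized
    volumes as a distribution summing to 100.
    """

    regions: list[str]
    raw_volume: dict[str, float]
    mf: dict[str, float]
    normalized_volume: dict[str, float]
    percent: dict[str, float]


def default_regions() -> list[FriRegion]:
    """The five FRI literature regions, to be clipped to the measured grid."""
    inf = math.inf
    return [
        FriRegion("I", (0.0, 250.0), (0.0, 330.0)),
        FriRegion("II", (0.0, 250.0), (330.0, 380.0)),
        FriRegion("III", (0.0, 250.0), (380.0, inf)),
        FriRegion("IV", (250.0, inf), (0.0, 380.0)),
        FriRegion("V", (250.0, inf), (380.0, inf)),
    ]


# ---------------------------------------------------------------------------
# text-grid I/O
# ---------------------------------------------------------------------------


def write_eem(eem: EEMSpectrum, path) -> None:
    """Write the EEM text grid: ``# key=value`` headers, then em wavelengths
    across the first row and ex wavelengths down the first column."""
    with open(path, "w") as fh:
        fh.write(f"# a254={eem.a254:.12g}\n")
        fh.write(f"# dilution={eem.dilution_factor}\n")
        fh.write("ex\\em\t" + "\t".join(f"{v:.12g}" for v in eem.em) + "\n")
        for x, row in zip(eem.ex, eem.intensity):
            fh.write(f"{x:.12g}\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_eem(path) -> EEMSpectrum:
    """Read the EEM text grid written by :func:`write_eem`."""
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(\w+)\s*=\s*(\S+)", line)
                if m:
                    meta[m.group(1)] = m.group(2)
                continue
            rows.append(line.split("\t"))
    if "a254" not in meta:
        raise EEMParseError("missing required header key: a254")
    if not rows:
        raise EEMParseError("no grid data")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise EEMParseError("ragged rows in EEM grid")
    try:
        em = np.array([float(v) for v in rows[0][1:]])
        ex = np.array([float(r[0]) for r in rows[1:]])
        intensity = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
    except ValueError as exc:
        raise EEMParseError(f"non-numeric value in EEM grid: {exc}") from exc
    try:
        return EEMSpectrum(
            ex=ex,
            em=em,
            intensity=intensity,
            a254=float(meta["a254"]),
            dilution_factor=int(meta.get("dilution", 1)),
        )
    except ValueError as exc:
        raise EEMParseError(str(exc)) from exc


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def dilution_for_inner_filter(a254: float, threshold: float = 0.1) -> int:
    """Smallest integer dilution bringing A254 to the inner-filter limit.

    Samples whose absorbance at 254 nm exceeds ``threshold`` must be diluted
    before fluorescence measurement; returns the smallest integer ``d >= 1``
    with ``a254 / d <= threshold``.
    """
    if a254 < 0:
        raise ValueError("a254 must be non-negative")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    # round() guards ratios that are integral up to float noise
    return max(1, math.ceil(round(a254 / threshold, 9)))


def _grid_weights(grid: np.ndarray) -> np.ndarray:
    """Per-node quadrature weights (trapezoid cell widths); they sum to the span."""
    w = np.empty_like(grid)
    w[0] = (grid[1] - grid[0]) / 2
    w[-1] = (grid[-1] - grid[-2]) / 2
    w[1:-1] = (grid[2:] - grid[:-2]) / 2
    return w


def _region_masks(eem: EEMSpectrum, region: FriRegion) -> tuple[np.ndarray, np.ndarray]:
    def mask(grid: np.ndarray, lo: float, hi: float) -> np.ndarray:
        m = (grid >= lo - _GRID_ATOL) & (grid < hi - _GRID_ATOL)
        # closed upper edge at the global grid maximum
        m |= (np.abs(grid - grid[-1]) <= _GRID_ATOL) & (hi >= grid[-1] - _GRID_ATOL)
        m &= grid >= lo - _GRID_ATOL
        return m

    return mask(eem.ex, *region.ex_range), mask(eem.em, *region.em_range)


def integrate_region(eem: EEMSpectrum, region: FriRegion) -> float:
    """Rectangle-rule volume of the EEM over one region (no dilution scaling).

    Sums intensity x local Δex x Δem over grid nodes inside the region;
    region edges are half-open above except at the global grid maxima.
    """
    ex_mask, em_mask = _region_masks(eem, region)
    if not ex_mask.any() or not em_mask.any():
        logger.warning("region %s does not overlap the measured grid", region.label)
        return 0.0
    wx = _grid_weights(eem.ex)[ex_mask]
    wy = _grid_weights(eem.em)[em_mask]
    block = eem.intensity[np.ix_(ex_mask, em_mask)]
    return float(wx @ block @ wy)


def fri(eem: EEMSpectrum, regions: list[FriRegion] | None = None) -> FriResult:
    """Fluorescence regional integration over a tiling region set.

    Regions must tile the measured grid without overlap (checked on grid
    nodes).  Raw volumes are scaled by the spectrum's dilution factor; the
    multiplication factor MF_i is the inverse fractional projected area,
    and the percent distribution is computed from the MF-normalized volumes.
    """
    if regions is None:
        regions = default_regions()
    coverage = np.zeros_like(eem.intensity, dtype=int)
    for region in regions:
        ex_mask, em_mask = _region_masks(eem, region)
        coverage[np.ix_(ex_mask, em_mask)] += 1
    if (coverage > 1).any():
        raise ValueError("FRI regions overlap on the measured grid")
    if (coverage == 0).any():
        raise ValueError("FRI regions do not cover the measured grid")

    wx = _grid_weights(eem.ex)
    wy = _grid_weights(eem.em)
    total_projected = float(wx.sum() * wy.sum())

    labels = [r.label for r in regions]
    raw: dict[str, float] = {}
    mf: dict[str, float] = {}
    for region in regions:
        ex_mask, em_mask = _region_masks(eem, region)
        raw[region.label] = integrate_region(eem, region) * eem.dilution_factor
        projected = float(wx[ex_mask].sum() * wy[em_mask].sum())
        mf[region.label] = total_projected / projected if projected > 0 else math.nan
    normalized = {lab: mf[lab] * raw[lab] for lab in labels}
    total_norm = sum(normalized.values())
    if total_norm > 0:
        percent = {lab: 100.0 * normalized[lab] / total_norm for lab in labels}
    else:
        percent = {lab: 0.0 for lab in labels}
    return FriResult(
        regions=labels, raw_volume=raw, mf=mf, normalized_volume=normalized, percent=percent
    )


def fri_retention(before: FriResult, after: FriResult) -> dict[str, float | None]:
    """Per-region DOM retention % between before/after-loading FRI results.

    ``100 x (V_before - V_after) / V_before`` on raw (dilution-corrected)
    volumes; regions with no before-signal yield None, and negative values
    (more signal after loading) are allowed with a warning.
    """
    if before.regions != after.regions:
        raise ValueError("before/after FRI results use different region definitions")
    out: dict[str, float | None] = {}
    for lab in before.regions:
        vb = before.raw_volume[lab]
        if vb == 0:
            logger.warning("region %s has zero before-volume; retention undefined", lab)
            out[lab] = None
            continue
        r = 100.0 * (vb - after.raw_volume[lab]) / vb
        if r < 0:
            logger.warning("negative retention in region %s (%.1f%%)", lab, r)
        out[lab] = r
    return out
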
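"""Internal-standard recovery, matrix-effect classification and system QC.

Extraction efficiency of an SPE cartridge is measured from isotopically
labeled internal standards spiked into the water sample before extraction:
the area of each standard detected in the extract is compared with the area
of the neat standard mix, after accounting for the enrichment of the
extraction (1 L of sample reconstituted in 1 mL -> concentration factor
1000 by default).  UV absorbance at 254 nm before/after cartridge loading
quantifies bulk DOM retention, and reference-standard injections gate
system suitability (mass error, peak width).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InternalStandard:
    """A deuterated standard spiked at known concentration.

    ``reference_area`` is the detector area of the neat standard mix per
    unit spike concentration at injection; with a linear detector response,
    an extract at full recovery gives ``reference_area x
    concentration_factor``.
    """

    name: str
    mz: float
    rt_window: tuple[float, float]
    spike_concentration: float = 100.0  # ng/L in the water sample
    reference_area: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.rt_window
        if not lo <= hi:
            raise ValueError("rt_window must be (low, high) with low <= high")
        if self.reference_area <= 0:
            raise ValueError("reference_area must be positive")


@dataclass
class RecoveryResult:
    standard: str
    sample: str
    recovery: float  # percent
    classification: str


@dataclass(frozen=True)
class QcThresholds:
    """System-suitability gates: ppm mass error and seconds peak width."""

    max_mass_error: float = 2.0
    max_peak_width: float = 3.0

    def __post_init__(self) -> None:
        if self.max_mass_error <= 0 or self.max_peak_width <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass
class DomRetention:
    """UV254 before/after cartridge loading and the derived % retention."""

    uv254_before: float
    uv254_after: float
    retention: float


@dataclass
class SuitabilityReport:
    passed: bool
    mean_mass_error: float
    mean_peak_width: float
    failures: list[str]


def compute_recovery(
    extract_area: float,
    standard: InternalStandard,
    concentration_factor: float = 1000.0,
    sample: str = "",
) -> RecoveryResult:
    """Recovery % of an internal standard from its extract area.

    ``recovery = 100 x extract_area / (reference_area x concentration_factor)``:
    the denominator is the area a fully recovered extract would give, the
    spike concentration cancelling because ``reference_area`` is expressed
    per unit spike concentration.  Raw (not matrix-corrected) by default;
    divide by the ultrapure-water recovery for a matrix-relative value.
    """
    if standard.reference_area <= 0:
        raise ValueError("reference_area must be positive")
    if concentration_factor <= 0:
        raise ValueError("concentration_factor must be positive")
    if extract_area < 0:
        raise ValueError("extract_area must be non-negative")
    recovery = 100.0 * extract_area / (standard.reference_area * concentration_factor)
    return RecoveryResult(
        standard=standard.name,
        sample=sample,
        recovery=recovery,
        classification=classify_recovery(recovery),
    )


def classify_recovery(
    recovery: float, low: float = 80.0, high: float = 120.0, outlier: float = 1000.0
) -> str:
    """Matrix-effect call: suppression (<low), ok, enhancement (>high),
    excluded_outlier (>outlier, e.g. anomalous >1000% values dropped from
    reporting)."""
    if recovery < 0:
        raise ValueError("recovery must be non-negative")
    if recovery > outlier:
        return "excluded_outlier"
    if recovery > high:
        return "enhancement"
    if recovery < low:
        return "suppression"
    return "ok"


def uv254_retention(before: float, after: float) -> float:
    """Bulk DOM retention % from UV254 before/after cartridge loading."""
    if before <= 0:
        raise ValueError("UV254 before loading must be positive")
    if after < 0:
        raise ValueError("UV254 after loading must be non-negative")
    retention = 100.0 * (before - after) / before
    if retention < 0:
        logger.warning(
            "negative UV254 retention (%.1f%%): outlet absorbance exceeds inlet", retention
        )
    return retention


def system_suitability(
    reference_injections: Sequence[tuple[float, float]],
    thresholds: QcThresholds = QcThresholds(),
) -> SuitabilityReport:
    """Gate the run on reference-standard injections (mass_error ppm, peak_width s).

    Fails when the mean absolute mass error exceeds the ppm gate or the mean
    peak width exceeds the width gate; a failing report calls for
    recalibration before acquisition.
    """
    if len(reference_injections) == 0:
        raise ValueError("need at least one reference injection")
    errors = np.array([abs(e) for e, _ in reference_injections], dtype=float)
    widths = np.array([w for _, w in reference_injections], dtype=float)
    mean_err = float(errors.mean())
    mean_width = float(widths.mean())
    failures = []
    if mean_err > thresholds.max_mass_error:
        failures.append(
            f"mean mass error {mean_err:.2f} ppm > {thresholds.max_mass_error} ppm"
        )
    if mean_width > thresholds.max_peak_width:
        failures.append(
            f"mean peak width {mean_width:.2f} s > {thresholds.max_peak_width} s"
        )
    return SuitabilityReport(
        passed=not failures,
        mean_mass_error=mean_err,
        mean_peak_width=mean_width,
        failures=failures,
    )
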
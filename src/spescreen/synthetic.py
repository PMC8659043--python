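"""Synthetic LC-HRMS study generator.

Emulates the acquisition design the analysis modules assume: a pool of
candidate compounds, SPE "cartridges" that each capture a characteristic
slice of that pool (a Gaussian retention-time window, per-charge-class
affinities, and competition from dissolved organic matter), randomized
triplicate injections with multiplicative intensity noise and a detection
limit, spiked internal standards with known true recoveries, and
Gaussian-fluorophore EEM spectra before/after cartridge loading.

The capture model is deliberately simple plumbing: it reproduces the
qualitative behaviors the indicators are meant to detect (distinct feature
sets per cartridge, DOM suppression on DOM-sensitive phases), not any
measured physics.  Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .eem_fri import EEMSpectrum, default_em_grid, default_ex_grid, dilution_for_inner_filter
from .feature_io import (
    DEFAULT_MZ_TOL_PPM,
    DEFAULT_RT_TOL,
    FeatureTable,
)
from .recovery_qc import InternalStandard

logger = logging.getLogger(__name__)

CHARGE_CLASSES = ("neutral", "acidic", "basic")

#: Reference DOC (mg C/L) at which DOM competition saturates; the default is
#: the wastewater-effluent DOC, so an effluent-like matrix competes maximally.
DOC_REF = 7.1

DEFAULT_CV = 0.15
DEFAULT_LOD = 1e3
DEFAULT_N_REPS = 3


@dataclass(frozen=True)
class Compound:
    """A candidate analyte with its true chromatographic/MS coordinates."""

    id: str
    mz: float
    rt_true: float
    charge_class: str
    base_area: float

    def __post_init__(self) -> None:
        if not 50.0 <= self.mz <= 1000.0:
            raise ValueError(f"mz {self.mz} outside the acquired scan range [50, 1000]")
        if self.rt_true < 0:
            raise ValueError("rt_true must be non-negative")
        if self.charge_class not in CHARGE_CLASSES:
            raise ValueError(f"unknown charge class {self.charge_class!r}")
        if self.base_area <= 0:
            raise ValueError("base_area must be positive")


@dataclass(frozen=True)
class Fluorophore:
    """A Gaussian EEM component (separable in excitation and emission)."""

    id: str
    ex_center: float
    em_center: float
    ex_sigma: float
    em_sigma: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.em_center <= self.ex_center:
            raise ValueError("Stokes shift requires em_center > ex_center")
        if self.ex_sigma <= 0 or self.em_sigma <= 0:
            raise ValueError("sigmas must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class CartridgeProfile:
    """What one SPE phase captures.

    ``rt_window_center``/``rt_window_width`` define a Gaussian retention
    window (width = standard deviation, min); ``charge_affinity`` multiplies
    capture per charge class; ``dom_sensitivity`` scales linear DOC
    competition; ``dom_retention_per_fluorophore`` gives the fraction of
    each EEM fluorophore removed during loading.
    """

    name: str
    rt_window_center: float
    rt_window_width: float
    charge_affinity: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in CHARGE_CLASSES}
    )
    dom_sensitivity: float = 0.0
    dom_retention_per_fluorophore: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rt_window_width <= 0:
            raise ValueError("rt_window_width must be positive")
        for c, a in self.charge_affinity.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"charge affinity for {c!r} outside [0, 1]")
        if not 0.0 <= self.dom_sensitivity <= 1.0:
            raise ValueError("dom_sensitivity must lie in [0, 1]")
        for fid, r in self.dom_retention_per_fluorophore.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"dom retention for fluorophore {fid!r} outside [0, 1]")


@dataclass(frozen=True)
class MatrixProfile:
    """Water-matrix metadata: DOC, A254 and fluorescent components."""

    name: str
    doc: float = 0.0
    a254: float = 0.0
    fluorophores: tuple[Fluorophore, ...] = ()

    def __post_init__(self) -> None:
        if self.doc < 0 or self.a254 < 0:
            raise ValueError("doc and a254 must be non-negative")
        object.__setattr__(self, "fluorophores", tuple(self.fluorophores))


# ---------------------------------------------------------------------------
# compound pool and capture
# ---------------------------------------------------------------------------


def generate_compound_pool(
    n: int,
    seed: int,
    mz_range: tuple[float, float] = (50.0, 1000.0),
    run_length: float = 34.0,
    base_area_range: tuple[float, float] = (1e4, 1e7),
) -> list[Compound]:
    """Draw ``n`` compounds with uniform m/z and retention time.

    Base areas are log-uniform over ``base_area_range`` (detector responses
    span orders of magnitude); charge classes are uniform over
    neutral/acidic/basic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    lo, hi = mz_range
    if not (50.0 <= lo < hi <= 1000.0):
        raise ValueError("mz_range must be a non-empty subinterval of [50, 1000]")
    if run_length <= 0:
        raise ValueError("run_length must be positive")
    rng = np.random.default_rng(seed)
    mz = rng.uniform(lo, hi, n)
    rt = rng.uniform(0.0, run_length, n)
    area = np.exp(rng.uniform(np.log(base_area_range[0]), np.log(base_area_range[1]), n))
    charge = rng.choice(CHARGE_CLASSES, n)
    return [
        Compound(
            id=f"C{i:05d}",
            mz=float(mz[i]),
            rt_true=float(rt[i]),
            charge_class=str(charge[i]),
            base_area=float(area[i]),
        )
        for i in range(n)
    ]


def capture_probability(
    compound: Compound,
    cartridge: CartridgeProfile,
    matrix: MatrixProfile,
    doc_ref: float = DOC_REF,
) -> float:
    """Deterministic capture probability of one compound on one cartridge.

    ``p = G(rt) x charge_affinity x (1 - dom_sensitivity x min(1, doc/doc_ref))``
    with ``G`` a Gaussian retention window normalized to 1 at its center.
    """
    g = math.exp(
        -((compound.rt_true - cartridge.rt_window_center) ** 2)
        / (2.0 * cartridge.rt_window_width**2)
    )
    affinity = cartridge.charge_affinity.get(compound.charge_class, 1.0)
    competition = 1.0 - cartridge.dom_sensitivity * min(1.0, matrix.doc / doc_ref)
    return g * affinity * competition


def simulate_capture(
    pool: list[Compound],
    cartridge: CartridgeProfile,
    matrix: MatrixProfile,
    seed: int | None = None,
    deterministic: bool = False,
    doc_ref: float = DOC_REF,
) -> dict[str, float]:
    """Capture the compound pool on one cartridge: compound id -> captured area.

    Captured area is ``base_area x p``.  In stochastic mode each compound is
    retained with Bernoulli(p) before scaling; deterministic mode keeps every
    compound with p > 0 (so descriptor tests are exact).
    """
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for c in pool:
        p = capture_probability(c, cartridge, matrix, doc_ref=doc_ref)
        if p <= 0:
            continue
        if deterministic or rng.random() < p:
            out[c.id] = c.base_area * p
    return out


def simulate_replicates(
    captured: dict[str, float],
    pool: list[Compound],
    sample_id: str,
    n_reps: int = DEFAULT_N_REPS,
    cv: float = DEFAULT_CV,
    lod: float = DEFAULT_LOD,
    seed: int | None = None,
    run_length: float = 34.0,
    scan_range: tuple[float, float] = (50.0, 1000.0),
) -> FeatureTable:
    """Inject a captured sample ``n_reps`` times with multiplicative noise.

    Each replicate area is ``captured_area x (1 + eps)`` with
    ``eps ~ Normal(0, cv)`` (clipped at zero); areas below ``lod`` are
    censored from that replicate.  Feature ids are the compound ids, stable
    across replicates of the sample.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if lod < 0:
        raise ValueError("lod must be non-negative")
    rng = np.random.default_rng(seed)
    by_id = {c.id: c for c in pool}
    rows = []
    for cid in sorted(captured):
        compound = by_id[cid]
        base = captured[cid]
        noise = rng.normal(0.0, cv, n_reps) if cv > 0 else np.zeros(n_reps)
        for r in range(n_reps):
            area = max(0.0, base * (1.0 + noise[r]))
            if area < lod:
                continue
            rows.append(
                (cid, compound.mz, compound.rt_true, area, sample_id, f"r{r + 1}")
            )
    df = pd.DataFrame(
        rows, columns=["feature_id", "mz", "rt", "area", "sample_id", "replicate_id"]
    )
    return FeatureTable(df, run_length=run_length, scan_range=scan_range)


def spike_internal_standards(
    table: FeatureTable,
    standards: list[InternalStandard],
    true_recovery: dict[str, float],
    concentration_factor: float = 1000.0,
    mz_tol_ppm: float = DEFAULT_MZ_TOL_PPM,
    rt_tol: float = DEFAULT_RT_TOL,
) -> FeatureTable:
    """Add one feature per internal standard per replicate at a known recovery.

    The spiked area is ``reference_area x true_recovery x
    concentration_factor``, i.e. exactly what the recovery calculation
    inverts; standards with zero recovery are absent.  A standard colliding
    with an existing feature at the alignment tolerance triggers a warning
    (areas would merge in real data), not an error.
    """
    records = table.records
    rows = []
    for std in standards:
        recovery = true_recovery.get(std.name, 0.0)
        if not 0.0 <= recovery:
            raise ValueError(f"negative true recovery for {std.name!r}")
        rt = (std.rt_window[0] + std.rt_window[1]) / 2.0
        close = (
            (np.abs(records["mz"] - std.mz) <= records["mz"] * mz_tol_ppm * 1e-6)
            & (np.abs(records["rt"] - rt) <= rt_tol)
        )
        if close.any():
            logger.warning(
                "standard %s collides with %d existing feature(s) at tolerance",
                std.name,
                int(close.sum()),
            )
        area = std.reference_area * recovery * concentration_factor
        if area <= 0:
            continue
        for (sample, replicate), _ in records.groupby(["sample_id", "replicate_id"]):
            rows.append((f"IS_{std.name}", std.mz, rt, area, sample, replicate))
    spiked = pd.DataFrame(
        rows, columns=["feature_id", "mz", "rt", "area", "sample_id", "replicate_id"]
    )
    frames = [df for df in (records, spiked) if not df.empty]
    combined = pd.concat(frames, ignore_index=True) if frames else records
    return FeatureTable(combined, run_length=table.run_length, scan_range=table.scan_range)


# ---------------------------------------------------------------------------
# EEM simulation
# ---------------------------------------------------------------------------


def generate_eem(
    fluorophores: list[Fluorophore] | tuple[Fluorophore, ...],
    ex_grid: np.ndarray | None = None,
    em_grid: np.ndarray | None = None,
    a254: float = 0.0,
    apply_dilution: bool = False,
) -> EEMSpectrum:
    """Sum of separable Gaussian fluorophores on the measurement grid.

    With ``apply_dilution`` the inner-filter rule is simulated: intensities
    are divided by the integer dilution factor required to bring A254 to the
    0.1 limit, and the factor is recorded on the spectrum.
    """
    ex = default_ex_grid() if ex_grid is None else np.asarray(ex_grid, dtype=float)
    em = default_em_grid() if em_grid is None else np.asarray(em_grid, dtype=float)
    if ex.size == 0 or em.size == 0:
        raise ValueError("wavelength grids must be non-empty")
    intensity = np.zeros((ex.size, em.size))
    for f in fluorophores:
        gx = np.exp(-((ex - f.ex_center) ** 2) / (2.0 * f.ex_sigma**2))
        gy = np.exp(-((em - f.em_center) ** 2) / (2.0 * f.em_sigma**2))
        intensity += f.amplitude * np.outer(gx, gy)
    dilution = 1
    if apply_dilution:
        dilution = dilution_for_inner_filter(a254)
        intensity = intensity / dilution
    return EEMSpectrum(ex=ex, em=em, intensity=intensity, a254=a254, dilution_factor=dilution)


def apply_cartridge_to_eem(
    eem_before: EEMSpectrum,
    cartridge: CartridgeProfile,
    fluorophores: list[Fluorophore] | tuple[Fluorophore, ...],
) -> EEMSpectrum:
    """After-loading spectrum: each fluorophore scaled by (1 - its retention)."""
    intensity = np.zeros_like(eem_before.intensity)
    for f in fluorophores:
        r = cartridge.dom_retention_per_fluorophore.get(f.id, 0.0)
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"retention fraction for {f.id!r} outside [0, 1]")
        gx = np.exp(-((eem_before.ex - f.ex_center) ** 2) / (2.0 * f.ex_sigma**2))
        gy = np.exp(-((eem_before.em - f.em_center) ** 2) / (2.0 * f.em_sigma**2))
        intensity += (1.0 - r) * f.amplitude * np.outer(gx, gy)
    intensity /= eem_before.dilution_factor
    return EEMSpectrum(
        ex=eem_before.ex.copy(),
        em=eem_before.em.copy(),
        intensity=intensity,
        a254=eem_before.a254,
        dilution_factor=eem_before.dilution_factor,
    )


# ---------------------------------------------------------------------------
# study-level defaults and config
# ---------------------------------------------------------------------------


def default_fluorophores() -> tuple[Fluorophore, ...]:
    """Two dominant river-water fluorophores: fulvic-like (region III) and
    humic-like (region V), plus a weak protein-like component (region I)."""
    return (
        Fluorophore("fulvic", ex_center=244.0, em_center=430.0, ex_sigma=3.0, em_sigma=25.0,
                    amplitude=800.0),
        Fluorophore("humic", ex_center=330.0, em_center=480.0, ex_sigma=25.0, em_sigma=30.0,
                    amplitude=600.0),
        Fluorophore("protein", ex_center=244.0, em_center=300.0, ex_sigma=3.0, em_sigma=12.0,
                    amplitude=150.0),
    )


def default_matrices() -> dict[str, MatrixProfile]:
    """Ultrapure, river and effluent matrices (DOC per the study waters)."""
    fl = default_fluorophores()
    return {
        "ultrapure": MatrixProfile("ultrapure", doc=0.0, a254=0.0, fluorophores=()),
        "river": MatrixProfile("river", doc=1.89, a254=0.05, fluorophores=fl),
        "effluent": MatrixProfile("effluent", doc=7.1, a254=0.18, fluorophores=fl),
    }


def default_cartridges() -> list[CartridgeProfile]:
    """Nine cartridge profiles in three designed capture-window groups.

    Groups differ in retention-time window (polar/early, mid, apolar/late);
    members within a group differ in charge affinity and DOM sensitivity,
    emulating phases of like polarity but different ionic character.
    """
    groups = {"polar": 7.0, "mid": 17.0, "apolar": 27.0}
    variants = [
        ("a", {"neutral": 1.0, "acidic": 0.9, "basic": 0.9}, 0.2),
        ("b", {"neutral": 0.7, "acidic": 1.0, "basic": 0.3}, 0.6),
        ("c", {"neutral": 0.7, "acidic": 0.3, "basic": 1.0}, 0.4),
    ]
    out = []
    for gname, center in groups.items():
        for v, affinity, dom in variants:
            out.append(
                CartridgeProfile(
                    name=f"{gname}_{v}",
                    rt_window_center=center,
                    rt_window_width=6.0,
                    charge_affinity=affinity,
                    dom_sensitivity=dom,
                    dom_retention_per_fluorophore={
                        "fulvic": 0.85 * (1 - dom * 0.3),
                        "humic": 0.55 * (1 - dom * 0.3),
                        "protein": 0.7 * (1 - dom * 0.3),
                    },
                )
            )
    return out


@dataclass
class StudyConfig:
    """Everything needed to simulate one acquisition campaign."""

    n_compounds: int = 1000
    run_length: float = 34.0
    mz_range: tuple[float, float] = (50.0, 1000.0)
    n_reps: int = DEFAULT_N_REPS
    cv: float = DEFAULT_CV
    lod: float = DEFAULT_LOD
    doc_ref: float = DOC_REF
    cartridges: list[CartridgeProfile] = field(default_factory=default_cartridges)
    matrix: MatrixProfile = field(default_factory=lambda: default_matrices()["river"])
    n_pools: int = 0


def load_study_config(path) -> StudyConfig:
    """Build a StudyConfig from a YAML file; unspecified keys keep defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = StudyConfig()
    for key in ("n_compounds", "run_length", "n_reps", "cv", "lod", "doc_ref", "n_pools"):
        if key in raw:
            setattr(cfg, key, type(getattr(cfg, key))(raw[key]))
    if "mz_range" in raw:
        cfg.mz_range = tuple(float(v) for v in raw["mz_range"])
    if "matrix" in raw:
        m = raw["matrix"]
        cfg.matrix = MatrixProfile(
            name=m.get("name", "matrix"),
            doc=float(m.get("doc", 0.0)),
            a254=float(m.get("a254", 0.0)),
            fluorophores=tuple(
                Fluorophore(
                    id=f["id"],
                    ex_center=float(f["ex_center"]),
                    em_center=float(f["em_center"]),
                    ex_sigma=float(f["ex_sigma"]),
                    em_sigma=float(f["em_sigma"]),
                    amplitude=float(f["amplitude"]),
                )
                for f in m.get("fluorophores", [])
            ),
        )
    if "cartridges" in raw:
        cfg.cartridges = [
            CartridgeProfile(
                name=c["name"],
                rt_window_center=float(c["rt_window_center"]),
                rt_window_width=float(c["rt_window_width"]),
                charge_affinity={
                    k: float(v)
                    for k, v in c.get(
                        "charge_affinity", {cc: 1.0 for cc in CHARGE_CLASSES}
                    ).items()
                },
                dom_sensitivity=float(c.get("dom_sensitivity", 0.0)),
                dom_retention_per_fluorophore={
                    k: float(v) for k, v in c.get("dom_retention_per_fluorophore", {}).items()
                },
            )
            for c in raw["cartridges"]
        ]
    return cfg


@dataclass
class SimulatedStudy:
    """Output bundle of :func:`simulate_study`."""

    pool: list[Compound]
    tables: dict[str, FeatureTable]
    combined: FeatureTable
    eems_before: dict[str, EEMSpectrum]
    eems_after: dict[str, EEMSpectrum]
    config: StudyConfig


def simulate_study(
    config: StudyConfig | None = None,
    seed: int = 0,
    deterministic: bool = False,
) -> SimulatedStudy:
    """Simulate a full cartridge-comparison campaign.

    One sample per cartridge (triplicate injections), optional pooled-QC
    samples (the mean captured profile across cartridges, injected with the
    same noise model), and before/after-loading EEMs per cartridge.  All
    randomness derives from ``seed``.
    """
    cfg = config or StudyConfig()
    rng = np.random.default_rng(seed)
    pool = generate_compound_pool(
        cfg.n_compounds, seed=int(rng.integers(2**31)), mz_range=cfg.mz_range,
        run_length=cfg.run_length,
    )
    tables: dict[str, FeatureTable] = {}
    captured_maps: dict[str, dict[str, float]] = {}
    for cart in cfg.cartridges:
        captured = simulate_capture(
            pool, cart, cfg.matrix, seed=int(rng.integers(2**31)),
            deterministic=deterministic, doc_ref=cfg.doc_ref,
        )
        captured_maps[cart.name] = captured
        tables[cart.name] = simulate_replicates(
            captured, pool, sample_id=cart.name, n_reps=cfg.n_reps,
            cv=0.0 if deterministic else cfg.cv, lod=cfg.lod,
            seed=int(rng.integers(2**31)), run_length=cfg.run_length,
            scan_range=cfg.mz_range,
        )
    for p in range(cfg.n_pools):
        pooled: dict[str, float] = {}
        for captured in captured_maps.values():
            for cid, area in captured.items():
                pooled[cid] = pooled.get(cid, 0.0) + area / len(captured_maps)
        tables[f"pool{p + 1}"] = simulate_replicates(
            pooled, pool, sample_id=f"pool{p + 1}", n_reps=1,
            cv=0.0 if deterministic else cfg.cv / 3.0, lod=cfg.lod,
            seed=int(rng.integers(2**31)), run_length=cfg.run_length,
            scan_range=cfg.mz_range,
        )
    combined = FeatureTable(
        pd.concat([t.records for t in tables.values()], ignore_index=True),
        run_length=cfg.run_length,
        scan_range=cfg.mz_range,
    )
    eems_before: dict[str, EEMSpectrum] = {}
    eems_after: dict[str, EEMSpectrum] = {}
    if cfg.matrix.fluorophores:
        before = generate_eem(cfg.matrix.fluorophores, a254=cfg.matrix.a254)
        for cart in cfg.cartridges:
            eems_before[cart.name] = before
            eems_after[cart.name] = apply_cartridge_to_eem(
                before, cart, cfg.matrix.fluorophores
            )
    return SimulatedStudy(
        pool=pool, tables=tables, combined=combined,
        eems_before=eems_before, eems_after=eems_after, config=cfg,
    )
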
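"""Feature-table I/O, replicate-consensus filtering and cross-sample alignment.

A *feature* is a detected LC-HRMS signal characterized by its m/z, retention
time and integrated area.  Feature tables hold one row per detected feature
per injection (sample x replicate).  Downstream comparison of SPE cartridges
rests on two reductions implemented here:

* the replicate-consensus rule — only features detected in every injection
  replicate of a sample are considered real;
* cross-sample alignment — consensus features from different samples that
  agree in m/z (ppm tolerance) and retention time are treated as the same
  molecule, yielding a features x samples area matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns required in a feature-table CSV, in canonical order.
FEATURE_COLUMNS = ["feature_id", "mz", "rt", "area", "sample_id", "replicate_id"]

#: Default matching tolerances (typical QTOF values).
DEFAULT_MZ_TOL_PPM = 5.0
DEFAULT_RT_TOL = 0.2


class FeatureTableError(ValueError):
    """Malformed feature-table input (missing column, bad value, duplicate key)."""


@dataclass
class FeatureTable:
    """Per-injection detected features with sample/replicate labels.

    Parameters
    ----------
    records : pandas.DataFrame
        One row per feature per injection, columns ``feature_id, mz, rt,
        area, sample_id, replicate_id``.
    run_length : float
        Chromatographic run length in minutes (0-based run time).
    scan_range : tuple of float
        Acquired m/z window in Th.
    """

    records: pd.DataFrame
    run_length: float = 34.0
    scan_range: tuple[float, float] = (50.0, 1000.0)

    def __post_init__(self) -> None:
        self.records = _validate_records(self.records, self.run_length, self.scan_range)

    @property
    def samples(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    def replicates(self, sample_id: str) -> list[str]:
        sub = self.records.loc[self.records["sample_id"] == sample_id, "replicate_id"]
        if sub.empty:
            raise KeyError(f"unknown sample_id: {sample_id!r}")
        return sorted(sub.unique())


@dataclass
class ConsensusFeature:
    """A feature detected in every replicate of one sample.

    m/z and retention time are the medians over the matched per-replicate
    features (robust to one outlier replicate); ``areas_per_replicate`` is
    ordered by sorted replicate label.
    """

    feature_id: str
    mz: float
    rt: float
    areas_per_replicate: list[float]
    mean_area: float


@dataclass
class AlignedFeatureMatrix:
    """Features x samples mean-area matrix plus per-feature coordinates.

    ``areas`` is indexed by aligned feature id (0 = absent from that sample);
    ``features`` carries the intensity-weighted consensus mz/rt of each
    aligned id, on the same index.
    """

    areas: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.areas.index.equals(self.features.index):
            raise ValueError("areas and features must share the same feature index")
        if (self.areas.to_numpy() < 0).any():
            raise ValueError("aligned areas must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.areas.columns)


def _validate_records(
    df: pd.DataFrame, run_length: float, scan_range: tuple[float, float]
) -> pd.DataFrame:
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FeatureTableError(f"missing column(s): {', '.join(missing)}")
    df = df[FEATURE_COLUMNS].copy()
    for col in ("mz", "rt", "area"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FeatureTableError(f"non-numeric {col} at row {row}: {df[col].iloc[row]!r}")
        df[col] = coerced.astype(float)
    if not np.isfinite(df[["mz", "rt", "area"]].to_numpy()).all():
        raise FeatureTableError("mz, rt and area must be finite")
    if (df["area"] < 0).any():
        row = int(np.flatnonzero((df["area"] < 0).to_numpy())[0])
        raise FeatureTableError(f"negative area at row {row}")
    df["feature_id"] = df["feature_id"].astype(str)
    df["sample_id"] = df["sample_id"].astype(str)
    df["replicate_id"] = df["replicate_id"].astype(str)
    key = df[["sample_id", "replicate_id", "feature_id"]]
    dup = key.duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise FeatureTableError(
            f"duplicate (sample_id, replicate_id, feature_id) key at row {row}: "
            f"{tuple(key.iloc[row])}"
        )
    lo, hi = scan_range
    out = (df["mz"] < lo) | (df["mz"] > hi) | (df["rt"] < 0) | (df["rt"] > run_length)
    if out.any():
        row = int(np.flatnonzero(out.to_numpy())[0])
        raise FeatureTableError(
            f"feature outside scan range / run length at row {row}: "
            f"mz={df['mz'].iloc[row]}, rt={df['rt'].iloc[row]}"
        )
    return df.reset_index(drop=True)


def read_feature_table(
    path,
    run_length: float = 34.0,
    scan_range: tuple[float, float] = (50.0, 1000.0),
) -> FeatureTable:
    """Read a feature-table CSV (comma separator, decimal point)."""
    try:
        df = pd.read_csv(path, dtype={"feature_id": str, "sample_id": str, "replicate_id": str})
    except pd.errors.EmptyDataError as exc:
        raise FeatureTableError(f"empty file (no header): {path}") from exc
    return FeatureTable(df, run_length=run_length, scan_range=scan_range)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table as CSV; floats at 12 significant digits."""
    table.records.to_csv(path, index=False, float_format="%.12g")


def read_mzml(path):  # pragma: no cover - documented stub
    """Not implemented: raw mzML ingestion requires external peak picking.

    This toolkit starts from picked feature tables (CSV).  Centroiding,
    chromatogram reconstruction and alignment of raw spectra are delegated to
    dedicated tools (e.g. OpenMS / patRoon); export their feature tables to
    the CSV dialect of :func:`read_feature_table`.
    """
    raise NotImplementedError(
        "mzML ingestion is out of scope; run peak picking externally and "
        "export a feature-table CSV"
    )


# ---------------------------------------------------------------------------
# tolerance grouping
# ---------------------------------------------------------------------------


def _greedy_group(
    df: pd.DataFrame, mz_tol_ppm: float, rt_tol: float, exclusive_key: str
) -> np.ndarray:
    """Group rows whose (mz, rt) agree within tolerance; returns group labels.

    Greedy mz-sorted agglomeration: rows are visited in deterministic order
    (mz, rt, -area, key); each row joins the nearest open group whose
    intensity-weighted mean mz is within ``mz_tol_ppm`` and mean rt within
    ``rt_tol``, or opens a new group.  At most one row per ``exclusive_key``
    value may occupy a group: on collision the higher-area row keeps the
    group (tie -> lower rt, then lower mz) and the loser is evicted to a
    fresh group, so no row is ever dropped.

    Rows are pre-split into blocks separated by mz gaps larger than the
    tolerance; no link can cross such a gap, which keeps the greedy scan
    local and fast.
    """
    n = len(df)
    if n == 0:
        return np.empty(0, dtype=int)
    order = np.lexsort(
        (
            df[exclusive_key].to_numpy(),
            -df["area"].to_numpy(),
            df["rt"].to_numpy(),
            df["mz"].to_numpy(),
        )
    )
    mz = df["mz"].to_numpy()[order]
    rt = df["rt"].to_numpy()[order]
    area = df["area"].to_numpy()[order]
    key = df[exclusive_key].to_numpy()[order]

    labels = np.full(n, -1, dtype=int)
    next_label = 0
    # block boundaries: consecutive sorted mz differing by more than the
    # ppm tolerance at the larger value can never share a group
    gaps = np.flatnonzero(np.diff(mz) > mz[1:] * mz_tol_ppm * 1e-6) + 1
    starts = np.concatenate(([0], gaps))
    stops = np.concatenate((gaps, [n]))

    for start, stop in zip(starts, stops):
        groups: list[dict] = []  # open groups within the block

        def _new_group(i: int) -> None:
            nonlocal next_label
            groups.append(
                {
                    "label": next_label,
                    "members": {key[i]: i},
                    "w": max(area[i], 1.0),
                    "wmz": max(area[i], 1.0) * mz[i],
                    "wrt": max(area[i], 1.0) * rt[i],
                }
            )
            labels[i] = next_label
            next_label += 1

        def _add(g: dict, i: int) -> None:
            g["members"][key[i]] = i
            w = max(area[i], 1.0)
            g["w"] += w
            g["wmz"] += w * mz[i]
            g["wrt"] += w * rt[i]
            labels[i] = g["label"]

        def _remove(g: dict, i: int) -> None:
            del g["members"][key[i]]
            w = max(area[i], 1.0)
            g["w"] -= w
            g["wmz"] -= w * mz[i]
            g["wrt"] -= w * rt[i]

        for i in range(start, stop):
            best = None
            best_rank = None
            for g in groups:
                gmz = g["wmz"] / g["w"]
                grt = g["wrt"] / g["w"]
                if abs(mz[i] - gmz) <= gmz * mz_tol_ppm * 1e-6 and abs(rt[i] - grt) <= rt_tol:
                    rank = (abs(mz[i] - gmz), abs(rt[i] - grt), g["label"])
                    if best_rank is None or rank < best_rank:
                        best, best_rank = g, rank
            if best is None:
                _new_group(i)
                continue
            incumbent = best["members"].get(key[i])
            if incumbent is None:
                _add(best, i)
            else:
                j = incumbent
                # higher area wins the slot; ties -> lower rt, then lower mz
                win_i = (-area[i], rt[i], mz[i]) < (-area[j], rt[j], mz[j])
                if win_i:
                    _remove(best, j)
                    _add(best, i)
                    _new_group(j)
                else:
                    _new_group(i)
    return labels[np.argsort(order, kind="stable")]


# ---------------------------------------------------------------------------
# consensus and alignment
# ---------------------------------------------------------------------------


def consensus_filter(
    table: FeatureTable,
    sample_id: str,
    mz_tol_ppm: float = DEFAULT_MZ_TOL_PPM,
    rt_tol: float = DEFAULT_RT_TOL,
) -> list[ConsensusFeature]:
    """Keep only features detected in every replicate of ``sample_id``.

    Features from different replicates are matched within ``mz_tol_ppm`` and
    ``rt_tol``; a consensus feature exists iff its group covers every
    replicate of the sample.  Output is sorted by (rt, mz).
    """
    replicates = table.replicates(sample_id)
    sub = table.records[table.records["sample_id"] == sample_id].reset_index(drop=True)
    labels = _greedy_group(sub, mz_tol_ppm, rt_tol, exclusive_key="replicate_id")
    sub = sub.assign(_group=labels)

    out: list[ConsensusFeature] = []
    for _, grp in sub.groupby("_group", sort=False):
        if set(grp["replicate_id"]) != set(replicates):
            continue
        grp = grp.sort_values("replicate_id")
        areas = grp["area"].tolist()
        # representative id: the highest-area member, deterministic tie-break
        rep = grp.sort_values(["area", "rt", "mz"], ascending=[False, True, True]).iloc[0]
        out.append(
            ConsensusFeature(
                feature_id=str(rep["feature_id"]),
                mz=float(grp["mz"].median()),
                rt=float(grp["rt"].median()),
                areas_per_replicate=[float(a) for a in areas],
                mean_area=float(np.mean(areas)),
            )
        )
    out.sort(key=lambda f: (f.rt, f.mz))
    return out


def consensus_to_frame(features: Sequence[ConsensusFeature]) -> pd.DataFrame:
    """Long-format view of consensus features (feature_id, mz, rt, mean_area)."""
    return pd.DataFrame(
        {
            "feature_id": [f.feature_id for f in features],
            "mz": [f.mz for f in features],
            "rt": [f.rt for f in features],
            "mean_area": [f.mean_area for f in features],
        }
    )


def align_features(
    consensus_sets: Mapping[str, Sequence[ConsensusFeature]],
    mz_tol_ppm: float = DEFAULT_MZ_TOL_PPM,
    rt_tol: float = DEFAULT_RT_TOL,
) -> AlignedFeatureMatrix:
    """Align per-sample consensus features into a features x samples matrix.

    Features from different samples within the m/z ppm and RT tolerances are
    linked to one aligned id whose coordinates are the intensity-weighted
    mean mz/rt of its members.  Each sample contributes at most one feature
    per aligned id (highest area wins; the displaced feature keeps its own
    aligned id so no feature is lost).
    """
    if mz_tol_ppm <= 0 or rt_tol <= 0:
        raise ValueError("alignment tolerances must be positive")
    rows = []
    for sample, feats in consensus_sets.items():
        for f in feats:
            rows.append((str(sample), f.mz, f.rt, f.mean_area))
    samples = sorted(str(s) for s in consensus_sets)
    if not rows:
        empty = pd.DataFrame(columns=samples, dtype=float)
        meta = pd.DataFrame(columns=["mz", "rt"], dtype=float)
        return AlignedFeatureMatrix(areas=empty, features=meta)
    df = pd.DataFrame(rows, columns=["sample_id", "mz", "rt", "area"])
    labels = _greedy_group(df, mz_tol_ppm, rt_tol, exclusive_key="sample_id")
    df = df.assign(_group=labels)

    w = df["area"].clip(lower=1.0)
    coords = pd.DataFrame(
        {
            "mz": (df["mz"] * w).groupby(labels).sum() / w.groupby(labels).sum(),
            "rt": (df["rt"] * w).groupby(labels).sum() / w.groupby(labels).sum(),
        }
    )
    coords = coords.sort_values(["mz", "rt"])
    ids = {g: f"F{i + 1:05d}" for i, g in enumerate(coords.index)}
    df["aligned_id"] = df["_group"].map(ids)
    coords.index = [ids[g] for g in coords.index]

    areas = (
        df.pivot_table(index="aligned_id", columns="sample_id", values="area", fill_value=0.0)
        .reindex(index=coords.index, columns=samples, fill_value=0.0)
        .astype(float)
    )
    areas.columns.name = None
    areas.index.name = "feature"
    coords.index.name = "feature"
    return AlignedFeatureMatrix(areas=areas, features=coords)


def write_aligned_matrix(matrix: AlignedFeatureMatrix, path) -> None:
    """Write an aligned matrix as CSV: mz, rt, then one area column per sample."""
    out = pd.concat([matrix.features, matrix.areas], axis=1)
    out.to_csv(path, index=True, float_format="%.12g")


def read_aligned_matrix(path) -> AlignedFeatureMatrix:
    df = pd.read_csv(path, index_col=0)
    if "mz" not in df.columns or "rt" not in df.columns:
        raise FeatureTableError("aligned-matrix CSV must have mz and rt columns")
    meta = df[["mz", "rt"]]
    areas = df.drop(columns=["mz", "rt"]).astype(float)
    return AlignedFeatureMatrix(areas=areas, features=meta)
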
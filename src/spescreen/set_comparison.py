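"""Presence/absence set algebra, fingerprint export and PCA with pool QC.

Cartridges are compared both by which features they share (UpSet-style
exclusive intersections: each feature belongs to exactly one sample subset,
its exact presence pattern) and by unsupervised ordination of their area
profiles (PCA on log-transformed areas, with pooled-QC clustering as a
reproducibility check).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .feature_io import AlignedFeatureMatrix, ConsensusFeature

logger = logging.getLogger(__name__)


@dataclass
class PresenceMatrix:
    """Boolean features x samples matrix; every retained row is present somewhere."""

    values: pd.DataFrame
    n_dropped: int = 0

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class IntersectionReport:
    """Exclusive-intersection (UpSet) summary.

    ``subsets`` has one row per non-empty presence pattern: the member
    samples, a pattern string (``A&B``), and the exclusive count of features
    showing exactly that pattern.  ``per_sample`` gives, for each sample, its
    set size, the number of multi-sample intersections it participates in,
    the total features in those intersections, and its specific (exclusive
    singleton) count.
    """

    subsets: pd.DataFrame
    per_sample: pd.DataFrame
    n_features: int


@dataclass
class PcaResult:
    """Sample scores, percent variance per component, and feature loadings."""

    scores: pd.DataFrame
    variance_explained: np.ndarray
    loadings: pd.DataFrame


def build_presence_matrix(
    matrix: AlignedFeatureMatrix, min_area: float = 0.0
) -> PresenceMatrix:
    """Threshold an aligned area matrix into presence/absence.

    A cell is present iff its area exceeds ``min_area``; features present in
    no sample are dropped (count logged).
    """
    if min_area < 0:
        raise ValueError("min_area must be non-negative")
    presence = matrix.areas > min_area
    keep = presence.any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d features absent from every sample", n_dropped)
    return PresenceMatrix(values=presence.loc[keep], n_dropped=n_dropped)


def exclusive_intersections(presence: PresenceMatrix) -> IntersectionReport:
    """Partition features by their exact presence pattern (UpSet counts).

    Every feature lands in exactly one subset, so exclusive counts sum to the
    number of features; a sample's set size is the sum of exclusive counts
    over subsets containing it.
    """
    vals = presence.values
    if vals.shape[1] < 1:
        raise ValueError("need at least one sample")
    samples = list(vals.columns)
    patterns: dict[tuple[str, ...], int] = {}
    arr = vals.to_numpy()
    for row in arr:
        members = tuple(s for s, p in zip(samples, row) if p)
        if members:
            patterns[members] = patterns.get(members, 0) + 1

    subset_rows = [
        {"samples": members, "pattern": "&".join(members), "exclusive_count": count}
        for members, count in patterns.items()
    ]
    subsets = pd.DataFrame(subset_rows, columns=["samples", "pattern", "exclusive_count"])
    subsets = subsets.sort_values(
        ["exclusive_count", "samples"], ascending=[False, True], ignore_index=True
    )

    per_sample = {}
    for s in samples:
        containing = [r for r in subset_rows if s in r["samples"]]
        multi = [r for r in containing if len(r["samples"]) >= 2]
        per_sample[s] = {
            "set_size": sum(r["exclusive_count"] for r in containing),
            "n_intersections": len(multi),
            "intersected_features": sum(r["exclusive_count"] for r in multi),
            "specific_count": next(
                (r["exclusive_count"] for r in containing if r["samples"] == (s,)), 0
            ),
        }
    return IntersectionReport(
        subsets=subsets,
        per_sample=pd.DataFrame.from_dict(per_sample, orient="index"),
        n_features=int(len(vals)),
    )


def shared_feature_count(presence: PresenceMatrix, sample_a: str, sample_b: str) -> int:
    """Features present in both samples, regardless of the other samples."""
    for s in (sample_a, sample_b):
        if s not in presence.values.columns:
            raise KeyError(f"unknown sample: {s!r}")
    return int((presence.values[sample_a] & presence.values[sample_b]).sum())


def pca(
    matrix: AlignedFeatureMatrix,
    transform: str = "log10p1",
    scale: str = "center",
    n_components: int | None = None,
) -> PcaResult:
    """PCA of samples in aligned-feature space.

    Samples are observations, aligned features variables.  Areas are
    log10(x+1)-transformed by default (absence maps to 0, i.e. absence is
    informative) and centered; ``scale='center_unit'`` adds unit-variance
    scaling.  Component signs are fixed so each component's
    largest-magnitude loading is positive.
    """
    if transform not in ("log10p1", "none"):
        raise ValueError("transform must be 'log10p1' or 'none'")
    if scale not in ("center", "center_unit"):
        raise ValueError("scale must be 'center' or 'center_unit'")
    X = matrix.areas.T  # samples x features
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    samples = list(X.index)
    feats = list(X.columns)
    X = X.to_numpy(dtype=float)
    if transform == "log10p1":
        X = np.log10(X + 1.0)
    X = X - X.mean(axis=0)
    if scale == "center_unit":
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = X / sd
    k = min(len(samples), len(feats)) if n_components is None else n_components
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # features x components
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=samples, columns=cols),
        variance_explained=model.explained_variance_ratio_ * 100.0,
        loadings=pd.DataFrame(loadings, index=feats, columns=cols),
    )


def pool_qc_metric(scores: pd.DataFrame, pool_labels: Sequence[bool]) -> float:
    """Pool-sample clustering check on the PC1-PC2 plane.

    Ratio of the mean pairwise distance among pooled-QC injections to the
    mean pairwise distance among the remaining samples; a ratio < 1 means
    the pools cluster more tightly than the samples spread (system
    reproducibility passes).
    """
    labels = np.asarray(pool_labels, dtype=bool)
    if labels.shape[0] != scores.shape[0]:
        raise ValueError("pool_labels length must match number of score rows")
    if labels.sum() < 2:
        raise ValueError("need at least two pool observations")
    if (~labels).sum() < 2:
        raise ValueError("need at least two non-pool observations")
    xy = scores[["PC1", "PC2"]].to_numpy(dtype=float)

    def mean_pairwise(points: np.ndarray) -> float:
        d = [float(np.linalg.norm(a - b)) for a, b in combinations(points, 2)]
        return float(np.mean(d))

    denom = mean_pairwise(xy[~labels])
    if denom == 0:
        return float("inf") if mean_pairwise(xy[labels]) > 0 else 0.0
    return mean_pairwise(xy[labels]) / denom


def export_fingerprint(
    consensus_sets: Mapping[str, Sequence[ConsensusFeature]]
) -> pd.DataFrame:
    """Long-format (rt, mz, area, sample) records for bubble-plot fingerprints."""
    rows = [
        (f.rt, f.mz, f.mean_area, str(sample))
        for sample, feats in consensus_sets.items()
        for f in feats
    ]
    return pd.DataFrame(rows, columns=["rt", "mz", "area", "sample"])
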
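"""Alpha diversity, Bray-Curtis dissimilarity, ordination, and outlier
detection.

Outliers are the extreme "burst" community structures seen in alcoholic
cohorts — samples overwhelmingly dominated by a single commensal genus.
They are detected exactly as abnormal metagenomes are flagged in
dissimilarity-based quality control: hierarchically cluster the samples,
cut the tree at the top level into two branches, and report the members of
the smaller branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from scipy.spatial.distance import squareform

from .tables_io import AbundanceMatrix, GutshiftError

__all__ = [
    "DissimilarityMatrix",
    "OutlierReport",
    "shannon",
    "shannon_per_sample",
    "welch_compare",
    "bray_curtis",
    "mds_ordinate",
    "detect_outliers",
    "dominance_report",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric sample x sample dissimilarities with a zero diagonal.

    Bray-Curtis values lie in [0, 1]; note Bray-Curtis is a dissimilarity,
    not a metric — the triangle inequality may fail.
    """

    values: pd.DataFrame
    metric: str = "braycurtis"

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if arr.shape[0] != arr.shape[1]:
            raise GutshiftError("dissimilarity matrix must be square")
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise GutshiftError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
            raise GutshiftError("dissimilarity matrix must have a zero diagonal")

    @property
    def sample_ids(self) -> list:
        return self.values.columns.tolist()

    def condensed(self) -> np.ndarray:
        arr = self.values.to_numpy(dtype=float).copy()
        np.fill_diagonal(arr, 0.0)
        return squareform((arr + arr.T) / 2.0, checks=False)


@dataclass
class OutlierReport:
    """Samples on the smaller branch of the top-level dendrogram cut, with
    each sample's dominant taxon and Shannon index when an abundance matrix
    was supplied."""

    outliers: list
    linkage: str
    metric: str
    tie: bool = False
    detail: pd.DataFrame | None = field(default=None, repr=False)


def shannon(abund_column) -> float:
    """Shannon diversity H = -sum p_i ln(p_i), in nats.

    The column is renormalized to sum 1 over its nonzero entries, so percent
    and fractional abundances give the same index.
    """
    p = np.asarray(abund_column, dtype=float)
    if (p < 0).any():
        raise GutshiftError("abundances must be non-negative")
    total = p.sum()
    if total <= 0:
        raise GutshiftError("cannot compute Shannon index of an all-zero sample")
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(abund: AbundanceMatrix) -> pd.Series:
    return pd.Series(
        {s: shannon(abund.values[s].to_numpy()) for s in abund.sample_ids},
        name="shannon",
    )


def welch_compare(group_a, group_b) -> tuple[float, float]:
    """Welch's unequal-variance two-sided t test -> (t, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise GutshiftError("Welch's test needs n >= 2 per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise GutshiftError("Welch's test undefined for two distinct constants")
    t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bray_curtis(abund: AbundanceMatrix) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis: BC(x, y) = 1 - 2 sum_i min(x_i, y_i) / (sum x + sum y)."""
    x = abund.values.to_numpy(dtype=float)
    totals = x.sum(axis=0)
    if (totals <= 0).any():
        sample = abund.values.columns[int(np.argmax(totals <= 0))]
        raise GutshiftError(f"sample {sample!r} has zero total abundance")
    n = x.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        shared = np.minimum(x[:, i : i + 1], x[:, i + 1 :]).sum(axis=0)
        d[i, i + 1 :] = 1.0 - 2.0 * shared / (totals[i] + totals[i + 1 :])
    d = d + d.T
    df = pd.DataFrame(d, index=abund.values.columns, columns=abund.values.columns)
    return DissimilarityMatrix(df, metric="braycurtis")


def mds_ordinate(d: DissimilarityMatrix, k: int = 2) -> pd.DataFrame:
    """Classical (metric) multidimensional scaling.

    Eigendecomposition of the double-centered squared-dissimilarity matrix;
    axes are ordered by decreasing eigenvalue and negative-eigenvalue axes
    are dropped (Bray-Curtis is non-Euclidean, so some always are).
    """
    if k < 1:
        raise GutshiftError("k must be >= 1")
    dm = d.values.to_numpy(dtype=float)
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > max(1e-10 * abs(eigval[0]), 1e-12) if eigval[0] > 0 else eigval > 0
    n_pos = int(positive.sum())
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating"
        )
        k = max(n_pos, 1)
    coords = eigvec[:, :k] * np.sqrt(np.maximum(eigval[:k], 0.0))
    return pd.DataFrame(
        coords, index=d.values.index, columns=[f"MDS{i + 1}" for i in range(k)]
    )


def detect_outliers(
    d: DissimilarityMatrix,
    linkage: str = "ward",
    abund: AbundanceMatrix | None = None,
    dominance_threshold: float = 50.0,
) -> OutlierReport:
    """Members of the smaller branch after cutting the clustering tree at the
    top level.

    An exact tie in branch sizes leaves "smaller" undefined and yields an
    empty outlier set with a warning.  When a genus-level abundance matrix
    is given, the report carries each sample's dominant taxon, its
    abundance, and the sample's Shannon index.
    """
    if linkage not in ("ward", "complete"):
        raise GutshiftError(f"unsupported linkage {linkage!r}")
    samples = d.sample_ids
    if len(samples) < 3:
        raise GutshiftError("outlier detection needs at least 3 samples")
    tree = sch.linkage(d.condensed(), method=linkage)
    branches = sch.fcluster(tree, t=2, criterion="maxclust")
    sizes = np.bincount(branches)[1:]
    tie = False
    if len(sizes) < 2:
        outliers: list = []
    elif sizes[0] == sizes[1]:
        warnings.warn("top-level branches are the same size; no outliers reported")
        outliers, tie = [], True
    else:
        smaller = 1 + int(np.argmin(sizes))
        outliers = [s for s, b in zip(samples, branches) if b == smaller]
    detail = None
    if abund is not None and outliers:
        dom = dominance_report(abund, threshold_percent=dominance_threshold)
        detail = dom.loc[outliers].copy()
        detail["shannon"] = shannon_per_sample(abund).loc[outliers]
    return OutlierReport(outliers=outliers, linkage=linkage, metric=d.metric, tie=tie, detail=detail)


def dominance_report(abund: AbundanceMatrix, threshold_percent: float = 50.0) -> pd.DataFrame:
    """Per-sample dominant taxon, its relative abundance, and whether it
    exceeds the dominance threshold (default 50%)."""
    values = abund.values
    top = values.idxmax(axis=0)
    top_abund = values.max(axis=0)
    return pd.DataFrame(
        {
            "top_taxon": top,
            "abundance_percent": top_abund,
            "dominated": top_abund > threshold_percent,
        },
        index=values.columns,
    )
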
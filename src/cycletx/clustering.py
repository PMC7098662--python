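"""Temporal clustering of periodic genes into expression waves.

Selected genes (z-scored profiles, usually of the replicate-averaged
dataset) are grouped by Euclidean-distance agglomerative clustering or by
k-means; clusters are re-indexed by the time at which their mean profile
peaks and labeled with the cell-cycle stage whose window contains that
peak.  Agreement between two clusterings is the pairwise overlap divided by
the size of the smaller cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .periodicity import ExpressionTimeCourse

logger = logging.getLogger("cycletx.clustering")

__all__ = [
    "ClusterAssignment",
    "DEFAULT_PHASE_WINDOWS",
    "hierarchical_clusters",
    "kmeans_clusters",
    "cluster_agreement",
    "assign_phase_labels",
]

# (start_hour, end_hour, label); checked in order, intervals closed; the G1
# window wraps around the late and initial part of the next cycle.
DEFAULT_PHASE_WINDOWS: list[tuple[float, float, str]] = [
    (2.0, 3.5, "G1/S"),
    (3.5, 5.75, "S"),
    (6.5, 7.25, "G2/M"),
    (9.5, 11.0, "M"),
    (11.0, float("inf"), "G1"),
]


@dataclass
class ClusterAssignment:
    """Gene -> cluster index (1..k), with per-cluster peak times and labels."""

    labels: dict[str, int]
    k: int
    peak_times: dict[int, float] = field(default_factory=dict)
    phase_labels: dict[int, str] = field(default_factory=dict)
    method: str = ""

    def __post_init__(self) -> None:
        present = set(self.labels.values())
        if present != set(range(1, self.k + 1)):
            raise ValueError(f"cluster indices must be exactly 1..{self.k}, got {sorted(present)}")

    def members(self, cluster: int) -> set[str]:
        return {g for g, c in self.labels.items() if c == cluster}

    def sizes(self) -> dict[int, int]:
        out = {c: 0 for c in range(1, self.k + 1)}
        for c in self.labels.values():
            out[c] += 1
        return out

    def as_sets(self) -> dict[int, set[str]]:
        return {c: self.members(c) for c in range(1, self.k + 1)}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gene_id": g, "cluster": c,
                 "phase_label": self.phase_labels.get(c, "")}
                for g, c in sorted(self.labels.items())]
        return pd.DataFrame(rows)


def _finalize(tc: ExpressionTimeCourse, raw_labels: np.ndarray, k: int, method: str) -> ClusterAssignment:
    """Re-index clusters by ascending peak time of their mean profile."""
    clusters = {}
    for c in np.unique(raw_labels):
        idx = np.flatnonzero(raw_labels == c)
        mean = tc.values[idx].mean(axis=0)
        peak = float(tc.times[int(np.argmax(mean))])
        clusters[c] = (peak, idx)
    order = sorted(clusters, key=lambda c: (clusters[c][0], int(c)))
    labels = {}
    peaks = {}
    for new, old in enumerate(order, start=1):
        peak, idx = clusters[old]
        peaks[new] = peak
        for i in idx:
            labels[tc.gene_ids[i]] = new
    return ClusterAssignment(labels=labels, k=k, peak_times=peaks, method=method)


def _check_profiles(tc: ExpressionTimeCourse, k: int) -> None:
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > tc.n_genes:
        raise ValueError(f"k={k} exceeds the {tc.n_genes} genes to cluster")


def hierarchical_clusters(profiles: ExpressionTimeCourse, k: int = 5,
                          linkage: str = "complete") -> ClusterAssignment:
    """Agglomerative clustering on Euclidean distances, cut at exactly k
    groups.  Linkage is configurable ({complete, average, ward}); the
    underlying reference does not pin it down, so the default is complete."""
    _check_profiles(profiles, k)
    if linkage not in ("complete", "average", "ward", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if profiles.n_genes == k:
        raw = np.arange(k)
    else:
        z = scipy_linkage(pdist(profiles.values, metric="euclidean"), method=linkage)
        raw = fcluster(z, t=k, criterion="maxclust")
        if np.unique(raw).size != k:
            raise ValueError(f"could not cut the dendrogram into exactly {k} clusters")
    return _finalize(profiles, np.asarray(raw), k, f"hierarchical/{linkage}")


def kmeans_clusters(profiles: ExpressionTimeCourse, k: int = 5, seed: int = 0,
                    n_init: int = 10) -> ClusterAssignment:
    """Seeded k-means with multiple restarts keeping the best within-cluster
    sum of squares."""
    _check_profiles(profiles, k)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(profiles.values)
    if np.unique(raw).size != k:
        raise ValueError(f"k-means returned fewer than {k} non-empty clusters")
    return _finalize(profiles, raw, k, "kmeans")


def cluster_agreement(a: ClusterAssignment, b: ClusterAssignment) -> pd.DataFrame:
    """Overlap matrix: entry (i, j) = |a_i and b_j| / min(|a_i|, |b_j|)."""
    if set(a.labels) != set(b.labels):
        raise ValueError("assignments cover different gene sets")
    sets_a, sets_b = a.as_sets(), b.as_sets()
    for name, sets in (("a", sets_a), ("b", sets_b)):
        empties = [c for c, s in sets.items() if not s]
        if empties:
            raise ValueError(f"empty clusters in {name}: {empties}")
    mat = pd.DataFrame(
        [[len(sets_a[i] & sets_b[j]) / min(len(sets_a[i]), len(sets_b[j]))
          for j in sorted(sets_b)] for i in sorted(sets_a)],
        index=sorted(sets_a), columns=sorted(sets_b),
    )
    return mat


def assign_phase_labels(
    assignment: ClusterAssignment,
    phase_windows: list[tuple[float, float, str]] | None = None,
) -> ClusterAssignment:
    """Label each cluster with the cell-cycle stage whose window contains its
    peak time; peaks outside every window get "unassigned" with a warning."""
    windows = phase_windows if phase_windows is not None else DEFAULT_PHASE_WINDOWS
    for c in range(1, assignment.k + 1):
        if c not in assignment.peak_times:
            raise ValueError(f"cluster {c} has no peak time")
        peak = assignment.peak_times[c]
        label = "unassigned"
        for start, end, name in windows:
            if start <= peak <= end:
                label = name
                break
        if label == "unassigned":
            logger.warning("cluster %d peak at %.2f h falls in no phase window", c, peak)
        assignment.phase_labels[c] = label
    return assignment


def cluster_mean_profiles(tc: ExpressionTimeCourse, assignment: ClusterAssignment) -> pd.DataFrame:
    """Mean profile per cluster (rows) over the time grid (columns)."""
    rows = {}
    gene_index = {g: i for i, g in enumerate(tc.gene_ids)}
    for c in range(1, assignment.k + 1):
        idx = [gene_index[g] for g in assignment.members(c) if g in gene_index]
        rows[c] = tc.values[idx].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"t{t:.2f}" for t in tc.times])


def plot_cluster_heatmap(tc: ExpressionTimeCourse, assignment: ClusterAssignment,
                         path: str) -> None:
    """Optional heatmap of profiles ordered by cluster (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = sorted(tc.gene_ids, key=lambda g: (assignment.labels[g], g))
    gene_index = {g: i for i, g in enumerate(tc.gene_ids)}
    mat = tc.values[[gene_index[g] for g in order]]
    fig, ax = plt.subplots(figsize=(6, 8))
    ax.imshow(mat, aspect="auto", cmap="RdBu_r", interpolation="nearest")
    ax.set_xlabel("time point")
    ax.set_ylabel("genes (by cluster)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
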
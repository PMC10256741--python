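"""Lateralization phenotype classification.

The five standardized metrics are clustered by agglomerative hierarchical
clustering (Euclidean distance, Ward's minimum-variance criterion). The
three-cluster solution defines the phenotype; clusters are named by their
mean network task asymmetry (highest -> strong typical, middle -> mild
typical, lowest -> atypical). A bootstrap Jaccard score quantifies how
stable each candidate cluster count is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .metrics import FEATURE_NAMES

__all__ = [
    "ClusteringResult",
    "GROUP_NAMES",
    "standardize_features",
    "ward_cluster",
    "label_groups",
    "cluster_stability",
]

GROUP_NAMES = ("strong_typical", "mild_typical", "atypical")


class ClusteringError(ValueError):
    pass


@dataclass
class ClusteringResult:
    labels: np.ndarray
    merge_heights: np.ndarray
    k: int
    linkage_matrix: np.ndarray
    group_names: dict[int, str] = field(default_factory=dict)
    ambiguous_atypical: bool = False

    def named_labels(self) -> np.ndarray:
        if not self.group_names:
            raise ClusteringError("clusters have not been named; run label_groups first")
        return np.array([self.group_names[int(c)] for c in self.labels], dtype=object)


def standardize_features(features: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Column-wise z-scoring (sample SD). Constant columns are an error since
    they would silently drop out of the Euclidean metric."""
    numeric = features.select_dtypes(include=[np.number])
    if len(numeric) < 2:
        raise ClusteringError("need at least 2 subjects to standardize")
    out = numeric.copy().astype(float)
    for col in out.columns:
        sd = out[col].std(ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            raise ClusteringError(f"feature {col!r} is constant; cannot standardize")
        out[col] = (out[col] - out[col].mean()) / sd
    return out


def ward_cluster(standardized: pd.DataFrame | np.ndarray, k: int) -> ClusteringResult:
    """Full Ward dendrogram (heights in Euclidean-distance units, Ward.D2
    convention) cut at ``k`` clusters. Labels are 0-based, renumbered by
    first appearance."""
    X = np.asarray(standardized, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ClusteringError(f"k={k} outside [1, n={n}]")
    if n == 1:
        return ClusteringResult(np.zeros(1, dtype=int), np.empty(0), 1, np.empty((0, 4)))
    Z = linkage(X, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # renumber by first appearance for determinism
    seen: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, c in enumerate(raw):
        if c not in seen:
            seen[c] = len(seen)
        labels[i] = seen[c]
    return ClusteringResult(labels=labels, merge_heights=Z[:, 2].copy(), k=k, linkage_matrix=Z)


def label_groups(result: ClusteringResult, features: pd.DataFrame) -> ClusteringResult:
    """Name the 3 clusters from their mean ``beta_network_asym`` (raw units):
    highest -> strong_typical, middle -> mild_typical, lowest -> atypical.
    Ties are broken by the hub asymmetry mean. If the lowest cluster's mean
    asymmetry is not negative it is still named atypical, with a warning.
    """
    if result.k != 3:
        raise ClusteringError("group naming is defined only for the 3-cluster solution")
    if "beta_network_asym" not in features.columns:
        raise ClusteringError("features table lacks beta_network_asym")
    net = features["beta_network_asym"].to_numpy(dtype=float)
    hub = (
        features["beta_hubs_asym"].to_numpy(dtype=float)
        if "beta_hubs_asym" in features.columns
        else np.zeros_like(net)
    )
    stats = []
    for c in range(3):
        mask = result.labels == c
        if not mask.any():
            raise ClusteringError(f"cluster {c} is empty")
        stats.append((float(net[mask].mean()), float(hub[mask].mean()), c))
    ranked = sorted(stats, key=lambda t: (t[0], t[1]), reverse=True)
    names = {ranked[0][2]: "strong_typical", ranked[1][2]: "mild_typical", ranked[2][2]: "atypical"}
    ambiguous = ranked[2][0] >= 0
    if ambiguous:
        warnings.warn(
            "lowest-asymmetry cluster has a nonnegative mean network asymmetry; "
            "naming it atypical anyway",
            stacklevel=2,
        )
    return ClusteringResult(
        labels=result.labels,
        merge_heights=result.merge_heights,
        k=result.k,
        linkage_matrix=result.linkage_matrix,
        group_names=names,
        ambiguous_atypical=ambiguous,
    )


def _bootstrap_jaccard(X: np.ndarray, full_labels: np.ndarray, k: int, rng) -> float:
    n = X.shape[0]
    idx = rng.integers(0, n, size=n)
    uniq = np.unique(idx)
    res = ward_cluster(X[idx], k)
    # label per original index: first occurrence in the resample
    boot_label = {}
    for j, orig in enumerate(idx):
        boot_label.setdefault(int(orig), int(res.labels[j]))
    scores = []
    for c in np.unique(full_labels):
        orig_set = {int(i) for i in uniq if full_labels[i] == c}
        if not orig_set:
            continue
        best = 0.0
        for cb in range(k):
            boot_set = {i for i in boot_label if boot_label[i] == cb}
            inter = len(orig_set & boot_set)
            union = len(orig_set | boot_set)
            if union:
                best = max(best, inter / union)
        scores.append(best)
    return float(np.mean(scores))


def cluster_stability(
    standardized: pd.DataFrame | np.ndarray,
    k_range=(2, 3, 4, 5),
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean bootstrap Jaccard similarity between the full-data clusters and
    the clusters found on resampled data, for each candidate k.

    An ordinary nonparametric bootstrap is used as the stability diagnostic
    (values near 1 indicate a reproducible partition).
    """
    X = np.asarray(standardized, dtype=float)
    n = X.shape[0]
    if n_boot < 100:
        raise ClusteringError("n_boot must be at least 100 for a usable stability estimate")
    for k in k_range:
        if not 2 <= k <= n - 1:
            raise ClusteringError(f"k={k} outside [2, n-1]")
    rng = np.random.default_rng(seed)
    rows = []
    for k in k_range:
        full = ward_cluster(X, k).labels
        vals = [_bootstrap_jaccard(X, full, k, rng) for _ in range(n_boot)]
        rows.append({"k": int(k), "jaccard": float(np.mean(vals))})
    return pd.DataFrame(rows)
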
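"""Sample-level structure and category-distribution tests.

Hierarchical clustering of the samples on Euclidean distances between
variance-stabilized expression profiles, PCA of the same matrix, a
Kolmogorov-Smirnov comparison of functional-category percentage
distributions, and a chi-square test of up/down balance against 50:50.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy import stats


def euclidean_distances(transformed: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between sample expression profiles.

    *transformed* is features x samples (variance-stabilized values).
    """
    if transformed.shape[1] < 2:
        raise ValueError("at least 2 samples are required")
    if transformed.isna().to_numpy().any():
        raise ValueError("missing values in the transformed matrix")
    dist = squareform(pdist(transformed.to_numpy().T, metric="euclidean"))
    return pd.DataFrame(dist, index=transformed.columns, columns=transformed.columns)


def hierarchical_cluster(dist: pd.DataFrame, linkage: str = "complete") -> np.ndarray:
    """Agglomerative clustering; returns the scipy linkage (merge) matrix."""
    if linkage not in ("complete", "average", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    values = dist.to_numpy()
    if np.isnan(values).any():
        raise ValueError("distance matrix contains NaN")
    condensed = squareform(values, checks=True)
    return hierarchy.linkage(condensed, method=linkage)


def cut_clusters(merge_matrix: np.ndarray, labels, k: int) -> pd.Series:
    """Flat cluster assignment from cutting the dendrogram into *k* clusters."""
    assignment = hierarchy.fcluster(merge_matrix, t=k, criterion="maxclust")
    return pd.Series(assignment, index=pd.Index(labels, name="sample_id"), name="cluster")


def dendrogram_newick(merge_matrix: np.ndarray, labels) -> str:
    """Newick serialization of the sample dendrogram (branch lengths = heights)."""
    tree = hierarchy.to_tree(merge_matrix)
    labels = list(labels)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"


def pca(transformed: pd.DataFrame, n_components: int | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Centered PCA over samples; returns scores and percent variance.

    Samples are observations (columns of the features x samples input);
    centering is over samples per feature.  A constant matrix is degenerate:
    all variance percentages are reported as zero.
    """
    if transformed.shape[1] < 2:
        raise ValueError("at least 2 samples are required")
    x = transformed.to_numpy().T  # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total = float((s**2).sum())
    k = len(s) if n_components is None else min(n_components, len(s))
    scores = pd.DataFrame(
        (u * s)[:, :k],
        index=transformed.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    if total == 0:
        pct = np.zeros(k)
    else:
        pct = 100.0 * (s[:k] ** 2) / total
    return scores, pd.Series(pct, index=scores.columns, name="pct_variance")


def ks_distribution_test(dist_a: pd.Series, dist_b: pd.Series) -> tuple[float, float]:
    """Two-sample KS test on paired category-percentage vectors.

    Both inputs are percentages indexed by the same ordered category axis;
    the vectors are treated as two samples of a distribution over that axis
    (a descriptive use of the KS statistic, mirroring functional-category
    comparisons of up- vs down-regulated gene sets).
    """
    if list(dist_a.index) != list(dist_b.index):
        raise ValueError("category universes differ or are not aligned")
    result = stats.ks_2samp(dist_a.to_numpy(float), dist_b.to_numpy(float),
                            method="auto")
    return float(result.statistic), float(result.pvalue)


def chisq_balance(n_up: int, n_down: int, continuity: bool = False) -> tuple[float, float]:
    """One-df chi-square of an up/down split against the 50:50 expectation."""
    if n_up < 0 or n_down < 0:
        raise ValueError("counts must be non-negative")
    total = n_up + n_down
    if total == 0:
        raise ValueError("at least one observation is required")
    expected = total / 2.0
    if continuity:
        x2 = sum((abs(o - expected) - 0.5) ** 2 / expected for o in (n_up, n_down))
    else:
        x2 = sum((o - expected) ** 2 / expected for o in (n_up, n_down))
    p = float(stats.chi2.sf(x2, df=1))
    return float(x2), p
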
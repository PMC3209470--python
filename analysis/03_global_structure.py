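#!/usr/bin/env python
"""Normalization and sample-level structure.

Computes median-of-ratios size factors, variance-stabilizes the normalized
counts, and asks whether the libraries separate by genotype: hierarchical
clustering on Euclidean distances (two-cluster cut) and PCA with the percent
variance carried by each component.

Writes size factors, the VST matrix, the distance matrix, a Newick
dendrogram, PCA scores and a distance-heatmap figure under results/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from senseq.counts import read_counts, read_samples
from senseq.detest import fit_local_variance
from senseq.downstream import (
    cut_clusters,
    dendrogram_newick,
    euclidean_distances,
    hierarchical_cluster,
    pca,
)
from senseq.normalization import size_factors_median_ratio, variance_stabilize

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts = read_counts(ROOT / "counts_clean.tsv")
    samples = read_samples(ROOT / "samples_clean.tsv")

    factors = size_factors_median_ratio(counts)
    factors.round(4).to_csv(ROOT / "size_factors.tsv", sep="\t")
    print("size factors:", factors.round(3).to_dict())

    varfun = fit_local_variance(counts, factors, samples)
    vst = variance_stabilize(counts, factors, varfun)
    vst.to_csv(ROOT / "vst_counts.tsv", sep="\t")

    dist = euclidean_distances(vst)
    dist.to_csv(ROOT / "sample_distances.tsv", sep="\t")
    merge = hierarchical_cluster(dist, linkage="complete")
    (ROOT / "sample_dendrogram.nwk").write_text(
        dendrogram_newick(merge, dist.index) + "\n"
    )
    clusters = cut_clusters(merge, dist.index, k=2)
    by_cluster = {
        c: sorted(clusters.index[clusters == c]) for c in sorted(clusters.unique())
    }
    print("two-cluster cut:", by_cluster)

    scores, pct = pca(vst)
    scores.round(4).to_csv(ROOT / "pca_scores.tsv", sep="\t")
    pct.round(2).to_csv(ROOT / "pca_variance.tsv", sep="\t")
    print("PCA percent variance:",
          ", ".join(f"{c}: {v:.1f}%" for c, v in pct.head(3).items()))

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(dist.to_numpy(), cmap="Reds_r")
    ax.set_xticks(range(len(dist)), dist.columns, rotation=90)
    ax.set_yticks(range(len(dist)), dist.index)
    fig.colorbar(im, ax=ax, label="Euclidean distance (VST)")
    fig.tight_layout()
    (ROOT / "figures").mkdir(exist_ok=True)
    fig.savefig(ROOT / "figures" / "sample_distances.png", dpi=150)
    print("wrote distance heatmap")


if __name__ == "__main__":
    main()
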
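"""End-to-end orchestration: QC -> aggregate -> normalize -> test -> permute -> report.

``run_pipeline`` wires the stages together with one configuration and a single
seed, writes every artifact as TSV/JSON under an output directory, and records
a manifest (seeds, row counts, sha256 checksums) so that a rerun with the same
configuration is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import counts as counts_mod
from . import readqc
from .detest import ConsensusThresholds, run_de_tests
from .downstream import (
    cut_clusters,
    dendrogram_newick,
    euclidean_distances,
    hierarchical_cluster,
    pca,
)
from .normalization import normalize, size_factors_median_ratio, variance_stabilize
from .detest import estimate_common_dispersion, fit_local_variance
from .permutation import (
    DEFAULT_SHAPE,
    empirical_rate,
    enumerate_constrained_permutations,
    run_permutation_null,
    sample_permutations,
)

logger = logging.getLogger("senseq.pipeline")


@dataclass
class PipelineConfig:
    counts_path: Path | None = None
    contig_map_path: Path | None = None
    samples_path: Path | None = None
    fastq_paths: dict[str, Path] = field(default_factory=dict)
    sentinel_path: Path | None = None
    output_dir: Path = Path("senseq_output")
    thresholds: ConsensusThresholds = field(default_factory=ConsensusThresholds)
    mww_mode: str = "normal"
    n_permutations: int = 10
    permutation_shape: tuple = DEFAULT_SHAPE
    seed: int = 0


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    counts: pd.DataFrame | None = None,
    samples: pd.DataFrame | None = None,
) -> dict:
    """Run all stages; returns the artifact dictionary (also written to disk).

    Count and sample tables may be passed in memory (as the analysis drivers
    do) or read from the configured paths.  Samples flagged by the sentinel
    contamination check are dropped automatically before testing.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"seed": config.seed}

    if counts is None:
        if config.counts_path is None:
            raise ValueError("either an in-memory count matrix or counts_path is required")
        counts = counts_mod.read_counts(config.counts_path)
    if samples is None:
        if config.samples_path is None:
            raise ValueError("either an in-memory sample table or samples_path is required")
        samples = counts_mod.read_samples(config.samples_path)

    # --- read QC / contamination sentinel ---------------------------------
    if config.fastq_paths:
        sentinel = (
            readqc.read_sentinel_fasta(config.sentinel_path)
            if config.sentinel_path
            else None
        )
        per_sample = {}
        for sample_id, path in config.fastq_paths.items():
            reads = readqc.read_fastq(path)
            _, qc = readqc.process_reads(reads, sentinel=sentinel)
            per_sample[sample_id] = qc
            logger.info("qc sample=%s input=%d passed=%d sentinel=%d",
                        sample_id, qc.n_input, qc.n_passed, qc.sentinel_count)
        qc_frame = readqc.qc_report_frame(per_sample)
        qc_frame.to_csv(out / "qc_report.tsv", sep="\t")
        artifacts["qc_report"] = qc_frame
        if sentinel is not None:
            flags = readqc.flag_contamination(
                qc_frame["sentinel_count"], samples["genotype"].reindex(qc_frame.index)
            )
            artifacts["contamination_flags"] = flags
            for sample_id in flags.index[flags]:
                logger.warning("dropping contaminated sample %s", sample_id)
                counts, samples = counts_mod.drop_sample(counts, samples, sample_id)

    # --- aggregation ------------------------------------------------------
    if config.contig_map_path is not None:
        mapping = counts_mod.read_contig_map(config.contig_map_path)
        counts, agg_report = counts_mod.aggregate_to_isogroups(counts, mapping)
        artifacts["aggregation_report"] = agg_report
        logger.info("aggregated %d contigs into %d isogroups",
                    agg_report["n_contigs"], agg_report["n_isogroups"])

    included = counts_mod.included_samples(samples)
    counts = counts[[c for c in counts.columns if c in included]]
    counts_mod.write_counts(counts, out / "counts.tsv")
    counts_mod.write_samples(samples, out / "samples.tsv")

    # --- normalization / global structure ---------------------------------
    factors = size_factors_median_ratio(counts)
    factors.to_csv(out / "size_factors.tsv", sep="\t")
    normalized = normalize(counts, factors)
    normalized.to_csv(out / "normalized_counts.tsv", sep="\t")
    alpha = estimate_common_dispersion(counts, factors, samples)
    varfun = fit_local_variance(counts, factors, samples)
    logger.info("size factors computed; common dispersion alpha=%.4f", alpha)

    transformed = variance_stabilize(counts, factors, varfun)
    transformed.to_csv(out / "vst_counts.tsv", sep="\t")
    dist = euclidean_distances(transformed)
    dist.to_csv(out / "sample_distances.tsv", sep="\t")
    merge = hierarchical_cluster(dist)
    clusters = cut_clusters(merge, dist.index, k=2)
    (out / "sample_dendrogram.nwk").write_text(dendrogram_newick(merge, dist.index) + "\n")
    scores, pct = pca(transformed)
    scores.to_csv(out / "pca_scores.tsv", sep="\t")
    pct.to_csv(out / "pca_variance.tsv", sep="\t")
    artifacts.update(
        size_factors=factors, dispersion=alpha, clusters=clusters,
        pca_scores=scores, pca_pct_variance=pct,
    )

    # --- differential testing / consensus ---------------------------------
    result = run_de_tests(
        counts, samples, thresholds=config.thresholds, mww_mode=config.mww_mode,
        factors=factors, alpha=alpha, varfun=varfun,
    )
    result.to_csv(out / "result_table.tsv", sep="\t")
    two_test = result[
        (result["q_pooled"] <= config.thresholds.q_pooled_max)
        & (result["q_local"] <= config.thresholds.q_local_max)
    ]
    three_test = result[result["consensus"] != "none"]
    two_test.to_csv(out / "consensus_two_test.tsv", sep="\t")
    three_test.to_csv(out / "consensus_three_test.tsv", sep="\t")
    volcano = pd.DataFrame(
        {
            "log2fc": result["log2fc"],
            "neg_log10_p": -np.log10(result["p_local"].clip(lower=1e-300)),
        }
    )
    volcano.to_csv(out / "volcano.tsv", sep="\t")
    artifacts.update(result_table=result, two_test_set=two_test, three_test_set=three_test)
    logger.info("two-test consensus: %d features; three-test consensus: %d features",
                len(two_test), len(three_test))

    # --- permutation null --------------------------------------------------
    try:
        scheme = enumerate_constrained_permutations(samples, config.permutation_shape)
    except ValueError:
        logger.warning("permutation shape infeasible for this design; stage skipped")
        scheme = None
    if scheme is not None:
        n = min(config.n_permutations, len(scheme))
        chosen = sample_permutations(scheme, n, seed=config.seed)
        report = run_permutation_null(counts, chosen, thresholds=config.thresholds)
        report.counts.to_csv(out / "permutation_counts.tsv", sep="\t")
        summary = report.summary()
        if len(two_test):
            summary["empirical_rate_pct"] = empirical_rate(
                report.mean("n_intersection"), len(two_test)
            )
        (out / "permutation_report.json").write_text(json.dumps(summary, indent=2))
        artifacts["permutation_report"] = report
        artifacts["permutation_summary"] = summary

    manifest = {
        "seed": config.seed,
        "n_features": int(counts.shape[0]),
        "n_samples": int(counts.shape[1]),
        "n_two_test": int(len(two_test)),
        "n_three_test": int(len(three_test)),
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = manifest
    return artifacts
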
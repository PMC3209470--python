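"""Count-matrix ingestion, contig-to-isogroup aggregation and sample management.

The unit of analysis is the *isogroup*: a set of assembled contigs connected by
shared reads, expected to merge splice variants, homoeologs and close paralogs
of one wheat gene.  Read counts are tabulated per contig by the upstream
aligner and summed within isogroups here.  A count matrix is a plain pandas
``DataFrame`` of non-negative integers with feature ids as the index and sample
ids as the columns; sample metadata lives in a second frame with a ``genotype``
column (``"WT"`` or ``"RNAi"``) and an ``included`` flag.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

WT = "WT"
RNAI = "RNAi"
GENOTYPES = (WT, RNAI)


def validate_count_matrix(counts: pd.DataFrame) -> None:
    """Raise ``ValueError`` unless *counts* is a valid feature x sample matrix."""
    if counts.index.has_duplicates:
        raise ValueError("duplicate feature ids in count matrix")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample ids in count matrix")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("count matrix must be numeric")
    if (values < 0).any():
        raise ValueError("count matrix contains negative entries")
    if not np.allclose(values, np.round(values)):
        raise ValueError("count matrix must be integer-valued")


def make_sample_table(sample_ids, genotypes) -> pd.DataFrame:
    """Build a sample table from parallel id / genotype sequences."""
    genotypes = list(genotypes)
    for g in genotypes:
        if g not in GENOTYPES:
            raise ValueError(f"unknown genotype label {g!r}")
    return pd.DataFrame(
        {"genotype": genotypes, "included": True},
        index=pd.Index(sample_ids, name="sample_id"),
    )


def included_samples(samples: pd.DataFrame, genotype: str | None = None) -> list[str]:
    mask = samples["included"]
    if genotype is not None:
        mask = mask & (samples["genotype"] == genotype)
    return list(samples.index[mask])


def aggregate_to_isogroups(
    contig_counts: pd.DataFrame,
    mapping: pd.Series,
    allow_unmapped: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Sum per-contig counts into per-isogroup counts.

    *mapping* maps contig id -> isogroup id (each contig to exactly one
    isogroup).  Contigs absent from the mapping raise by default; with
    ``allow_unmapped`` they are dropped with a warning and tallied in the
    returned report.
    """
    validate_count_matrix(contig_counts)
    if mapping.index.has_duplicates:
        raise ValueError("a contig maps to more than one isogroup")
    unmapped = contig_counts.index.difference(mapping.index)
    if len(unmapped) and not allow_unmapped:
        raise ValueError(
            f"{len(unmapped)} contigs missing from the contig->isogroup mapping "
            f"(first: {unmapped[0]!r}); pass allow_unmapped=True to drop them"
        )
    if len(unmapped):
        warnings.warn(f"dropping {len(unmapped)} unmapped contigs", stacklevel=2)
    mapped = contig_counts.drop(index=unmapped)
    groups = mapping.reindex(mapped.index)
    aggregated = mapped.groupby(groups, sort=True).sum()
    aggregated.index.name = "feature_id"
    report = {
        "n_contigs": int(contig_counts.shape[0]),
        "n_unmapped_dropped": int(len(unmapped)),
        "n_isogroups": int(aggregated.shape[0]),
        "total_counts_in": int(mapped.to_numpy().sum()),
        "total_counts_out": int(aggregated.to_numpy().sum()),
    }
    return aggregated, report


def drop_sample(
    counts: pd.DataFrame, samples: pd.DataFrame, sample_id: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove one sample (e.g. a contaminated library) from the analysis.

    The sample is dropped from the matrix and marked ``included=False`` in the
    sample table.  A warning is emitted if a genotype is left with fewer than
    two included samples, which would invalidate the testing stages.
    """
    if sample_id not in counts.columns or sample_id not in samples.index:
        raise KeyError(f"unknown sample id {sample_id!r}")
    new_counts = counts.drop(columns=sample_id)
    new_samples = samples.copy()
    new_samples.loc[sample_id, "included"] = False
    remaining = new_samples[new_samples["included"]]
    for genotype, n in remaining["genotype"].value_counts().items():
        if n < 2:
            warnings.warn(
                f"genotype {genotype} has {n} included sample(s); "
                "differential testing requires at least 2",
                stacklevel=2,
            )
    return new_counts, new_samples


# ---------------------------------------------------------------------------
# TSV round-trips.  Tab-separated, header row of sample ids, first column the
# feature id, UTF-8, no quoting.
# ---------------------------------------------------------------------------

def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    validate_count_matrix(counts)
    return counts.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_samples(path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", index_col=0)
    if "included" not in samples.columns:
        samples["included"] = True
    samples["included"] = samples["included"].astype(bool)
    return samples


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_contig_map(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.iloc[:, 0]


def write_contig_map(mapping: pd.Series, path) -> None:
    mapping.rename("isogroup_id").to_csv(path, sep="\t", index_label="contig_id")
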
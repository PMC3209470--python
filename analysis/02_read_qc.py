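#!/usr/bin/env python
"""Read QC and the contamination sentinel.

Trims every library's reads at the first failed-quality call, applies the
40-nt length and 20-80% GC filters, counts exact sentinel matches per
library, and flags non-carrier libraries with sentinel evidence.  The flagged
library (WT4 in the simulated scenario) is dropped, leaving the 4 RNAi + 3 WT
design used by all downstream stages.

Writes results/qc_report.tsv and the cleaned counts/samples tables.
"""

from pathlib import Path

import pandas as pd

from senseq.counts import drop_sample, read_counts, read_samples, write_counts, write_samples
from senseq.readqc import (
    flag_contamination,
    process_reads,
    qc_report_frame,
    read_fastq,
    read_sentinel_fasta,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"


def main() -> None:
    counts = read_counts(DATA / "counts.tsv")
    samples = read_samples(DATA / "samples.tsv")
    sentinel = read_sentinel_fasta(DATA / "sentinel.fasta")

    per_sample = {}
    for sample_id in samples.index:
        reads = read_fastq(DATA / f"{sample_id}.fastq")
        _, qc = process_reads(reads, sentinel=sentinel)
        per_sample[sample_id] = qc
    report = qc_report_frame(per_sample)
    report.to_csv(ROOT / "qc_report.tsv", sep="\t")
    print(report)

    flags = flag_contamination(report["sentinel_count"], samples["genotype"])
    for sample_id in flags.index[flags]:
        print(f"flagged {sample_id}: {report.loc[sample_id, 'sentinel_count']} "
              "sentinel reads in a non-carrier library -> removed")
        counts, samples = drop_sample(counts, samples, sample_id)

    included = samples[samples.included]
    print("remaining design:", included.genotype.value_counts().to_dict())
    write_counts(counts, ROOT / "counts_clean.tsv")
    write_samples(samples, ROOT / "samples_clean.tsv")


if __name__ == "__main__":
    main()
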
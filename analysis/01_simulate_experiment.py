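#!/usr/bin/env python
"""Simulate the full study's inputs.

Generates an 8-library flag-leaf experiment (4 RNAi + 4 WT) with the default
differential-expression structure (5.5% DE features, 30% of them higher in
WT, two-fold median effects, NB dispersion 0.1, unequal library sizes), plus
per-library FASTQ reads in which every RNAi library and exactly one WT
library (WT4) carry reads from the RNAi-vector sentinel sequence — the
cross-contamination scenario the QC stage must catch.

Writes counts, truth labels, sample metadata, FASTQ files and the sentinel
FASTA under results/data/.
"""

from pathlib import Path

from senseq.counts import write_counts, write_samples
from senseq.readqc import write_fastq, write_sentinel_fasta
from senseq.synthetic import (
    SimulationConfig,
    make_sentinel,
    simulate_counts,
    simulate_qpcr,
    simulate_reads,
)

SEED = 17
DATA = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)

    config = SimulationConfig(n_features=2000, n_group_a=4, n_group_b=4, seed=SEED)
    experiment = simulate_counts(config)
    write_counts(experiment.counts, DATA / "counts.tsv")
    write_samples(experiment.samples, DATA / "samples.tsv")
    experiment.truth.to_csv(DATA / "truth.tsv", sep="\t")
    config.to_yaml(DATA / "simulation_config.yaml")
    n_de = int(experiment.truth.is_de.sum())
    print(f"simulated {config.n_features} isogroups x 8 libraries "
          f"({n_de} truly differential, "
          f"{int((experiment.truth.direction == 'up').sum())} up in WT)")

    sentinel = make_sentinel(1138, seed=SEED)
    write_sentinel_fasta(sentinel, DATA / "sentinel.fasta")
    for sample_id in experiment.samples.index:
        genotype = experiment.samples.loc[sample_id, "genotype"]
        n_sentinel = 0
        if genotype == "RNAi":
            n_sentinel = 40  # construct carriers legitimately express the vector
        elif sample_id == "WT4":
            n_sentinel = 15  # the contaminated wild-type library
        reads, _ = simulate_reads(
            2000, read_length=85, frac_failed_tail=0.25,
            sentinel_seq=sentinel, n_sentinel_reads=n_sentinel,
            seed=SEED + hash(sample_id) % 1000,
        )
        write_fastq(reads, DATA / f"{sample_id}.fastq")
    print("wrote per-library FASTQ files (WT4 deliberately contaminated)")

    qpcr = simulate_qpcr(22, n_replicates=10, cv=0.44, fold_change=2.0, seed=SEED)
    qpcr.to_csv(DATA / "qpcr_measurements.tsv", sep="\t", index=False)
    print("wrote a 22-gene, 10-replicate qPCR panel (CV 44%, true fold 2)")


if __name__ == "__main__":
    main()
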
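"""Illumina read trimming/filtering and the vector-sentinel contamination check.

Reads are trimmed at the first *failed* base-call symbol in the quality string
(the symbol ``'B'`` in the Illumina 1.3+ convention; matched literally, not by
score), then filtered on length (>= 40 nt) and GC content (within 20-80%,
inclusive).

Cross-contamination between libraries is detected with a *sentinel* sequence:
a construct-specific nucleotide sequence (here emulating the rice waxy-a
intron of the RNAi vector) absent from the host genome.  Reads matching the
sentinel exactly (no gaps, no mismatches, either strand) are counted per
sample; any positive count in a sample that is not expected to carry the
construct flags that sample for removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import gc_fraction

from .counts import RNAI

DEFAULT_FAILED_CHAR = "B"
DEFAULT_MIN_LENGTH = 40
DEFAULT_GC_RANGE = (0.20, 0.80)
QUALITY_OFFSET = 33  # Sanger; configurable at the FASTQ io boundary


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with its per-base quality symbols."""

    id: str
    sequence: str
    quality: str

    def __len__(self) -> int:
        return len(self.sequence)


def _check(read: ReadRecord) -> None:
    if len(read.sequence) != len(read.quality):
        raise ValueError(
            f"read {read.id!r}: sequence and quality lengths differ "
            f"({len(read.sequence)} vs {len(read.quality)})"
        )


def trim_at_first_failed(read: ReadRecord, failed_char: str = DEFAULT_FAILED_CHAR) -> ReadRecord:
    """Keep the prefix strictly before the first failed-score symbol.

    The read is returned unchanged when the symbol is absent.  A failed first
    base yields an empty read (dropped by the length filter downstream).
    """
    if len(failed_char) != 1:
        raise ValueError("failed_char must be a single quality symbol")
    _check(read)
    cut = read.quality.find(failed_char)
    if cut < 0:
        return read
    return ReadRecord(read.id, read.sequence[:cut], read.quality[:cut])


def filter_read(
    read: ReadRecord,
    min_length: int = DEFAULT_MIN_LENGTH,
    gc_min: float = DEFAULT_GC_RANGE[0],
    gc_max: float = DEFAULT_GC_RANGE[1],
) -> tuple[bool, str | None]:
    """Length and GC filters; returns ``(passed, reason)``; bounds inclusive."""
    _check(read)
    if len(read) < min_length:
        return False, "length"
    gc = gc_fraction(read.sequence)
    if gc < gc_min or gc > gc_max:
        return False, "gc"
    return True, None


def count_sentinel_reads(
    reads, sentinel: str, include_revcomp: bool = True
) -> int:
    """Count reads that are exact substrings of the sentinel (either strand)."""
    if not sentinel:
        raise ValueError("sentinel sequence is empty")
    sentinel = sentinel.upper()
    revcomp = str(Seq(sentinel).reverse_complement()) if include_revcomp else None
    n = 0
    for read in reads:
        seq = read.sequence.upper()
        if not seq or len(seq) > len(sentinel):
            continue
        if seq in sentinel or (revcomp is not None and seq in revcomp):
            n += 1
    return n


def flag_contamination(
    sentinel_counts: pd.Series, genotypes: pd.Series, carrier_label: str = RNAI
) -> pd.Series:
    """Flag non-carrier samples with any sentinel evidence for removal.

    Samples whose genotype is expected to carry the construct (``RNAi``) are
    never flagged, whatever their count.
    """
    if set(sentinel_counts.index) != set(genotypes.index):
        raise ValueError("sentinel counts and genotype labels cover different samples")
    genotypes = genotypes.reindex(sentinel_counts.index)
    flags = (genotypes != carrier_label) & (sentinel_counts > 0)
    return flags.rename("contaminated")


@dataclass
class SampleQC:
    """Per-sample trimming/filter tallies; ``n_passed`` is derived."""

    n_input: int = 0
    n_trimmed: int = 0
    n_dropped_length: int = 0
    n_dropped_gc: int = 0
    sentinel_count: int = 0

    @property
    def n_passed(self) -> int:
        return self.n_input - self.n_dropped_length - self.n_dropped_gc


def process_reads(
    reads,
    failed_char: str = DEFAULT_FAILED_CHAR,
    min_length: int = DEFAULT_MIN_LENGTH,
    gc_min: float = DEFAULT_GC_RANGE[0],
    gc_max: float = DEFAULT_GC_RANGE[1],
    sentinel: str | None = None,
) -> tuple[list[ReadRecord], SampleQC]:
    """Trim and filter one sample's reads; optionally count sentinel matches.

    Sentinel matching is done on the trimmed reads that pass the filters,
    mirroring a pipeline that aligns only high-quality reads.
    """
    qc = SampleQC()
    passed: list[ReadRecord] = []
    for read in reads:
        qc.n_input += 1
        trimmed = trim_at_first_failed(read, failed_char)
        if len(trimmed) < len(read):
            qc.n_trimmed += 1
        ok, reason = filter_read(trimmed, min_length, gc_min, gc_max)
        if not ok:
            if reason == "length":
                qc.n_dropped_length += 1
            else:
                qc.n_dropped_gc += 1
            continue
        passed.append(trimmed)
    if sentinel is not None:
        qc.sentinel_count = count_sentinel_reads(passed, sentinel)
    return passed, qc


def qc_report_frame(per_sample: dict[str, SampleQC]) -> pd.DataFrame:
    rows = {
        name: {
            "n_input": qc.n_input,
            "n_trimmed": qc.n_trimmed,
            "n_dropped_length": qc.n_dropped_length,
            "n_dropped_gc": qc.n_dropped_gc,
            "n_passed": qc.n_passed,
            "sentinel_count": qc.sentinel_count,
        }
        for name, qc in per_sample.items()
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sample_id"
    return frame


# ---------------------------------------------------------------------------
# FASTQ / FASTA io (Biopython-backed)
# ---------------------------------------------------------------------------

def read_fastq(path, offset: int = QUALITY_OFFSET) -> list[ReadRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quality = "".join(
            chr(q + offset) for q in rec.letter_annotations["phred_quality"]
        )
        records.append(ReadRecord(rec.id, str(rec.seq), quality))
    return records


def write_fastq(reads, path, offset: int = QUALITY_OFFSET) -> None:
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.sequence), id=read.id, description="")
        rec.letter_annotations["phred_quality"] = [
            ord(c) - offset for c in read.quality
        ]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_sentinel_fasta(path) -> str:
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq)


def write_sentinel_fasta(sequence: str, path, name: str = "sentinel") -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")
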
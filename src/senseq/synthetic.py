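"""Synthetic data with the statistical structure of a low-replicate mRNA-seq study.

The generator emulates the design of the wheat GPC-RNAi flag-leaf experiment:
negative-binomial isogroup counts for 4 RNAi and 3 wild-type libraries with a
small fraction of truly differential features (default 5.5%, of which 30% are
higher in WT, i.e. up-regulated during senescence), roughly two-fold median
effects, mean-dependent dispersion and unequal library sizes.  It also
produces qPCR replicate tables with a controlled coefficient of variation and
FASTQ reads carrying failed-quality tails and spiked sentinel-derived
contaminant reads, so that every pipeline stage is testable without external
downloads.

All randomness flows from a single integer seed through a named
``numpy.random.Generator``; identical configurations give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from .counts import RNAI, WT, make_sample_table
from .readqc import ReadRecord


@dataclass(frozen=True)
class LfcDistribution:
    """Magnitudes of true log2 fold changes: ``location * exp(scale * Z)``.

    The median |log2FC| equals ``location`` exactly (default 1, i.e. two-fold
    median effects).  ``scale=0`` gives a fixed effect size.
    """

    location: float = 1.0
    scale: float = 0.5


@dataclass(frozen=True)
class MeanDistribution:
    """Log-normal baseline expression means (median ``exp(meanlog)``)."""

    meanlog: float = float(np.log(100.0))
    sdlog: float = 1.0


@dataclass(frozen=True)
class DispersionModel:
    """NB dispersion ``alpha(mu) = alpha0 + alpha1 / mu`` (variance mu + alpha*mu^2)."""

    alpha0: float = 0.1
    alpha1: float = 0.0

    def alpha(self, mu: np.ndarray) -> np.ndarray:
        return self.alpha0 + self.alpha1 / np.maximum(np.asarray(mu, float), 1e-12)


@dataclass(frozen=True)
class SimulationConfig:
    n_features: int = 2000
    n_group_a: int = 4  # RNAi libraries
    n_group_b: int = 3  # WT libraries
    frac_de: float = 0.055
    frac_up: float = 0.30  # fraction of DE features higher in WT
    lfc: LfcDistribution = field(default_factory=LfcDistribution)
    mean: MeanDistribution = field(default_factory=MeanDistribution)
    dispersion: DispersionModel = field(default_factory=DispersionModel)
    library_size_factors: tuple[float, ...] | None = None  # default log-uniform [0.7, 1.4]
    seed: int = 0

    def __post_init__(self):
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("each group needs at least one sample")
        for name in ("frac_de", "frac_up"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dispersion.alpha0 < 0 or self.dispersion.alpha1 < 0:
            raise ValueError("dispersion coefficients must be non-negative")
        if self.library_size_factors is not None:
            n = self.n_group_a + self.n_group_b
            if len(self.library_size_factors) != n:
                raise ValueError("one library size factor per sample is required")
            if any(s <= 0 for s in self.library_size_factors):
                raise ValueError("library size factors must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SimulatedExperiment:
    counts: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.DataFrame
    size_factors: pd.Series
    contig_counts: pd.DataFrame | None = None
    contig_map: pd.Series | None = None


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean mu, variance mu + alpha*mu^2); alpha == 0 is the Poisson limit."""
    if np.any(mu <= 0):
        raise ValueError("negative-binomial means must be positive")
    if np.any(alpha < 0):
        raise ValueError("dispersion must be non-negative")
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = alpha <= 0
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    if (~poisson).any():
        n = 1.0 / alpha[~poisson]
        p = n / (n + mu[~poisson])
        out[~poisson] = rng.negative_binomial(n, p)
    return out


def simulate_counts(config: SimulationConfig) -> SimulatedExperiment:
    """Draw an NB count matrix with known differential-expression truth labels.

    Truth convention: ``direction == "up"`` means higher in WT than in RNAi
    (up-regulated during senescence); ``true_log2fc`` is log2(WT/RNAi).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_features
    n_a, n_b = config.n_group_a, config.n_group_b
    sample_ids = [f"RNAi{i + 1}" for i in range(n_a)] + [f"WT{i + 1}" for i in range(n_b)]
    samples = make_sample_table(sample_ids, [RNAI] * n_a + [WT] * n_b)

    if config.library_size_factors is None:
        factors = np.exp(rng.uniform(np.log(0.7), np.log(1.4), size=n_a + n_b))
    else:
        factors = np.asarray(config.library_size_factors, dtype=float)

    q = np.exp(rng.normal(config.mean.meanlog, config.mean.sdlog, size=n))

    n_de = int(round(config.frac_de * n))
    n_up = int(round(config.frac_up * n_de))
    de_idx = rng.choice(n, size=n_de, replace=False)
    up_idx = de_idx[:n_up]
    down_idx = de_idx[n_up:]

    lfc = np.zeros(n)
    magnitudes = config.lfc.location * np.exp(
        config.lfc.scale * rng.standard_normal(n_de)
    )
    lfc[up_idx] = magnitudes[:n_up]
    lfc[down_idx] = -magnitudes[n_up:]

    # symmetric split of the effect keeps the feature's average level stable
    mu_wt = q * np.power(2.0, lfc / 2.0)
    mu_rnai = q * np.power(2.0, -lfc / 2.0)
    group_mu = np.column_stack([np.tile(mu_rnai[:, None], n_a), np.tile(mu_wt[:, None], n_b)])
    mu = group_mu * factors[None, :]
    alpha = np.tile(config.dispersion.alpha(q)[:, None], n_a + n_b)

    values = _nb_draw(rng, mu, alpha)
    feature_ids = [f"isogroup{i:05d}" for i in range(n)]
    counts = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"),
                          columns=sample_ids)

    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True
    direction = np.array(["none"] * n, dtype=object)
    direction[up_idx] = "up"
    direction[down_idx] = "down"
    truth = pd.DataFrame(
        {
            "is_de": is_de,
            "direction": direction,
            "true_log2fc": lfc,
            "baseline_mean": q,
        },
        index=counts.index,
    )
    size_factors = pd.Series(factors, index=sample_ids, name="size_factor")
    return SimulatedExperiment(counts=counts, samples=samples, truth=truth,
                               size_factors=size_factors)


def expand_to_contigs(
    experiment: SimulatedExperiment, mean_contigs: float = 1.6, seed: int = 0
) -> SimulatedExperiment:
    """Split each isogroup's counts over member contigs (multinomial per sample).

    Mirrors the assembly structure in which most isogroups hold one or two
    contigs; aggregation of the returned contig matrix recovers the isogroup
    matrix exactly.
    """
    rng = np.random.default_rng(seed)
    counts = experiment.counts
    n_contigs = 1 + rng.poisson(max(mean_contigs - 1.0, 0.0), size=counts.shape[0])
    contig_rows, contig_ids, map_pairs = [], [], []
    for (feature, row), k in zip(counts.iterrows(), n_contigs):
        weights = rng.dirichlet(np.ones(k))
        split = np.stack([rng.multinomial(v, weights) for v in row.to_numpy()], axis=1)
        for c in range(k):
            cid = f"contig_{feature}_{c}"
            contig_ids.append(cid)
            contig_rows.append(split[c])
            map_pairs.append((cid, feature))
    contig_counts = pd.DataFrame(
        np.asarray(contig_rows), index=pd.Index(contig_ids, name="contig_id"),
        columns=counts.columns,
    )
    contig_map = pd.Series(
        {cid: iso for cid, iso in map_pairs}, name="isogroup_id"
    ).rename_axis("contig_id")
    experiment.contig_counts = contig_counts
    experiment.contig_map = contig_map
    return experiment


def simulate_qpcr(
    n_genes: int,
    n_replicates: int = 10,
    cv: float = 0.44,
    fold_change: float = 2.0,
    seed: int = 0,
    reference_ct: float = 20.0,
) -> pd.DataFrame:
    """qPCR replicate table with a controlled between-plant coefficient of variation.

    Linearized expression values are drawn per genotype with SD = cv x group
    mean (RNAi mean 1, WT mean ``fold_change``; the default CV of 0.44 matches
    the between-plant variability typical of flag-leaf validation panels).
    Threshold cycles are back-computed so that the 2^-ddCt transform with a
    zero calibrator delta-Ct recovers the linearized values exactly.
    """
    if cv <= 0:
        raise ValueError("cv must be positive")
    if n_replicates < 2:
        raise ValueError("at least 2 replicates per genotype are required")
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_genes):
        gene = f"gene{g + 1:03d}"
        for genotype, mean in ((WT, fold_change), (RNAI, 1.0)):
            # clipped at a small positive floor (linearized expression cannot
            # be negative); clipping perturbs the group moments far less than
            # redrawing would, keeping empirical power close to the analytic
            # normal-theory value
            values = np.maximum(rng.normal(mean, cv * mean, size=n_replicates), 1e-6)
            for r, value in enumerate(values):
                rows.append(
                    {
                        "gene_id": gene,
                        "sample_id": f"{genotype}{r + 1}",
                        "genotype": genotype,
                        "ct_target": reference_ct - np.log2(value),
                        "ct_reference": reference_ct,
                        "expression": value,
                    }
                )
    return pd.DataFrame(rows)


def make_sentinel(length: int = 1138, seed: int = 0) -> str:
    """A random nucleotide sentinel emulating the construct-specific vector intron."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


def simulate_reads(
    n_reads: int,
    read_length: int = 85,
    frac_failed_tail: float = 0.2,
    sentinel_seq: str | None = None,
    n_sentinel_reads: int = 0,
    seed: int = 0,
    fail_position: int | None = None,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """FASTQ-style reads with known trimming, filtering and sentinel outcomes.

    A fraction of reads carries a failed-quality tail (``'B'`` symbols) from a
    random position (or ``fail_position`` when fixed); ``n_sentinel_reads``
    extra reads are exact substrings of the sentinel, half of them
    reverse-complemented.  Returns the reads and a bookkeeping table with the
    expected trimmed length and pass/fail status of every read.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if n_sentinel_reads and not sentinel_seq:
        raise ValueError("sentinel reads requested without a sentinel sequence")
    rng = np.random.default_rng(seed)
    good_q = "I" * read_length
    reads, rows = [], []
    n_failed = int(round(frac_failed_tail * n_reads))
    for i in range(n_reads):
        seq = "".join(rng.choice(list("ACGT"), size=read_length))
        if i < n_failed:
            pos = fail_position if fail_position is not None else int(rng.integers(0, read_length))
            quality = "I" * pos + "B" * (read_length - pos)
            trimmed_length = pos
        else:
            quality = good_q
            trimmed_length = read_length
        reads.append(ReadRecord(f"read{i + 1:06d}", seq, quality))
        rows.append(
            {
                "read_id": reads[-1].id,
                "is_sentinel": False,
                "failed_tail": i < n_failed,
                "expected_trimmed_length": trimmed_length,
            }
        )
    for i in range(n_sentinel_reads):
        span = min(read_length, len(sentinel_seq))
        start = int(rng.integers(0, len(sentinel_seq) - span + 1))
        seq = sentinel_seq[start : start + span]
        if i % 2 == 1:
            seq = str(Seq(seq).reverse_complement())
        reads.append(ReadRecord(f"sentinel{i + 1:04d}", seq, "I" * len(seq)))
        rows.append(
            {
                "read_id": reads[-1].id,
                "is_sentinel": True,
                "failed_tail": False,
                "expected_trimmed_length": len(seq),
            }
        )
    truth = pd.DataFrame(rows).set_index("read_id")
    return reads, truth
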
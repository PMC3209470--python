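"""Constrained label permutations and the empirical type-I-error estimate.

The calling pipeline's empirical false-positive behaviour is probed by
re-running it on *mixed* pseudo-groups: label assignments that place samples
of both genotypes in both groups, so that any real genotype effect is broken.
For the 4 RNAi + 3 WT design the shape used is (2 RNAi + 2 WT) vs
(2 RNAi + 1 WT), giving C(4,2) * C(3,2) = 18 distinct assignments from which
10 are drawn.  The mean number of significant features per permutation,
relative to the number of discoveries under the true labels, is the empirical
type-I error rate of the whole procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .counts import RNAI, WT, included_samples, make_sample_table
from .detest import ConsensusThresholds, run_de_tests

#: one pseudo-group of 2 RNAi + 2 WT against one of 2 RNAi + 1 WT
DEFAULT_SHAPE = ((2, 2), (2, 1))


@dataclass
class PermutationScheme:
    """A set of pseudo-group label assignments.

    Each assignment is a pair of sample-id tuples ``(group_1, group_2)``.
    """

    assignments: list[tuple[tuple[str, ...], tuple[str, ...]]]
    shape: tuple[tuple[int, int], tuple[int, int]] = DEFAULT_SHAPE
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.assignments)


def enumerate_constrained_permutations(
    samples: pd.DataFrame,
    shape: tuple[tuple[int, int], tuple[int, int]] = DEFAULT_SHAPE,
    deduplicate_symmetric: bool = False,
) -> PermutationScheme:
    """All distinct assignments of included samples matching *shape*.

    ``shape = ((r1, w1), (r2, w2))`` requests r1 RNAi + w1 WT in the first
    pseudo-group and the rest in the second; all included samples must be
    used.  The enumeration size is ``C(n_rnai, r1) * C(n_wt, w1)``; for a
    symmetric shape the optional deduplication collapses pairs that differ
    only by swapping the two pseudo-group labels.
    """
    rnai = included_samples(samples, RNAI)
    wt = included_samples(samples, WT)
    (r1, w1), (r2, w2) = shape
    if min(r1, w1, r2, w2) < 0 or r1 + w1 == 0 or r2 + w2 == 0:
        raise ValueError(f"shape {shape} infeasible: group sizes must be positive")
    if r1 + r2 != len(rnai) or w1 + w2 != len(wt):
        raise ValueError(
            f"shape {shape} infeasible for {len(rnai)} RNAi + {len(wt)} WT samples"
        )
    assignments = []
    for r_pick in combinations(rnai, r1):
        for w_pick in combinations(wt, w1):
            group1 = tuple(r_pick) + tuple(w_pick)
            group2 = tuple(s for s in rnai if s not in r_pick) + tuple(
                s for s in wt if s not in w_pick
            )
            assignments.append((group1, group2))
    assert len(assignments) == comb(len(rnai), r1) * comb(len(wt), w1)
    if deduplicate_symmetric and (r1, w1) == (r2, w2):
        seen, unique = set(), []
        for g1, g2 in assignments:
            key = frozenset((frozenset(g1), frozenset(g2)))
            if key not in seen:
                seen.add(key)
                unique.append((g1, g2))
        assignments = unique
    return PermutationScheme(assignments=assignments, shape=shape)


def sample_permutations(scheme: PermutationScheme, n: int, seed: int) -> PermutationScheme:
    """Draw *n* distinct assignments without replacement, reproducibly."""
    if n > len(scheme):
        raise ValueError(f"requested {n} permutations but only {len(scheme)} exist")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(scheme), size=n, replace=False)
    return PermutationScheme(
        assignments=[scheme.assignments[i] for i in sorted(idx)],
        shape=scheme.shape,
        seed=seed,
    )


@dataclass
class PermutationReport:
    """Significant-feature counts per permutation and their summaries."""

    counts: pd.DataFrame  # columns: n_pooled, n_local, n_intersection
    thresholds: ConsensusThresholds
    with_mww: bool = False

    def mean(self, column: str = "n_intersection") -> float:
        return float(self.counts[column].mean())

    def se(self, column: str = "n_intersection") -> float | None:
        if len(self.counts) < 2:
            return None
        return float(self.counts[column].std(ddof=1) / np.sqrt(len(self.counts)))

    def summary(self) -> dict:
        out = {"n_permutations": int(len(self.counts))}
        for column in self.counts.columns:
            out[f"mean_{column}"] = self.mean(column)
            out[f"se_{column}"] = self.se(column)
        return out


def _pseudo_sample_table(group1, group2) -> pd.DataFrame:
    # arbitrary but fixed genotype relabelling of the two pseudo-groups
    ids = list(group1) + list(group2)
    labels = [RNAI] * len(group1) + [WT] * len(group2)
    return make_sample_table(ids, labels)


def run_permutation_null(
    counts: pd.DataFrame,
    scheme: PermutationScheme,
    thresholds: ConsensusThresholds = ConsensusThresholds(),
    with_mww: bool = False,
    mww_mode: str = "normal",
) -> PermutationReport:
    """Re-run normalization + NB testing for every pseudo-group assignment.

    Per assignment the report records the number of features significant in
    the pooled-dispersion test, in the local-variance test (BH-adjusted,
    inclusive thresholds), and in their intersection.  The MWW stage is
    excluded by default (it was layered on top of the permutation analysis,
    not inside it); ``with_mww`` adds it to the intersection.
    """
    rows = []
    for group1, group2 in scheme.assignments:
        pseudo = _pseudo_sample_table(group1, group2)
        result = run_de_tests(
            counts[list(group1) + list(group2)],
            pseudo,
            thresholds=thresholds,
            mww_mode=mww_mode,
            run_mww=with_mww,
        )
        sig_pooled = result["q_pooled"] <= thresholds.q_pooled_max
        sig_local = result["q_local"] <= thresholds.q_local_max
        intersection = sig_pooled & sig_local
        if with_mww:
            intersection &= result["p_mww"] <= thresholds.p_mww_max
        rows.append(
            {
                "n_pooled": int(sig_pooled.sum()),
                "n_local": int(sig_local.sum()),
                "n_intersection": int(intersection.sum()),
            }
        )
    frame = pd.DataFrame(rows, index=pd.RangeIndex(len(rows), name="permutation"))
    return PermutationReport(counts=frame, thresholds=thresholds, with_mww=with_mww)


def empirical_rate(mean_null_count: float, n_discoveries: int) -> float:
    """Empirical type-I error: 100 * mean null count / discoveries, one decimal."""
    if n_discoveries <= 0:
        raise ValueError("the reference discovery count must be positive")
    return round(100.0 * mean_null_count / n_discoveries, 1)
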
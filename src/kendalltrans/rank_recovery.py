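"""Inverting pair-state vectors back into rankings via Copeland scoring.

Every object collects +1 for each pair ``(i, .)`` it ascends in and -1 for
each it descends in; ordering objects by decreasing score recovers the
original ranking exactly for any valid transform (rank 1 = smallest value,
which wins all its ascending comparisons).  The same scoring doubles as a
heuristic for invalid inputs — a three-cycle, for instance, collapses to
all-tied ranks — and extends naturally to fuzzy per-state probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .pairspace import ASC, DESC, KendallVector, PairIndex, ValidityReport, validate_kendall_vector

__all__ = [
    "RankingResult",
    "FuzzyVotes",
    "copeland_scores",
    "invert_transform",
    "aggregate_fuzzy_votes",
]


@dataclass(frozen=True)
class RankingResult:
    """Recovered ranking: per-object Copeland scores and min-ranks.

    Ranks use the competition (min-rank) convention; equal scores share the
    smallest rank of their block.  Rank 1 corresponds to the smallest
    recovered value.
    """

    scores: np.ndarray
    ranks: np.ndarray
    n: int
    validity: ValidityReport | None = field(default=None, compare=False)


@dataclass(eq=False)
class FuzzyVotes:
    """Per-pair state probabilities, e.g. averaged classifier votes.

    For each ordered pair the three probabilities may sum to less than one;
    the residual mass is treated as missing and contributes nothing.
    """

    pair_index: PairIndex
    p_asc: np.ndarray
    p_desc: np.ndarray
    p_tie: np.ndarray

    def __post_init__(self) -> None:
        m = self.pair_index.m
        self.p_asc = np.broadcast_to(np.asarray(self.p_asc, float), (m,)).copy()
        self.p_desc = np.broadcast_to(np.asarray(self.p_desc, float), (m,)).copy()
        self.p_tie = np.broadcast_to(np.asarray(self.p_tie, float), (m,)).copy()
        for p in (self.p_asc, self.p_desc, self.p_tie):
            if np.any((p < 0.0) | (p > 1.0)):
                raise ValueError("state probabilities must lie in [0, 1]")
        total = self.p_asc + self.p_desc + self.p_tie
        if np.any(total > 1.0 + 1e-9):
            raise ValueError("state probabilities must sum to at most 1 per pair")


def copeland_scores(k: KendallVector) -> np.ndarray:
    """Copeland score of each object: ascending wins minus descending losses.

    For a valid transform of a tie-free vector the scores are exactly
    ``n-1, n-3, ..., -(n-1)`` in some order; their sum is zero for any
    mirror-consistent input.
    """
    idx = k.pair_index
    scores = np.zeros(idx.n, dtype=float)
    np.add.at(scores, idx.a[k.states == ASC], 1.0)
    np.subtract.at(scores, idx.a[k.states == DESC], 1.0)
    return scores


def _ranks_from_scores(scores: np.ndarray) -> np.ndarray:
    return rankdata(-scores, method="min").astype(int)


def invert_transform(k: KendallVector) -> RankingResult:
    """Recover the ranking encoded by a pair-state vector.

    Exact inverse on any genuine transform (including tie structure); on
    invalid input the Copeland heuristic is applied and the attached
    validity report flags the defect rather than raising.
    """
    scores = copeland_scores(k)
    return RankingResult(
        scores=scores,
        ranks=_ranks_from_scores(scores),
        n=k.pair_index.n,
        validity=validate_kendall_vector(k),
    )


def aggregate_fuzzy_votes(v: FuzzyVotes) -> RankingResult:
    """Rank objects from probabilistic pair states.

    Each object's score sums ``p_asc - p_desc`` over its outgoing pairs;
    degenerate 0/1 votes reduce exactly to :func:`invert_transform`.
    """
    idx = v.pair_index
    scores = np.zeros(idx.n, dtype=float)
    np.add.at(scores, idx.a, v.p_asc - v.p_desc)
    return RankingResult(scores=scores, ranks=_ranks_from_scores(scores), n=idx.n)
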
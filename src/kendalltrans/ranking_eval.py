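"""Mutual-information feature rankings and agreement with a reference set.

Agreement between a scored ranking and a golden-standard feature set G is
the maximum Jaccard index over every threshold cut of the scores,

    Jmax(G, s) = max_t J(G, {x : s(x) > t}),

so tied scores cross each threshold jointly (the cut is a strict
inequality) and the measure is invariant to any strictly increasing
rescaling of the scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .infotheory import mutual_information
from .pairspace import TransformedFrame

__all__ = ["ScoreTable", "mi_ranking", "jaccard", "jmax"]


@dataclass(eq=False)
class ScoreTable:
    """Feature scores (greater = more important) with an optional golden set."""

    scores: pd.Series
    golden: frozenset | None = None

    def __post_init__(self) -> None:
        self.scores = pd.Series(self.scores, dtype=float)
        if self.scores.index.duplicated().any():
            raise ValueError("feature names must be unique")
        if self.golden is not None:
            self.golden = frozenset(self.golden)
            extra = self.golden - set(self.scores.index)
            if extra:
                raise ValueError(f"golden features not in universe: {sorted(extra)}")

    @property
    def universe(self) -> frozenset:
        return frozenset(self.scores.index)

    def ranking(self) -> pd.Series:
        return self.scores.sort_values(ascending=False, kind="mergesort")


def mi_ranking(system, decision: str, golden=None) -> ScoreTable:
    """Score every predictor by its mutual information with the decision.

    ``system`` is either a :class:`TransformedFrame` (pairwise states are
    compared, within-batch pairs only on merged frames) or any table of
    categorical columns.  A constant decision yields all-zero scores with a
    warning.
    """
    if isinstance(system, TransformedFrame):
        columns = {name: system.features[name] for name in system.feature_names}
    else:
        df = pd.DataFrame(system)
        columns = {str(c): df[c] for c in df.columns}
    if decision not in columns:
        raise KeyError(f"decision feature {decision!r} not present")
    dec = columns.pop(decision)
    dec_vals = dec.states if hasattr(dec, "states") else np.asarray(dec)
    if np.unique(dec_vals).size <= 1:
        warnings.warn("decision feature is constant; all scores are zero",
                      UserWarning, stacklevel=2)
    scores = pd.Series(
        {name: mutual_information(col, dec) for name, col in columns.items()}
    )
    return ScoreTable(scores=scores, golden=golden)


def jaccard(A, B) -> float:
    """Jaccard set similarity |A & B| / |A | B|; both sets empty gives 1."""
    A, B = set(A), set(B)
    union = A | B
    if not union:
        return 1.0
    return len(A & B) / len(union)


def jmax(G, s) -> float:
    """Best Jaccard agreement of the golden set G over all score cut-offs.

    The sweep visits every distinct score value (features with equal scores
    enter together) plus the empty cut, which equals brute-force
    maximisation over all real thresholds.
    """
    if isinstance(s, ScoreTable):
        s = s.scores
    s = pd.Series(s, dtype=float)
    if s.empty:
        raise ValueError("empty feature universe")
    G = set(G)
    extra = G - set(s.index)
    if extra:
        raise ValueError(f"golden features not in universe: {sorted(extra)}")
    best = jaccard(G, set())
    for v in np.unique(s.to_numpy())[::-1]:
        selected = set(s.index[s.to_numpy() >= v])
        best = max(best, jaccard(G, selected))
    return best
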
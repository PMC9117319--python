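"""Plug-in information theory over categorical (incl. Kendall-transformed) data.

All quantities are maximum-likelihood ("plug-in") estimates in nats, so the
closed-form statements about transformed vectors hold verbatim: a tie-free
transform has entropy exactly log 2, the mutual information between two
tie-free transforms is an exact function of their Kendall tau,

    I_K(tau) = tau * log sqrt((1+tau)/(1-tau)) + log sqrt(1-tau^2),

and against a binary feature it is an exact function of the AUROC A with
class sizes a and b:

    I_K(A; a, b) = 2ab/(n(n-1)) * (A log(A/(1-A)) + log(2-2A)).

Missing pair states are handled by listwise deletion over the variables
entering each score (complete-pair or complete-triple analysis), which is
what makes scores on merged multi-batch frames depend only on within-batch
comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy

from .pairspace import ASC, DESC, MISSING, KendallVector, build_pair_index, kendall_transform

__all__ = [
    "ContingencyTable",
    "AurocResult",
    "contingency_table",
    "ml_entropy",
    "mutual_information",
    "conditional_mi",
    "joint_mi",
    "interaction_information",
    "kendall_tau",
    "mi_from_tau",
    "mi_from_rho",
    "auroc",
    "mi_from_auroc",
    "quantise",
]

LOG2 = float(np.log(2.0))


@dataclass(frozen=True)
class ContingencyTable:
    """Joint counts of one to three categorical variables."""

    counts: np.ndarray
    labels: tuple

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _codes(seq) -> tuple[np.ndarray, np.ndarray]:
    """Integer category codes plus missingness mask for any categorical input."""
    if isinstance(seq, KendallVector):
        states = seq.states.astype(np.int64)
        return states, states == MISSING
    codes, _ = pd.factorize(np.asarray(seq), use_na_sentinel=True)
    return codes.astype(np.int64), codes < 0


def _complete_cases(*seqs) -> list[np.ndarray]:
    coded = [_codes(s) for s in seqs]
    lengths = {c.size for c, _ in coded}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths {sorted(lengths)}")
    keep = ~np.logical_or.reduce([m for _, m in coded])
    if not keep.any():
        raise ValueError("no complete observations left after missing-data deletion")
    return [c[keep] for c, _ in coded]


def _joint_codes(*cols: np.ndarray) -> np.ndarray:
    out = cols[0]
    for c in cols[1:]:
        out = out * (int(c.max()) + 1) + c
    return out


def _entropy_codes(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    return float(_scipy_entropy(counts))


def contingency_table(*seqs) -> ContingencyTable:
    """Joint count table of 1-3 categorical sequences (complete cases only)."""
    if not 1 <= len(seqs) <= 3:
        raise ValueError("contingency_table supports 1 to 3 variables")
    coded = _complete_cases(*seqs)
    factored = [np.unique(c, return_inverse=True) for c in coded]
    shape = tuple(len(u) for u, _ in factored)
    counts = np.zeros(shape, dtype=np.int64)
    np.add.at(counts, tuple(inv for _, inv in factored), 1)
    return ContingencyTable(counts=counts, labels=tuple(u for u, _ in factored))


def ml_entropy(table) -> float:
    """Plug-in entropy, -sum p log p in nats, of a count table or marginal."""
    if isinstance(table, ContingencyTable):
        counts = table.counts
    else:
        counts = np.asarray(table, dtype=float)
    counts = counts.ravel()
    if counts.size == 0 or counts.sum() <= 0:
        raise ValueError("entropy of an empty table is undefined")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    return float(_scipy_entropy(counts))


def mutual_information(k1, k2) -> float:
    """Plug-in mutual information I(X;Y) in nats, complete-pair deletion."""
    c1, c2 = _complete_cases(k1, k2)
    mi = _entropy_codes(c1) + _entropy_codes(c2) - _entropy_codes(_joint_codes(c1, c2))
    return max(mi, 0.0)


def conditional_mi(k1, k2, k3) -> float:
    """Conditional mutual information I(X;Y|Z) in nats, complete-triple deletion."""
    c1, c2, c3 = _complete_cases(k1, k2, k3)
    cmi = (
        _entropy_codes(_joint_codes(c1, c3))
        + _entropy_codes(_joint_codes(c2, c3))
        - _entropy_codes(_joint_codes(c1, c2, c3))
        - _entropy_codes(c3)
    )
    return max(cmi, 0.0)


def joint_mi(k1, k2, k3) -> float:
    """Joint mutual information I(X,Y;Z): the pair (X,Y) as one variable."""
    c1, c2, c3 = _complete_cases(k1, k2, k3)
    c12 = _joint_codes(c1, c2)
    mi = _entropy_codes(c12) + _entropy_codes(c3) - _entropy_codes(_joint_codes(c12, c3))
    return max(mi, 0.0)


def interaction_information(k1, k2, k3) -> float:
    """Three-way interaction information I(X;Y) - I(X;Y|Z), signed, in nats.

    Negative values indicate synergy: conditioning on Z reveals dependence
    between X and Y beyond their marginal association.  For marginally
    independent X, Y this is approximately -I(X;Y|Z).
    """
    c1, c2, c3 = _complete_cases(k1, k2, k3)
    h1 = _entropy_codes(c1)
    h2 = _entropy_codes(c2)
    h3 = _entropy_codes(c3)
    h12 = _entropy_codes(_joint_codes(c1, c2))
    h13 = _entropy_codes(_joint_codes(c1, c3))
    h23 = _entropy_codes(_joint_codes(c2, c3))
    h123 = _entropy_codes(_joint_codes(c1, c2, c3))
    mi12 = h1 + h2 - h12
    cmi12_3 = h13 + h23 - h123 - h3
    return mi12 - cmi12_3


def kendall_tau(x, y) -> float:
    """Kendall rank correlation via the shared pair enumeration.

    tau = (concordant - discordant) / m over all m = n(n-1) ordered pairs;
    pairs tied (or missing) in either feature count as neither, so for
    tie-free data this is the classical coefficient.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    idx = build_pair_index(x.size)
    kx = kendall_transform(x, idx).states
    ky = kendall_transform(y, idx).states
    conc = int(np.sum(((kx == ASC) & (ky == ASC)) | ((kx == DESC) & (ky == DESC))))
    disc = int(np.sum(((kx == ASC) & (ky == DESC)) | ((kx == DESC) & (ky == ASC))))
    return (conc - disc) / idx.m


def mi_from_tau(tau: float) -> float:
    """Exact MI (nats) between two tie-free transforms with Kendall tau.

    Even in tau, strictly increasing for tau > 0, and capped at log 2 (the
    entropy of a tie-free transform), which it attains in the limit
    |tau| -> 1.
    """
    tau = float(tau)
    if not -1.0 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [-1, 1], got {tau}")
    if abs(tau) == 1.0:
        return LOG2
    if tau == 0.0:
        return 0.0
    return 0.5 * tau * np.log((1.0 + tau) / (1.0 - tau)) + 0.5 * np.log(1.0 - tau * tau)


def mi_from_rho(rho: float) -> float:
    """Gaussian mutual information -log sqrt(1 - rho^2) in nats.

    The bivariate-normal closed form; unlike the Kendall-transform MI it
    diverges as |rho| -> 1.
    """
    rho = float(rho)
    if not -1.0 < rho < 1.0:
        raise ValueError(f"rho must lie strictly inside (-1, 1), got {rho}")
    return -0.5 * float(np.log1p(-rho * rho))


@dataclass(frozen=True)
class AurocResult:
    """AUROC of a tie-free score against a binary class, with the U statistic."""

    auroc: float
    a: int
    b: int
    u: float


def auroc(x, y) -> AurocResult:
    """AUROC A of tie-free scores ``x`` against binary labels ``y``.

    A is the fraction of the ``a * b`` cross-class pairs in which the
    positive-class (larger label) value exceeds the negative-class value;
    the Mann-Whitney statistic is recovered as U = ab(1 - A).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.unique(x).size != x.size:
        raise ValueError("x must be tie-free for the AUROC pair count")
    levels = np.unique(y)
    if levels.size != 2:
        raise ValueError(f"y must have exactly two classes, found {levels.size}")
    pos = x[y == levels[1]]
    neg = x[y == levels[0]]
    a, b = pos.size, neg.size
    A = float(np.mean(pos[:, None] > neg[None, :]))
    return AurocResult(auroc=A, a=a, b=b, u=a * b * (1.0 - A))


def mi_from_auroc(A: float, a: int, b: int) -> float:
    """Exact MI (nats) between a tie-free transform and a binary one.

    Closed form in the AUROC A and the class sizes a, b (n = a + b);
    endpoints A in {0, 1} are evaluated as continuous limits,
    2ab/(n(n-1)) * log 2.
    """
    A = float(A)
    if not 0.0 <= A <= 1.0:
        raise ValueError(f"AUROC must lie in [0, 1], got {A}")
    if a < 1 or b < 1:
        raise ValueError("both class sizes must be positive")
    n = a + b
    scale = 2.0 * a * b / (n * (n - 1))
    if A in (0.0, 1.0):
        return scale * LOG2
    return scale * (A * np.log(A / (1.0 - A)) + np.log(2.0 - 2.0 * A))


def quantise(x, k: int, method: str = "equal-width") -> np.ndarray:
    """Bin a numeric feature into ``k`` interval labels (1-based ints).

    equal-width splits [min, max] into k equal intervals (last one
    right-closed); equal-frequency cuts at the i/k sample quantiles with
    linear interpolation, collapsing bins when ties make edges coincide.
    A constant input yields a single category with a warning.
    """
    x = np.asarray(x, dtype=float)
    if k < 2:
        raise ValueError("need at least 2 bins")
    lo, hi = np.min(x), np.max(x)
    if lo == hi:
        warnings.warn("constant input: quantisation yields a single category",
                      UserWarning, stacklevel=2)
        return np.ones(x.size, dtype=int)
    if method == "equal-width":
        edges = np.linspace(lo, hi, k + 1)
        return np.digitize(x, edges[1:-1], right=False) + 1
    if method == "equal-frequency":
        qs = np.quantile(x, np.linspace(0.0, 1.0, k + 1))
        edges = np.unique(qs)
        return np.digitize(x, edges[1:-1], right=True) + 1
    raise ValueError(f"unknown binning method {method!r}")
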
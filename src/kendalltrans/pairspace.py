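"""Pairwise order-relation (Kendall) encoding of ordinal features.

The Kendall transformation maps an ``n``-vector over a totally ordered set
to the ``m = n(n-1)`` outcomes of all ordered pairwise comparisons: for the
ordered pair ``(a, b)`` of distinct observation indices the encoded symbol
records whether ``x_a < x_b`` (ascending), ``x_a > x_b`` (descending) or
``x_a = x_b`` (tie).  The result is purely categorical yet preserves the
complete ranking of the input, so any strictly increasing distortion of the
raw values leaves the encoding bit-identical.

Pairs are enumerated in a fixed, column-wise traversal of the ``n x n``
comparison matrix with the diagonal skipped; the pair at position ``j`` is
``(a_j, b_j) = (row, column)``.  This order is frozen because it defines the
on-disk layout of transformed frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ASC",
    "DESC",
    "TIE",
    "MISSING",
    "PairIndex",
    "KendallVector",
    "TransformedFrame",
    "ValidityReport",
    "build_pair_index",
    "pair_position",
    "kendall_transform",
    "transform_system",
    "expand_categorical",
    "jitter_ties",
    "validate_kendall_vector",
]

# state codes of a transformed pair; MISSING doubles as the sentinel used
# when a comparison is undefined (missing input, cross-batch pair, policy)
MISSING: int = 0
ASC: int = 1
DESC: int = 2
TIE: int = 3

#: mirror image of each state under reversal of the pair direction
_MIRROR = np.array([MISSING, DESC, ASC, TIE], dtype=np.int8)

STATE_TO_SYMBOL = {ASC: "<", DESC: ">", TIE: "=", MISSING: ""}
UNICODE_STATE_TO_SYMBOL = {ASC: "△", DESC: "▽", TIE: "□", MISSING: ""}
SYMBOL_TO_STATE = {
    "<": ASC,
    ">": DESC,
    "=": TIE,
    "": MISSING,
    "△": ASC,
    "▽": DESC,
    "□": TIE,
}


def pair_position(a: np.ndarray | int, b: np.ndarray | int, n: int) -> np.ndarray | int:
    """Position of the ordered pair ``(a, b)`` (0-based) in the canonical order.

    The canonical order scans the ``n x n`` comparison matrix column by
    column, skipping the diagonal, so column ``b`` contributes ``n - 1``
    consecutive positions.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if np.any(a == b):
        raise ValueError("pair indices must be distinct")
    pos = b * (n - 1) + a - (a > b)
    return pos if pos.ndim else int(pos)


@dataclass(frozen=True)
class PairIndex:
    """Fixed enumeration of all ``m = n(n-1)`` ordered pairs of observations.

    Attributes
    ----------
    n : int
        Number of observations.
    a, b : ndarray of int
        0-based observation indices of each ordered pair; ``(a[j], b[j])``
        is the *j*-th comparison ``x[a[j]]`` versus ``x[b[j]]``.
    swap : ndarray of int
        Involution mapping each pair to its reverse: ``(a[swap[j]],
        b[swap[j]]) == (b[j], a[j])``.
    """

    n: int
    a: np.ndarray = field(repr=False)
    b: np.ndarray = field(repr=False)
    swap: np.ndarray = field(repr=False)

    @property
    def m(self) -> int:
        return self.n * (self.n - 1)

    def pairs_1based(self) -> tuple[np.ndarray, np.ndarray]:
        """The pair indices in the 1-based convention used by file formats."""
        return self.a + 1, self.b + 1


def build_pair_index(n: int) -> PairIndex:
    """Enumerate all ordered pairs of ``n`` observations in canonical order.

    Raises
    ------
    ValueError
        If ``n < 2`` (no pair can be formed).
    """
    if n < 2:
        raise ValueError(f"need at least 2 observations to form pairs, got n={n}")
    rows = np.tile(np.arange(n), n)
    cols = np.repeat(np.arange(n), n)
    keep = rows != cols
    a = rows[keep]
    b = cols[keep]
    swap = pair_position(b, a, n)
    return PairIndex(n=n, a=a, b=b, swap=swap)


@dataclass(eq=False)
class KendallVector:
    """A Kendall-transformed feature: ``m`` categorical pair states."""

    states: np.ndarray
    pair_index: PairIndex
    name: str | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (self.pair_index.m,):
            raise ValueError(
                f"state vector has length {self.states.size}, "
                f"pair index expects m={self.pair_index.m}"
            )

    def __len__(self) -> int:
        return self.states.size

    @property
    def n_missing(self) -> int:
        return int(np.sum(self.states == MISSING))

    def symbols(self, unicode: bool = False) -> list[str]:
        table = UNICODE_STATE_TO_SYMBOL if unicode else STATE_TO_SYMBOL
        return [table[int(s)] for s in self.states]


@dataclass(eq=False)
class TransformedFrame:
    """A set of Kendall-transformed features over one shared pair index.

    ``batch`` optionally tags every observation with the measurement batch
    it came from; merged frames keep it so that inversion can be performed
    per batch.
    """

    pair_index: PairIndex
    features: dict[str, KendallVector]
    batch: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, kv in self.features.items():
            if kv.pair_index is not self.pair_index and kv.pair_index.n != self.pair_index.n:
                raise ValueError(f"feature {name!r} uses a different pair index")
        if self.batch is not None:
            self.batch = np.asarray(self.batch, dtype=object)
            if self.batch.shape != (self.pair_index.n,):
                raise ValueError("batch labels must be given per observation")

    @property
    def n(self) -> int:
        return self.pair_index.n

    @property
    def m(self) -> int:
        return self.pair_index.m

    @property
    def feature_names(self) -> list[str]:
        return list(self.features)

    def __getitem__(self, name: str) -> KendallVector:
        return self.features[name]


def _as_ordinal(x) -> tuple[np.ndarray, np.ndarray]:
    """Coerce input to a comparable value array plus a missingness mask.

    Accepts numeric sequences (NaN = missing), pandas Series (NA-aware) and
    *ordered* pandas Categoricals (codes are used; -1 = missing).  Unordered
    categoricals are rejected: they carry no order to encode.
    """
    if isinstance(x, pd.Series):
        if isinstance(x.dtype, pd.CategoricalDtype):
            x = x.array
        else:
            miss = x.isna().to_numpy()
            return x.to_numpy(), miss
    if isinstance(x, pd.Categorical):
        if not x.ordered:
            raise TypeError(
                "unordered categorical input has no pairwise order; "
                "expand it into indicator features with expand_categorical()"
            )
        codes = np.asarray(x.codes, dtype=np.int64)
        return codes, codes == -1
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise ValueError("expected a one-dimensional sequence of values")
    if arr.dtype == object:
        try:
            arr = arr.astype(float)
        except (TypeError, ValueError):
            pass
    miss = np.asarray(pd.isna(arr))
    return arr, miss


def kendall_transform(
    x,
    idx: PairIndex | None = None,
    tie_policy: str = "keep",
    name: str | None = None,
) -> KendallVector:
    """Kendall-transform one ordinal feature into its pair-state vector.

    Parameters
    ----------
    x : sequence
        Values over a totally ordered set; NaN/NA marks a missing value,
        whose comparisons all become MISSING.
    idx : PairIndex, optional
        Shared pair enumeration; built from ``len(x)`` when omitted.
    tie_policy : {"keep", "missing"}
        ``"keep"`` encodes exactly equal values as the tie state, the
        semantics appropriate for genuine ties.  ``"missing"`` marks them
        missing instead, appropriate when ties are resolution artefacts.
    """
    if tie_policy not in ("keep", "missing"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    vals, miss = _as_ordinal(x)
    n = vals.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if idx is None:
        idx = build_pair_index(n)
    elif idx.n != n:
        raise ValueError(f"feature has {n} observations but pair index expects {idx.n}")

    xa = vals[idx.a]
    xb = vals[idx.b]
    fill = TIE if tie_policy == "keep" else MISSING
    states = np.full(idx.m, fill, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        try:
            states[np.less(xa, xb)] = ASC
            states[np.greater(xa, xb)] = DESC
        except TypeError as exc:
            raise TypeError(f"values are not totally comparable: {exc}") from exc
    pair_missing = miss[idx.a] | miss[idx.b]
    if pair_missing.any():
        states[pair_missing] = MISSING
    return KendallVector(states=states, pair_index=idx, name=name)


def transform_system(
    data, tie_policy: str = "keep", batch_labels=None
) -> TransformedFrame:
    """Kendall-transform every column of a table over one shared pair index.

    All columns must be totally ordered (numeric, ordinal or binary);
    unordered categorical columns must be expanded into indicators first.
    """
    df = pd.DataFrame(data)
    if df.columns.duplicated().any():
        raise ValueError("feature names must be unique")
    if len(df) < 2:
        raise ValueError("need at least 2 observations")
    idx = build_pair_index(len(df))
    features: dict[str, KendallVector] = {}
    for col in df.columns:
        series = df[col]
        if series.dtype == object:
            try:
                series = series.astype(float)
            except (TypeError, ValueError) as exc:
                raise TypeError(
                    f"column {col!r} is not totally ordered; expand it with "
                    "expand_categorical() before transforming"
                ) from exc
        features[str(col)] = kendall_transform(
            series, idx, tie_policy=tie_policy, name=str(col)
        )
    return TransformedFrame(pair_index=idx, features=features, batch=batch_labels)


def expand_categorical(x, name: str = "x") -> pd.DataFrame:
    """Expand an unordered categorical into binary category-vs-other indicators.

    Each observed level yields one 0/1 column named ``<name>=<level>``;
    missing inputs propagate as NaN in every indicator.
    """
    series = pd.Series(x)
    levels = series.dropna().unique()
    if len(levels) == 0:
        raise ValueError("no observed levels in categorical input")
    if len(levels) == 1:
        warnings.warn(
            f"categorical {name!r} has a single level; its indicator is constant",
            UserWarning,
            stacklevel=2,
        )
    out = {}
    na = series.isna().to_numpy()
    for level in levels:
        ind = (series == level).to_numpy().astype(float)
        ind[na] = np.nan
        out[f"{name}={level}"] = ind
    return pd.DataFrame(out)


def jitter_ties(x, seed=None) -> np.ndarray:
    """Break resolution-artefact ties with sub-gap uniform jitter.

    The noise amplitude is a quarter of the smallest gap between distinct
    values, so every non-tied order relation is preserved exactly while
    tied values separate.  Deterministic for a fixed seed.
    """
    arr = np.asarray(x, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("jitter_ties requires fully observed numeric input")
    uniq = np.unique(arr)
    if uniq.size < 2:
        raise ValueError("constant vector: no gap to scale jitter by")
    amp = np.min(np.diff(uniq)) / 4.0
    rng = np.random.default_rng(seed)
    out = arr + rng.uniform(0.0, amp, size=arr.size)
    while np.unique(out).size < out.size:  # pragma: no cover - measure-zero event
        out = arr + rng.uniform(0.0, amp, size=arr.size)
    return out


@dataclass(frozen=True)
class ValidityReport:
    """Diagnostics of a pair-state vector against the image of the transform."""

    mirror_consistent: bool
    acyclic: bool
    n_missing: int

    @property
    def is_valid(self) -> bool:
        return self.mirror_consistent and self.acyclic


def validate_kendall_vector(k: KendallVector) -> ValidityReport:
    """Check whether a pair-state vector can arise from a real transform.

    A genuine transform is mirror-antisymmetric under pair reversal and its
    strict-order digraph (an edge ``a -> b`` whenever ``x_a < x_b``) is
    acyclic.  Vectors assembled from predictions or edits can violate both.
    """
    idx = k.pair_index
    mirrored = _MIRROR[k.states[idx.swap]]
    mirror_ok = bool(np.array_equal(mirrored, k.states))

    ts: TopologicalSorter = TopologicalSorter()
    for node in range(idx.n):
        ts.add(node)
    asc = k.states == ASC
    desc = k.states == DESC
    # edge u -> v encodes x_u < x_v
    for u, v in zip(idx.a[asc], idx.b[asc]):
        ts.add(int(v), int(u))
    for u, v in zip(idx.b[desc], idx.a[desc]):
        ts.add(int(v), int(u))
    try:
        ts.prepare()
        acyclic = True
    except CycleError:
        acyclic = False
    return ValidityReport(
        mirror_consistent=mirror_ok, acyclic=acyclic, n_missing=k.n_missing
    )
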
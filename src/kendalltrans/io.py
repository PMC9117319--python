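"""Reading and writing transformed frames as long CSV/TSV files.

The on-disk layout is one row per ordered pair in canonical order, with
1-based observation indices::

    a,b,<feature1>,<feature2>,...
    2,1,<,>,...

States are encoded ``<`` (ascending), ``>`` (descending), ``=`` (tie) and
an empty field for missing; ``--unicode`` style output uses the glyphs
``△ ▽ □`` instead.  Batched frames add ``batch_a,batch_b`` columns carrying
the batch label of each side of the pair.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .pairspace import (
    STATE_TO_SYMBOL,
    SYMBOL_TO_STATE,
    UNICODE_STATE_TO_SYMBOL,
    KendallVector,
    TransformedFrame,
    build_pair_index,
    pair_position,
)

__all__ = ["write_transformed_csv", "read_transformed_csv", "frame_to_dataframe"]

logger = logging.getLogger("kendalltrans")

_RESERVED = {"a", "b", "batch_a", "batch_b"}


def frame_to_dataframe(frame: TransformedFrame, unicode: bool = False) -> pd.DataFrame:
    """Render a transformed frame as the long table written to disk."""
    idx = frame.pair_index
    a1, b1 = idx.pairs_1based()
    data: dict[str, object] = {"a": a1, "b": b1}
    if frame.batch is not None:
        data["batch_a"] = frame.batch[idx.a]
        data["batch_b"] = frame.batch[idx.b]
    table = UNICODE_STATE_TO_SYMBOL if unicode else STATE_TO_SYMBOL
    lut = np.array([table[s] for s in range(4)], dtype=object)
    for name, kv in frame.features.items():
        if name in _RESERVED:
            raise ValueError(f"feature name {name!r} collides with an index column")
        data[name] = lut[kv.states]
    return pd.DataFrame(data)


def write_transformed_csv(
    frame: TransformedFrame, destination, unicode: bool = False, sep: str = ","
) -> None:
    """Write a transformed frame to ``destination`` in the long layout."""
    df = frame_to_dataframe(frame, unicode=unicode)
    try:
        df.to_csv(destination, index=False, sep=sep)
    except OSError as exc:
        raise OSError(f"cannot write transformed frame to {destination}: {exc}") from exc


def read_transformed_csv(source, sep: str = ",") -> TransformedFrame:
    """Read a long transformed CSV back into a :class:`TransformedFrame`.

    The number of observations is inferred from the largest index and
    validated against the row count ``n(n-1)``; rows in non-canonical order
    are re-sorted (and logged), unknown state symbols are format errors.
    """
    try:
        df = pd.read_csv(source, sep=sep, keep_default_na=False, dtype=str)
    except OSError as exc:
        raise OSError(f"cannot read transformed frame from {source}: {exc}") from exc
    for col in ("a", "b"):
        if col not in df.columns:
            raise ValueError(f"transformed file lacks required column {col!r}")
    a = df["a"].astype(int).to_numpy() - 1
    b = df["b"].astype(int).to_numpy() - 1
    n = int(max(a.max(), b.max())) + 1
    if len(df) != n * (n - 1):
        raise ValueError(
            f"expected n(n-1) = {n * (n - 1)} pair rows for n = {n}, found {len(df)}"
        )
    pos = pair_position(a, b, n)
    if np.unique(pos).size != pos.size:
        raise ValueError("duplicate pair rows in transformed file")
    order = np.argsort(pos)
    if not np.array_equal(order, np.arange(pos.size)):
        logger.info("rows of %s were not in canonical order; re-sorted", source)
        df = df.iloc[order].reset_index(drop=True)
        a, b = a[order], b[order]
    idx = build_pair_index(n)

    batch = None
    if "batch_a" in df.columns and "batch_b" in df.columns:
        batch = np.empty(n, dtype=object)
        batch[a] = df["batch_a"].to_numpy()
        batch[b] = df["batch_b"].to_numpy()

    features: dict[str, KendallVector] = {}
    for col in df.columns:
        if col in _RESERVED:
            continue
        symbols = df[col].to_numpy()
        states = np.empty(symbols.size, dtype=np.int8)
        for i, sym in enumerate(symbols):
            try:
                states[i] = SYMBOL_TO_STATE[sym]
            except KeyError:
                raise ValueError(
                    f"unknown pair-state symbol {sym!r} in column {col!r}"
                ) from None
        features[col] = KendallVector(states=states, pair_index=idx, name=col)
    if not features:
        raise ValueError("transformed file contains no feature columns")
    return TransformedFrame(pair_index=idx, features=features, batch=batch)
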
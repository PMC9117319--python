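"""Merging independently transformed batches into one frame.

Measurement batches that differ by an arbitrary strictly increasing
dis-calibration (a common artefact of high-throughput assays) produce
bit-identical pair states within each batch, so frames transformed per
batch can be concatenated safely: within-batch pair states are copied and
every cross-batch pair, whose order relation was never observed, is marked
missing.  Downstream scores use complete-pair deletion and therefore see
only the calibration-free, within-batch information.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .pairspace import (
    MISSING,
    KendallVector,
    TransformedFrame,
    build_pair_index,
    pair_position,
)

__all__ = ["merge_transformed"]


def merge_transformed(
    frames: Sequence[TransformedFrame],
    batch_names: Sequence[str] | None = None,
) -> TransformedFrame:
    """Merge transformed frames over disjoint observation sets.

    All frames must carry the same feature names.  The merged observation
    order is the concatenation order of the inputs; the pair index is
    rebuilt over the union and cross-batch pair states are MISSING.  Batch
    labels are retained per observation so that inversion back to rankings
    can be performed within each batch.
    """
    if len(frames) == 0:
        raise ValueError("nothing to merge")
    names = frames[0].feature_names
    for f in frames[1:]:
        if set(f.feature_names) != set(names):
            raise ValueError(
                "frames carry different feature sets: "
                f"{sorted(names)} vs {sorted(f.feature_names)}"
            )
    if batch_names is None:
        batch_names = [f"batch{i + 1}" for i in range(len(frames))]
    if len(batch_names) != len(frames):
        raise ValueError("need one batch name per frame")

    ns = [f.n for f in frames]
    n = sum(ns)
    offsets = np.concatenate([[0], np.cumsum(ns)[:-1]])
    idx = build_pair_index(n)

    batch = np.empty(n, dtype=object)
    for f, off, name in zip(frames, offsets, batch_names):
        if f.batch is not None:  # keep finer labels when merging merges
            batch[off : off + f.n] = f.batch
        else:
            batch[off : off + f.n] = name

    features: dict[str, KendallVector] = {}
    for name in names:
        states = np.full(idx.m, MISSING, dtype=np.int8)
        for f, off in zip(frames, offsets):
            pi = f.pair_index
            j = pair_position(pi.a + off, pi.b + off, n)
            states[j] = f.features[name].states
        features[name] = KendallVector(states=states, pair_index=idx, name=name)
    return TransformedFrame(pair_index=idx, features=features, batch=batch)
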
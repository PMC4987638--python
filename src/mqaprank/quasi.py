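"""Quasi single-model re-scoring.

A competent single-model ranking picks the top-k decoys as reference
structures; every decoy is then re-scored by its mean structural similarity
(GDT_TS or TM-score) to the references.  A reference decoy is compared to
the other references only (its trivial self-similarity is excluded).  This
combines single-model ranking with the consensus idea that near-native
conformations resemble each other, without requiring an all-against-all
similarity matrix: only n * k comparisons are made.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .ranker import QualityEstimate
from .similarity import similarity
from .structures import DecoySet

__all__ = ["quasi_rescore"]


def quasi_rescore(
    ds: DecoySet,
    initial: QualityEstimate,
    k: int = 5,
    metric: str = "gdt_ts",
    refs: Sequence[str] | None = None,
) -> QualityEstimate:
    """Re-score every decoy by mean similarity to the top-k of ``initial``.

    ``refs`` overrides the reference selection with an explicit decoy_id list
    (e.g. references taken from another decoy set).  The returned estimate
    carries the mean similarities in ``quasi_quality`` and is re-ranked by
    them (descending, decoy_id tie-break).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ids = list(initial.decoy_ids)
    if set(ids) != set(ds.decoy_ids):
        raise ValueError("initial ranking and decoy set disagree on decoy_ids")
    if len(ids) == 1:
        warnings.warn("single decoy: quasi re-scoring is a passthrough")
        return QualityEstimate(
            target_id=initial.target_id,
            decoy_ids=ids,
            raw_score=initial.raw_score.copy(),
            rank=np.array([1]),
            reciprocal_rank=np.array([1.0]),
            quasi_quality=initial.raw_score.copy(),
        )
    if refs is None:
        refs = initial.order()[: min(k, len(ids))]
    else:
        refs = list(refs)
        missing = [r for r in refs if r not in set(ds.decoy_ids)]
        if missing:
            raise KeyError(f"reference decoys not in decoy set: {missing}")

    ref_structs = {r: ds.structure(r) for r in refs}
    cache: dict[tuple[str, str], float] = {}

    def sim(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            cache[key] = similarity(ds.structure(a), ref_structs[b], metric).value
        return cache[key]

    quasi = np.empty(len(ids))
    ref_set = set(refs)
    for i, d in enumerate(ids):
        others = [r for r in refs if r != d] if d in ref_set else refs
        if not others:  # single reference scoring itself
            quasi[i] = initial.raw_score[i]
            continue
        quasi[i] = float(np.mean([sim(d, r) for r in others]))

    order = sorted(range(len(ids)), key=lambda i: (-quasi[i], ids[i]))
    rank = np.empty(len(ids), dtype=int)
    for pos, i in enumerate(order, start=1):
        rank[i] = pos
    return QualityEstimate(
        target_id=initial.target_id,
        decoy_ids=ids,
        raw_score=initial.raw_score.copy(),
        rank=rank,
        reciprocal_rank=1.0 / rank,
        quasi_quality=quasi,
    )
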
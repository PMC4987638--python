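"""GDT_TS and TM-score structure similarity metrics.

Both metrics compare CA traces of a model and its native structure under a
1:1 positional residue correspondence and search over rigid superpositions
for the best score:

* ``GDT_TS = 25 * (N_1 + N_2 + N_4 + N_8) / L_N`` where ``N_c`` is the
  largest number of residues simultaneously fitting within ``c`` Angstrom
  of the native under some superposition (cutoffs 1, 2, 4, 8 A; 0-100 scale).
* ``TM = max over superpositions of (1/L_N) * sum_i 1 / (1 + (d_i/d0)^2)``
  with the standard length-dependent normalization scale
  ``d0 = max(0.5, 1.24 * (L_N - 15)^(1/3) - 1.8)``.

The maximal-substructure search is an LGA-style seeded heuristic: initial
superpositions are fitted on sliding windows of the chain plus the full
chain -- every window length for chains of up to 32 residues, where
exhaustive seeding is affordable, and a geometric ladder of window lengths
(3, 5, 7, 10, 15, ...) above that; each seed is refined by alternating
"superpose on the
current inlier set" / "recompute inliers within the cutoff" to a fixed point
(at most 20 iterations), and every superposition visited along the way is
scored.  The best score over all visited superpositions is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import Structure, batched_kabsch, kabsch_superpose

__all__ = ["SimilarityResult", "tm_score", "gdt_ts", "tm_d0", "similarity"]

GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)
_EXHAUSTIVE_MAX_L = 32
_MAX_ITER = 20


def _window_lengths(L: int) -> list[int]:
    """Seed window lengths: every length for short chains, a geometric
    ladder (3, 5, 7, 10, 15, ... ~x1.5) for longer ones."""
    if L <= _EXHAUSTIVE_MAX_L:
        return list(range(3, L + 1))
    lengths = [3, 5, 7]
    w = 10
    while w < L:
        lengths.append(w)
        w = int(round(w * 1.5))
    return lengths


@dataclass
class SimilarityResult:
    """Outcome of one model-vs-native comparison."""

    metric: str                 # "gdt_ts" or "tm"
    value: float                # GDT_TS on 0-100 or TM on (0, 1]
    L_N: int                    # native length
    L_T: int                    # number of aligned residues
    d_i: np.ndarray             # per-residue CA distances under full-chain superposition
    d0: float | None = None     # TM normalization scale (TM only)
    N_c: dict[float, int] | None = None  # per-cutoff counts (GDT only)


def tm_d0(L_N: int) -> float:
    """Length-dependent TM-score normalization scale, floored at 0.5 A."""
    if L_N <= 15:
        return 0.5
    return max(0.5, 1.24 * (L_N - 15) ** (1.0 / 3.0) - 1.8)


def _aligned_ca(model: Structure, native: Structure) -> tuple[np.ndarray, np.ndarray]:
    pos_m = {r.seq_pos: r.CA for r in model.residues}
    pos_n = {r.seq_pos: r.CA for r in native.residues}
    common = sorted(set(pos_m) & set(pos_n))
    if not common:
        raise ValueError("model and native share no residue positions")
    mob = np.array([pos_m[p] for p in common], float)
    fix = np.array([pos_n[p] for p in common], float)
    return mob, fix


def _seed_masks(L: int, window_lengths=None) -> np.ndarray:
    """Boolean seed masks: every sliding window of each length, plus the full chain."""
    if window_lengths is None:
        window_lengths = _window_lengths(L)
    masks = [np.ones(L, dtype=bool)]
    for w in window_lengths:
        if w > L:
            continue
        for start in range(0, L - w + 1):
            m = np.zeros(L, dtype=bool)
            m[start : start + w] = True
            masks.append(m)
    return np.array(masks)


def _ensure_min_inliers(d: np.ndarray, masks: np.ndarray, k: int = 3) -> np.ndarray:
    """Rows selecting < k residues fall back to the k smallest distances."""
    short = masks.sum(axis=1) < k
    if np.any(short):
        idx = np.argsort(d[short], axis=1)[:, :k]
        repl = np.zeros((short.sum(), masks.shape[1]), dtype=bool)
        np.put_along_axis(repl, idx, True, axis=1)
        masks = masks.copy()
        masks[short] = repl
    return masks


def _visited_distances(mob: np.ndarray, fix: np.ndarray, cutoff: float) -> list[np.ndarray]:
    """Run the seeded refinement at one inlier cutoff.

    Returns the (S, L) residue-distance array of every iteration visited,
    so callers can score all candidate superpositions.
    """
    L = len(mob)
    masks = _seed_masks(L)
    visited: list[np.ndarray] = []
    for _ in range(_MAX_ITER):
        R, t = batched_kabsch(mob, fix, masks)
        moved = np.einsum("sjk,ik->sij", R, mob) + t[:, None, :]
        d = np.linalg.norm(moved - fix[None], axis=2)
        visited.append(d)
        new = _ensure_min_inliers(d, d <= cutoff)
        if np.array_equal(new, masks):
            break
        masks = new
    return visited


def gdt_ts(model: Structure, native: Structure) -> SimilarityResult:
    """Global distance test total score of ``model`` against ``native`` (0-100)."""
    mob, fix = _aligned_ca(model, native)
    L_N = len(native)
    if L_N < 3 or len(mob) < 3:
        raise ValueError("GDT_TS requires at least 3 aligned residues")
    all_d = []
    for c in GDT_CUTOFFS:
        all_d.extend(_visited_distances(mob, fix, c))
    stacked = np.vstack(all_d)  # (n_candidates, L)
    N_c = {c: int((stacked <= c).sum(axis=1).max()) for c in GDT_CUTOFFS}
    value = 25.0 * sum(N_c.values()) / L_N
    full = kabsch_superpose(mob, fix)
    d_full = np.linalg.norm(full.apply(mob) - fix, axis=1)
    return SimilarityResult(
        metric="gdt_ts", value=float(value), L_N=L_N, L_T=len(mob), d_i=d_full, N_c=N_c
    )


def tm_score(model: Structure, native: Structure) -> SimilarityResult:
    """TM-score of ``model`` against ``native``, normalized by native length."""
    mob, fix = _aligned_ca(model, native)
    L_N = len(native)
    if L_N < 3 or len(mob) < 3:
        raise ValueError("TM-score requires at least 3 aligned residues")
    d0 = tm_d0(L_N)
    visited = _visited_distances(mob, fix, max(d0, 1.0))
    stacked = np.vstack(visited)
    tm_all = (1.0 / (1.0 + (stacked / d0) ** 2)).sum(axis=1) / L_N
    full = kabsch_superpose(mob, fix)
    d_full = np.linalg.norm(full.apply(mob) - fix, axis=1)
    value = float(max(tm_all.max(), tm_from_distances(d_full, L_N, d0)))
    return SimilarityResult(
        metric="tm", value=value, L_N=L_N, L_T=len(mob), d_i=d_full, d0=d0
    )


def tm_from_distances(d: np.ndarray, L_N: int, d0: float) -> float:
    """TM-score aggregation for a fixed set of aligned CA distances."""
    return float((1.0 / (1.0 + (np.asarray(d, float) / d0) ** 2)).sum() / L_N)


def similarity(model: Structure, native: Structure, metric: str) -> SimilarityResult:
    """Dispatch on metric name: ``gdt_ts`` or ``tm``."""
    if metric == "gdt_ts":
        return gdt_ts(model, native)
    if metric == "tm":
        return tm_score(model, native)
    raise ValueError(f"unknown similarity metric: {metric!r}")
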
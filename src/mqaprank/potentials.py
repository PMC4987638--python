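"""Trainable knowledge-based statistical potentials.

Two inverse-Boltzmann pseudo-energies are implemented, both trained from a
set of reference structures and both oriented *lower is better*:

* a single-body backbone-dihedral potential: the negative log propensity of
  each amino acid for each (phi, psi) bin;
* a two-body residue-level distance potential with a distance-scaled
  finite ideal-gas reference state, using side-chain interaction centers
  (CB, or CA for glycine).

Tables are plain dataclasses with text serialization so trained potentials
can be versioned alongside results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structures import Structure, backbone_dihedrals

__all__ = [
    "AMINO_ACIDS",
    "DihedralTable",
    "PairPotentialTable",
    "train_dihedral_table",
    "dihedral_energy",
    "train_pair_potential",
    "pair_potential_energy",
    "interaction_centers",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


# ---------------------------------------------------------------------------
# Dihedral (phi/psi propensity) potential


@dataclass
class DihedralTable:
    """-ln propensity of each amino acid for each (phi, psi) bin."""

    bin_width: float
    scores: np.ndarray       # (20, nbins, nbins)
    counts: np.ndarray       # raw training tallies, same shape
    pseudocount: float

    @property
    def nbins(self) -> int:
        return self.scores.shape[1]

    def bin_of(self, angle: float) -> int:
        b = int(math.floor((angle + 180.0) / self.bin_width))
        return min(max(b, 0), self.nbins - 1)

    def save(self, path: str | Path) -> None:
        _save_table(path, "dihedral-table v1",
                    {"bin_width": self.bin_width, "pseudocount": self.pseudocount},
                    {"scores": self.scores, "counts": self.counts})

    @classmethod
    def load(cls, path: str | Path) -> "DihedralTable":
        meta, arrays = _load_table(path, "dihedral-table v1")
        nb = int(round(360.0 / meta["bin_width"]))
        return cls(
            bin_width=meta["bin_width"],
            scores=arrays["scores"].reshape(20, nb, nb),
            counts=arrays["counts"].reshape(20, nb, nb),
            pseudocount=meta["pseudocount"],
        )


def train_dihedral_table(
    training: list[Structure], bin_width: float = 20.0, pseudocount: float = 1.0
) -> DihedralTable:
    """Tally (aa, phi-bin, psi-bin) propensities from interior residues.

    score(aa, b) = -ln[ (n(aa,b) + q) / (n(aa) + q * nbins^2) ], the
    pseudocount-smoothed conditional propensity of amino acid ``aa`` for the
    joint (phi, psi) bin ``b``.  A bin never observed for an amino acid is
    maximally unfavorable but stays finite for q > 0.
    """
    if not training:
        raise ValueError("training set must contain at least one structure")
    if 360.0 % bin_width:
        raise ValueError("bin_width must divide 360")
    nb = int(round(360.0 / bin_width))
    counts = np.zeros((20, nb, nb))
    interior = 0
    for s in training:
        if len(s) < 3:
            continue
        for r, (phi, psi) in zip(s.residues, backbone_dihedrals(s)):
            if phi is None or psi is None or r.aa not in _AA_INDEX:
                continue
            bp = min(int((phi + 180.0) / bin_width), nb - 1)
            bs = min(int((psi + 180.0) / bin_width), nb - 1)
            counts[_AA_INDEX[r.aa], bp, bs] += 1
            interior += 1
    if interior == 0:
        raise ValueError("training set has no interior residues")
    q = pseudocount
    n_aa = counts.sum(axis=(1, 2))          # (20,)
    scores = -np.log((counts + q) / (n_aa[:, None, None] + q * nb * nb))
    return DihedralTable(bin_width=bin_width, scores=scores, counts=counts, pseudocount=q)


def dihedral_energy(s: Structure, table: DihedralTable) -> float:
    """Sum of -ln propensity over residues with defined (phi, psi); lower is better."""
    if len(s) < 3:
        raise ValueError("dihedral energy requires length >= 3")
    total = 0.0
    for r, (phi, psi) in zip(s.residues, backbone_dihedrals(s)):
        if phi is None or psi is None or r.aa not in _AA_INDEX:
            continue
        total += table.scores[_AA_INDEX[r.aa], table.bin_of(phi), table.bin_of(psi)]
    return float(total)


# ---------------------------------------------------------------------------
# Pairwise distance potential (DFIRE-style reference state)


@dataclass
class PairPotentialTable:
    """Residue-pair distance potential with an r^alpha reference state."""

    scores: np.ndarray           # (20, 20, nbins), symmetric in the first two axes
    bin_edges: np.ndarray        # (nbins + 1,), last edge = r_cut
    alpha: float
    min_separation: int
    pseudocount: float
    counts: np.ndarray | None = field(default=None, repr=False)

    @property
    def r_cut(self) -> float:
        return float(self.bin_edges[-1])

    def save(self, path: str | Path) -> None:
        _save_table(path, "pair-potential v1",
                    {"alpha": self.alpha, "min_separation": self.min_separation,
                     "pseudocount": self.pseudocount},
                    {"bin_edges": self.bin_edges, "scores": self.scores})

    @classmethod
    def load(cls, path: str | Path) -> "PairPotentialTable":
        meta, arrays = _load_table(path, "pair-potential v1")
        edges = arrays["bin_edges"]
        nb = len(edges) - 1
        return cls(
            scores=arrays["scores"].reshape(20, 20, nb),
            bin_edges=edges,
            alpha=meta["alpha"],
            min_separation=int(meta["min_separation"]),
            pseudocount=meta["pseudocount"],
        )


def interaction_centers(s: Structure) -> np.ndarray:
    """(L, 3) side-chain interaction centers: CB, CA for glycine.

    A missing CB on a non-glycine residue is rebuilt at the ideal tetrahedral
    position from the local N/CA/C frame.
    """
    out = np.empty((len(s), 3))
    for i, r in enumerate(s.residues):
        if r.aa == "G":
            out[i] = r.CA
        elif r.CB is not None:
            out[i] = r.CB
        else:
            out[i] = _ideal_cb(r.N, r.CA, r.C)
    return out


def _ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # tetrahedral CB from the backbone frame, 1.53 A from CA
    v1 = (n - ca) / np.linalg.norm(n - ca)
    v2 = (c - ca) / np.linalg.norm(c - ca)
    bisector = -(v1 + v2)
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(v2, v1)
    perp /= np.linalg.norm(perp)
    direction = bisector * math.cos(0.9521) + perp * math.sin(0.9521)
    return ca + 1.53 * direction / np.linalg.norm(direction)


def default_bin_edges(width: float = 0.5, r_cut: float = 14.5) -> np.ndarray:
    return np.arange(0.0, r_cut + width / 2, width)


def _pair_tally(
    structures: list[Structure], bin_edges: np.ndarray, min_separation: int
) -> np.ndarray:
    nb = len(bin_edges) - 1
    counts = np.zeros((20, 20, nb))
    r_cut = bin_edges[-1]
    for s in structures:
        centers = interaction_centers(s)
        aa_idx = np.array([_AA_INDEX.get(r.aa, -1) for r in s.residues])
        pos = np.array([r.seq_pos for r in s.residues])
        diff = centers[:, None, :] - centers[None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        sep = np.abs(pos[:, None] - pos[None, :])
        iu, ju = np.triu_indices(len(s), k=1)
        keep = (sep[iu, ju] >= min_separation)
        keep &= (dist[iu, ju] < r_cut) & (dist[iu, ju] >= bin_edges[0])
        keep &= (aa_idx[iu] >= 0) & (aa_idx[ju] >= 0)
        ii, jj = iu[keep], ju[keep]
        bins = np.clip(np.searchsorted(bin_edges, dist[ii, jj], side="right") - 1, 0, nb - 1)
        np.add.at(counts, (aa_idx[ii], aa_idx[jj], bins), 1.0)
        np.add.at(counts, (aa_idx[jj], aa_idx[ii], bins), 1.0)
    return counts


def train_pair_potential(
    training: list[Structure],
    bin_edges: np.ndarray | None = None,
    alpha: float = 1.61,
    min_separation: int = 2,
    pseudocount: float = 0.5,
) -> PairPotentialTable:
    """Train the distance potential against an r^alpha ideal-gas reference.

    score(i, j, b) = -ln[ (N(i,j,b)+q) /
                          ((r_b/r_bcut)^alpha * (dr_b/dr_cut) * (N(i,j,b_cut)+q)) ]
    with r_b the bin midpoint and b_cut the outermost bin.
    """
    if not training:
        raise ValueError("training set must contain at least one structure")
    if bin_edges is None:
        bin_edges = default_bin_edges()
    bin_edges = np.asarray(bin_edges, float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    counts = _pair_tally(training, bin_edges, min_separation)
    q = pseudocount
    mids = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    widths = np.diff(bin_edges)
    ref = (mids / mids[-1]) ** alpha * (widths / widths[-1])  # (nbins,)
    scores = -np.log((counts + q) / (ref[None, None, :] * (counts[:, :, -1:] + q)))
    return PairPotentialTable(
        scores=scores, bin_edges=bin_edges, alpha=alpha,
        min_separation=min_separation, pseudocount=q, counts=counts,
    )


def pair_potential_energy(s: Structure, table: PairPotentialTable) -> float:
    """Sum of binned pair scores over qualifying residue pairs; lower is better.

    Pairs separated in sequence by less than ``min_separation`` or in space by
    more than ``r_cut`` contribute nothing.
    """
    centers = interaction_centers(s)
    aa_idx = np.array([_AA_INDEX.get(r.aa, -1) for r in s.residues])
    pos = np.array([r.seq_pos for r in s.residues])
    dist = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    sep = np.abs(pos[:, None] - pos[None, :])
    iu, ju = np.triu_indices(len(s), k=1)
    keep = (sep[iu, ju] >= table.min_separation)
    keep &= (dist[iu, ju] < table.r_cut) & (dist[iu, ju] >= table.bin_edges[0])
    keep &= (aa_idx[iu] >= 0) & (aa_idx[ju] >= 0)
    ii, jj = iu[keep], ju[keep]
    nb = table.scores.shape[2]
    bins = np.clip(np.searchsorted(table.bin_edges, dist[ii, jj], side="right") - 1, 0, nb - 1)
    return float(table.scores[aa_idx[ii], aa_idx[jj], bins].sum())


# ---------------------------------------------------------------------------
# text serialization shared by both tables


def _save_table(path, header, meta: dict, arrays: dict[str, np.ndarray]) -> None:
    lines = [f"# {header}"]
    for k, v in meta.items():
        lines.append(f"{k}\t{v!r}")
    for name, arr in arrays.items():
        flat = np.asarray(arr, float).ravel()
        lines.append(f"@{name}\t{len(flat)}")
        lines.append(" ".join(f"{x:.12g}" for x in flat))
    Path(path).write_text("\n".join(lines) + "\n")


def _load_table(path, header) -> tuple[dict, dict[str, np.ndarray]]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != f"# {header}":
        raise ValueError(f"{path}: not a {header} file")
    meta: dict = {}
    arrays: dict[str, np.ndarray] = {}
    i = 1
    while i < len(lines):
        line = lines[i]
        if line.startswith("@"):
            name, _n = line[1:].split("\t")
            arrays[name] = np.array(lines[i + 1].split(), dtype=float)
            i += 2
        else:
            k, v = line.split("\t")
            meta[k] = float(v)
            i += 1
    return meta, arrays
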
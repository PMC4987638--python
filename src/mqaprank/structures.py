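"""Protein chain containers, PDB I/O, optimal superposition and backbone geometry.

A :class:`Structure` holds a single chain's residues with backbone coordinates
(N, CA, C, optionally O and CB) in Angstroms.  It is the unit consumed by the
similarity metrics, the knowledge-based potentials and the feature layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Residue",
    "Structure",
    "DecoySet",
    "Superposition",
    "read_pdb",
    "write_pdb",
    "kabsch_superpose",
    "backbone_dihedrals",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


@dataclass
class Residue:
    """One amino acid with backbone coordinates (Angstrom)."""

    aa: str
    seq_pos: int
    N: np.ndarray
    CA: np.ndarray
    C: np.ndarray
    O: np.ndarray | None = None
    CB: np.ndarray | None = None


@dataclass
class Structure:
    """A single protein chain: ordered residues with backbone coordinates.

    Residues are renumbered 1..L on construction order; seq_pos is strictly
    increasing.  All stored coordinates must be finite.
    """

    target_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        pos = [r.seq_pos for r in self.residues]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("residue seq_pos must be strictly increasing")
        for r in self.residues:
            for atom in (r.N, r.CA, r.C, r.O, r.CB):
                if atom is not None and not np.all(np.isfinite(atom)):
                    raise ValueError("non-finite coordinate in structure")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(L, 3) array of CA coordinates."""
        return np.array([r.CA for r in self.residues], dtype=float)

    def atom_table(self) -> tuple[list[tuple[int, str]], np.ndarray]:
        """All stored heavy atoms as ((residue index, atom name), (n, 3) coords)."""
        keys: list[tuple[int, str]] = []
        coords: list[np.ndarray] = []
        for i, r in enumerate(self.residues):
            for name in ("N", "CA", "C", "O", "CB"):
                xyz = getattr(r, name)
                if xyz is not None:
                    keys.append((i, name))
                    coords.append(np.asarray(xyz, dtype=float))
        return keys, np.array(coords, dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with every stored atom mapped through x -> R x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        out = []
        for r in self.residues:
            kw = {}
            for name in ("N", "CA", "C", "O", "CB"):
                xyz = getattr(r, name)
                kw[name] = None if xyz is None else R @ np.asarray(xyz, float) + t
            out.append(Residue(r.aa, r.seq_pos, **kw))
        return Structure(self.target_id, out)


@dataclass
class DecoySet:
    """A target with its decoy structures and optional true qualities.

    ``true_quality`` maps decoy_id -> quality on the chosen metric scale
    (GDT_TS 0-100 or TM-score 0-1).
    """

    target_id: str
    decoys: list[tuple[str, Structure]]
    native: Structure | None = None
    true_quality: dict[str, float] | None = None

    def __post_init__(self) -> None:
        ids = [d for d, _ in self.decoys]
        if len(set(ids)) != len(ids):
            raise ValueError("decoy_ids must be unique")

    @property
    def decoy_ids(self) -> list[str]:
        return [d for d, _ in self.decoys]

    def structure(self, decoy_id: str) -> Structure:
        for d, s in self.decoys:
            if d == decoy_id:
                return s
        raise KeyError(decoy_id)


@dataclass
class Superposition:
    """Least-squares rigid superposition: x_mobile -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# PDB I/O


def read_pdb(path: str | Path, chain: str | None = None, target_id: str | None = None) -> Structure:
    """Parse a single chain from a PDB file into a :class:`Structure`.

    Only the first MODEL is read; HETATM records and altlocs other than blank
    or 'A' are ignored.  Residues missing any of N/CA/C are dropped with a
    warning, and surviving residues are renumbered 1..L in order of appearance.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc

    residues: dict[tuple[str, str, str], dict[str, np.ndarray | str]] = {}
    order: list[tuple[str, str, str]] = []
    selected_chain = chain
    for line in text.splitlines():
        if line.startswith("ENDMDL"):
            break
        if not line.startswith("ATOM"):
            continue
        altloc = line[16]
        if altloc not in (" ", "A"):
            continue
        ch = line[21]
        if selected_chain is None:
            selected_chain = ch
        if ch != selected_chain:
            continue
        name = line[12:16].strip()
        if name not in ("N", "CA", "C", "O", "CB"):
            continue
        resname = line[17:20].strip()
        if resname not in _THREE_TO_ONE:
            continue
        key = (ch, line[22:26].strip(), line[26].strip())
        if key not in residues:
            residues[key] = {"aa": _THREE_TO_ONE[resname]}
            order.append(key)
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        residues[key].setdefault(name, xyz)

    out: list[Residue] = []
    dropped = 0
    for key in order:
        rec = residues[key]
        if not all(a in rec for a in ("N", "CA", "C")):
            dropped += 1
            continue
        out.append(
            Residue(
                aa=rec["aa"],  # type: ignore[arg-type]
                seq_pos=len(out) + 1,
                N=rec["N"], CA=rec["CA"], C=rec["C"],
                O=rec.get("O"), CB=rec.get("CB"),
            )
        )
    if dropped:
        warnings.warn(f"{path.name}: dropped {dropped} residue(s) with incomplete backbone")
    if not out:
        raise ValueError(f"{path}: no complete residues in chain {selected_chain!r}")
    return Structure(target_id or path.stem, out)


def write_pdb(s: Structure, path: str | Path, chain: str = "A") -> None:
    """Write a Structure as minimal ATOM records (3-decimal coordinates)."""
    lines = []
    serial = 1
    for r in s.residues:
        res3 = _ONE_TO_THREE.get(r.aa, "ALA")
        for name in ("N", "CA", "C", "O", "CB"):
            xyz = getattr(r, name)
            if xyz is None:
                continue
            element = name[0]
            name4 = (" " + name).ljust(4)  # cols 13-16, left-padded short names
            lines.append(
                f"ATOM  {serial:5d} {name4} {res3:>3s} {chain}{r.seq_pos:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Superposition


def kabsch_superpose(mobile: Sequence | np.ndarray, fixed: Sequence | np.ndarray) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``fixed`` (Kabsch).

    Returns the proper rotation (reflections corrected) and translation
    minimizing the RMSD between the mapped mobile points and the fixed points.
    """
    X = np.asarray(mobile, dtype=float)
    Y = np.asarray(fixed, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("mobile and fixed must be matching (n, 3) arrays")
    if X.shape[0] < 3:
        raise ValueError("at least 3 points are required for superposition")
    cm = X.mean(axis=0)
    cf = Y.mean(axis=0)
    H = (X - cm).T @ (Y - cf)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    diff = X @ R.T + t - Y
    rmsd = float(np.sqrt((diff**2).sum() / X.shape[0]))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def batched_kabsch(
    mobile: np.ndarray, fixed: np.ndarray, masks: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Kabsch superposition for S subsets of one point pair, simultaneously.

    ``mobile``/``fixed`` are (L, 3); ``masks`` is a boolean (S, L) selection.
    Returns rotations (S, 3, 3) and translations (S, 3).  Each mask must
    select >= 3 points.
    """
    w = masks.astype(float)
    n = w.sum(axis=1)
    if np.any(n < 3):
        raise ValueError("every mask must select at least 3 points")
    cm = (w @ mobile) / n[:, None]
    cf = (w @ fixed) / n[:, None]
    H = np.einsum("si,ij,ik->sjk", w, mobile, fixed) - n[:, None, None] * np.einsum(
        "sj,sk->sjk", cm, cf
    )
    U, _, Vt = np.linalg.svd(H)
    V = np.swapaxes(Vt, 1, 2)
    Ut = np.swapaxes(U, 1, 2)
    det = np.linalg.det(V @ Ut)
    D = np.repeat(np.eye(3)[None], len(w), axis=0)
    D[:, 2, 2] = np.sign(det)
    R = V @ D @ Ut
    t = cf - np.einsum("sjk,sk->sj", R, cm)
    return R, t


# ---------------------------------------------------------------------------
# Dihedral geometry


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def backbone_dihedrals(s: Structure) -> list[tuple[float | None, float | None]]:
    """Per-residue (phi, psi) in degrees; undefined entries are None.

    phi is undefined for the first residue, psi for the last.
    """
    if len(s) < 3:
        raise ValueError("dihedral computation requires length >= 3")
    out: list[tuple[float | None, float | None]] = []
    res = s.residues
    for i, r in enumerate(res):
        phi = psi = None
        if i > 0:
            phi = dihedral_angle(res[i - 1].C, r.N, r.CA, r.C)
        if i < len(res) - 1:
            psi = dihedral_angle(r.N, r.CA, r.C, res[i + 1].N)
        out.append((phi, psi))
    return out
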
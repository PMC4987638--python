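"""Per-decoy feature extraction and assembly into a feature matrix.

Internal features are computed from the model itself: the two trainable
potentials (see :mod:`mqaprank.potentials`), secondary-structure agreement
between a dihedral-based assignment on the model and an externally predicted
string, and solvent-accessibility agreement between a sphere-sampling
(Shrake-Rupley) surface computed on the model and externally predicted
relative accessibilities.  External per-decoy scores from other quality
assessment programs are ingested from a TSV keyed by (target_id, decoy_id).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .structures import DecoySet, Structure, backbone_dihedrals

__all__ = [
    "FeatureMatrix",
    "assign_secondary_structure",
    "ss_consistency",
    "solvent_accessibility",
    "relative_accessibility",
    "accessibility_agreement",
    "assemble_features",
    "potential_provider",
    "ss_agreement_provider",
    "rsa_agreement_provider",
    "read_external_table",
    "read_ss2",
    "MAX_ASA",
]

# Theoretical maximum accessible surface areas per residue (A^2), used to
# normalize absolute areas into relative solvent accessibility.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

_ATOM_RADII = {"N": 1.55, "CA": 1.70, "C": 1.70, "O": 1.52, "CB": 1.70}


# ---------------------------------------------------------------------------
# Secondary structure


def assign_secondary_structure(s: Structure) -> str:
    """Three-state secondary structure from backbone dihedral windows.

    H if phi in [-100, -30] and psi in [-80, -5]; E if phi in [-180, -40] and
    psi in [60, 180]; C otherwise.  Terminal residues (undefined phi or psi)
    are C.  This is a deliberately simple stand-in for a hydrogen-bond-based
    assignment: it keys on the same Ramachandran basins.
    """
    if len(s) < 3:
        raise ValueError("secondary structure assignment requires length >= 3")
    labels = []
    for phi, psi in backbone_dihedrals(s):
        if phi is None or psi is None:
            labels.append("C")
        elif -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0:
            labels.append("H")
        elif -180.0 <= phi <= -40.0 and 60.0 <= psi <= 180.0:
            labels.append("E")
        else:
            labels.append("C")
    return "".join(labels)


def ss_consistency(assigned: str, predicted: str) -> tuple[float, float, float, float]:
    """Per-class and total agreement fractions between two SS strings.

    Returns (frac_H, frac_E, frac_C, frac_total), each the number of positions
    where both strings agree on that class (or agree at all), divided by the
    chain length.
    """
    if len(assigned) != len(predicted):
        raise ValueError("assigned and predicted strings must have equal length")
    L = len(assigned)
    agree = [a for a, p in zip(assigned, predicted) if a == p]
    frac = {c: agree.count(c) / L for c in "HEC"}
    return frac["H"], frac["E"], frac["C"], len(agree) / L


def read_ss2(path: str | Path) -> str:
    """Read a predicted secondary-structure string.

    Accepts either a PSIPRED ss2-style file (columns: idx, aa, label, probs)
    or a single-line string over the {H, E, C} alphabet.
    """
    lines = [l for l in Path(path).read_text().splitlines()
             if l.strip() and not l.startswith("#")]
    if len(lines) == 1 and set(lines[0].strip()) <= set("HEC"):
        return lines[0].strip()
    labels = []
    for line in lines:
        parts = line.split()
        if len(parts) >= 3 and parts[0].isdigit():
            labels.append("C" if parts[2] not in "HEC" else parts[2])
    if not labels:
        raise ValueError(f"{path}: unrecognized secondary-structure format")
    return "".join(labels)


# ---------------------------------------------------------------------------
# Solvent accessibility (Shrake-Rupley)


def _sphere_lattice(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


def solvent_accessibility(
    s: Structure, probe_radius: float = 1.4, n_points: int = 240
) -> np.ndarray:
    """Per-residue solvent-accessible surface area (A^2) over stored heavy atoms."""
    if len(s) < 1:
        raise ValueError("empty structure")
    keys, coords = s.atom_table()
    radii = np.array([_ATOM_RADII[name] for _, name in keys]) + probe_radius
    lattice = _sphere_lattice(n_points)
    per_residue = np.zeros(len(s))
    n_atoms = len(coords)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    for a in range(n_atoms):
        pts = coords[a] + radii[a] * lattice  # (n_points, 3)
        # neighbors that could occlude this atom's sphere
        nbr = np.where((d2[a] < (radii[a] + radii) ** 2) & (np.arange(n_atoms) != a))[0]
        accessible = np.ones(n_points, dtype=bool)
        for b in nbr:
            accessible &= ((pts - coords[b]) ** 2).sum(axis=1) > radii[b] ** 2
            if not accessible.any():
                break
        area = 4.0 * np.pi * radii[a] ** 2 * accessible.sum() / n_points
        per_residue[keys[a][0]] += area
    return per_residue


def relative_accessibility(s: Structure, **kwargs) -> np.ndarray:
    """Per-residue area normalized by the per-amino-acid maximum (clipped to [0, 1.5])."""
    area = solvent_accessibility(s, **kwargs)
    maxima = np.array([MAX_ASA.get(r.aa, 200.0) for r in s.residues])
    return np.clip(area / maxima, 0.0, 1.5)


def accessibility_agreement(
    model_rsa: Sequence[float], predicted_rsa: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation and cosine similarity between two RSA vectors.

    A zero-variance vector makes the correlation undefined; it is imputed 0
    with a warning.
    """
    x = np.asarray(model_rsa, float)
    y = np.asarray(predicted_rsa, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("RSA vectors must be equal-length 1-D with length >= 3")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    cosine = float(x @ y / (nx * ny)) if nx > 0 and ny > 0 else 0.0
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance RSA vector: correlation imputed as 0")
        return 0.0, cosine
    pmcc = float(np.corrcoef(x, y)[0, 1])
    return pmcc, cosine


def read_rsa(path: str | Path) -> np.ndarray:
    """Read a predicted RSA vector from a two-column TSV (seq_pos, rsa)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["seq_pos", "rsa"])
    return df.sort_values("seq_pos")["rsa"].to_numpy(float)


# ---------------------------------------------------------------------------
# Feature matrix assembly


@dataclass
class FeatureMatrix:
    """Per-decoy named feature vectors for one target."""

    target_id: str
    decoy_ids: list[str]
    feature_names: list[str]
    values: np.ndarray                                   # (n_decoys, n_features)
    orientation: dict[str, str] = field(default_factory=dict)  # higher_better / lower_better
    norm_stats: dict[str, tuple[float, float]] | None = None   # per-feature (mean, sd)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.decoy_ids), len(self.feature_names)):
            raise ValueError("values shape does not match decoy_ids x feature_names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite cells")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.decoy_ids, columns=self.feature_names)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def row(self, decoy_id: str) -> np.ndarray:
        return self.values[self.decoy_ids.index(decoy_id)]


# A feature provider maps a Structure to {feature_name: value}.
Provider = Callable[[Structure], dict[str, float]]


def potential_provider(dihedral_table=None, pair_table=None) -> Provider:
    """Provider computing the trained potential energies (orientation lower_better)."""
    from .potentials import dihedral_energy, pair_potential_energy

    def compute(s: Structure) -> dict[str, float]:
        out: dict[str, float] = {}
        if dihedral_table is not None:
            out["dih_potential"] = dihedral_energy(s, dihedral_table)
        if pair_table is not None:
            out["pair_potential"] = pair_potential_energy(s, pair_table)
        return out

    compute.orientation = {"dih_potential": "lower_better", "pair_potential": "lower_better"}
    return compute


def ss_agreement_provider(predicted_ss: str) -> Provider:
    """Provider computing SS agreement fractions against a predicted string."""

    def compute(s: Structure) -> dict[str, float]:
        assigned = assign_secondary_structure(s)
        h, e, c, total = ss_consistency(assigned, predicted_ss)
        return {"ss_frac_H": h, "ss_frac_E": e, "ss_frac_C": c, "ss_frac_total": total}

    compute.orientation = {k: "higher_better"
                           for k in ("ss_frac_H", "ss_frac_E", "ss_frac_C", "ss_frac_total")}
    return compute


def rsa_agreement_provider(predicted_rsa: np.ndarray, **sasa_kwargs) -> Provider:
    """Provider computing RSA Pearson/cosine agreement against a predicted vector."""

    def compute(s: Structure) -> dict[str, float]:
        model_rsa = relative_accessibility(s, **sasa_kwargs)
        pmcc, cosine = accessibility_agreement(model_rsa, predicted_rsa)
        return {"rsa_pmcc": pmcc, "rsa_cosine": cosine}

    compute.orientation = {"rsa_pmcc": "higher_better", "rsa_cosine": "higher_better"}
    return compute


def read_external_table(path: str | Path) -> pd.DataFrame:
    """Read an external per-decoy score TSV with columns target_id, decoy_id, <features...>."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"target_id", "decoy_id"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: external table must have columns {sorted(required)}")
    df["decoy_id"] = df["decoy_id"].astype(str)
    return df


def assemble_features(
    ds: DecoySet,
    internal_providers: Sequence[Provider] = (),
    external_table: pd.DataFrame | str | Path | None = None,
    normalize: bool = False,
) -> FeatureMatrix:
    """Build the per-decoy feature matrix for one target.

    Internal providers are evaluated on every decoy structure; external
    columns are joined on (target_id, decoy_id).  Missing external cells are
    imputed with the target-level column mean (logged as a warning).  With
    ``normalize``, every feature is z-scored and the statistics stored in
    ``norm_stats``; constant features are dropped with a warning.
    """
    rows: list[dict[str, float]] = []
    orientation: dict[str, str] = {}
    for decoy_id, s in ds.decoys:
        row: dict[str, float] = {}
        for provider in internal_providers:
            row.update(provider(s))
            orientation.update(getattr(provider, "orientation", {}))
        rows.append(row)
    df = pd.DataFrame(rows, index=ds.decoy_ids)

    if external_table is not None:
        if not isinstance(external_table, pd.DataFrame):
            external_table = read_external_table(external_table)
        ext = external_table[external_table["target_id"] == ds.target_id]
        unknown = set(ext["decoy_id"]) - set(ds.decoy_ids)
        if unknown:
            raise ValueError(
                f"external table has unknown decoy_ids for {ds.target_id}: {sorted(unknown)}"
            )
        ext = ext.drop(columns=["target_id"]).set_index("decoy_id")
        ext = ext.reindex(ds.decoy_ids)
        n_missing = int(ext.isna().sum().sum())
        if n_missing:
            warnings.warn(
                f"{ds.target_id}: imputing {n_missing} missing external cell(s) "
                "with target-level column means"
            )
            ext = ext.fillna(ext.mean())
        df = pd.concat([df, ext], axis=1)

    if df.shape[1] == 0:
        raise ValueError("no features: provide internal providers or an external table")
    if df.isna().any().any():
        raise ValueError("feature assembly produced missing cells")

    norm_stats = None
    if normalize:
        norm_stats = {}
        keep = []
        for name in df.columns:
            mu = float(df[name].mean())
            sd = float(df[name].std(ddof=0))
            if sd == 0.0:
                warnings.warn(f"{ds.target_id}: dropping constant feature {name!r}")
                continue
            df[name] = (df[name] - mu) / sd
            norm_stats[name] = (mu, sd)
            keep.append(name)
        df = df[keep]

    return FeatureMatrix(
        target_id=ds.target_id,
        decoy_ids=list(df.index),
        feature_names=list(df.columns),
        values=df.to_numpy(float),
        orientation=orientation,
        norm_stats=norm_stats,
    )
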
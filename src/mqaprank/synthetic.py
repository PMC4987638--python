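"""Seeded generators for toy natives, decoy ensembles and ranking benchmarks.

The structural generator emulates the shape of a decoy-set benchmark: one
native per target and an ensemble of decoys obtained by Gaussian coordinate
perturbation whose magnitude is drawn per decoy from a stated interval, so
true qualities span the whole GDT_TS spectrum.  The feature generator
emulates a quality-assessment feature table: each feature is an affine
function of the latent quality plus Gaussian noise plus a per-target offset.
The offsets mimic the strong target-level component of real statistical
potentials, whose absolute scale varies with protein size and composition
far more than with decoy quality; they are what separates within-target
ranking from pooled regression on this benchmark.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import FeatureMatrix
from .similarity import similarity
from .structures import DecoySet, Residue, Structure

__all__ = [
    "FeatureSpec",
    "SyntheticBenchmark",
    "make_native",
    "perturb_decoys",
    "simulate_feature_benchmark",
    "make_structural_benchmark",
    "default_feature_spec",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"

# backbone internal coordinates (Angstrom / degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N = 121.7, 110.4, 116.6


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d given chain a-b-c, bond |cd|, angle b-c-d, torsion a-b-c-d."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * math.cos(ang),
         bond * math.sin(ang) * math.cos(tor),
         bond * math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(phis: np.ndarray, psis: np.ndarray) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """NeRF chain build from per-residue (phi, psi); omega fixed at 180."""
    L = len(phis)
    atoms: list[np.ndarray] = [
        np.array([0.0, 0.0, 0.0]),                       # N1
        np.array([_B_N_CA, 0.0, 0.0]),                   # CA1
    ]
    # C1 at the N-CA-C angle in the xy plane
    ang = math.radians(_A_N_CA_C)
    atoms.append(atoms[1] + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0]))
    for i in range(1, L):
        n = _place(atoms[-3], atoms[-2], atoms[-1], _B_C_N, _A_CA_C_N, psis[i - 1])
        ca = _place(atoms[-2], atoms[-1], n, _B_N_CA, _A_C_N_CA, 180.0)
        c = _place(atoms[-1], n, ca, _B_CA_C, _A_N_CA_C, phis[i])
        atoms.extend([n, ca, c])
    return [(atoms[3 * i], atoms[3 * i + 1], atoms[3 * i + 2]) for i in range(L)]


def _finish_residues(seq: str, backbone) -> list[Residue]:
    residues = []
    L = len(seq)
    for i, (n, ca, c) in enumerate(backbone):
        n_next = backbone[i + 1][0] if i < L - 1 else None
        if n_next is not None:
            o = _place(n, ca, c, 1.231, 120.5, 180.0 + _dihedral4(n, ca, c, n_next))
        else:
            o = _place(n, ca, c, 1.231, 120.5, 0.0)
        cb = None
        if seq[i] != "G":
            cb = _place(c, n, ca, 1.53, 110.5, -122.5)
        residues.append(Residue(seq[i], i + 1, N=n, CA=ca, C=c, O=o, CB=cb))
    return residues


def _dihedral4(p0, p1, p2, p3) -> float:
    from .structures import dihedral_angle

    return dihedral_angle(p0, p1, p2, p3)


def make_native(length: int, fold: str = "helix", seed: int = 0) -> Structure:
    """Deterministic toy native: ideal alpha-helix or compact self-avoiding trace.

    The helix uses phi = -57, psi = -47 with standard backbone bond geometry.
    The mixed fold draws a seeded self-avoiding compact CA walk (3.8 A steps)
    and rebuilds an approximate backbone around it.
    """
    if length < 10:
        raise ValueError("native length must be >= 10")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(_AA), size=length))
    if fold == "helix":
        phis = np.full(length, -57.0)
        psis = np.full(length, -47.0)
        backbone = _build_backbone(phis, psis)
    elif fold == "mixed":
        ca = _compact_trace(length, rng)
        backbone = _backbone_from_trace(ca)
    else:
        raise ValueError("fold must be 'helix' or 'mixed'")
    return Structure(f"synthetic_{fold}_{length}_{seed}", _finish_residues(seq, backbone))


def _compact_trace(length: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding CA walk with 3.8 A steps biased toward the centroid."""
    target_radius = 3.0 * length ** (1.0 / 3.0)
    pts = [np.zeros(3)]
    direction = np.array([1.0, 0.0, 0.0])
    while len(pts) < length:
        for _attempt in range(200):
            step = direction + 0.9 * rng.normal(size=3)
            centroid = np.mean(pts, axis=0)
            if np.linalg.norm(pts[-1] - centroid) > target_radius:
                step += 0.8 * (centroid - pts[-1]) / np.linalg.norm(centroid - pts[-1])
            step /= np.linalg.norm(step)
            cand = pts[-1] + 3.8 * step
            d = np.linalg.norm(np.array(pts[:-1]) - cand, axis=1) if len(pts) > 1 else np.array([9.9])
            if d.min() >= 3.6:
                pts.append(cand)
                direction = step
                break
        else:  # stuck: restart the walk deterministically from the same rng
            pts = [np.zeros(3)]
            direction = np.array([1.0, 0.0, 0.0])
    return np.array(pts)


def _backbone_from_trace(ca: np.ndarray) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Approximate N/C placement around a CA trace (geometry is not ideal)."""
    L = len(ca)
    backbone = []
    ref = np.array([0.0, 0.0, 1.0])
    for i in range(L):
        prev_ca = ca[i - 1] if i > 0 else ca[i] - (ca[i + 1] - ca[i])
        next_ca = ca[i + 1] if i < L - 1 else ca[i] + (ca[i] - ca[i - 1])
        t = next_ca - prev_ca
        t /= np.linalg.norm(t)
        n_perp = np.cross(t, ref)
        if np.linalg.norm(n_perp) < 1e-6:
            n_perp = np.cross(t, np.array([0.0, 1.0, 0.0]))
        n_perp /= np.linalg.norm(n_perp)
        n_dir = -(t + 0.6 * n_perp)
        c_dir = t - 0.6 * n_perp
        n_atom = ca[i] + _B_N_CA * n_dir / np.linalg.norm(n_dir)
        c_atom = ca[i] + _B_CA_C * c_dir / np.linalg.norm(c_dir)
        backbone.append((n_atom, ca[i], c_atom))
    return backbone


def perturb_decoys(
    native: Structure,
    n: int,
    sigma_range: tuple[float, float] = (0.0, 6.0),
    seed: int = 0,
    metric: str = "gdt_ts",
) -> DecoySet:
    """Decoy ensemble by per-decoy Gaussian coordinate noise.

    For each decoy a noise scale sigma is drawn uniformly from
    ``sigma_range`` (Angstrom) and every stored atom is displaced by
    independent zero-mean Gaussian noise of that scale; true qualities are
    computed against the native with the chosen metric.
    """
    if n < 2:
        raise ValueError("need n >= 2 decoys")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n - 1)))
    decoys: list[tuple[str, Structure]] = []
    quality: dict[str, float] = {}
    for i in range(n):
        sigma = float(rng.uniform(*sigma_range))
        residues = []
        for r in native.residues:
            kw = {}
            for name in ("N", "CA", "C", "O", "CB"):
                xyz = getattr(r, name)
                kw[name] = None if xyz is None else xyz + sigma * rng.normal(size=3)
            residues.append(Residue(r.aa, r.seq_pos, **kw))
        decoy_id = f"d{i:0{width}d}"
        s = Structure(native.target_id, residues)
        decoys.append((decoy_id, s))
        quality[decoy_id] = similarity(s, native, metric).value
    return DecoySet(target_id=native.target_id, decoys=decoys, native=native,
                    true_quality=quality)


# ---------------------------------------------------------------------------
# Feature benchmarks


@dataclass
class FeatureSpec:
    """One simulated feature: value = slope * q + offset(target) + noise."""

    name: str
    slope: float
    noise_sd: float
    offset_sd: float = 0.0


def default_feature_spec(
    n_features: int = 8,
    pmcc_range: tuple[float, float] = (0.3, 0.9),
    q_sd: float = 90.0 / math.sqrt(12.0),
    offset_scale: float = 1.5,
) -> list[FeatureSpec]:
    """Features whose within-target |PMCC| with quality spans ``pmcc_range``.

    Half the features carry negative slope (potential-like, lower is
    better).  noise_sd is solved from the requested correlation:
    sd = |a| * sd(q) * sqrt(1/rho^2 - 1).  Per-target offsets have standard
    deviation ``offset_scale * |a| * sd(q)``, emulating the dominant
    target-level component of real potential scores.
    """
    rhos = np.linspace(pmcc_range[0], pmcc_range[1], n_features)
    specs = []
    for j, rho in enumerate(rhos):
        a = 1.0 if j % 2 == 0 else -1.0
        noise = abs(a) * q_sd * math.sqrt(1.0 / rho**2 - 1.0)
        specs.append(
            FeatureSpec(
                name=f"f{j}_rho{rho:.2f}",
                slope=a,
                noise_sd=noise,
                offset_sd=offset_scale * abs(a) * q_sd,
            )
        )
    return specs


@dataclass
class SyntheticBenchmark:
    """A reproducible multi-target benchmark for the ranking pipeline."""

    decoy_sets: list[DecoySet]
    feature_matrices: dict[str, FeatureMatrix]
    latent_quality: dict[str, dict[str, float]]     # target -> decoy -> q
    native_features: dict[str, np.ndarray]
    generator_params: dict

    @property
    def target_ids(self) -> list[str]:
        return sorted(self.feature_matrices)

    def ranking_sets(self) -> list[tuple[FeatureMatrix, dict[str, float]]]:
        return [(self.feature_matrices[t], self.latent_quality[t]) for t in self.target_ids]

    def classification_sets(self) -> list[tuple[FeatureMatrix, np.ndarray]]:
        return [(self.feature_matrices[t], self.native_features[t]) for t in self.target_ids]


def _features_from_quality(
    q: np.ndarray, specs: Sequence[FeatureSpec], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated feature block for one target; returns (values, native_row)."""
    offsets = np.array([rng.normal(0.0, s.offset_sd) if s.offset_sd else 0.0 for s in specs])
    values = np.empty((len(q), len(specs)))
    for j, s in enumerate(specs):
        values[:, j] = s.slope * q + offsets[j] + rng.normal(0.0, s.noise_sd, size=len(q))
    native_row = np.array(
        [s.slope * 100.0 + offsets[j] + rng.normal(0.0, s.noise_sd) for j, s in enumerate(specs)]
    )
    return values, native_row


def simulate_feature_benchmark(
    n_targets: int = 40,
    n_decoys: int = 100,
    feature_spec: Sequence[FeatureSpec] | None = None,
    seed: int = 0,
    q_range: tuple[float, float] = (5.0, 95.0),
) -> SyntheticBenchmark:
    """Structure-free ranking benchmark: latent quality plus noisy features.

    Latent quality is uniform on ``q_range`` (GDT_TS scale).  No structures
    are generated; only feature matrices, latent qualities and a native
    feature row (at q = 100) per target.
    """
    specs = list(feature_spec) if feature_spec is not None else default_feature_spec()
    if all(s.slope == 0 for s in specs):
        import warnings

        warnings.warn("all feature slopes are zero: benchmark carries no signal")
    rng = np.random.default_rng(seed)
    fms: dict[str, FeatureMatrix] = {}
    latent: dict[str, dict[str, float]] = {}
    natives: dict[str, np.ndarray] = {}
    width = max(2, len(str(n_decoys - 1)))
    for t in range(n_targets):
        tid = f"T{t:04d}"
        q = rng.uniform(*q_range, size=n_decoys)
        values, native_row = _features_from_quality(q, specs, rng)
        ids = [f"d{i:0{width}d}" for i in range(n_decoys)]
        fms[tid] = FeatureMatrix(
            target_id=tid, decoy_ids=ids,
            feature_names=[s.name for s in specs], values=values,
            orientation={s.name: ("higher_better" if s.slope >= 0 else "lower_better")
                         for s in specs},
        )
        latent[tid] = dict(zip(ids, q.astype(float)))
        natives[tid] = native_row
    return SyntheticBenchmark(
        decoy_sets=[],
        feature_matrices=fms,
        latent_quality=latent,
        native_features=natives,
        generator_params={
            "n_targets": n_targets, "n_decoys": n_decoys, "seed": seed,
            "q_range": q_range,
            "feature_spec": [(s.name, s.slope, s.noise_sd, s.offset_sd) for s in specs],
        },
    )


def make_structural_benchmark(
    n_targets: int = 8,
    n_decoys: int = 25,
    length: int = 40,
    sigma_range: tuple[float, float] = (0.0, 6.0),
    feature_spec: Sequence[FeatureSpec] | None = None,
    seed: int = 0,
    metric: str = "gdt_ts",
) -> SyntheticBenchmark:
    """Benchmark with real decoy structures and quality-linked features.

    Natives alternate helix / mixed folds; decoys come from
    :func:`perturb_decoys`; true quality is the similarity to the native on
    the chosen metric; features follow the same model as
    :func:`simulate_feature_benchmark` but are driven by the true structural
    quality, so the feature-based ranking and the structure-based quasi
    re-scoring operate on consistent ground truth.
    """
    specs = list(feature_spec) if feature_spec is not None else default_feature_spec()
    rng = np.random.default_rng(seed)
    decoy_sets: list[DecoySet] = []
    fms: dict[str, FeatureMatrix] = {}
    latent: dict[str, dict[str, float]] = {}
    natives: dict[str, np.ndarray] = {}
    for t in range(n_targets):
        fold = "helix" if t % 2 == 0 else "mixed"
        sub = int(rng.integers(0, 2**31 - 1))
        native = make_native(length, fold=fold, seed=sub)
        native.target_id = f"T{t:04d}"
        ds = perturb_decoys(native, n_decoys, sigma_range,
                            seed=int(rng.integers(0, 2**31 - 1)), metric=metric)
        q = np.array([ds.true_quality[d] for d in ds.decoy_ids])
        values, native_row = _features_from_quality(q, specs, rng)
        fms[ds.target_id] = FeatureMatrix(
            target_id=ds.target_id, decoy_ids=list(ds.decoy_ids),
            feature_names=[s.name for s in specs], values=values,
        )
        latent[ds.target_id] = dict(ds.true_quality)
        natives[ds.target_id] = native_row
        decoy_sets.append(ds)
    return SyntheticBenchmark(
        decoy_sets=decoy_sets,
        feature_matrices=fms,
        latent_quality=latent,
        native_features=natives,
        generator_params={
            "n_targets": n_targets, "n_decoys": n_decoys, "length": length,
            "sigma_range": sigma_range, "seed": seed, "metric": metric,
            "feature_spec": [(s.name, s.slope, s.noise_sd, s.offset_sd) for s in specs],
        },
    )
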
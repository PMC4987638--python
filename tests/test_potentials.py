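"""Knowledge-based potentials: tally oracles, symmetry, invariances."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from mqaprank.potentials import (
    AMINO_ACIDS,
    DihedralTable,
    PairPotentialTable,
    default_bin_edges,
    dihedral_energy,
    interaction_centers,
    pair_potential_energy,
    train_dihedral_table,
    train_pair_potential,
)
from mqaprank.structures import Residue, Structure, backbone_dihedrals
from mqaprank.synthetic import make_native, perturb_decoys

from conftest import random_rotation


class TestDihedralTable:
    def test_helix_training_puts_minimum_in_helix_bin(self):
        helices = [make_native(25, "helix", seed=i) for i in range(3)]
        table = train_dihedral_table(helices, bin_width=20.0, pseudocount=1.0)
        bp = table.bin_of(-57.0)
        bs = table.bin_of(-47.0)
        for aa in set("".join(h.sequence for h in helices)):
            i = AMINO_ACIDS.index(aa)
            if table.counts[i].sum() == 0:
                continue
            assert table.scores[i, bp, bs] == table.scores[i].min()

    def test_empty_bins_finite_with_pseudocount(self):
        table = train_dihedral_table([make_native(20, "helix", seed=0)])
        assert np.all(np.isfinite(table.scores))

    def test_matches_direct_tally_oracle(self):
        """Scores equal a hand tally of -ln[(n_ab+q)/(n_a+q*B)] (B = joint bins)."""
        structures = [make_native(15, "mixed", seed=s) for s in (1, 2, 3)]
        q, bw = 1.0, 20.0
        table = train_dihedral_table(structures, bin_width=bw, pseudocount=q)
        # independent tally with plain dicts
        tally: dict[tuple, int] = {}
        for s in structures:
            for r, (phi, psi) in zip(s.residues, backbone_dihedrals(s)):
                if phi is None or psi is None:
                    continue
                bp = min(int((phi + 180) / bw), 17)
                bs = min(int((psi + 180) / bw), 17)
                tally[(r.aa, bp, bs)] = tally.get((r.aa, bp, bs), 0) + 1
        for (aa, bp, bs), n_ab in tally.items():
            n_a = sum(v for (a, _, _), v in tally.items() if a == aa)
            expected = -math.log((n_ab + q) / (n_a + q * 18 * 18))
            assert table.scores[AMINO_ACIDS.index(aa), bp, bs] == pytest.approx(
                expected, abs=1e-12
            )
        # unobserved bin for an observed amino acid: maximally unfavorable
        aa0 = structures[0].residues[1].aa
        i = AMINO_ACIDS.index(aa0)
        assert table.scores[i].max() == pytest.approx(
            -math.log(q / (table.counts[i].sum() + q * 18 * 18)), abs=1e-12
        )

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_dihedral_table([])

    def test_round_trip_serialization(self, tmp_path):
        table = train_dihedral_table([make_native(20, "helix", seed=0)])
        table.save(tmp_path / "dih.txt")
        back = DihedralTable.load(tmp_path / "dih.txt")
        np.testing.assert_allclose(back.scores, table.scores, rtol=1e-10)
        assert back.bin_width == table.bin_width


class TestDihedralEnergy:
    def test_helix_scores_below_perturbed_torsions(self):
        helices = [make_native(25, "helix", seed=i) for i in range(4)]
        table = train_dihedral_table(helices)
        clean = make_native(25, "helix", seed=99)
        scrambled = perturb_decoys(clean, 2, (3.0, 3.0), seed=7).decoys[0][1]
        assert dihedral_energy(clean, table) < dihedral_energy(scrambled, table)

    def test_rigid_motion_invariant(self, helix30, rng):
        table = train_dihedral_table([helix30])
        e0 = dihedral_energy(helix30, table)
        moved = helix30.transformed(random_rotation(rng), rng.normal(size=3) * 8.0)
        assert dihedral_energy(moved, table) == pytest.approx(e0, abs=1e-9)

    def test_short_structure_rejected(self, helix30):
        table = train_dihedral_table([helix30])
        short = Structure("s", helix30.residues[:2])
        with pytest.raises(ValueError):
            dihedral_energy(short, table)


def _random_point_structures(n_struct, length, box, rng):
    """Dense uniform-random 'structures' (CA=CB at uniform points in a box)."""
    out = []
    for _ in range(n_struct):
        residues = []
        for i in range(length):
            p = rng.uniform(0, box, size=3)
            aa = "A"
            residues.append(Residue(aa, i + 1, N=p.copy(), CA=p.copy(), C=p.copy(), CB=p.copy()))
        out.append(Structure("unif", residues))
    return out


class TestPairPotential:
    def test_symmetry_in_residue_types(self):
        structures = [make_native(30, "mixed", seed=s) for s in (0, 1)]
        table = train_pair_potential(structures)
        np.testing.assert_allclose(
            table.scores, np.swapaxes(table.scores, 0, 1), atol=0
        )

    def test_matches_direct_tally_oracle(self):
        """Scores equal -ln[(N_b+q)/((r_b/r_cut)^a (dr_b/dr_cut)(N_cut+q))] hand-computed."""
        structures = [make_native(20, "mixed", seed=s) for s in (5, 6)]
        edges = np.arange(0.0, 15.0, 1.0)
        alpha, q, msep = 1.61, 0.5, 2
        table = train_pair_potential(structures, edges, alpha, msep, q)
        # independent tally
        nb = len(edges) - 1
        counts: dict[tuple, float] = {}
        for s in structures:
            centers = interaction_centers(s)
            for i in range(len(s)):
                for j in range(i + 1, len(s)):
                    if abs(s.residues[i].seq_pos - s.residues[j].seq_pos) < msep:
                        continue
                    r = float(np.linalg.norm(centers[i] - centers[j]))
                    if r >= edges[-1]:
                        continue
                    b = min(int(np.searchsorted(edges, r, side="right")) - 1, nb - 1)
                    for key in [
                        (s.residues[i].aa, s.residues[j].aa, b),
                        (s.residues[j].aa, s.residues[i].aa, b),
                    ]:
                        counts[key] = counts.get(key, 0) + 1
        mids = 0.5 * (edges[:-1] + edges[1:])
        widths = np.diff(edges)
        for a1 in set(structures[0].sequence):
            for a2 in set(structures[0].sequence):
                i1, i2 = AMINO_ACIDS.index(a1), AMINO_ACIDS.index(a2)
                ncut = counts.get((a1, a2, nb - 1), 0)
                for b in range(nb):
                    n_b = counts.get((a1, a2, b), 0)
                    ref = (mids[b] / mids[-1]) ** alpha * (widths[b] / widths[-1])
                    expected = -math.log((n_b + q) / (ref * (ncut + q)))
                    assert table.scores[i1, i2, b] == pytest.approx(expected, abs=1e-10)

    def test_uniform_density_scores_near_zero_with_alpha_two(self, rng):
        """At uniform 3-D density the r^2 reference absorbs the distance
        dependence, so every bin scores ~0 (box much larger than r_cut to
        keep boundary truncation small)."""
        structures = _random_point_structures(150, 300, box=60.0, rng=rng)
        edges = np.arange(1.0, 5.0, 1.0)
        table = train_pair_potential(structures, edges, alpha=2.0, min_separation=2,
                                     pseudocount=0.5)
        i = AMINO_ACIDS.index("A")
        assert np.all(np.abs(table.scores[i, i]) < 0.1)

    def test_energy_matches_bruteforce_double_loop(self):
        structures = [make_native(25, "mixed", seed=s) for s in (0, 1)]
        table = train_pair_potential(structures)
        decoy = perturb_decoys(structures[0], 2, (2.0, 2.0), seed=3).decoys[0][1]
        expected = 0.0
        centers = interaction_centers(decoy)
        nb = table.scores.shape[2]
        for i in range(len(decoy)):
            for j in range(i + 1, len(decoy)):
                if abs(decoy.residues[i].seq_pos - decoy.residues[j].seq_pos) < table.min_separation:
                    continue
                r = float(np.linalg.norm(centers[i] - centers[j]))
                if r >= table.r_cut:
                    continue
                b = min(int(np.searchsorted(table.bin_edges, r, side="right")) - 1, nb - 1)
                expected += table.scores[
                    AMINO_ACIDS.index(decoy.residues[i].aa),
                    AMINO_ACIDS.index(decoy.residues[j].aa),
                    b,
                ]
        assert pair_potential_energy(decoy, table) == pytest.approx(expected, rel=1e-12)

    def test_all_pairs_beyond_cutoff_give_zero(self):
        residues = [
            Residue("A", i + 1, N=np.array([50.0 * i, 0, 0]), CA=np.array([50.0 * i, 1, 0]),
                    C=np.array([50.0 * i, 2, 0]), CB=np.array([50.0 * i, 3, 0]))
            for i in range(5)
        ]
        s = Structure("sparse", residues)
        table = train_pair_potential([make_native(20, "helix", seed=0)])
        assert pair_potential_energy(s, table) == 0.0

    def test_rigid_motion_invariant(self, mixed40, rng):
        table = train_pair_potential([mixed40])
        e0 = pair_potential_energy(mixed40, table)
        moved = mixed40.transformed(random_rotation(rng), rng.normal(size=3) * 15.0)
        assert pair_potential_energy(moved, table) == pytest.approx(e0, abs=1e-9)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            train_pair_potential([])
        with pytest.raises(ValueError):
            train_pair_potential([make_native(20, "helix", seed=0)],
                                 bin_edges=np.array([3.0, 2.0, 1.0]))

    def test_round_trip_serialization(self, tmp_path):
        table = train_pair_potential([make_native(20, "mixed", seed=1)])
        table.save(tmp_path / "pair.txt")
        back = PairPotentialTable.load(tmp_path / "pair.txt")
        np.testing.assert_allclose(back.scores, table.scores, rtol=1e-10)
        assert back.alpha == table.alpha
        assert back.min_separation == table.min_separation


class TestQualityCorrelation:
    @pytest.mark.parametrize(
        "potential,sigma_max",
        [
            # torsion bins fully decorrelate beyond ~1.5 A of coordinate
            # noise, so the single-body potential is probed below saturation
            ("dihedral", 1.5),
            ("pair", 5.0),
        ],
    )
    def test_energies_increase_with_perturbation_magnitude(self, potential, sigma_max):
        """Both potentials correlate positively with decoy perturbation size."""
        training = [make_native(30, f, seed=s) for f in ("helix", "mixed") for s in range(3)]
        if potential == "dihedral":
            table = train_dihedral_table(training)
            energy = dihedral_energy
        else:
            table = train_pair_potential(training)
            energy = pair_potential_energy
        native = make_native(30, "helix", seed=50)
        rng = np.random.default_rng(42)
        sigmas, energies = [], []
        for k in range(100):
            sigma = float(rng.uniform(0.05, sigma_max))
            ds = perturb_decoys(native, 2, (sigma, sigma), seed=1000 + k)
            sigmas.append(sigma)
            energies.append(energy(ds.decoys[0][1], table))
        rho, p = spearmanr(sigmas, energies)
        assert rho > 0
        assert p < 0.01
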
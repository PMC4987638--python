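"""Train the two knowledge-based potentials and assemble a feature matrix.

Trains the dihedral-propensity and pair-distance potentials on a small set
of toy structures, then scores a decoy ensemble and assembles a per-decoy
feature matrix.  Lower potential energy means more native-like geometry.
"""

from mqaprank import train_dihedral_table, train_pair_potential
from mqaprank.features import assemble_features, potential_provider
from mqaprank.synthetic import make_native, perturb_decoys

training = [make_native(30, fold, seed=s) for fold in ("helix", "mixed") for s in range(3)]
dih = train_dihedral_table(training)
pair = train_pair_potential(training)

native = make_native(30, "helix", seed=99)
ds = perturb_decoys(native, n=6, sigma_range=(0.0, 4.0), seed=5)
fm = assemble_features(ds, [potential_provider(dih, pair)])

print(f"{'decoy':>6}  {'true GDT':>8}  {'dih':>8}  {'pair':>9}")
for i, d in enumerate(fm.decoy_ids):
    print(f"{d:>6}  {ds.true_quality[d]:8.1f}  "
          f"{fm.values[i, 0]:8.2f}  {fm.values[i, 1]:9.2f}")
print("\nBoth potentials are oriented lower-is-better: energies rise as the "
      "true GDT_TS falls.")
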
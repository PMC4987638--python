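"""Compare a perturbed decoy against its native with GDT_TS and TM-score.

Builds a 30-residue toy native, makes five decoys of increasing coordinate
noise, and prints both similarity values: GDT_TS on the 0-100 scale and
TM-score on (0, 1].  Both should decrease as the noise grows.
"""

from mqaprank import gdt_ts, tm_score
from mqaprank.synthetic import make_native, perturb_decoys

native = make_native(30, fold="mixed", seed=1)
ds = perturb_decoys(native, n=5, sigma_range=(0.0, 5.0), seed=2)

print(f"native: {native.target_id}, {len(native)} residues")
print(f"{'decoy':>6}  {'GDT_TS':>7}  {'TM':>6}")
for decoy_id, s in ds.decoys:
    g = gdt_ts(s, native)
    t = tm_score(s, native)
    print(f"{decoy_id:>6}  {g.value:7.2f}  {t.value:6.3f}")
print("\nHigher = closer to the native; GDT_TS > 50 / TM > 0.5 is a 'good' model.")
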
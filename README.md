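# mqaprank

Learning-to-rank quality assessment for protein structure decoys.

Protein structure prediction produces many candidate 3D models ("decoys")
per target sequence, spanning a wide accuracy range. Model quality
assessment (MQA) is the problem of ranking those decoys — and picking the
best one — *without* the native structure. `mqaprank` implements a
single-model method based on pairwise learning-to-rank, a quasi
single-model extension that re-scores decoys by similarity to the top-ranked
reference models, the structure similarity metrics the rankings are
evaluated against, a self-contained feature layer, and the full CASP-style
evaluation suite. It is aimed at structural bioinformaticians who want a
transparent, fully reproducible MQA stack that runs on synthetic or real
decoy sets from the command line or from Python.

## The method

Each decoy d of target t is described by a feature vector Φ(t, d):
knowledge-based potential energies computed from the model itself
(a backbone-dihedral propensity potential and a distance potential with a
distance-scaled ideal-gas reference state), agreement features between
model properties and externally predicted secondary structure / solvent
accessibility, and optional score columns from other assessment programs.

Ranking is learned from intra-target decoy pairs. For q(d_i) > q(d_j) the
difference vector x_k = Φ(t,d_i) − Φ(t,d_j) receives label +1, and a linear
scorer f(d) = ω·Φ(t,d) is trained by solving

    min  ½‖ω‖² + C Σ_k ξ_k    s.t.   ω·x_k ≥ 1 − ξ_k,   ξ_k ≥ 0,

the classic ranking-via-classification reduction (hinge loss on difference
vectors). Differencing cancels per-target offsets — the dominant nuisance
in potential-like features — which is what lets the pairwise ranker beat
pointwise regression and native-vs-decoy classification trained on the same
features. The quasi single-model step takes the top-5 ranked decoys as
references and re-scores every decoy by its mean GDT_TS (or TM-score) to
them.

True quality is measured by CA-based superposition metrics: GDT_TS
(25·Σ_c N_c / L_N over cutoffs 1/2/4/8 Å, scale 0–100) and TM-score
((1/L_N) Σ 1/(1+(d_i/d0)²) maximized over superpositions, scale (0,1]).
Predictors are assessed with wmPMCC (per-target Pearson r combined through
Fisher's z), pooled PMCC, ROC/AUC under the good-model rule (GDT_TS > 50),
Loss (quality forfeited by the predicted-best choice), Top, and paired
t-tests between methods. See `docs/methods.md` for the full specification.

## Worked example

Everything runs on synthetic data with no downloads. End to end from the
shell:

```sh
mqaprank simulate --targets 8 --decoys 25 --length 40 --seed 1 --out run/
mqaprank train    --features run/features.tsv --quality run/truth.tsv \
                  --cv 5 --seed 1 --out run/model.txt
mqaprank rank     --model run/model.txt --features run/features.tsv \
                  --out run/scores.tsv
mqaprank quasi    --decoys run/decoys/T0000 --scores run/scores.tsv \
                  --k 5 --metric gdt_ts --out run/quasi_T0000.tsv
mqaprank eval     --scores run/scores.tsv --truth run/truth.tsv \
                  --basis gdt_ts --out run/report.tsv
```

or in one step, `mqaprank run --config config.yaml`. From Python
(`examples/03_rank_and_quasi.py`):

```text
trained on 5 targets, 8 feature weights

 target   r(rank-SVM)   r(quasi)
  T0005         0.938      0.989
  T0006         0.898      0.987
```

The first column is the per-target Pearson correlation between the
rank-SVM's raw scores and the true GDT_TS on held-out targets (a competent
but imperfect feature-based ranking); the second is the same correlation
after quasi re-scoring, which is near-perfect because the top-5 references
are near-native, so mean similarity-to-references approximates
similarity-to-native. The other scripts in `examples/` demonstrate the
similarity metrics, the trainable potentials, and the evaluation report.

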
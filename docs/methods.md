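# Methods

`mqaprank` estimates the quality of protein structure decoys — candidate 3D
models predicted for a target sequence — without access to the native
structure, by learning to *rank* decoys rather than to score them in
isolation. This note documents the models, numerical choices and synthetic
study designs the package implements, and what its tests do and do not show
about real data.

## Structure similarity metrics

Decoy quality is defined against the native structure with two standard
superposition metrics computed on CA atoms under a 1:1 positional residue
correspondence (decoys share the target sequence, so the i-th complete
residue of the model corresponds to the i-th of the native; author numbering
is discarded at parse time).

**TM-score.** `TM = max over superpositions of (1/L_N) Σ_i 1/(1+(d_i/d0)²)`
with `L_N` the native length, `d_i` the i-th aligned CA distance, and the
length-dependent scale `d0 = max(0.5, 1.24 (L_N−15)^(1/3) − 1.8)` Å, the
de facto convention for this metric. Range (0, 1]; self-comparison is
exactly 1.

**GDT_TS.** For cutoffs c ∈ {1, 2, 4, 8} Å, `N_c` is the largest number of
residues simultaneously fitting within c Å of the native under some rigid
superposition; `GDT_TS = 25 Σ_c N_c / L_N` on the 0–100 scale.

**Maximal-substructure search.** Both metrics require maximizing over
superpositions. The package uses an LGA-style seeded refinement: initial
superpositions are least-squares fits (Kabsch, proper rotations enforced) of
sliding windows of the chain plus the full chain; each seed alternates
"superpose on the current inlier set" / "recompute inliers within the
cutoff" to a fixed point (≤ 20 iterations, minimum 3 inliers kept via the
smallest distances), and every superposition visited is scored against all
cutoffs. For chains of ≤ 32 residues every window length is seeded —
exhaustive seeding is affordable there and makes the search provably equal
to an all-fragment reference search, which the test-suite checks. Longer
chains use a geometric ladder of window lengths (3, 5, 7, 10, 15, …, ×1.5),
a sparse set that keeps the cost near-linear in chain length; a ladder
restricted to lengths {3, 5, 7} was tried first and measurably missed optima
found by intermediate-length windows, which is why the ladder extends
upward. The per-cutoff counts are taken as maxima over *all* visited
superpositions, which also guarantees `N_1 ≤ N_2 ≤ N_4 ≤ N_8` by
construction. All search steps are batched over seeds with stacked 3×3
SVDs, so one comparison of 40-residue chains takes ~30 ms.

## Knowledge-based potentials

Two trainable inverse-Boltzmann pseudo-energies provide structure-only
features; both are rigid-motion invariant and oriented lower-is-better.

**Dihedral propensity (single-body).** Backbone (φ, ψ) torsions are binned
on a 20°×20° grid (18×18 joint bins). The score of amino acid *a* in joint
bin *b* is the smoothed negative log conditional propensity
`−ln[(n(a,b)+q)/(n(a)+qB)]` with pseudocount q = 1 and B = 324 joint bins.
A bin never observed for an amino acid is maximally unfavorable but finite.
(A normalization by the bin marginal — an odds-ratio form — was considered
and rejected: with it, bins absent from training score as *favorable*,
inverting the potential's meaning for out-of-distribution torsions.) The
decoy energy is the sum over residues with defined (φ, ψ).

**Pair distance potential (two-body).** Interaction centers are CB (CA for
glycine; an ideal tetrahedral CB is rebuilt from the backbone frame when the
atom is absent). Distances up to r_cut = 14.5 Å are binned at 0.5 Å; pairs
closer than 2 in sequence are excluded. The reference state is the
distance-scaled finite ideal gas: the score of residue types (i, j) in bin
*b* is `−ln[(N(i,j,b)+q) / ((r_b/r_bcut)^α (Δr_b/Δr_cut) (N(i,j,b_cut)+q))]`
with α = 1.61, pseudocount q = 0.5, `r_b` the bin midpoint and `b_cut` the
outermost bin. All parameters are arguments and are recorded in the
serialized table files. With α = 2 and uniform-density training data every
bin scores ≈ 0, which the tests verify.

## Comparison features

Agreement features compare properties computed on the model against
externally *predicted* properties of the target sequence (predictions are
inputs; no secondary-structure or accessibility predictor is bundled):

- Secondary structure is assigned on the model by Ramachandran windows
  (H: φ∈[−100,−30], ψ∈[−80,−5]; E: φ∈[−180,−40], ψ∈[60,180]; else C;
  termini C). This keys on the same backbone geometry as hydrogen-bond-based
  assignments but is deliberately simpler; its labels are only consumed in
  *agreement fractions* (per-class and total) against the predicted string,
  where systematic assignment style cancels between decoys of one target.
- Solvent accessibility is computed by Shrake–Rupley sphere sampling over
  the stored heavy atoms (N, CA, C, O, CB; probe 1.4 Å; deterministic
  golden-spiral lattice, 240 points/atom by default — per-residue totals
  change by < 1% on doubling). Per-residue areas are normalized by
  theoretical per-amino-acid maxima to relative accessibility, and compared
  with the predicted vector via Pearson correlation and cosine similarity.

External per-decoy scores of other assessment programs are ingested from a
TSV keyed by (target_id, decoy_id); missing cells are imputed with the
target-level column mean (rank-neutral for that feature within the target)
and logged. Optional per-feature z-scoring stores its statistics so scoring
can reproduce the training transform; z-scoring is off by default since the
pairwise ranker is scale-equivariant.

## The ranker

With feature vector Φ(t, d) for decoy d of target t, the scorer is linear:
f(d) = ω·Φ(t, d). Training instances are intra-target ordered pairs: for
q(d_i) > q(d_j) (gap > tie tolerance 10⁻⁶), the difference vector
x_k = Φ(t,d_i) − Φ(t,d_j) gets label +1, and ω solves

    min  V = ½‖ω‖² + C Σ_k ξ_k   s.t.  ω·x_k ≥ 1 − ξ_k,  ξ_k ≥ 0,

hinge-loss classification of difference vectors — the pairwise
ranking-via-classification reduction. Differencing within a target cancels
any per-target additive offset in a feature; this is the decisive property
on potential-like features, whose absolute scale varies far more between
proteins than between decoys of one protein (it is also why the pooled
correlation of a raw potential can be near zero while its per-target
correlation is high).

**Solver.** The primal is minimized directly in weight space with a
Huber-smoothed hinge (quadratic zone of width ε on the margin) and a
continuation schedule ε = 10⁻¹ → 10⁻⁹ with warm starts, each stage by
L-BFGS-B. This is deterministic, needs only matrix–vector products with the
pair matrix, and on instances of ≤ 50 pairs agrees with a generic
constrained-QP solution of the same problem to ~10⁻⁸ in the objective
(tests assert 10⁻⁴). The reported `objective_V` and `slack_sum` are exact
hinge quantities at the returned ω. Pair counts are capped at 5000 per
target by uniform seeded subsampling.

**Hyperparameters.** C is selected by k-fold cross-validation *split by
target* (never by decoy) over the grid {10⁻³…10²}, maximizing held-out
wmPMCC; folds, grid, cap and tie tolerance are all arguments. Ranks are
1-based by descending score with lexicographic decoy_id tie-break; both the
raw score and the reciprocal rank are exported. Evaluation here uses raw
scores: reciprocal rank is a monotone but strongly convex transform that
deflates linear correlation even for a perfect ranking, while selection
metrics (Loss, Top) are identical under either.

**Baselines.** The classification baseline trains a linear hinge classifier
of natives (+1) against all decoys (−1) and scores by decision value; the
regression baseline fits quality directly with a linear ε-insensitive (or
least-squares) regression. Both share the ranker's scoring interface.

## Quasi single-model re-scoring

The top-k decoys of an initial ranking (k = 5 by default) become reference
models; every decoy is re-scored by its mean GDT_TS (or TM-score) to the
references, a reference being compared only to the *other* references —
including self-similarity would pin every reference at the metric maximum
by construction. An explicit reference list can be supplied instead (e.g.
references drawn from a different decoy pool). Only n·k structure
comparisons are made, cached symmetrically. If the initial ranking is
competent, the references are near-native and mean similarity-to-references
approximates similarity-to-native, which is why this step sharpens a good
ranking into near-perfect quality estimates.

## Evaluation statistics

- **wmPMCC**: per-target Pearson r between predicted and observed quality is
  Fisher-transformed (z = arctanh r, with |r| clamped to 1−10⁻⁸), the z
  values are averaged arithmetically, and the mean is transformed back.
  Inverse-variance weighting by (n−3) is available as an option. Targets
  with fewer than 4 decoys, or zero-variance scores, are excluded with a
  warning.
- **Pooled PMCC**: ordinary correlation over all targets' decoys pooled.
- **ROC/AUC**: good models are those with observed GDT_TS strictly above 50
  (TM-score above 0.5). AUC is the Mann–Whitney rank statistic with half
  credit for score ties, which equals the trapezoidal area under the
  reported (FPR, TPR) curve exactly — an identity the tests assert per
  instance.
- **Loss**: per target, max observed quality minus the observed quality of
  the predicted-best decoy; reported per target and as the mean.
- **Top**: number of targets whose predicted-best decoy attains the true
  maximum (any maximizer counts under ties).
- **Method comparison**: two-sided paired Student's t-test on per-target
  correlation differences; all-zero differences give p = 1 by convention.

## Synthetic study designs

The generators make the package testable end-to-end with no downloads; all
are pure functions of their parameters and seed.

**Toy natives.** Ideal α-helices (φ = −57°, ψ = −47°, standard backbone bond
geometry, NeRF chain construction, O and CB placed at ideal positions) or
compact self-avoiding CA walks (3.8 Å steps, centroid bias, 3.6 Å clash
floor) with an approximate rebuilt backbone. The walks are compact (radius
of gyration well under half the extended-chain value) but are not real
folds.

**Decoy ensembles.** Every atom is displaced by iid Gaussian noise with a
per-decoy scale σ drawn uniformly from (0, 6) Å, producing true GDT_TS
values that span both sides of the good-model threshold 50 in a 100-decoy
ensemble. This emulates a benchmark whose per-target quality distribution
is broad and roughly uniform — the regime in which quality assessment
methods are separable — not the tight quality distributions of
competition-style model sets, and Gaussian noise is not a physically
realistic decoy-generation mechanism (no fragment re-assembly, no
compactness preservation at large σ).

**Feature benchmarks.** Latent quality q is uniform on (5, 95) on the
GDT_TS scale; feature j of a decoy is `a_j q + τ_j(target) + N(0, σ_j)`,
where the per-target offset τ_j ~ N(0, 1.5 |a_j| sd(q)) emulates the
dominant target-level component of real potential scores. The default
specification has 8 features with within-target |PMCC| evenly spanning
0.3–0.9 (σ_j solved from the requested correlation), half of them
negatively sloped like potentials. Native feature rows are drawn at
q = 100. The structural benchmark couples the same feature model to real
generated ensembles, with q the true GDT_TS, so feature-based ranking and
structure-based quasi re-scoring share one ground truth.

Because features are linear in quality with Gaussian noise, these
benchmarks *favor* any correctly specified linear method; what they probe
is the relative robustness of the four training objectives to per-target
offsets, not feature engineering. Passing results show the machinery is
correct and that the pairwise reduction confers the expected offset
immunity; they do not certify performance on real decoy sets.

**Benchmark experiments.** `benchmarks.feature_cv_experiment` runs 40
targets × 100 decoys under five-fold CV by target and reports held-out
wmPMCC at the selected C. `benchmarks.method_comparison_experiment` runs 10
replicates of an 8-target × 25-decoy × 40-residue structural benchmark
(5 train / 3 test targets per replicate, C = 1 — CV inside each small
replicate would be underpowered and is exercised separately), and compares
methods by paired t-test on per-target correlations pooled across
replicates, the same pairing unit the CASP-style comparison uses. Problem
sizes were chosen so the full suite runs on a laptop-class single core in a
few minutes.

## Numerical details and edge cases

- Kabsch superposition enforces det(R) = +1 via sign correction of the
  smallest singular vector; degenerate (< 3 point) inputs are rejected.
- Torsions follow the IUPAC sign convention (verified against an
  independent structural library during development); angles lie in
  (−180°, 180°].
- PDB parsing: first MODEL, one chain (first encountered if unspecified),
  altloc blank/'A', HETATM ignored; residues missing any of N/CA/C are
  dropped with a warning and the survivors renumbered 1..L.
- Zero-variance vectors: correlation features are imputed 0 with a warning;
  zero-variance targets are excluded from wmPMCC (configurable at the
  evaluation layer); one-class ROC data yields a missing AUC rather than a
  number.
- Ties: ranking tie-breaks are lexicographic in decoy_id and logged through
  determinism tests; AUC handles score ties by half credit.
- All TSV artifacts carry a manifest header (version, seed, config hash)
  and fixed float formatting, so pipeline reruns with the same config and
  seed are byte-identical.

## Known limitations

- Sequence-identical comparison only: no alignment of non-identical
  sequences, no mmCIF, no multi-chain assemblies.
- The internal algorithms of DFIRE, DOPE, GOAP, RWplus, Frst, ProQ, SIFT
  and SELECTpro are out of scope; their outputs enter as external TSV
  columns.
- The dihedral-window secondary-structure assignment and sphere-sampling
  accessibility are simpler than hydrogen-bond-based assignment and
  analytic surface areas; they are used only inside agreement features.
- Synthetic benchmarks demonstrate correctness and qualitative behavior;
  absolute performance numbers on them do not transfer to real decoy sets.
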
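"""CASP-style assessment of a predictor: wmPMCC, AUC, Loss and Top.

Simulates a feature-only benchmark, scores it with a trained rank-SVM, and
aggregates the full evaluation report.
"""

import numpy as np

from mqaprank import evaluate, score_decoys, train_rank_svm
from mqaprank.ranker import build_training_pairs
from mqaprank.synthetic import simulate_feature_benchmark

bench = simulate_feature_benchmark(n_targets=12, n_decoys=40, seed=8)
sets = bench.ranking_sets()
model = train_rank_svm(build_training_pairs(sets[:8]), C=1.0)

preds, truth = {}, {}
for fm, q in sets[8:]:
    est = score_decoys(model, fm)
    preds[fm.target_id] = dict(zip(est.decoy_ids, est.raw_score))
    truth[fm.target_id] = q

report = evaluate(preds, truth, basis="gdt_ts")
print(f"held-out targets : {report.n_targets}")
print(f"wmPMCC           : {report.wmpmcc:.3f}   (Fisher-z combined per-target r)")
print(f"pooled PMCC      : {report.pooled_pmcc:.3f}")
print(f"AUC (GDT>50 rule): {report.auc:.3f}")
print(f"mean Loss        : {report.mean_loss:.2f}  (GDT_TS points lost by model choice)")
print(f"Top              : {report.top_count} / {report.n_targets} targets")
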
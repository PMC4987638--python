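"""CASP-style assessment statistics for model quality predictors.

Per-target Pearson correlations are combined through the Fisher
z-transformation: z = arctanh(r) per target, the arithmetic mean of the z
values is transformed back with tanh to give the wmPMCC.  Alongside it the
module computes the pooled PMCC over all targets' decoys, ROC/AUC under the
good-model rule (observed GDT_TS > 50, or TM-score > 0.5), the per-target
Loss (quality of the best available decoy minus the quality of the
predicted-best decoy), the Top count (targets whose predicted-best decoy is
a truly best one), and a paired Student's t-test for comparing two methods'
per-target correlations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PerTargetCorrelation",
    "EvaluationReport",
    "fisher_z",
    "fisher_z_inverse",
    "wmpmcc",
    "pooled_pmcc",
    "roc_auc",
    "loss_metric",
    "top_metric",
    "compare_methods",
    "evaluate",
]

_CLAMP = 1.0 - 1e-8


@dataclass
class PerTargetCorrelation:
    target_id: str
    r: float
    n: int

    @property
    def z(self) -> float:
        return fisher_z(self.r)

    @property
    def se(self) -> float:
        if self.n < 4:
            raise ValueError("standard error of z requires n >= 4")
        return 1.0 / math.sqrt(self.n - 3)


@dataclass
class EvaluationReport:
    """Aggregate assessment of one method on one benchmark."""

    metric_basis: str                               # gdt_ts or tm
    per_target: list[PerTargetCorrelation]
    wmpmcc: float
    mean_z: float
    pooled_pmcc: float | None
    auc: float | None
    roc_curve: tuple[np.ndarray, np.ndarray] | None  # (FPR, TPR)
    per_target_loss: dict[str, float]
    mean_loss: float
    top_count: int
    n_targets: int
    good_threshold: float
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Correlation aggregation


def fisher_z(r: float) -> float:
    """Fisher transformation z = arctanh(r), with |r| clamped to 1 - 1e-8."""
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation out of range: {r}")
    r = min(max(r, -_CLAMP), _CLAMP)
    return 0.5 * math.log((1.0 + r) / (1.0 - r))


def fisher_z_inverse(z: float) -> float:
    return math.tanh(z)


def wmpmcc(
    per_target: Sequence[tuple[float, int]], weighted: bool = False
) -> float:
    """Combine per-target correlations through Fisher z.

    ``per_target`` holds (r, n) tuples; targets with n < 4 are excluded with
    a warning.  By default the arithmetic mean of z is used; with
    ``weighted`` the mean is inverse-variance weighted by (n - 3).
    """
    usable = [(r, n) for r, n in per_target if n >= 4]
    if len(usable) < len(per_target):
        warnings.warn(f"excluded {len(per_target) - len(usable)} target(s) with n < 4")
    if not usable:
        raise ValueError("no targets with n >= 4")
    z = np.array([fisher_z(r) for r, _ in usable])
    if weighted:
        w = np.array([n - 3 for _, n in usable], float)
        mean_z = float((w * z).sum() / w.sum())
    else:
        mean_z = float(z.mean())
    return fisher_z_inverse(mean_z)


def pooled_pmcc(predicted: Sequence[float], observed: Sequence[float]) -> float | None:
    """Product-moment correlation over the pooled decoy set; None if undefined."""
    x = np.asarray(predicted, float)
    y = np.asarray(observed, float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("predicted and observed must be equal-length with n >= 3")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance: pooled PMCC undefined, reported as missing")
        return None
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_auc(
    predicted: Sequence[float], observed: Sequence[float], threshold: float
) -> tuple[float | None, tuple[np.ndarray, np.ndarray] | None]:
    """ROC under the good-model rule: observed quality strictly above threshold.

    AUC comes from the Mann-Whitney rank statistic with half credit for
    predicted-score ties, which is exactly the trapezoidal area under the
    returned (FPR, TPR) curve.
    """
    x = np.asarray(predicted, float)
    y = np.asarray(observed, float)
    pos = y > threshold
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn("one-class data after thresholding: AUC undefined")
        return None, None
    ranks = stats.rankdata(x)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    # curve: sweep thresholds over descending unique scores
    order = np.argsort(-x, kind="stable")
    sx, spos = x[order], pos[order]
    tps = np.cumsum(spos)
    fps = np.cumsum(~spos)
    last = np.r_[np.nonzero(np.diff(sx))[0], len(sx) - 1]
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    return float(auc), (fpr, tpr)


# ---------------------------------------------------------------------------
# Best-model selection metrics


def loss_metric(
    per_target: Sequence[tuple[Sequence[float], Sequence[int]]]
) -> tuple[list[float], float]:
    """Loss per target and its mean.

    Each element is (observed qualities, predicted ranking) with ranking
    1-based over the same decoy order; loss = max(observed) - observed at the
    predicted rank-1 decoy.
    """
    losses = []
    for observed, ranking in per_target:
        observed = np.asarray(observed, float)
        ranking = np.asarray(ranking)
        if len(observed) < 1 or len(observed) != len(ranking):
            raise ValueError("observed and ranking must be non-empty and aligned")
        top = int(np.argmin(ranking))
        losses.append(float(observed.max() - observed[top]))
    return losses, float(np.mean(losses))


def top_metric(per_target: Sequence[tuple[Sequence[float], Sequence[int]]]) -> int:
    """Number of targets whose predicted rank-1 decoy attains the true maximum."""
    count = 0
    for observed, ranking in per_target:
        observed = np.asarray(observed, float)
        top = int(np.argmin(np.asarray(ranking)))
        if observed[top] == observed.max():
            count += 1
    return count


# ---------------------------------------------------------------------------
# Method comparison


def compare_methods(
    per_target_r_A: Sequence[float], per_target_r_B: Sequence[float]
) -> tuple[float, float]:
    """Two-sided paired Student's t-test on per-target correlation differences.

    Returns (t, p).  All-zero differences give (0, 1) by convention; a
    constant nonzero difference gives p = 0.
    """
    a = np.asarray(per_target_r_A, float)
    b = np.asarray(per_target_r_B, float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need >= 3 paired targets")
    d = a - b
    if np.all(d == 0):
        warnings.warn("identical per-target correlations: p = 1 by convention")
        return 0.0, 1.0
    if d.std(ddof=1) == 0:
        return math.copysign(math.inf, d.mean()), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Full report


def evaluate(
    predictions: dict[str, dict[str, float]],
    truth: dict[str, dict[str, float]],
    basis: str = "gdt_ts",
    threshold: float | None = None,
    absolute_r: bool = False,
) -> EvaluationReport:
    """Aggregate every assessment statistic for one method.

    ``predictions`` and ``truth`` map target_id -> {decoy_id: value}; keys
    must align.  ``threshold`` defaults to 50 for GDT_TS and 0.5 for
    TM-score.  With ``absolute_r`` the per-target correlations enter as
    absolute values (the convention for evaluating a raw potential, whose
    sign is arbitrary).
    """
    if threshold is None:
        threshold = 50.0 if basis == "gdt_ts" else 0.5
    if set(predictions) != set(truth):
        raise ValueError(
            "target mismatch: "
            f"prediction-only={sorted(set(predictions) - set(truth))}, "
            f"truth-only={sorted(set(truth) - set(predictions))}"
        )
    per_target: list[PerTargetCorrelation] = []
    pooled_pred: list[float] = []
    pooled_obs: list[float] = []
    selection: list[tuple[list[float], list[int]]] = []
    loss_by_target: dict[str, float] = {}
    for tid in sorted(predictions):
        pred_map, obs_map = predictions[tid], truth[tid]
        if set(pred_map) != set(obs_map):
            raise ValueError(
                f"{tid}: decoy mismatch: "
                f"prediction-only={sorted(set(pred_map) - set(obs_map))}, "
                f"truth-only={sorted(set(obs_map) - set(pred_map))}"
            )
        ids = sorted(pred_map)
        pred = np.array([pred_map[d] for d in ids], float)
        obs = np.array([obs_map[d] for d in ids], float)
        pooled_pred.extend(pred)
        pooled_obs.extend(obs)
        ranking = stats.rankdata(-pred, method="ordinal")
        selection.append((list(obs), list(ranking)))
        loss_by_target[tid] = float(obs.max() - obs[int(np.argmin(ranking))])
        if pred.std() == 0 or obs.std() == 0:
            warnings.warn(f"{tid}: zero-variance scores, excluded from wmPMCC")
            continue
        r = float(np.corrcoef(pred, obs)[0, 1])
        if absolute_r:
            r = abs(r)
        per_target.append(PerTargetCorrelation(tid, r, len(ids)))

    w = wmpmcc([(c.r, c.n) for c in per_target])
    mean_z = float(np.mean([c.z for c in per_target]))
    pooled = pooled_pmcc(pooled_pred, pooled_obs)
    auc, curve = roc_auc(pooled_pred, pooled_obs, threshold)
    losses, mean_loss = loss_metric(selection)
    top = top_metric(selection)
    return EvaluationReport(
        metric_basis=basis,
        per_target=per_target,
        wmpmcc=w,
        mean_z=mean_z,
        pooled_pmcc=pooled,
        auc=auc,
        roc_curve=curve,
        per_target_loss=loss_by_target,
        mean_loss=mean_loss,
        top_count=top,
        n_targets=len(predictions),
        good_threshold=threshold,
    )
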
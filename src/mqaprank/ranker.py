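"""Pairwise learning-to-rank core: pair extraction, linear rank-SVM, scoring,
cross-validation and the classification / regression baselines.

Training instances are intra-target ordered decoy pairs: for decoys d_i, d_j
of the same target with true quality q(d_i) > q(d_j), the difference vector
x_k = phi(t, d_i) - phi(t, d_j) receives label +1.  The ranker solves the
soft-margin problem

    minimize   V = 1/2 ||w||^2 + C * sum_k xi_k
    subject to w . x_k >= 1 - xi_k,  xi_k >= 0

i.e. hinge-loss classification of difference vectors with all-positive
labels and no intercept, which is equivalent to an ordinary SVM
classification problem.  Differencing within a target cancels any per-target
offset in a feature, which is what lets the ranker cope with potential-like
features whose absolute scale varies strongly between proteins.

The dual is a box-constrained concave quadratic,

    maximize   sum_k a_k - 1/2 || sum_k a_k x_k ||^2,   0 <= a_k <= C,

solved here deterministically with L-BFGS-B; w = sum_k a_k x_k.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .features import FeatureMatrix

__all__ = [
    "TrainingPairSet",
    "RankModel",
    "QualityEstimate",
    "extract_pairs",
    "merge_pair_sets",
    "build_training_pairs",
    "train_rank_svm",
    "score_decoys",
    "cross_validate",
    "train_classification_baseline",
    "train_regression_baseline",
]


@dataclass
class TrainingPairSet:
    """Oriented intra-target difference vectors, all labelled +1."""

    X: np.ndarray                     # (n_pairs, n_features), better-minus-worse
    target_ids: list[str]
    feature_names: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, float))
        if self.X.size and not np.all(np.isfinite(self.X)):
            raise ValueError("difference vectors must be finite")

    @property
    def n_pairs(self) -> int:
        return 0 if self.X.size == 0 else self.X.shape[0]


@dataclass
class RankModel:
    """Learned linear scorer f(d) = omega . phi(t, d) + intercept."""

    omega: np.ndarray
    feature_names: list[str]
    C: float
    tol: float
    norm_stats: dict[str, tuple[float, float]] | None = None
    objective_V: float = 0.0
    slack_sum: float = 0.0
    seed: int = 0
    intercept: float = 0.0
    kind: str = "rank_svm"

    def save(self, path: str | Path) -> None:
        lines = [
            "# mqaprank-model v1",
            f"kind\t{self.kind}",
            f"C\t{float(self.C)!r}",
            f"tol\t{float(self.tol)!r}",
            f"seed\t{self.seed}",
            f"intercept\t{float(self.intercept)!r}",
            f"objective_V\t{float(self.objective_V)!r}",
            f"slack_sum\t{float(self.slack_sum)!r}",
        ]
        for name, w in zip(self.feature_names, self.omega):
            stats = (self.norm_stats or {}).get(name)
            mu, sd = (f"{stats[0]!r}", f"{stats[1]!r}") if stats else ("", "")
            lines.append(f"w\t{name}\t{float(w)!r}\t{mu}\t{sd}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RankModel":
        lines = Path(path).read_text().splitlines()
        if not lines or lines[0] != "# mqaprank-model v1":
            raise ValueError(f"{path}: not a mqaprank model file")
        meta: dict[str, str] = {}
        names, weights = [], []
        norm_stats: dict[str, tuple[float, float]] = {}
        for line in lines[1:]:
            parts = line.split("\t")
            if parts[0] == "w":
                names.append(parts[1])
                weights.append(float(parts[2]))
                if parts[3] != "":
                    norm_stats[parts[1]] = (float(parts[3]), float(parts[4]))
            else:
                meta[parts[0]] = parts[1]
        return cls(
            omega=np.array(weights),
            feature_names=names,
            C=float(meta["C"]),
            tol=float(meta["tol"]),
            norm_stats=norm_stats or None,
            objective_V=float(meta["objective_V"]),
            slack_sum=float(meta["slack_sum"]),
            seed=int(meta["seed"]),
            intercept=float(meta.get("intercept", 0.0)),
            kind=meta.get("kind", "rank_svm"),
        )


@dataclass
class QualityEstimate:
    """Scores and ranks for the decoys of one target."""

    target_id: str
    decoy_ids: list[str]
    raw_score: np.ndarray
    rank: np.ndarray                  # 1-based, by descending raw_score
    reciprocal_rank: np.ndarray
    quasi_quality: np.ndarray | None = None

    def order(self) -> list[str]:
        """Decoy ids from predicted best to worst."""
        return [self.decoy_ids[i] for i in np.argsort(self.rank)]


# ---------------------------------------------------------------------------
# Pair extraction


def extract_pairs(
    fm: FeatureMatrix,
    true_quality: dict[str, float],
    cap_per_target: int | None = 5000,
    tie_tol: float = 1e-6,
    seed: int = 0,
) -> TrainingPairSet:
    """All oriented intra-target pairs with quality gap > tie_tol.

    The better decoy comes first in each difference vector.  When the pair
    count exceeds ``cap_per_target`` a uniform seeded subsample is taken.
    """
    missing = [d for d in fm.decoy_ids if d not in true_quality]
    if missing:
        raise ValueError(f"{fm.target_id}: no true quality for decoys {missing}")
    if len(fm.decoy_ids) < 2:
        warnings.warn(f"{fm.target_id}: fewer than 2 decoys, no pairs extracted")
        return TrainingPairSet(
            X=np.empty((0, len(fm.feature_names))),
            target_ids=[], feature_names=list(fm.feature_names),
        )
    q = np.array([true_quality[d] for d in fm.decoy_ids], float)
    diffs = []
    for i, j in itertools.combinations(range(len(q)), 2):
        gap = q[i] - q[j]
        if abs(gap) <= tie_tol:
            continue
        if gap > 0:
            diffs.append(fm.values[i] - fm.values[j])
        else:
            diffs.append(fm.values[j] - fm.values[i])
    X = np.array(diffs) if diffs else np.empty((0, len(fm.feature_names)))
    if cap_per_target is not None and len(X) > cap_per_target:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(X), size=cap_per_target, replace=False)
        X = X[np.sort(keep)]
    return TrainingPairSet(
        X=X,
        target_ids=[fm.target_id] * len(X),
        feature_names=list(fm.feature_names),
        provenance={"tie_tol": tie_tol, "cap_per_target": cap_per_target, "seed": seed},
    )


def merge_pair_sets(sets: Sequence[TrainingPairSet]) -> TrainingPairSet:
    sets = [s for s in sets if s.n_pairs]
    if not sets:
        raise ValueError("no non-empty pair sets to merge")
    names = sets[0].feature_names
    for s in sets[1:]:
        if s.feature_names != names:
            raise ValueError("pair sets have mismatched feature names")
    return TrainingPairSet(
        X=np.vstack([s.X for s in sets]),
        target_ids=sum((s.target_ids for s in sets), []),
        feature_names=list(names),
        provenance=sets[0].provenance,
    )


def build_training_pairs(
    sets: Sequence[tuple[FeatureMatrix, dict[str, float]]],
    cap_per_target: int | None = 5000,
    tie_tol: float = 1e-6,
    seed: int = 0,
) -> TrainingPairSet:
    """Extract and merge pairs from several targets."""
    return merge_pair_sets(
        [extract_pairs(fm, q, cap_per_target, tie_tol, seed) for fm, q in sets]
    )


# ---------------------------------------------------------------------------
# Rank-SVM training


def train_rank_svm(ps: TrainingPairSet, C: float = 1.0, tol: float = 1e-6) -> RankModel:
    """Solve the pairwise soft-margin problem on difference vectors.

    The primal objective is minimized directly in weight space with a
    Huber-smoothed hinge and a continuation schedule driving the smoothing
    to zero (final smoothing 1e-9 on the margin), warm-starting each stage.
    The optimization is deterministic; the reported objective is the exact
    hinge objective at the final weights.
    """
    if ps.n_pairs < 1:
        raise ValueError("at least one training pair is required")
    if C <= 0:
        raise ValueError("C must be positive")
    X = ps.X
    n, d = X.shape

    def objective(eps: float):
        def fg(w: np.ndarray):
            u = 1.0 - X @ w  # per-pair hinge argument
            lin = u >= eps
            quad = (u > 0.0) & ~lin
            f = 0.5 * w @ w + C * (
                (u[lin] - eps / 2.0).sum() + (u[quad] ** 2).sum() / (2.0 * eps)
            )
            coef = np.zeros(n)
            coef[lin] = 1.0
            coef[quad] = u[quad] / eps
            return f, w - C * (X.T @ coef)

        return fg

    w = np.zeros(d)
    for eps in (1e-1, 1e-3, 1e-5, 1e-7, 1e-9):
        res = minimize(
            objective(eps), w, jac=True, method="L-BFGS-B",
            options={"maxiter": 5000, "ftol": 1e-18, "gtol": tol * 1e-3},
        )
        w = res.x
    omega = w
    slack = np.maximum(0.0, 1.0 - X @ omega)
    V = 0.5 * omega @ omega + C * slack.sum()
    return RankModel(
        omega=omega,
        feature_names=list(ps.feature_names),
        C=C,
        tol=tol,
        objective_V=float(V),
        slack_sum=float(slack.sum()),
        seed=int(ps.provenance.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# Scoring


def _apply_norm(m: RankModel, fm: FeatureMatrix) -> np.ndarray:
    values = fm.values
    if m.norm_stats:
        cols = []
        for k, name in enumerate(fm.feature_names):
            mu, sd = m.norm_stats[name]
            cols.append((values[:, k] - mu) / sd)
        values = np.stack(cols, axis=1)
    return values


def score_decoys(m: RankModel, fm: FeatureMatrix) -> QualityEstimate:
    """Score f = omega . phi per decoy and rank descending.

    Ties in raw score are broken by lexicographic decoy_id order.
    """
    if list(fm.feature_names) != list(m.feature_names):
        raise ValueError(
            "feature-name mismatch between model and matrix: "
            f"model-only={sorted(set(m.feature_names) - set(fm.feature_names))}, "
            f"matrix-only={sorted(set(fm.feature_names) - set(m.feature_names))}"
        )
    values = _apply_norm(m, fm)
    raw = values @ m.omega + m.intercept
    order = sorted(range(len(raw)), key=lambda i: (-raw[i], fm.decoy_ids[i]))
    rank = np.empty(len(raw), dtype=int)
    for pos, i in enumerate(order, start=1):
        rank[i] = pos
    return QualityEstimate(
        target_id=fm.target_id,
        decoy_ids=list(fm.decoy_ids),
        raw_score=raw,
        rank=rank,
        reciprocal_rank=1.0 / rank,
    )


# ---------------------------------------------------------------------------
# Cross-validation


DEFAULT_C_GRID = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)


def cross_validate(
    sets: Sequence[tuple[FeatureMatrix, dict[str, float]]],
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    n_folds: int = 5,
    seed: int = 0,
    cap_per_target: int | None = 5000,
    tie_tol: float = 1e-6,
    tol: float = 1e-6,
):
    """Target-level k-fold cross-validation over a C grid.

    Folds split by target, never by decoy.  Returns (best_C, table) where the
    table rows are (C, fold, wmpmcc) for every held-out fold; best_C maximizes
    the mean held-out wmPMCC (computed on raw scores).
    """
    from .evaluation import wmpmcc as _wmpmcc
    from scipy.stats import pearsonr

    if len(sets) < n_folds:
        raise ValueError(f"need at least {n_folds} targets for {n_folds}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sets))
    folds = np.array_split(order, n_folds)

    rows = []
    means = {}
    for C in C_grid:
        fold_scores = []
        for f, test_idx in enumerate(folds):
            train_sets = [sets[i] for i in order if i not in set(test_idx)]
            ps = build_training_pairs(train_sets, cap_per_target, tie_tol, seed)
            model = train_rank_svm(ps, C=C, tol=tol)
            per_target = []
            for i in test_idx:
                fm, q = sets[i]
                est = score_decoys(model, fm)
                truth = np.array([q[d] for d in est.decoy_ids])
                if truth.std() == 0 or est.raw_score.std() == 0:
                    continue
                r = float(pearsonr(est.raw_score, truth)[0])
                per_target.append((r, len(truth)))
            w = _wmpmcc(per_target) if per_target else float("nan")
            fold_scores.append(w)
            rows.append({"C": C, "fold": f, "wmpmcc": w})
        means[C] = float(np.nanmean(fold_scores))
    best_C = max(C_grid, key=lambda c: means[c])
    return best_C, rows


# ---------------------------------------------------------------------------
# Baselines


def train_classification_baseline(
    sets: Sequence[tuple[FeatureMatrix, np.ndarray]], C: float = 1.0
) -> RankModel:
    """Native-vs-decoy linear hinge classifier; decision value used as score.

    Each training element is (decoy FeatureMatrix, native feature row).  The
    natives form the positive class, every decoy the negative class.
    """
    from sklearn.svm import LinearSVC

    X_rows, y = [], []
    for fm, native_row in sets:
        native_row = np.asarray(native_row, float)
        if native_row.shape != (len(fm.feature_names),):
            raise ValueError(f"{fm.target_id}: missing or malformed native feature row")
        X_rows.append(native_row)
        y.append(1)
        X_rows.extend(fm.values)
        y.extend([-1] * len(fm.decoy_ids))
    clf = LinearSVC(C=C, loss="hinge", tol=1e-8, max_iter=200000, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # liblinear convergence chatter
        clf.fit(np.array(X_rows), np.array(y))
    return RankModel(
        omega=clf.coef_.ravel().copy(),
        feature_names=list(sets[0][0].feature_names),
        C=C, tol=1e-8,
        intercept=float(clf.intercept_[0]),
        kind="classification_baseline",
    )


def train_regression_baseline(
    sets: Sequence[tuple[FeatureMatrix, dict[str, float]]],
    C: float = 1.0,
    mode: str = "svr",
    epsilon: float = 1.0,
) -> RankModel:
    """Pointwise baseline: regress true quality on features; prediction = score.

    ``mode='svr'`` uses a linear epsilon-insensitive fit, ``mode='ols'`` an
    ordinary least-squares fit.
    """
    X_rows, y = [], []
    for fm, q in sets:
        truth = np.array([q[d] for d in fm.decoy_ids], float)
        if truth.std() == 0:
            warnings.warn(f"{fm.target_id}: constant quality, no ranking signal")
        X_rows.extend(fm.values)
        y.extend(truth)
    X = np.array(X_rows)
    y = np.array(y)
    if mode == "svr":
        from sklearn.svm import LinearSVR

        reg = LinearSVR(C=C, epsilon=epsilon, tol=1e-8, max_iter=200000, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reg.fit(X, y)
        omega, b = reg.coef_.copy(), float(reg.intercept_[0] if np.ndim(reg.intercept_) else reg.intercept_)
    elif mode == "ols":
        from sklearn.linear_model import LinearRegression

        reg = LinearRegression().fit(X, y)
        omega, b = reg.coef_.copy(), float(reg.intercept_)
    else:
        raise ValueError("mode must be 'svr' or 'ols'")
    return RankModel(
        omega=omega,
        feature_names=list(sets[0][0].feature_names),
        C=C, tol=1e-8,
        intercept=b,
        kind="regression_baseline",
    )
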
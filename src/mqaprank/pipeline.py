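"""End-to-end pipeline: simulate -> features -> train -> rank -> quasi -> eval.

Every stage reads and writes tab-separated UTF-8 files with a manifest
header (version, seed, config hash) so a run can be audited and reproduced;
reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import FeatureMatrix
from .ranker import (
    RankModel,
    build_training_pairs,
    cross_validate,
    score_decoys,
    train_rank_svm,
)
from .quasi import quasi_rescore
from .similarity import similarity
from .structures import DecoySet, read_pdb, write_pdb
from .synthetic import make_structural_benchmark
from .evaluation import evaluate

log = logging.getLogger("mqaprank")

__all__ = ["RunConfig", "run_pipeline", "write_tsv", "read_tsv"]

_STAGES = ("simulate", "train", "rank", "quasi", "eval")


@dataclass
class RunConfig:
    """Flat configuration for :func:`run_pipeline`; unknown keys are rejected."""

    workdir: str = "mqaprank_run"
    seed: int = 0
    metric: str = "gdt_ts"
    stages: tuple[str, ...] = _STAGES
    # simulate
    n_targets: int = 8
    n_decoys: int = 25
    length: int = 40
    sigma_min: float = 0.0
    sigma_max: float = 6.0
    # ranker
    c_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)
    n_folds: int = 5
    cap_per_target: int = 5000
    tie_tol: float = 1e-6
    # quasi
    quasi_k: int = 5
    # eval
    good_threshold: float | None = None
    score_column: str = "raw_score"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "c_grid"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["c_grid"] = list(self.c_grid)
        return yaml.safe_dump(d, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths and logging excluded)."""
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["c_grid"] = list(self.c_grid)
        d.pop("workdir")
        d.pop("log_level")
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# TSV I/O with manifest headers


def write_tsv(df: pd.DataFrame, path: str | Path, manifest: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = ""
    if manifest is not None:
        items = " ".join(f"{k}={v}" for k, v in manifest.items())
        header = f"# mqaprank {__version__} {items}\n"
    body = df.to_csv(sep="\t", index=False, float_format="%.10g")
    path.write_text(header + body)


def read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "decoy_id" in df.columns:
        df["decoy_id"] = df["decoy_id"].astype(str)
    if "target_id" in df.columns:
        df["target_id"] = df["target_id"].astype(str)
    return df


def load_decoy_dir(decoy_dir: str | Path) -> DecoySet:
    """Read one target's decoys from a directory of PDB files.

    A file named ``native.pdb`` (if present) becomes the native structure.
    """
    decoy_dir = Path(decoy_dir)
    if not decoy_dir.is_dir():
        raise FileNotFoundError(f"decoy directory not found: {decoy_dir}")
    native = None
    decoys = []
    for p in sorted(decoy_dir.glob("*.pdb")):
        if p.stem == "native":
            native = read_pdb(p, target_id=decoy_dir.name)
        else:
            decoys.append((p.stem, read_pdb(p, target_id=decoy_dir.name)))
    if not decoys:
        raise FileNotFoundError(f"no decoy PDB files in {decoy_dir}")
    return DecoySet(target_id=decoy_dir.name, decoys=decoys, native=native)


def frames_to_sets(
    features: pd.DataFrame, quality: pd.DataFrame, metric_col: str
) -> list[tuple[FeatureMatrix, dict[str, float]]]:
    """Join a long feature table and a truth table into per-target sets."""
    qmap = {
        (row.target_id, row.decoy_id): getattr(row, metric_col)
        for row in quality.itertuples()
    }
    sets = []
    feat_cols = [c for c in features.columns if c not in ("target_id", "decoy_id")]
    for tid, grp in features.groupby("target_id", sort=True):
        grp = grp.sort_values("decoy_id")
        fm = FeatureMatrix(
            target_id=str(tid),
            decoy_ids=list(grp["decoy_id"]),
            feature_names=feat_cols,
            values=grp[feat_cols].to_numpy(float),
        )
        sets.append((fm, {d: qmap[(tid, d)] for d in fm.decoy_ids}))
    return sets


# ---------------------------------------------------------------------------
# Pipeline stages


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns a summary dict.

    Artifacts land under ``config.workdir``: decoy PDBs, ``truth.tsv``,
    ``features.tsv``, ``model.txt``, ``scores.tsv``, ``quasi.tsv`` and
    ``report.tsv``, each carrying the run manifest header.
    """
    logging.basicConfig(level=config.log_level)
    work = Path(config.workdir)
    work.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "config": config.config_hash()}
    (work / "manifest.yaml").write_text(config.to_yaml())
    summary: dict = {}

    for stage in config.stages:
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}; valid: {_STAGES}")
        log.info("stage %s", stage)
        try:
            if stage == "simulate":
                _stage_simulate(config, work, manifest)
            elif stage == "train":
                summary["best_C"] = _stage_train(config, work, manifest)
            elif stage == "rank":
                _stage_rank(config, work, manifest)
            elif stage == "quasi":
                _stage_quasi(config, work, manifest)
            elif stage == "eval":
                summary["report"] = _stage_eval(config, work, manifest)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return summary


def _stage_simulate(config: RunConfig, work: Path, manifest: dict) -> None:
    bench = make_structural_benchmark(
        n_targets=config.n_targets,
        n_decoys=config.n_decoys,
        length=config.length,
        sigma_range=(config.sigma_min, config.sigma_max),
        seed=config.seed,
        metric=config.metric,
    )
    truth_rows, feat_rows = [], []
    for ds in bench.decoy_sets:
        tdir = work / "decoys" / ds.target_id
        tdir.mkdir(parents=True, exist_ok=True)
        write_pdb(ds.native, tdir / "native.pdb")
        for decoy_id, s in ds.decoys:
            write_pdb(s, tdir / f"{decoy_id}.pdb")
        fm = bench.feature_matrices[ds.target_id]
        for i, d in enumerate(ds.decoy_ids):
            truth_rows.append(
                {"target_id": ds.target_id, "decoy_id": d, config.metric: ds.true_quality[d]}
            )
            feat_rows.append(
                {"target_id": ds.target_id, "decoy_id": d,
                 **dict(zip(fm.feature_names, fm.values[i]))}
            )
    write_tsv(pd.DataFrame(truth_rows), work / "truth.tsv", manifest)
    write_tsv(pd.DataFrame(feat_rows), work / "features.tsv", manifest)


def _stage_train(config: RunConfig, work: Path, manifest: dict) -> float:
    features = read_tsv(work / "features.tsv")
    truth = read_tsv(work / "truth.tsv")
    sets = frames_to_sets(features, truth, config.metric)
    best_C, table = cross_validate(
        sets, C_grid=config.c_grid, n_folds=min(config.n_folds, len(sets)),
        seed=config.seed, cap_per_target=config.cap_per_target, tie_tol=config.tie_tol,
    )
    write_tsv(pd.DataFrame(table), work / "cv.tsv", manifest)
    ps = build_training_pairs(sets, config.cap_per_target, config.tie_tol, config.seed)
    model = train_rank_svm(ps, C=best_C)
    model.seed = config.seed
    model.save(work / "model.txt")
    return best_C


def _stage_rank(config: RunConfig, work: Path, manifest: dict) -> None:
    model = RankModel.load(work / "model.txt")
    features = read_tsv(work / "features.tsv")
    truth = read_tsv(work / "truth.tsv")
    sets = frames_to_sets(features, truth, config.metric)
    rows = []
    for fm, _q in sets:
        est = score_decoys(model, fm)
        for i, d in enumerate(est.decoy_ids):
            rows.append(
                {"target_id": fm.target_id, "decoy_id": d,
                 "raw_score": est.raw_score[i], "rank": int(est.rank[i]),
                 "reciprocal_rank": est.reciprocal_rank[i]}
            )
    write_tsv(pd.DataFrame(rows), work / "scores.tsv", manifest)


def _stage_quasi(config: RunConfig, work: Path, manifest: dict) -> None:
    scores = read_tsv(work / "scores.tsv")
    rows = []
    for tid, grp in scores.groupby("target_id", sort=True):
        ds = load_decoy_dir(work / "decoys" / str(tid))
        est = _estimate_from_frame(str(tid), grp)
        q = quasi_rescore(ds, est, k=config.quasi_k, metric=config.metric)
        for i, d in enumerate(q.decoy_ids):
            rows.append(
                {"target_id": tid, "decoy_id": d, "raw_score": q.raw_score[i],
                 "quasi_quality": q.quasi_quality[i], "rank": int(q.rank[i]),
                 "reciprocal_rank": q.reciprocal_rank[i]}
            )
    write_tsv(pd.DataFrame(rows), work / "quasi.tsv", manifest)


def _estimate_from_frame(target_id: str, frame: pd.DataFrame):
    from .ranker import QualityEstimate

    frame = frame.sort_values("decoy_id")
    return QualityEstimate(
        target_id=target_id,
        decoy_ids=list(frame["decoy_id"]),
        raw_score=frame["raw_score"].to_numpy(float),
        rank=frame["rank"].to_numpy(int),
        reciprocal_rank=frame["reciprocal_rank"].to_numpy(float),
    )


def _stage_eval(config: RunConfig, work: Path, manifest: dict) -> dict:
    truth = read_tsv(work / "truth.tsv")
    results = {}
    for name, filename, column in (
        ("mqaprank", "scores.tsv", config.score_column),
        ("quasi_mqaprank", "quasi.tsv", "quasi_quality"),
    ):
        path = work / filename
        if not path.exists():
            continue
        scores = read_tsv(path)
        preds = {
            str(tid): dict(zip(grp["decoy_id"], grp[column].astype(float)))
            for tid, grp in scores.groupby("target_id")
        }
        obs = {
            str(tid): dict(zip(grp["decoy_id"], grp[config.metric].astype(float)))
            for tid, grp in truth.groupby("target_id")
        }
        report = evaluate(preds, obs, basis=config.metric, threshold=config.good_threshold)
        results[name] = report
    rows = [
        {"method": name, "wmpmcc": r.wmpmcc, "pooled_pmcc": r.pooled_pmcc,
         "auc": r.auc, "mean_loss": r.mean_loss, "top": r.top_count,
         "n_targets": r.n_targets}
        for name, r in results.items()
    ]
    write_tsv(pd.DataFrame(rows), work / "report.tsv", manifest)
    return {name: {"wmpmcc": r.wmpmcc, "auc": r.auc, "mean_loss": r.mean_loss,
                   "top": r.top_count} for name, r in results.items()}
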
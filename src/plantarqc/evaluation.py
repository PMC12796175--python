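"""Nested grouped cross-validation and the SPM-vs-CNN comparison.

Outer 5-fold assignment and the inner 80/20 tuning split are both
*grouped by subject* — every sample of a subject, including synthetic
outliers derived from that subject's maps, lands in exactly one
partition — and approximately stratified by the 5-class label using a
greedy divergence-minimizing heuristic (exact grouped stratification is
combinatorial).  Both detection branches are evaluated on identical
test folds; CNN predictions are reduced to binary (outlier vs valid)
for the head-to-head comparison, and every metric is also reported with
synthetic test samples excluded.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnn import (PlantarCNN, TrainConfig, compute_fold_stats,
                  dataset_arrays, predict, train)
from .dataio import Dataset
from .metrics import binary_confusion, confusion, f1, mcc
from .spm import SPMDetector, tune_spm
from .types import ALL_LABELS, LABEL_VALID, Provenance

__all__ = ["FoldPlan", "make_outer_folds", "make_inner_split",
           "confusion", "mcc", "f1", "run_comparison", "run_fold",
           "MetricReport"]


@dataclass
class FoldPlan:
    """subject -> outer fold index, plus per-fold inner subject splits."""

    n_folds: int
    assignment: dict                      # subject_id -> fold
    inner: dict = field(default_factory=dict)   # fold -> (train_subjects, val_subjects)

    def fold_subjects(self, fold: int) -> list:
        return [s for s, f in self.assignment.items() if f == fold]


def _label_distribution(manifest: pd.DataFrame) -> np.ndarray:
    counts = np.zeros(len(ALL_LABELS))
    for lab, c in manifest["label"].astype(int).value_counts().items():
        counts[lab] = c
    return counts


def _per_subject_counts(m: pd.DataFrame, subjects) -> dict:
    counts = {s: np.zeros(len(ALL_LABELS)) for s in subjects}
    for subj, lab in zip(m["subject_id"].astype(str), m["label"].astype(int)):
        if subj in counts:
            counts[subj][lab] += 1
    return counts


def _greedy_grouped_stratified(per_subject: dict, order: list,
                               weights: np.ndarray) -> dict:
    """Assign whole subjects to partitions with target size ``weights``.

    Each subject (visited in ``order``) goes to the partition that
    minimizes the across-partition spread of target-normalized label
    counts — the greedy heuristic behind stratified grouped k-fold
    splitters — with the most under-filled partition as tie-breaker.
    """
    k = len(weights)
    counts = np.zeros((k, len(ALL_LABELS)))
    assignment: dict[str, int] = {}
    for subj in order:
        best, best_key = None, None
        for f in range(k):
            cand = counts.copy()
            cand[f] += per_subject[subj]
            normalized = cand / weights[:, None]
            score = normalized.std(axis=0).sum()
            key = (score, counts[f].sum() / weights[f])
            if best_key is None or key < best_key:
                best, best_key = f, key
        assignment[subj] = best
        counts[best] += per_subject[subj]
    return assignment


def make_outer_folds(ds: Dataset, k: int = 5, seed: int = 0) -> FoldPlan:
    """Greedy grouped-stratified assignment of subjects to ``k`` folds.

    Subjects are visited by decreasing sample count (ties shuffled by
    seed); each goes to the fold that keeps per-fold label counts most
    even.  All samples of a subject — including synthetic outliers
    derived from them — share the subject's fold.
    """
    m = ds.manifest
    subjects = m["subject_id"].astype(str).unique().tolist()
    if len(subjects) < k:
        raise ValueError(f"{len(subjects)} subjects < {k} folds")
    rng = np.random.default_rng(seed)
    per_subject = _per_subject_counts(m, subjects)
    order = sorted(subjects,
                   key=lambda s: (-per_subject[s].sum(), rng.random()))
    assignment = _greedy_grouped_stratified(per_subject, order,
                                            np.full(k, 1.0 / k))
    plan = FoldPlan(n_folds=k, assignment=assignment)
    for f in range(k):
        train_subj = [s for s in subjects if assignment[s] != f]
        # k=1 has no held-out complement to split
        plan.inner[f] = (make_inner_split(ds, train_subj, seed=seed + f)
                         if len(train_subj) >= 2 else (train_subj, []))
    return plan


def make_inner_split(ds: Dataset, subjects: list, ratio: float = 0.8,
                     seed: int = 0) -> tuple[list, list]:
    """Grouped, approximately stratified train/validation split
    (``ratio`` of samples to train)."""
    subjects = list(subjects)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects to split")
    rng = np.random.default_rng(seed)
    per_subject = _per_subject_counts(ds.manifest, subjects)
    order = sorted(subjects,
                   key=lambda s: (-per_subject[s].sum(), rng.random()))
    assignment = _greedy_grouped_stratified(
        per_subject, order, np.array([ratio, 1 - ratio]))
    train_subj = [s for s in subjects if assignment[s] == 0]
    val_subj = [s for s in subjects if assignment[s] == 1]
    if not train_subj or not val_subj:
        cut = min(max(1, int(round(len(order) * ratio))), len(order) - 1)
        return order[:cut], order[cut:]
    return train_subj, val_subj


def _subset_by_subjects(ds: Dataset, subjects) -> Dataset:
    mask = ds.manifest["subject_id"].astype(str).isin(set(subjects)).to_numpy()
    return ds.subset(mask)


# ---------------------------------------------------------------------
# the comparison protocol
# ---------------------------------------------------------------------
@dataclass
class FoldResult:
    fold: int
    branch: str                      # "spm" or "cnn"
    sample_ids: list
    y_true: np.ndarray               # 5-class truth
    y_pred: np.ndarray               # 5-class for cnn, binary {0,1} for spm
    synthetic: np.ndarray            # bool mask
    detail: dict = field(default_factory=dict)

    def binary_metrics(self, exclude_synthetic: bool = False) -> dict:
        keep = ~self.synthetic if exclude_synthetic else np.ones(
            len(self.y_true), dtype=bool)
        t = (self.y_true[keep] != LABEL_VALID).astype(int)
        p = (np.asarray(self.y_pred)[keep] != LABEL_VALID).astype(int)
        cm = binary_confusion(t, p)
        return {"confusion": cm, "mcc": mcc(cm), "f1": f1(cm), "n": keep.sum()}


@dataclass
class MetricReport:
    fold_results: list
    folds: FoldPlan

    def summary(self) -> pd.DataFrame:
        rows = []
        for fr in self.fold_results:
            for variant, excl in (("all", False), ("real_only", True)):
                met = fr.binary_metrics(exclude_synthetic=excl)
                rows.append({"fold": fr.fold, "branch": fr.branch,
                             "variant": variant, "mcc": met["mcc"],
                             "f1": met["f1"], "n": met["n"]})
        return pd.DataFrame(rows)

    def pooled_confusion(self, branch: str, exclude_synthetic: bool = False
                         ) -> np.ndarray:
        cm = np.zeros((2, 2), dtype=int)
        for fr in self.fold_results:
            if fr.branch == branch:
                cm += fr.binary_metrics(exclude_synthetic)["confusion"]
        return cm

    def multiclass_confusion(self, branch: str = "cnn") -> np.ndarray:
        ys, ps = [], []
        for fr in self.fold_results:
            if fr.branch == branch and fr.detail.get("multiclass", False):
                ys.append(fr.y_true)
                ps.append(fr.y_pred)
        if not ys:
            return np.zeros((5, 5), dtype=int)
        return confusion(np.concatenate(ys), np.concatenate(ps),
                         classes=list(ALL_LABELS))


def run_fold(ds: Dataset, plan: FoldPlan, fold: int, seed: int = 0,
             train_config: TrainConfig | None = None,
             spm_candidates: int = 8, spm_permutations: int = 1000,
             branches=("spm", "cnn")) -> list[FoldResult]:
    """Run one outer fold of the nested protocol for both branches."""
    from .registration import build_reference, register_dataset
    from .types import Side

    test_subj = set(plan.fold_subjects(fold))
    inner_train_subj, inner_val_subj = plan.inner[fold]
    test_ds = _subset_by_subjects(ds, test_subj)
    train_ds = _subset_by_subjects(ds, inner_train_subj)
    val_ds = _subset_by_subjects(ds, inner_val_subj)

    y_true = test_ds.manifest["label"].astype(int).to_numpy()
    synthetic = (test_ds.manifest["provenance"] == Provenance.SYNTHETIC.value
                 ).to_numpy()
    ids = test_ds.manifest["sample_id"].tolist()
    results = []

    if "spm" in branches:
        templates = {s: build_reference(train_ds, s) for s in Side}
        # only valid training maps feed the normative cohorts
        train_valid = train_ds.subset(
            (train_ds.manifest["label"].astype(int) == LABEL_VALID).to_numpy())
        reg_train, _ = register_dataset(train_valid, templates)
        reg_val, _ = register_dataset(val_ds, templates)
        reg_test, _ = register_dataset(test_ds, templates)
        config, _ = tune_spm(reg_train, reg_val, n_candidates=spm_candidates,
                             seed=seed, n_permutations=spm_permutations)
        detector = SPMDetector.fit(reg_train, config, seed=seed)
        flags = detector.predict(reg_test)
        results.append(FoldResult(
            fold=fold, branch="spm", sample_ids=ids, y_true=y_true,
            y_pred=flags, synthetic=synthetic,
            detail={"config": config, "multiclass": False}))

    if "cnn" in branches:
        tc = train_config or TrainConfig()
        tg, ts, tl = dataset_arrays(train_ds)
        vg, vs, vl = dataset_arrays(val_ds)
        stats = compute_fold_stats(tg)
        mean, sd = stats
        model = PlantarCNN(seed=tc.seed + fold)
        history = train(model, ((tg - mean) / sd, ts, tl),
                        ((vg - mean) / sd, vs, vl), tc)
        eg, es, _ = dataset_arrays(test_ds)
        preds = predict(model, eg, es, stats)
        results.append(FoldResult(
            fold=fold, branch="cnn", sample_ids=ids, y_true=y_true,
            y_pred=np.array([p.label for p in preds]), synthetic=synthetic,
            detail={"history": history, "multiclass": True,
                    "fold_stats": stats}))
    return results


def run_comparison(ds: Dataset, seed: int = 0, k: int = 5,
                   train_config: TrainConfig | None = None,
                   spm_candidates: int = 8, spm_permutations: int = 1000,
                   folds: list | None = None,
                   branches=("spm", "cnn")) -> MetricReport:
    """Full nested protocol: identical partitions for both branches.

    A branch failing on a fold is recorded (``branch='<name>:failed'``)
    and the run continues.
    """
    plan = make_outer_folds(ds, k=k, seed=seed)
    fold_results = []
    for fold in (folds if folds is not None else range(k)):
        for branch in branches:
            try:
                fold_results.extend(run_fold(
                    ds, plan, fold, seed=seed, train_config=train_config,
                    spm_candidates=spm_candidates,
                    spm_permutations=spm_permutations, branches=(branch,)))
            except Exception as exc:   # noqa: BLE001 - protocol continues
                fold_results.append(FoldResult(
                    fold=fold, branch=f"{branch}:failed", sample_ids=[],
                    y_true=np.array([], dtype=int),
                    y_pred=np.array([], dtype=int),
                    synthetic=np.array([], dtype=bool),
                    detail={"error": str(exc)}))
    return MetricReport(fold_results=fold_results, folds=plan)
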
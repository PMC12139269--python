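"""Metric panel, stratified repeated cross-validation, and the experiment
harness for edge-count / edge-strategy / ablation comparisons.

The panel mirrors standard binary-classification reporting: accuracy,
sensitivity, specificity, Matthews correlation coefficient, ROC AUC,
average precision (AUPRC) and F1.  The confusion matrix thresholds the
case probability at 0.5 (exactly 0.5 counts as control, consistent with
the deployment tie rule).

Evaluation is transductive: features are computed once from the recorded
labels, the full graph is assembled per fold, and only the train /
validation / test masks change.  Within each fold the validation split is
a stratified 1/9 hold-out of the non-test patients, preserving the 10-fold
test geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

from .features import BM25Params, compute_feature_matrix, compute_nm_features, compute_rf_table
from .gat_model import GATConfig, predict_proba, train_gat
from .hetero_graph import EdgeConfig, assemble_graph
from .synthetic import CohortBundle

METRICS = ("accuracy", "sensitivity", "specificity", "mcc", "auc", "auprc", "f1")

__all__ = [
    "CVPlan",
    "EvalReport",
    "compute_metrics",
    "stratified_repeated_folds",
    "cross_validate",
    "run_ablation_suite",
]


@dataclass(frozen=True)
class CVPlan:
    """Repeated stratified k-fold plan (reference: 3 repeats, 10 folds)."""

    repeats: int = 3
    folds: int = 10
    seed: int = 0
    val_fraction: float = 1.0 / 9.0


@dataclass
class EvalReport:
    """Per-fold metric rows plus their mean/std aggregates."""

    descriptor: dict
    folds: pd.DataFrame

    def mean(self, metric: str = "accuracy") -> float:
        return float(self.folds[metric].mean())

    def std(self, metric: str = "accuracy") -> float:
        return float(self.folds[metric].std(ddof=1)) if len(self.folds) > 1 else 0.0

    def aggregates(self) -> dict:
        return {
            m: {"mean": self.mean(m), "std": self.std(m)}
            for m in METRICS
            if m in self.folds.columns
        }

    def summary(self) -> dict:
        return {"descriptor": self.descriptor, "metrics": self.aggregates(),
                "auprc_convention": "average-precision (step integration)",
                "std_convention": "over all repeat x fold runs"}

    def save(self, prefix) -> None:
        """Per-fold rows to ``<prefix>.csv``, aggregates to ``<prefix>.json``."""
        import json
        from pathlib import Path

        self.folds.to_csv(f"{prefix}.csv", index=False)
        Path(f"{prefix}.json").write_text(json.dumps(self.summary(), indent=1) + "\n")


def compute_metrics(probs: np.ndarray, labels: Sequence[int]) -> dict[str, float]:
    """Panel of threshold and ranking metrics for one evaluation set.

    ``probs`` is either the (n, 2) probability pairs or the case
    probability vector.  Requires at least one case and one control.
    """
    probs = np.asarray(probs, dtype=np.float64)
    p_case = probs[:, 1] if probs.ndim == 2 else probs
    y = np.asarray(labels, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("metrics need at least one case and one control")
    pred = (p_case > 0.5).astype(np.int64)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return {
        "accuracy": (tp + tn) / y.size,
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
        "mcc": float(mcc),
        "auc": float(roc_auc_score(y, p_case)),
        "auprc": float(average_precision_score(y, p_case)),
        "f1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0,
    }


def stratified_repeated_folds(labels: Sequence[int], plan: CVPlan) -> list[tuple[int, int, np.ndarray]]:
    """Deterministic fold assignments ``(repeat, fold, test_indices)``.

    Within each repeat the folds partition the patients with the
    case:control ratio equal across folds up to rounding.
    """
    y = np.asarray(labels, dtype=np.int64)
    minority = min(np.bincount(y, minlength=2))
    if plan.folds > minority:
        raise ValueError(f"{plan.folds} folds exceed the minority class size {minority}")
    splitter = RepeatedStratifiedKFold(
        n_splits=plan.folds, n_repeats=plan.repeats, random_state=plan.seed
    )
    out = []
    for i, (_, test_idx) in enumerate(splitter.split(np.zeros_like(y), y)):
        out.append((i // plan.folds, i % plan.folds, np.sort(test_idx)))
    return out


def _fold_seed(plan: CVPlan, repeat: int, fold: int, offset: int = 0) -> int:
    return int((plan.seed * 1_000_003 + repeat * 7919 + fold * 101 + offset) % (2**31 - 1))


def fold_masks(
    y: np.ndarray, test_idx: np.ndarray, seed: int, val_fraction: float = 1.0 / 9.0
) -> dict[str, np.ndarray]:
    """Train/val/test masks for one fold: validation is a stratified
    ``val_fraction`` hold-out of the non-test patients."""
    n = y.size
    rest = np.setdiff1d(np.arange(n), test_idx)
    train_idx, val_idx = train_test_split(
        rest, test_size=val_fraction, stratify=y[rest], random_state=seed
    )
    masks = {k: np.zeros(n, dtype=bool) for k in ("train", "val", "test")}
    masks["train"][train_idx] = True
    masks["val"][val_idx] = True
    masks["test"][test_idx] = True
    return masks


def _features_for(bundle: CohortBundle, feature_mode: str, bm25: BM25Params, support_mode: str):
    if feature_mode == "bm25":
        rf = compute_rf_table(bundle.matrix, bundle.labels, support_mode=support_mode)
        return compute_feature_matrix(bundle.matrix, rf, dict(bundle.labels.label), bm25)
    if feature_mode == "nm":
        return compute_nm_features(bundle.matrix)
    raise ValueError(f"unknown feature_mode {feature_mode!r}")


def cross_validate(
    bundle: CohortBundle,
    model: str = "gat",
    plan: CVPlan = CVPlan(),
    edge_config: EdgeConfig = EdgeConfig(),
    gat_config: GATConfig = GATConfig(),
    feature_mode: str = "bm25",
    bm25: BM25Params = BM25Params(),
    support_mode: str = "patients",
) -> EvalReport:
    """Repeated stratified CV of one model; metrics on each held-out fold.

    ``model`` is one of ``gat`` (heterogeneous graph classifier), ``homog``
    (per-patient homogeneous graph baseline), ``lr`` or ``mlp``.
    """
    from . import baselines  # deferred: avoids a cycle for baseline models

    y = bundle.labels.vector(bundle.matrix.patients)
    feats = _features_for(bundle, feature_mode, bm25, support_mode)
    rows = []
    for repeat, fold, test_idx in stratified_repeated_folds(y, plan):
        seed = _fold_seed(plan, repeat, fold)
        masks = fold_masks(y, test_idx, seed, plan.val_fraction)
        if model == "gat":
            graph = assemble_graph(
                feats, y, bundle.ppi, bundle.catalog,
                replace(edge_config, seed=_fold_seed(plan, repeat, fold, 1)), masks,
            )
            trained = train_gat(graph, replace(gat_config, seed=seed))
            probs = predict_proba(trained, graph)
        elif model == "lr":
            probs = baselines.fit_predict_lr(feats, y, masks)
        elif model == "mlp":
            probs = baselines.fit_predict_mlp(feats, y, masks, seed=seed, gat_config=gat_config)
        elif model == "homog":
            graphset = baselines.HomogeneousGraphSet.from_bundle(feats, bundle)
            probs = baselines.homogeneous_gnn_classify(
                graphset, replace(gat_config, seed=seed), y, masks
            )
        else:
            raise ValueError(f"unknown model {model!r}")
        try:
            metrics = compute_metrics(probs[test_idx], y[test_idx])
        except Exception as exc:
            raise RuntimeError(f"repeat {repeat} fold {fold}: {exc}") from exc
        rows.append({"repeat": repeat, "fold": fold, **metrics})
    return EvalReport(
        descriptor={
            "model": model,
            "feature_mode": feature_mode,
            "edge_strategy": edge_config.strategy if model == "gat" else None,
            "k_edges": edge_config.k_edges if model == "gat" else None,
            "repeats": plan.repeats,
            "folds": plan.folds,
            "seed": plan.seed,
        },
        folds=pd.DataFrame(rows),
    )


def run_ablation_suite(
    bundle: CohortBundle,
    plan: CVPlan = CVPlan(),
    edge_config: EdgeConfig = EdgeConfig(),
    gat_config: GATConfig = GATConfig(),
) -> dict[str, EvalReport | None]:
    """One report per ablation arm, structurally matching the component
    knock-out table: full model, random-edge variant, normalized-count
    feature variant, homogeneous baseline, and the tabular baselines.

    The prior-work tabular model is listed as unavailable (defined outside
    this package's scope)."""
    suite: dict[str, EvalReport | None] = {}
    suite["full"] = cross_validate(
        bundle, "gat", plan, edge_config, gat_config, feature_mode="bm25"
    )
    suite["random_edges"] = cross_validate(
        bundle, "gat", plan, replace(edge_config, strategy="random"), gat_config, "bm25"
    )
    suite["nm_features"] = cross_validate(
        bundle, "gat", plan, edge_config, gat_config, feature_mode="nm"
    )
    suite["homogeneous"] = cross_validate(bundle, "homog", plan, edge_config, gat_config)
    suite["lr"] = cross_validate(bundle, "lr", plan, edge_config, gat_config)
    suite["mlp"] = cross_validate(bundle, "mlp", plan, edge_config, gat_config)
    suite["model_half"] = None  # prior-work baseline, unavailable here
    return suite
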
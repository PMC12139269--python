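"""Class-conditional BM25-tf-rf patient feature vectors.

Each patient is treated like a document and each mutated gene like a term.
The per-gene feature is the product of two factors:

* a saturating term-frequency transform ``bm25_tf(tf) = (k+1)*tf / (k+tf)``
  that bounds the influence of highly mutated genes by ``k+1``; and
* a supervised relevance frequency ``rf = log(2 + a / max(1, b))`` where
  ``a`` is the gene's support in the patient's (assumed) class and ``b``
  its support in the other class.

Because rf is class-conditional, featurisation depends on the class each
patient is *assumed* to belong to.  In transductive evaluation the recorded
labels are used for all patients; the deployment protocol
(:mod:`mutgraph.simulation`) instead runs once under each assumption for an
unlabeled patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_io import CASE, CONTROL, CohortLabels, MutationMatrix, ValidationError

__all__ = [
    "BM25Params",
    "RFTable",
    "FeatureMatrix",
    "bm25_tf",
    "compute_rf_table",
    "compute_feature_matrix",
    "compute_nm_features",
]


@dataclass(frozen=True)
class BM25Params:
    """Smoothing constant of the saturating term-frequency transform."""

    k: float = 1.2

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("BM25 k must be positive")


@dataclass
class RFTable:
    """Per-gene, per-class relevance frequencies with their a/b supports.

    Arrays are aligned with the mutation matrix's gene catalog.
    """

    a_case: np.ndarray
    b_case: np.ndarray
    rf_case: np.ndarray
    a_control: np.ndarray
    b_control: np.ndarray
    rf_control: np.ndarray
    support_mode: str = "patients"
    log_base: float = 2.0

    def rf_for(self, cls: int) -> np.ndarray:
        return self.rf_case if cls == CASE else self.rf_control


@dataclass
class FeatureMatrix:
    """Patients x genes nonnegative real feature block."""

    patients: tuple[str, ...]
    values: np.ndarray
    class_assumption: dict[str, int] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def save(self, tsv_path, genes=None) -> None:
        """TSV of the feature block plus a ``<path>.json`` sidecar with
        the weighting provenance (k, log base, support mode, class
        assumptions)."""
        import json
        from pathlib import Path

        path = Path(tsv_path)
        cols = list(genes) if genes is not None else [f"g{j}" for j in range(self.values.shape[1])]
        header = "patient\t" + "\t".join(cols)
        rows = [
            p + "\t" + "\t".join(f"{v:.10g}" for v in self.values[i])
            for i, p in enumerate(self.patients)
        ]
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        sidecar = {"meta": self.meta, "class_assumption": self.class_assumption}
        Path(f"{path}.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n")


def bm25_tf(tf, k: float = 1.2):
    """Saturating transform ``(k+1)*tf / (k+tf)``; strictly increasing,
    bounded above by ``k+1``, with ``bm25_tf(1) == 1`` for every k."""
    tf = np.asarray(tf, dtype=np.float64)
    if np.any(tf < 0):
        raise ValueError("term frequency must be nonnegative")
    return ((k + 1.0) * tf) / (k + tf)


def _rf(a: np.ndarray, b: np.ndarray, log_base: float) -> np.ndarray:
    return np.log(2.0 + a / np.maximum(1.0, b)) / np.log(log_base)


def compute_rf_table(
    matrix: MutationMatrix,
    labels: CohortLabels,
    support_mode: str = "patients",
    log_base: float = 2.0,
) -> RFTable:
    """Relevance frequencies from class-wise gene supports.

    ``support_mode='patients'`` counts patients carrying at least one
    mutation in the gene (the document-frequency analogue);
    ``'events'`` sums mutation counts instead.
    """
    if log_base <= 1:
        raise ValueError("log base must exceed 1")
    if support_mode not in ("patients", "events"):
        raise ValueError(f"unknown support_mode {support_mode!r}")
    y = labels.vector(matrix.patients)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present to compute rf")
    case_rows = matrix.counts[y == CASE]
    control_rows = matrix.counts[y == CONTROL]
    if support_mode == "patients":
        a_case = (case_rows >= 1).sum(axis=0).astype(np.float64)
        a_control = (control_rows >= 1).sum(axis=0).astype(np.float64)
    else:
        a_case = case_rows.sum(axis=0).astype(np.float64)
        a_control = control_rows.sum(axis=0).astype(np.float64)
    return RFTable(
        a_case=a_case,
        b_case=a_control,
        rf_case=_rf(a_case, a_control, log_base),
        a_control=a_control,
        b_control=a_case,
        rf_control=_rf(a_control, a_case, log_base),
        support_mode=support_mode,
        log_base=log_base,
    )


def compute_feature_matrix(
    matrix: MutationMatrix,
    rf: RFTable,
    class_assumption: dict[str, int],
    params: BM25Params = BM25Params(),
) -> FeatureMatrix:
    """BM25-tf-rf features: ``bm25_tf(count) * rf_assumed_class(gene)``.

    Zero counts always map to zero features, so the support of a patient's
    feature row equals the support of their count row.
    """
    missing = [p for p in matrix.patients if p not in class_assumption]
    if missing:
        raise ValueError(f"class assumption missing for patients: {missing[:5]}")
    saturated = bm25_tf(matrix.counts, params.k)
    values = np.empty_like(saturated)
    for i, patient in enumerate(matrix.patients):
        values[i] = saturated[i] * rf.rf_for(class_assumption[patient])
    return FeatureMatrix(
        patients=matrix.patients,
        values=values,
        class_assumption=dict(class_assumption),
        meta={
            "scheme": "bm25-tf-rf",
            "k": params.k,
            "log_base": rf.log_base,
            "support_mode": rf.support_mode,
        },
    )


def compute_nm_features(matrix: MutationMatrix, norm: str = "total") -> FeatureMatrix:
    """Normalized mutation counts (ablation features): each row divided by
    the patient's total mutation count (``norm='l2'``: by its L2 norm).
    All-zero rows stay zero."""
    counts = matrix.counts.astype(np.float64)
    if norm == "total":
        denom = counts.sum(axis=1, keepdims=True)
    elif norm == "l2":
        denom = np.linalg.norm(counts, axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown norm {norm!r}")
    values = np.divide(counts, denom, out=np.zeros_like(counts), where=denom > 0)
    return FeatureMatrix(
        patients=matrix.patients,
        values=values,
        class_assumption={},
        meta={"scheme": "normalized-counts", "norm": norm},
    )
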
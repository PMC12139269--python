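"""Deployment protocol: dual-assumption runs for unlabeled patients.

The class-conditional features require a class for every patient, which an
incoming patient does not have.  The protocol therefore featurises the
patient twice — once assuming case, once assuming control — trains and
predicts on each of the two resulting graphs, sums the two probability
pairs component-wise, and decides by the larger sum (ties go to control,
the conservative choice).

Each run's relevance-frequency table is computed from the training labels
plus the single assumed label only; the test patient's true label is never
read before the decision.  Runs for different test patients are fully
independent, so decisions do not depend on which other patients are being
tested.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .cohort_io import CASE, CONTROL, CohortLabels, MutationMatrix
from .evaluation import compute_metrics  # shared metric definitions
from .features import BM25Params, compute_feature_matrix, compute_rf_table
from .gat_model import GATConfig, predict_proba, train_gat
from .hetero_graph import EdgeConfig, assemble_graph
from .synthetic import CohortBundle

__all__ = ["DualRunResult", "dual_run_decide", "run_simulation"]


@dataclass
class DualRunResult:
    """Outcome of the two assumption runs for one test patient."""

    patient: str
    proba_case_run: tuple[float, float]  # (p_control, p_case) under case assumption
    proba_control_run: tuple[float, float]
    summed: tuple[float, float]
    decision: int

    def __post_init__(self):
        assert abs(sum(self.proba_case_run) - 1) < 1e-6
        assert abs(sum(self.proba_control_run) - 1) < 1e-6


def dual_run_decide(
    matrix: MutationMatrix,
    train_labels: CohortLabels,
    test_patient: str,
    bundle: CohortBundle,
    edge_config: EdgeConfig = EdgeConfig(),
    gat_config: GATConfig = GATConfig(),
    bm25: BM25Params = BM25Params(),
    val_fraction: float = 1.0 / 9.0,
    seed: int = 0,
) -> DualRunResult:
    """Train/predict twice for one unlabeled patient and sum probabilities.

    ``matrix`` holds the training patients plus the single test patient;
    ``train_labels`` must label exactly the training patients.  The two
    runs use distinct derived seeds.
    """
    if test_patient in train_labels.label:
        raise ValueError(f"test patient {test_patient!r} must not carry a training label")
    test_pos = matrix.patients.index(test_patient)
    y_train_map = dict(train_labels.label)
    pairs = {}
    for offset, assumption in enumerate((CASE, CONTROL)):
        labels_assumed = CohortLabels({**y_train_map, test_patient: assumption})
        rf = compute_rf_table(matrix, labels_assumed)
        feats = compute_feature_matrix(matrix, rf, dict(labels_assumed.label), bm25)
        y = labels_assumed.vector(matrix.patients)
        run_seed = int((seed * 1_000_003 + offset * 7919) % (2**31 - 1))
        train_rows = np.array([i for i in range(len(matrix.patients)) if i != test_pos])
        rest_y = y[train_rows]
        tr, va = train_test_split(
            train_rows, test_size=val_fraction, stratify=rest_y, random_state=run_seed
        )
        masks = {k: np.zeros(len(matrix.patients), dtype=bool) for k in ("train", "val", "test")}
        masks["train"][tr] = True
        masks["val"][va] = True
        masks["test"][test_pos] = True
        graph = assemble_graph(
            feats, y, bundle.ppi, bundle.catalog,
            replace(edge_config, seed=run_seed), masks,
        )
        model = train_gat(graph, replace(gat_config, seed=run_seed))
        pairs[assumption] = tuple(predict_proba(model, graph)[test_pos])
    summed = (
        pairs[CASE][0] + pairs[CONTROL][0],
        pairs[CASE][1] + pairs[CONTROL][1],
    )
    decision = CASE if summed[1] > summed[0] else CONTROL  # tie -> control
    return DualRunResult(
        patient=test_patient,
        proba_case_run=pairs[CASE],
        proba_control_run=pairs[CONTROL],
        summed=summed,
        decision=decision,
    )


def run_simulation(
    bundle: CohortBundle,
    test_fraction: float = 0.1,
    seed: int = 0,
    edge_config: EdgeConfig = EdgeConfig(),
    gat_config: GATConfig = GATConfig(),
    bm25: BM25Params = BM25Params(),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Stratified 90/10 split, dual-run decision per test patient.

    Returns the per-patient table (assumption-run case probabilities,
    summed pair, decision, truth) and accuracy/sensitivity/specificity of
    the decisions.
    """
    patients = list(bundle.matrix.patients)
    y = bundle.labels.vector(patients)
    train_idx, test_idx = train_test_split(
        np.arange(len(patients)), test_size=test_fraction, stratify=y, random_state=seed
    )
    train_idx, test_idx = np.sort(train_idx), np.sort(test_idx)
    rows = []
    for j, ti in enumerate(test_idx):
        keep = np.sort(np.concatenate([train_idx, [ti]]))
        sub = MutationMatrix(
            tuple(patients[i] for i in keep), bundle.matrix.counts[keep], bundle.catalog
        )
        train_labels = CohortLabels({patients[i]: int(y[i]) for i in train_idx})
        result = dual_run_decide(
            sub, train_labels, patients[ti], bundle,
            edge_config, gat_config, bm25,
            seed=int((seed * 31 + j * 977) % (2**31 - 1)),
        )
        rows.append(
            {
                "patient": result.patient,
                "p_case_case_run": result.proba_case_run[1],
                "p_case_control_run": result.proba_control_run[1],
                "summed_p_case": result.summed[1],
                "decision": result.decision,
                "truth": int(y[ti]),
            }
        )
    df = pd.DataFrame(rows)
    tp = int(((df.decision == CASE) & (df.truth == CASE)).sum())
    tn = int(((df.decision == CONTROL) & (df.truth == CONTROL)).sum())
    fp = int(((df.decision == CASE) & (df.truth == CONTROL)).sum())
    fn = int(((df.decision == CONTROL) & (df.truth == CASE)).sum())
    metrics = {
        "accuracy": (tp + tn) / len(df),
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
    }
    return df, metrics
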
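"""Two-layer heterogeneous graph attention classifier.

Message passing follows the multi-head attention scheme of graph attention
networks, specialised to the two edge types of the patient/protein graph:

* protein -> protein (both directions of each undirected PPI edge);
* protein -> patient (directed mutation edges).

For each edge type and head, source nodes are linearly projected into
head-specific messages; an attention logit is a learned function
(LeakyReLU of added source and target scores) of the projected source and
target representations; coefficients are softmax-normalised over each
target's incoming edges of that type.  Layer 1 concatenates heads and
applies an ELU; layer 2 averages heads; a linear head maps the final
patient representation to two logits.

Patient nodes have no self-loop on the protein->patient edge type: their
own features enter only the input projection used for attention scoring,
so a patient's representation is built entirely from incoming protein
messages.  Protein nodes are updated by the PPI edges alone.

Training minimises cross-entropy on train-mask patients with Adam,
early-stopping on validation accuracy and restoring the best-validation
parameters.  Everything is seeded and single-threaded numpy, so repeated
runs are bit-identical.

An optional per-mutation-edge mask (0 = edge absent, 1 = edge present)
scales the messages of the protein->patient edge type in both layers; the
integrated-gradients explainer differentiates the case logit with respect
to this mask.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import SegmentIndex, Tensor
from .hetero_graph import HeteroGraph

__all__ = ["GATConfig", "TrainedModel", "train_gat", "predict_proba"]


@dataclass(frozen=True)
class GATConfig:
    """Reference configuration: 2 layers, 128 hidden units, 8 heads,
    learning rate 0.001; ``hidden_units`` is the per-head width."""

    layers: int = 2
    hidden_units: int = 128
    heads: int = 8
    learning_rate: float = 0.001
    max_epochs: int = 300
    patience: int = 30
    seed: int = 0
    leaky_slope: float = 0.2

    def __post_init__(self):
        if self.layers != 2:
            raise ValueError("the reference architecture is fixed at 2 layers")
        for name in ("hidden_units", "heads", "max_epochs", "patience"):
            if getattr(self, name) < 0 or (name in ("hidden_units", "heads") and getattr(self, name) < 1):
                raise ValueError(f"{name} must be positive")


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> Tensor:
    fan_in, fan_out = shape[0], int(np.prod(shape[1:]))
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def init_params(n_genes: int, n_proteins: int, config: GATConfig) -> dict[str, Tensor]:
    """Glorot-initialised parameter set for the fixed 2-layer architecture."""
    rng = np.random.default_rng(config.seed)
    h, d = config.heads, config.hidden_units
    hd = h * d
    p: dict[str, Tensor] = {}
    # layer 1: protein->protein and protein->patient
    p["l1.ppi.W_src"] = _glorot(rng, (n_proteins, hd))
    p["l1.ppi.W_dst"] = _glorot(rng, (n_proteins, hd))
    p["l1.ppi.a_src"] = _glorot(rng, (h, d))
    p["l1.ppi.a_dst"] = _glorot(rng, (h, d))
    p["l1.mut.W_src"] = _glorot(rng, (n_proteins, hd))
    p["l1.mut.W_dst"] = _glorot(rng, (n_genes, hd))
    p["l1.mut.a_src"] = _glorot(rng, (h, d))
    p["l1.mut.a_dst"] = _glorot(rng, (h, d))
    p["l1.bias_protein"] = Tensor(np.zeros(hd), requires_grad=True)
    p["l1.bias_patient"] = Tensor(np.zeros(hd), requires_grad=True)
    # layer 2: protein->patient on layer-1 representations
    p["l2.mut.W_src"] = _glorot(rng, (hd, hd))
    p["l2.mut.W_dst"] = _glorot(rng, (hd, hd))
    p["l2.mut.a_src"] = _glorot(rng, (h, d))
    p["l2.mut.a_dst"] = _glorot(rng, (h, d))
    p["l2.bias_patient"] = Tensor(np.zeros(d), requires_grad=True)
    # classifier head
    p["head.W"] = _glorot(rng, (d, 2))
    p["head.b"] = Tensor(np.zeros(2), requires_grad=True)
    return p


class _GraphArrays:
    """Graph tensors and the precomputed segment indices."""

    def __init__(self, graph: HeteroGraph):
        self.graph = graph
        self.x_patient = Tensor(graph.x_patient)
        self.x_protein = Tensor(graph.x_protein())
        src = np.concatenate([graph.e_ppi[0], graph.e_ppi[1]])
        dst = np.concatenate([graph.e_ppi[1], graph.e_ppi[0]])
        self.ppi_src = SegmentIndex(src, graph.n_proteins)
        self.ppi_dst = SegmentIndex(dst, graph.n_proteins)
        self.mut_src = SegmentIndex(graph.e_mut_src, graph.n_proteins)
        self.mut_dst = SegmentIndex(graph.e_mut_dst, graph.n_patients)
        self.n_mut_edges = graph.e_mut_src.size


def _attend(
    h_src: Tensor,
    h_dst: Tensor,
    a_src: Tensor,
    a_dst: Tensor,
    seg_src: SegmentIndex,
    seg_dst: SegmentIndex,
    heads: int,
    dim: int,
    slope: float,
    edge_mask: Tensor | None = None,
):
    """One edge type of one layer; returns (aggregate, attention)."""
    n_edges = seg_src.idx.size
    if n_edges == 0:
        zero = Tensor(np.zeros((seg_dst.n_nodes, heads, dim)))
        return zero, None
    hs = ad.reshape(h_src, (-1, heads, dim))
    hd = ad.reshape(h_dst, (-1, heads, dim))
    score_src = ad.t_sum(hs * a_src, axis=-1)  # (n_src, H)
    score_dst = ad.t_sum(hd * a_dst, axis=-1)  # (n_dst, H)
    logit = ad.leaky_relu(ad.gather(score_src, seg_src) + ad.gather(score_dst, seg_dst), slope)
    m = seg_dst.scatter_max(logit.data)  # detached stabiliser
    z = ad.t_exp(logit - Tensor(np.take(m, seg_dst.idx, axis=0)))
    denom = ad.segment_sum(z, seg_dst)
    att = z / ad.gather(denom, seg_dst)  # (E, H), sums to 1 per target
    msg = ad.gather(hs, seg_src) * ad.reshape(att, (n_edges, heads, 1))
    if edge_mask is not None:
        msg = msg * ad.reshape(edge_mask, (n_edges, 1, 1))
    return ad.segment_sum(msg, seg_dst), att


def forward(
    params: dict[str, Tensor],
    arrays: _GraphArrays,
    config: GATConfig,
    edge_mask: Tensor | None = None,
    collect_attention: bool = False,
):
    """Full forward pass; returns patient logits (and attention if asked)."""
    h, d = config.heads, config.hidden_units
    attn: dict[str, np.ndarray] = {}

    # ---- layer 1
    prot_in = ad.matmul(arrays.x_protein, params["l1.ppi.W_src"])
    prot_in_att = ad.matmul(arrays.x_protein, params["l1.ppi.W_dst"])
    agg_r, att = _attend(
        prot_in, prot_in_att, params["l1.ppi.a_src"], params["l1.ppi.a_dst"],
        arrays.ppi_src, arrays.ppi_dst, h, d, config.leaky_slope,
    )
    if collect_attention and att is not None:
        attn["l1.ppi"] = att.data
    h_protein = ad.elu(ad.reshape(agg_r, (-1, h * d)) + params["l1.bias_protein"])

    mut_src_in = ad.matmul(arrays.x_protein, params["l1.mut.W_src"])
    mut_dst_in = ad.matmul(arrays.x_patient, params["l1.mut.W_dst"])
    agg_p, att = _attend(
        mut_src_in, mut_dst_in, params["l1.mut.a_src"], params["l1.mut.a_dst"],
        arrays.mut_src, arrays.mut_dst, h, d, config.leaky_slope, edge_mask,
    )
    if collect_attention and att is not None:
        attn["l1.mut"] = att.data
    h_patient = ad.elu(ad.reshape(agg_p, (-1, h * d)) + params["l1.bias_patient"])

    # ---- layer 2 (only the patient update is needed for classification)
    src2 = ad.matmul(h_protein, params["l2.mut.W_src"])
    dst2 = ad.matmul(h_patient, params["l2.mut.W_dst"])
    agg2, att = _attend(
        src2, dst2, params["l2.mut.a_src"], params["l2.mut.a_dst"],
        arrays.mut_src, arrays.mut_dst, h, d, config.leaky_slope, edge_mask,
    )
    if collect_attention and att is not None:
        attn["l2.mut"] = att.data
    h_out = ad.t_sum(agg2, axis=1) * (1.0 / h) + params["l2.bias_patient"]  # head average
    logits = ad.matmul(h_out, params["head.W"]) + params["head.b"]
    if collect_attention:
        return logits, attn
    return logits


def _cross_entropy(logits: Tensor, labels: np.ndarray, mask: np.ndarray) -> Tensor:
    lp = ad.log_softmax(logits)
    weight = np.zeros_like(lp.data)
    rows = np.flatnonzero(mask)
    weight[rows, labels[rows]] = -1.0 / rows.size
    return ad.t_sum(lp * Tensor(weight))


@dataclass
class TrainedModel:
    """Trained parameters plus the configuration and training log."""

    params: dict[str, Tensor]
    config: GATConfig
    n_genes: int
    n_proteins: int
    training_log: list[dict] = field(default_factory=list)
    best_val_accuracy: float = float("nan")
    best_epoch: int = -1

    def forward_arrays(self, graph: HeteroGraph) -> _GraphArrays:
        if graph.x_patient.shape[1] != self.n_genes or graph.n_proteins != self.n_proteins:
            raise ValueError(
                f"graph schema mismatch: trained on {self.n_genes} genes / "
                f"{self.n_proteins} proteins, got {graph.x_patient.shape[1]} / {graph.n_proteins}"
            )
        return _GraphArrays(graph)

    def logits(self, graph: HeteroGraph, edge_mask: Tensor | None = None) -> Tensor:
        return forward(self.params, self.forward_arrays(graph), self.config, edge_mask)

    def checksum(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.params[name].data).tobytes())
        return h.hexdigest()

    # Checkpointing --------------------------------------------------
    def save(self, path) -> None:
        """Parameters plus config and schema in one ``.npz`` checkpoint;
        the training log goes to ``<path>.log.csv``."""
        import dataclasses
        import json

        meta = {
            "config": dataclasses.asdict(self.config),
            "n_genes": self.n_genes,
            "n_proteins": self.n_proteins,
            "best_val_accuracy": self.best_val_accuracy,
            "best_epoch": self.best_epoch,
            "checksum": self.checksum(),
        }
        arrays = {name: p.data for name, p in self.params.items()}
        np.savez(path, __meta__=json.dumps(meta), **arrays)
        if self.training_log:
            import pandas as pd

            pd.DataFrame(self.training_log).to_csv(f"{path}.log.csv", index=False)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        import json

        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            params = {
                name: Tensor(data[name], requires_grad=True)
                for name in data.files
                if name != "__meta__"
            }
        model = cls(
            params=params,
            config=GATConfig(**meta["config"]),
            n_genes=meta["n_genes"],
            n_proteins=meta["n_proteins"],
            best_val_accuracy=meta["best_val_accuracy"],
            best_epoch=meta["best_epoch"],
        )
        if model.checksum() != meta["checksum"]:
            raise ValueError(f"checkpoint {path} is corrupt: checksum mismatch")
        return model


def _accuracy(logits: np.ndarray, labels: np.ndarray, mask: np.ndarray) -> float:
    rows = np.flatnonzero(mask)
    pred = logits[rows].argmax(axis=1)
    return float((pred == labels[rows]).mean())


def train_gat(graph: HeteroGraph, config: GATConfig) -> TrainedModel:
    """Train on the train mask, early-stop on validation accuracy.

    Stops after ``patience`` epochs without validation improvement or at
    ``max_epochs``; parameters are restored from the best-validation epoch.
    """
    train_mask = graph.masks["train"]
    val_mask = graph.masks["val"]
    if not train_mask.any() or not val_mask.any():
        raise ValueError("train and validation masks must be nonempty")
    if len(np.unique(graph.labels[train_mask])) < 2:
        raise ValueError("train mask must contain both classes")

    arrays = _GraphArrays(graph)
    params = init_params(graph.x_patient.shape[1], graph.n_proteins, config)
    model = TrainedModel(params, config, graph.x_patient.shape[1], graph.n_proteins)
    opt = ad.Adam(params.values(), lr=config.learning_rate)

    best = {name: p.data.copy() for name, p in params.items()}
    best_val, best_loss, best_epoch, stale = -np.inf, np.inf, -1, 0
    for epoch in range(config.max_epochs):
        opt.zero_grad()
        logits = forward(params, arrays, config)
        loss = _cross_entropy(logits, graph.labels, train_mask)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        # metrics and the best-parameter snapshot refer to the parameters
        # this forward pass evaluated, i.e. before the update below
        val_acc = _accuracy(logits.data, graph.labels, val_mask)
        model.training_log.append(
            {
                "epoch": epoch,
                "train_loss": float(loss.data),
                "train_accuracy": _accuracy(logits.data, graph.labels, train_mask),
                "val_accuracy": val_acc,
            }
        )
        improved = val_acc > best_val
        # equal validation accuracy: prefer the better-fit parameters, but
        # only a strict validation improvement resets the patience clock
        if improved or (val_acc == best_val and loss.data < best_loss):
            best_loss, best_epoch = float(loss.data), epoch
            best = {name: p.data.copy() for name, p in params.items()}
        if improved:
            best_val, stale = val_acc, 0
        else:
            stale += 1
            if stale >= config.patience:
                break
        loss.backward()
        opt.step()
    for name, p in params.items():
        p.data = best[name]
    model.best_val_accuracy = best_val if np.isfinite(best_val) else float("nan")
    model.best_epoch = best_epoch
    return model


def predict_proba(model: TrainedModel, graph: HeteroGraph) -> np.ndarray:
    """Per-patient (p_control, p_case) by softmax over the two logits."""
    logits = model.logits(graph).data
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)
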
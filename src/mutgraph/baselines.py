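"""Comparison models: logistic regression, a 4-layer MLP, and the
per-patient homogeneous-graph classifier.

All three consume the identical patient feature matrix the heterogeneous
model uses.  The homogeneous baseline follows the common PPI-network
setup: one graph per patient with the shared PPI topology, protein nodes
carrying the patient's scalar feature for the corresponding gene, and a
graph-level prediction by mean pooling — a graph classification problem
rather than node classification.  Because every patient graph shares its
topology, all graphs are processed in one batched forward pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from . import _autodiff as ad
from ._autodiff import SegmentIndex, Tensor
from .features import FeatureMatrix
from .gat_model import GATConfig
from .synthetic import CohortBundle

__all__ = ["HomogeneousGraphSet", "fit_predict_lr", "fit_predict_mlp", "homogeneous_gnn_classify"]


def fit_predict_lr(features: FeatureMatrix, labels: np.ndarray, masks) -> np.ndarray:
    """Unregularised maximum-likelihood logistic regression on train rows;
    (p_control, p_case) for every patient."""
    X, y = features.values, np.asarray(labels)
    train = masks["train"]
    if len(np.unique(y[train])) < 2:
        raise ValueError("train mask must contain both classes")
    if np.any(X[train].std(axis=0) == 0):
        warnings.warn("constant feature column(s) in training rows", stacklevel=2)
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)  # unregularised
    clf.fit(X[train], y[train])
    proba = clf.predict_proba(X)
    order = np.argsort(clf.classes_)
    return proba[:, order]


def _mlp_widths(d_in: int, n_weight_layers: int = 4) -> list[int]:
    """Geometric taper from the input width down to the 2 logits, with a
    floor of 16 hidden units so narrow inputs still get capacity."""
    ratio = (2.0 / d_in) ** (1.0 / n_weight_layers)
    dims = [d_in] + [max(16, round(d_in * ratio**i)) for i in range(1, n_weight_layers)] + [2]
    return dims


def fit_predict_mlp(
    features: FeatureMatrix,
    labels: np.ndarray,
    masks,
    seed: int = 0,
    hidden_layers: int = 4,
    gat_config: GATConfig = GATConfig(),
) -> np.ndarray:
    """Feed-forward classifier with 4 weight layers (geometric taper), ELU
    activations, Adam at the shared learning rate, and the same
    early-stopping contract as the graph model."""
    X, y = features.values, np.asarray(labels)
    train, val = masks["train"], masks["val"]
    if len(np.unique(y[train])) < 2:
        raise ValueError("train mask must contain both classes")
    dims = _mlp_widths(X.shape[1], hidden_layers)
    rng = np.random.default_rng(seed)
    params = []
    for a, b in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (a + b))
        params.append(Tensor(rng.uniform(-limit, limit, size=(a, b)), requires_grad=True))
        params.append(Tensor(np.zeros(b), requires_grad=True))
    opt = ad.Adam(params, lr=gat_config.learning_rate)
    Xt = Tensor(X)

    def forward() -> Tensor:
        h = Xt
        for i in range(0, len(params), 2):
            h = ad.matmul(h, params[i]) + params[i + 1]
            if i < len(params) - 2:
                h = ad.elu(h)
        return h

    weight = np.zeros((y.size, 2))
    rows = np.flatnonzero(train)
    weight[rows, y[rows]] = -1.0 / rows.size
    best = [p.data.copy() for p in params]
    best_val, best_loss, stale = -np.inf, np.inf, 0
    for epoch in range(gat_config.max_epochs):
        opt.zero_grad()
        logits = forward()
        loss = ad.t_sum(ad.log_softmax(logits) * Tensor(weight))
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite MLP loss at epoch {epoch}")
        val_acc = float((logits.data[val].argmax(axis=1) == y[val]).mean())
        improved = val_acc > best_val
        if improved or (val_acc == best_val and loss.data < best_loss):
            best_loss = float(loss.data)
            best = [p.data.copy() for p in params]
        if improved:
            best_val, stale = val_acc, 0
        else:
            stale += 1
            if stale >= gat_config.patience:
                break
        loss.backward()
        opt.step()
    for p, b in zip(params, best):
        p.data = b
    logits = forward().data
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class HomogeneousGraphSet:
    """One PPI-topology graph per patient; only the node scalars differ.

    ``node_scalars[p, j]`` is patient p's feature value for the gene of
    protein j; ``edges`` holds both directions of every PPI pair.
    """

    node_scalars: np.ndarray  # n_patients x n_proteins
    edge_src: np.ndarray
    edge_dst: np.ndarray
    n_proteins: int

    @classmethod
    def from_bundle(cls, features: FeatureMatrix, bundle: CohortBundle) -> "HomogeneousGraphSet":
        e = bundle.ppi
        prot_index = {p: i for i, p in enumerate(bundle.catalog.proteins)}
        pairs = sorted(tuple(sorted(x)) for x in e.edges)
        src = np.array([prot_index[a] for a, b in pairs] + [prot_index[b] for a, b in pairs])
        dst = np.array([prot_index[b] for a, b in pairs] + [prot_index[a] for a, b in pairs])
        return cls(features.values, src, dst, len(bundle.catalog))


def homogeneous_gnn_classify(
    graphset: HomogeneousGraphSet,
    config: GATConfig,
    labels: np.ndarray,
    masks,
    chunk_size: int = 40,
) -> np.ndarray:
    """Two attention layers on each patient graph, mean pooling over
    nodes, then a two-logit head; same training contract as the
    heterogeneous model.

    Because all patient graphs share topology they are evaluated as one
    batched tensor program; patients are processed in chunks of
    ``chunk_size`` with gradient accumulation, which reproduces the
    full-batch gradient while bounding memory."""
    y = np.asarray(labels)
    train, val = masks["train"], masks["val"]
    if len(np.unique(y[train])) < 2:
        raise ValueError("train mask must contain both classes")
    h, d = config.heads, config.hidden_units
    hd = h * d
    n_prot = graphset.n_proteins
    seg_src = SegmentIndex(graphset.edge_src, n_prot)
    seg_dst = SegmentIndex(graphset.edge_dst, n_prot)
    n_edges = graphset.edge_src.size

    rng = np.random.default_rng(config.seed)

    def glorot(shape):
        fan_in, fan_out = shape[0], int(np.prod(shape[1:]))
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)

    p = {
        "l1.W": glorot((1, hd)), "l1.a_src": glorot((h, d)), "l1.a_dst": glorot((h, d)),
        "l1.b": Tensor(np.zeros(hd), requires_grad=True),
        "l2.W": glorot((hd, hd)), "l2.a_src": glorot((h, d)), "l2.a_dst": glorot((h, d)),
        "l2.b": Tensor(np.zeros(d), requires_grad=True),
        "head.W": glorot((d, 2)), "head.b": Tensor(np.zeros(2), requires_grad=True),
    }
    B = graphset.node_scalars.shape[0]
    chunks = [np.arange(i, min(i + chunk_size, B)) for i in range(0, B, chunk_size)]

    def layer(h_in: Tensor, b: int, W, a_src, a_dst, bias, final: bool) -> Tensor:
        hp = ad.reshape(ad.matmul(h_in, W), (b, n_prot, h, d))
        ss = ad.t_sum(hp * a_src, axis=-1)  # (b, N, H)
        sd = ad.t_sum(hp * a_dst, axis=-1)
        logit = ad.leaky_relu(
            ad.gather(ss, seg_src, axis=1) + ad.gather(sd, seg_dst, axis=1), config.leaky_slope
        )
        m = seg_dst.scatter_max(logit.data, axis=1)
        z = ad.t_exp(logit - Tensor(np.take(m, seg_dst.idx, axis=1)))
        denom = ad.segment_sum(z, seg_dst, axis=1)
        att = z / ad.gather(denom, seg_dst, axis=1)
        msg = ad.gather(hp, seg_src, axis=1) * ad.reshape(att, (b, n_edges, h, 1))
        agg = ad.segment_sum(msg, seg_dst, axis=1)  # (b, N, H, D)
        if final:
            return ad.t_sum(agg, axis=2) * (1.0 / h) + bias  # head average
        return ad.elu(ad.reshape(agg, (b, n_prot, hd)) + bias)

    def forward_chunk(idx: np.ndarray) -> Tensor:
        x = Tensor(graphset.node_scalars[idx][:, :, None])  # (b, N, 1)
        b = idx.size
        h1 = layer(x, b, p["l1.W"], p["l1.a_src"], p["l1.a_dst"], p["l1.b"], final=False)
        h2 = layer(h1, b, p["l2.W"], p["l2.a_src"], p["l2.a_dst"], p["l2.b"], final=True)
        pooled = ad.t_sum(h2, axis=1) * (1.0 / n_prot)  # mean over nodes
        return ad.matmul(pooled, p["head.W"]) + p["head.b"]

    opt = ad.Adam(p.values(), lr=config.learning_rate)
    weight = np.zeros((B, 2))
    rows = np.flatnonzero(train)
    weight[rows, y[rows]] = -1.0 / rows.size
    best = {k: v.data.copy() for k, v in p.items()}
    best_val, best_loss, stale = -np.inf, np.inf, 0
    for epoch in range(config.max_epochs):
        opt.zero_grad()
        total_loss, logits_np = 0.0, np.empty((B, 2))
        for idx in chunks:
            logits = forward_chunk(idx)
            logits_np[idx] = logits.data
            if weight[idx].any():
                loss = ad.t_sum(ad.log_softmax(logits) * Tensor(weight[idx]))
                loss.backward()  # leaf grads accumulate across chunks
                total_loss += float(loss.data)
        if not np.isfinite(total_loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        val_acc = float((logits_np[val].argmax(axis=1) == y[val]).mean())
        improved = val_acc > best_val
        if improved or (val_acc == best_val and total_loss < best_loss):
            best_loss = total_loss
            best = {k: v.data.copy() for k, v in p.items()}
        if improved:
            best_val, stale = val_acc, 0
        else:
            stale += 1
            if stale >= config.patience:
                break
        opt.step()
    for k, v in p.items():
        v.data = best[k]
    logits_np = np.concatenate([forward_chunk(idx).data for idx in chunks])
    e = np.exp(logits_np - logits_np.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)
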
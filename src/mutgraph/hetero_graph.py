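"""Assembly of the heterogeneous patient/protein graph.

The graph holds two node types and two edge types:

* protein-protein edges copied from the physical PPI network (undirected;
  the model layer materialises both directions for message passing);
* directed protein -> patient "mutation" edges.  Under the ``max``
  strategy a patient connects to the proteins of the ``k_edges`` genes with
  the largest strictly positive feature values; under ``random`` to
  ``k_edges`` proteins drawn uniformly without replacement (the
  information-free control arm).

Patient nodes carry their feature vectors; protein nodes carry one-hot
identity vectors of dimension |proteins|.  There are never patient->protein
or patient->patient edges, so patients are classified purely through
incoming protein messages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort_io import GeneCatalog, PPINetwork, ValidationError
from .features import FeatureMatrix

__all__ = ["EdgeConfig", "HeteroGraph", "select_top_genes", "make_mutation_edges", "assemble_graph"]


@dataclass(frozen=True)
class EdgeConfig:
    """Protein->patient edge construction policy."""

    strategy: str = "max"  # or "random"
    k_edges: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in ("max", "random"):
            raise ValueError(f"unknown edge strategy {self.strategy!r}")
        if self.k_edges < 1:
            raise ValueError("k_edges must be >= 1")


@dataclass
class HeteroGraph:
    """The assembled graph plus split masks and labels on patients."""

    patients: tuple[str, ...]
    proteins: tuple[str, ...]
    genes: tuple[str, ...]
    x_patient: np.ndarray  # |P| x |genes|
    e_ppi: np.ndarray  # 2 x E_ppi, one row per unordered pair
    e_mut_src: np.ndarray  # protein index per directed mutation edge
    e_mut_dst: np.ndarray  # patient index per directed mutation edge
    labels: np.ndarray  # |P|, case=1/control=0
    masks: dict[str, np.ndarray]  # train/val/test boolean masks over P
    config: EdgeConfig = field(default_factory=EdgeConfig)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def x_protein(self) -> np.ndarray:
        """One-hot protein feature block (identity under catalog order)."""
        return np.eye(self.n_proteins)

    def validate(self) -> None:
        if self.e_mut_src.size and (
            self.e_mut_src.max() >= self.n_proteins or self.e_mut_dst.max() >= self.n_patients
        ):
            raise ValidationError("mutation edge endpoint out of range")
        stacked = np.stack([m.astype(bool) for m in self.masks.values()])
        if not np.all(stacked.sum(axis=0) == 1):
            raise ValidationError("masks must partition the patient set")

    # Serialization ---------------------------------------------------
    def save(self, out_dir) -> dict[str, Path]:
        """Three TSVs (patient features, PPI edges, mutation edges) plus a
        JSON manifest; byte-identical for identical inputs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "features": out / "patient_features.tsv",
            "ppi": out / "protein_protein_edges.tsv",
            "mut": out / "protein_patient_edges.tsv",
            "manifest": out / "manifest.json",
        }
        rows = ["patient\t" + "\t".join(self.genes)]
        for i, p in enumerate(self.patients):
            rows.append(p + "\t" + "\t".join(f"{v:.10g}" for v in self.x_patient[i]))
        paths["features"].write_text("\n".join(rows) + "\n")
        paths["ppi"].write_text(
            "".join(
                f"{self.proteins[a]}\t{self.proteins[b]}\n" for a, b in self.e_ppi.T
            )
        )
        paths["mut"].write_text(
            "".join(
                f"{self.proteins[s]}\t{self.patients[d]}\n"
                for s, d in zip(self.e_mut_src, self.e_mut_dst)
            )
        )
        mask_of = {}
        for name, m in self.masks.items():
            for i in np.flatnonzero(m):
                mask_of[self.patients[i]] = name
        manifest = {
            "n_patients": self.n_patients,
            "n_proteins": self.n_proteins,
            "n_ppi_edges": int(self.e_ppi.shape[1]),
            "n_mut_edges": int(self.e_mut_src.size),
            "edge_strategy": self.config.strategy,
            "k_edges": self.config.k_edges,
            "seed": self.config.seed,
            "masks": mask_of,
        }
        paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
        return paths

    def checksum(self) -> str:
        h = hashlib.sha256()
        for arr in (self.x_patient, self.e_ppi, self.e_mut_src, self.e_mut_dst, self.labels):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


def select_top_genes(feature_row: np.ndarray, k_edges: int) -> np.ndarray:
    """Indices of the ``k_edges`` largest strictly positive features.

    Ties break toward the smaller gene index; with fewer than ``k_edges``
    positive features all positive indices are returned.  Order of the
    result is by descending feature value.
    """
    row = np.asarray(feature_row, dtype=np.float64)
    order = np.lexsort((np.arange(row.size), -row))  # by -value, then index
    order = order[row[order] > 0]
    return order[:k_edges]


def make_mutation_edges(
    features: FeatureMatrix, config: EdgeConfig, n_proteins: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Build the directed protein->patient edge lists.

    Feature columns must align with the protein order, so gene index j is
    protein index j.  Returns (source protein indices, target patient
    indices).
    """
    values = features.values
    n_pat, n_genes = values.shape
    n_prot = n_genes if n_proteins is None else n_proteins
    src_parts, dst_parts = [], []
    if config.strategy == "max":
        for i in range(n_pat):
            top = select_top_genes(values[i], config.k_edges)
            src_parts.append(top)
            dst_parts.append(np.full(top.size, i, dtype=np.int64))
    else:
        if config.k_edges > n_prot:
            raise ValueError(
                f"random strategy needs k_edges <= n_proteins ({config.k_edges} > {n_prot})"
            )
        rng = np.random.default_rng(config.seed)
        for i in range(n_pat):
            chosen = rng.choice(n_prot, size=config.k_edges, replace=False)
            src_parts.append(np.sort(chosen))
            dst_parts.append(np.full(config.k_edges, i, dtype=np.int64))
    src = np.concatenate(src_parts) if src_parts else np.empty(0, dtype=np.int64)
    dst = np.concatenate(dst_parts) if dst_parts else np.empty(0, dtype=np.int64)
    return src.astype(np.int64), dst


def assemble_graph(
    features: FeatureMatrix,
    labels: np.ndarray,
    ppi: PPINetwork,
    catalog: GeneCatalog,
    config: EdgeConfig,
    masks: dict[str, np.ndarray],
) -> HeteroGraph:
    """Assemble the full heterogeneous graph.

    Requires the gene<->protein bijection between feature columns (catalog
    order) and the PPI protein set; protein index j corresponds to gene j.
    """
    proteins = catalog.proteins
    unmapped = set(ppi.proteins) - set(proteins)
    missing = set(proteins) - set(ppi.proteins)
    if missing:
        raise ValidationError(
            f"catalog proteins absent from the PPI network: {sorted(missing)[:5]}"
        )
    if unmapped:
        raise ValidationError(
            f"PPI proteins without a catalog gene: {sorted(unmapped)[:5]}"
        )
    prot_index = {p: i for i, p in enumerate(proteins)}
    pairs = sorted(tuple(sorted(e)) for e in ppi.edges)
    e_ppi = (
        np.array([[prot_index[a] for a, _ in pairs], [prot_index[b] for _, b in pairs]])
        if pairs
        else np.empty((2, 0), dtype=np.int64)
    )
    src, dst = make_mutation_edges(features, config, n_proteins=len(proteins))
    graph = HeteroGraph(
        patients=features.patients,
        proteins=proteins,
        genes=catalog.genes,
        x_patient=features.values.astype(np.float64),
        e_ppi=e_ppi.astype(np.int64),
        e_mut_src=src,
        e_mut_dst=dst,
        labels=np.asarray(labels, dtype=np.int64),
        masks={k: np.asarray(v, dtype=bool) for k, v in masks.items()},
        config=config,
    )
    graph.validate()
    return graph
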
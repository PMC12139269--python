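"""Synthetic cohorts with planted disease genes and a scale-free PPI.

The generator emulates the statistical structure the classifier assumes: a
balanced case/control cohort, background mutation counts in every gene, a
subset of "planted" disease-associated genes whose mutation rate is
elevated in cases, and a connected undirected protein network grown by
preferential attachment.  Planted genes are the recovery ground truth for
the explainer.

Counts are Poisson by default; a negative-binomial option adds the
overdispersion real exome counts show.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .cohort_io import (
    CASE,
    CONTROL,
    CohortLabels,
    GeneCatalog,
    MutationMatrix,
    PPINetwork,
)

__all__ = ["SyntheticSpec", "CohortBundle", "generate_ppi", "generate_cohort", "write_fixture_files"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters of the planted-signal cohort.

    ``background_rate`` is the expected number of mutation events per gene
    per patient; planted genes in case patients mutate at
    ``background_rate * effect_multiplier``.
    """

    n_case: int = 100
    n_control: int = 100
    n_genes: int = 500
    n_planted: int = 25
    background_rate: float = 0.2
    effect_multiplier: float = 5.0
    ppi_attachment: int = 2
    dispersion: float | None = None  # negative-binomial shape; None = Poisson
    plant_on_hubs: bool = False  # place planted genes on the highest-degree proteins
    seed: int = 0

    def __post_init__(self):
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted must not exceed n_genes")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be positive")
        if self.effect_multiplier < 1:
            raise ValueError("effect_multiplier must be >= 1")


@dataclass
class CohortBundle:
    """Everything one analysis needs, plus the planted ground truth."""

    matrix: MutationMatrix
    labels: CohortLabels
    catalog: GeneCatalog
    ppi: PPINetwork
    planted_genes: tuple[str, ...]
    spec: SyntheticSpec


def generate_ppi(n_proteins: int, attachment: int = 2, seed: int = 0) -> PPINetwork:
    """Connected undirected network grown by preferential attachment
    (uniform confidence score 999), proteins named ``PR%05d``."""
    if not n_proteins > attachment >= 1:
        raise ValueError("need n_proteins > attachment >= 1")
    g = nx.barabasi_albert_graph(n_proteins, attachment, seed=seed)
    names = [f"PR{i:05d}" for i in range(n_proteins)]
    edges = {frozenset((names[u], names[v])) for u, v in g.edges()}
    return PPINetwork(
        proteins=tuple(names),
        edges=edges,
        score={e: 999 for e in edges},
        gene_of={f"PR{i:05d}": f"G{i:05d}" for i in range(n_proteins)},
    )


def generate_cohort(spec: SyntheticSpec = SyntheticSpec()) -> CohortBundle:
    """Draw a balanced cohort with planted genes and its PPI network.

    Counts follow Poisson(background_rate), except planted genes in case
    patients which follow Poisson(background_rate * effect_multiplier).
    Planted genes are chosen uniformly among catalog genes by default, so
    graph topology carries no planting information; with
    ``plant_on_hubs`` they sit on the highest-degree proteins instead,
    for studying the interaction-borne signal path.
    """
    rng = np.random.default_rng(spec.seed)
    ppi = generate_ppi(spec.n_genes, spec.ppi_attachment, seed=spec.seed)
    genes = tuple(sorted(ppi.gene_of[p] for p in ppi.proteins))
    protein_by_gene = {g: p for p, g in ppi.gene_of.items()}
    catalog = GeneCatalog(genes, {g: protein_by_gene[g] for g in genes})

    n = spec.n_case + spec.n_control
    patients = tuple(f"P{i:05d}" for i in range(n))
    y = np.array([CASE] * spec.n_case + [CONTROL] * spec.n_control)
    if spec.plant_on_hubs:
        degree: dict[str, int] = {}
        for e in ppi.edges:
            for prot in e:
                degree[prot] = degree.get(prot, 0) + 1
        hubs = sorted(ppi.proteins, key=lambda prot: (-degree.get(prot, 0), prot))
        hub_genes = [ppi.gene_of[prot] for prot in hubs[: spec.n_planted]]
        planted_idx = np.sort([catalog.index_of[g] for g in hub_genes])
    else:
        planted_idx = np.sort(rng.choice(spec.n_genes, size=spec.n_planted, replace=False))
    mean = np.full((n, spec.n_genes), spec.background_rate)
    mean[np.ix_(y == CASE, planted_idx)] *= spec.effect_multiplier
    if spec.dispersion is None:
        counts = rng.poisson(mean)
    else:  # gamma-Poisson mixture with shape = dispersion
        lam = rng.gamma(spec.dispersion, mean / spec.dispersion)
        counts = rng.poisson(lam)
    matrix = MutationMatrix(patients, counts.astype(np.int64), catalog)
    labels = CohortLabels({p: int(c) for p, c in zip(patients, y)})
    return CohortBundle(
        matrix=matrix,
        labels=labels,
        catalog=catalog,
        ppi=ppi,
        planted_genes=tuple(genes[i] for i in planted_idx),
        spec=spec,
    )


def write_fixture_files(bundle: CohortBundle, out_dir, vcf: bool = False) -> dict[str, Path]:
    """Serialize a bundle into the input dialects the readers accept.

    Emits a count TSV, labels TSV, gene list, StringDB-dialect links file
    and protein->gene mapping TSV; with ``vcf=True`` also one minimal
    sites-only VCF per patient carrying ``GENE=`` INFO tags.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genes = bundle.catalog.genes
    lines = ["patient\t" + "\t".join(genes)]
    for i, p in enumerate(bundle.matrix.patients):
        lines.append(p + "\t" + "\t".join(str(c) for c in bundle.matrix.counts[i]))
    paths["counts"] = out / "counts.tsv"
    paths["counts"].write_text("\n".join(lines) + "\n")

    paths["labels"] = out / "labels.tsv"
    paths["labels"].write_text(
        "".join(f"{p}\t{'case' if c == CASE else 'control'}\n" for p, c in bundle.labels.label.items())
    )

    paths["genes"] = out / "genes.txt"
    paths["genes"].write_text("".join(g + "\n" for g in genes))

    paths["links"] = out / "ppi_links.txt"
    rows = sorted(tuple(sorted(e)) for e in bundle.ppi.edges)
    paths["links"].write_text(
        "protein1 protein2 combined_score\n"
        + "".join(f"{a} {b} {bundle.ppi.score[frozenset((a, b))]}\n" for a, b in rows)
    )

    paths["mapping"] = out / "protein_gene_map.tsv"
    paths["mapping"].write_text(
        "".join(f"{p}\t{bundle.ppi.gene_of[p]}\n" for p in bundle.ppi.proteins)
    )

    if vcf:
        vcf_dir = out / "vcf"
        vcf_dir.mkdir(exist_ok=True)
        header = (
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=GENE,Number=.,Type=String,Description="Annotated gene symbol">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        for i, p in enumerate(bundle.matrix.patients):
            body, pos = [], 1000
            for j, g in enumerate(genes):
                for _ in range(int(bundle.matrix.counts[i, j])):
                    body.append(f"1\t{pos}\t.\tA\tT\t.\tPASS\tGENE={g}\n")
                    pos += 10
            (vcf_dir / f"{p}.vcf").write_text(header + "".join(body))
        paths["vcf_dir"] = vcf_dir
    return paths
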
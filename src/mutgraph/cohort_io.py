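"""Reading and validation of cohort inputs.

The analysis consumes four kinds of files: per-patient variant calls (VCF)
or a pre-tabulated patients x genes mutation-count table, a case/control
label table, a candidate gene list (plain text or GMT), and a physical
protein-protein interaction (PPI) edge list in the whitespace-separated
StringDB links dialect together with a protein-to-gene mapping.

The gene universe for an analysis is the intersection of (i) genes mutated
in the cohort, (ii) genes on the candidate list, and (iii) genes whose
protein appears in the PPI network; see :func:`build_gene_catalog`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CASE, CONTROL = 1, 0

_LABEL_ALIASES = {"case": CASE, "1": CASE, "control": CONTROL, "0": CONTROL}


class ValidationError(ValueError):
    """An input violates a structural invariant."""


@dataclass(frozen=True)
class GeneCatalog:
    """Ordered analysis gene universe with its gene<->protein bijection."""

    genes: tuple[str, ...]
    protein_of: Mapping[str, str]

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene identifiers in catalog")
        prots = [self.protein_of[g] for g in self.genes]
        if len(set(prots)) != len(prots):
            raise ValidationError("gene->protein map is not one-to-one")

    @property
    def index_of(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(self.protein_of[g] for g in self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class MutationMatrix:
    """Patients x genes nonnegative integer mutation-event counts."""

    patients: tuple[str, ...]
    counts: np.ndarray
    catalog: GeneCatalog

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if len(set(self.patients)) != len(self.patients):
            raise ValidationError("duplicate patient identifiers")
        if self.counts.shape != (len(self.patients), len(self.catalog)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.patients)} patients x {len(self.catalog)} genes"
            )
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)) or np.any(self.counts < 0):
                raise ValidationError("counts must be nonnegative integers")
            self.counts = self.counts.astype(np.int64)


@dataclass
class CohortLabels:
    """Case/control assignment, one label per patient."""

    label: dict[str, int]

    def vector(self, patients: Sequence[str]) -> np.ndarray:
        missing = [p for p in patients if p not in self.label]
        if missing:
            raise ValidationError(f"patients without a label: {missing[:5]}")
        return np.array([self.label[p] for p in patients], dtype=np.int64)


@dataclass
class PPINetwork:
    """Undirected physical PPI network restricted to gene-mapped proteins."""

    proteins: tuple[str, ...]
    edges: set[frozenset]
    score: dict[frozenset, int] = field(default_factory=dict)
    gene_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        known = set(self.proteins)
        for e in self.edges:
            if len(e) != 2:
                raise ValidationError(f"self-edge or malformed edge {set(e)}")
            if not e <= known:
                raise ValidationError(f"edge endpoint outside protein list: {set(e)}")

    @property
    def genes(self) -> set[str]:
        return {self.gene_of[p] for p in self.proteins if p in self.gene_of}


def read_labels(path) -> CohortLabels:
    """Read a two-column TSV ``patient<TAB>label``, label in {case,control,1,0}."""
    label: dict[str, int] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{ln}: expected patient<TAB>label")
        patient, raw = parts[0].strip(), parts[1].strip().lower()
        if raw not in _LABEL_ALIASES:
            raise ValidationError(f"{path}:{ln}: unknown label {parts[1]!r}")
        if patient in label:
            raise ValidationError(f"{path}:{ln}: duplicate patient {patient!r}")
        label[patient] = _LABEL_ALIASES[raw]
    return CohortLabels(label)


def read_gene_list(path) -> set[str]:
    """Read a candidate gene list: one symbol per line, or GMT rows
    (set name, description, then member genes)."""
    genes: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        if "\t" in line:
            fields = line.split("\t")
            genes.update(g.strip() for g in fields[2:] if g.strip())
        else:
            genes.add(line.strip())
    return genes


def read_mutation_counts(
    vcf_paths: Mapping[str, str | Path],
    catalog: GeneCatalog,
    gene_key: str = "GENE",
    pass_only: bool = False,
    allele_dosage: bool = False,
) -> MutationMatrix:
    """Count variant records per catalog gene, one VCF file per patient.

    ``vcf_paths`` maps patient identifier -> VCF path.  Each record counts
    one mutation event for every catalog gene listed (comma-separated) in
    its ``gene_key`` INFO field; records without the field are skipped.
    With ``pass_only``, records whose FILTER is neither PASS nor missing
    ('.') are skipped.  With ``allele_dosage``, a record counts the number
    of alternate alleles carried by the (single) sample instead of one
    event per record; sites-only records still count one.
    """
    from cyvcf2 import VCF

    patients = tuple(vcf_paths)
    if len(set(patients)) != len(patients):
        raise ValidationError("duplicate patient identifier among VCF inputs")
    index_of = catalog.index_of
    counts = np.zeros((len(patients), len(catalog)), dtype=np.int64)
    for i, patient in enumerate(patients):
        path = str(vcf_paths[patient])
        try:
            reader = VCF(path)
        except Exception as exc:
            raise ValidationError(f"cannot parse VCF {path}: {exc}") from exc
        try:
            for rec in reader:
                if pass_only and rec.FILTER is not None:  # cyvcf2: None == PASS/'.'
                    continue
                value = rec.INFO.get(gene_key)
                if value is None:
                    continue
                weight = 1
                if allele_dosage and rec.gt_types is not None and len(rec.gt_types) == 1:
                    # 0=hom-ref, 1=het, 3=hom-alt (2 is unknown)
                    weight = {0: 0, 1: 1, 2: 0, 3: 2}[int(rec.gt_types[0])]
                for gene in str(value).split(","):
                    j = index_of.get(gene.strip())
                    if j is not None:
                        counts[i, j] += weight
        except Exception as exc:
            raise ValidationError(f"malformed record in {path}: {exc}") from exc
        finally:
            reader.close()
    return MutationMatrix(patients, counts, catalog)


def read_count_table(tsv_path, catalog: GeneCatalog) -> MutationMatrix:
    """Read a patients x genes count TSV and align columns to the catalog.

    Header row holds gene identifiers; the first column holds patient
    identifiers.  Catalog genes absent from the table become zero columns.
    """
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    try:
        values = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{tsv_path}: non-numeric cell in count table: {exc}") from exc
    bad = np.argwhere(~np.isfinite(values) | (values < 0) | (np.mod(values, 1) != 0))
    if bad.size:
        r, c = bad[0]
        raise ValidationError(
            f"{tsv_path}: non-integer or negative count at patient "
            f"{df.index[r]!r}, gene {df.columns[c]!r}"
        )
    counts = np.zeros((df.shape[0], len(catalog)), dtype=np.int64)
    for j, gene in enumerate(catalog.genes):
        if gene in df.columns:
            counts[:, j] = df[gene].to_numpy(dtype=np.int64)
    return MutationMatrix(tuple(str(p) for p in df.index), counts, catalog)


def read_ppi(links_path, mapping_path, min_score: int = 0) -> PPINetwork:
    """Read a StringDB-dialect physical links file plus a protein->gene TSV.

    Edges with combined score >= ``min_score`` are kept; reciprocal
    duplicate rows collapse to one undirected edge; self-edges are rejected
    with a warning; proteins without a mapped gene are dropped together
    with their edges.
    """
    gene_of: dict[str, str] = {}
    for ln, line in enumerate(Path(mapping_path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValidationError(f"{mapping_path}:{ln}: expected protein<TAB>gene")
        prot, gene = parts[0].strip(), parts[1].strip()
        if prot in gene_of:
            raise ValidationError(f"{mapping_path}:{ln}: protein {prot!r} mapped twice")
        gene_of[prot] = gene
    if len(set(gene_of.values())) != len(gene_of):
        raise ValidationError(f"{mapping_path}: protein<->gene mapping is not one-to-one")

    edges: set[frozenset] = set()
    score: dict[frozenset, int] = {}
    lines = Path(links_path).read_text().splitlines()
    for ln, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        p1, p2, raw = line.split()[:3]
        if ln == 1 and not raw.lstrip("-").isdigit():
            continue  # header row
        try:
            s = int(raw)
        except ValueError as exc:
            raise ValidationError(f"{links_path}:{ln}: non-numeric score {raw!r}") from exc
        if p1 == p2:
            warnings.warn(f"{links_path}:{ln}: self-edge {p1!r} ignored", stacklevel=2)
            continue
        if s < min_score or p1 not in gene_of or p2 not in gene_of:
            continue
        e = frozenset((p1, p2))
        edges.add(e)
        score[e] = max(s, score.get(e, s))
    proteins = tuple(sorted({p for e in edges for p in e}))
    return PPINetwork(proteins, edges, score, {p: gene_of[p] for p in proteins})


def build_gene_catalog(
    mutated_genes: Iterable[str],
    hallmark_genes: Iterable[str],
    ppi: PPINetwork,
) -> GeneCatalog:
    """Intersect cohort-mutated genes, the candidate list, and PPI-mapped
    genes into the ordered (lexicographic) analysis catalog."""
    mutated, hallmark = set(mutated_genes), set(hallmark_genes)
    if not mutated or not hallmark:
        raise ValidationError("mutated and candidate gene sets must be nonempty")
    protein_by_gene = {g: p for p, g in ppi.gene_of.items()}
    genes = sorted(mutated & hallmark & set(protein_by_gene))
    if not genes:
        raise ValidationError(
            "empty gene catalog: no gene is simultaneously mutated, on the "
            "candidate list, and mapped into the PPI network; review the "
            "score threshold and the protein->gene mapping"
        )
    return GeneCatalog(tuple(genes), {g: protein_by_gene[g] for g in genes})
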
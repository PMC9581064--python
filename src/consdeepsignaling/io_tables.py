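"""Reading, validation, filtering and alignment of the five input tables.

The model consumes GDSC-style CSV tables: a gene-expression matrix
(genes x cell lines, FPKM), a copy-number matrix (genes x cell lines,
integer GISTIC scores in {-2..2}), a fitted dose-response table of
(drug, cell line, AUC) triples, a drug -> target-gene map, and a
gene -> signaling-pathway membership table.  This module turns those five
tables into one aligned training dataset: a design matrix of per-sample
input vectors (K=3 features per gene, gene-major) plus AUC targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicsTable",
    "ResponseRecord",
    "PathwayMembership",
    "Alignment",
    "AlignedDataset",
    "read_omics_table",
    "write_omics_table",
    "read_response_table",
    "write_response_table",
    "read_drug_gene_pathway",
    "write_drug_gene_pathway",
    "filter_genes",
    "align_datasets",
    "build_sample_vector",
    "build_aligned_dataset",
    "write_predictions",
]

# Features per gene in the input layer: expression, copy number, is_target flag.
N_FEATURES_PER_GENE = 3


class TableError(ValueError):
    """Raised when an input table violates its format or invariants."""


@dataclass
class OmicsTable:
    """A named genes x cell-lines numeric matrix for one omics feature type.

    Parameters
    ----------
    feature_name
        Either ``"expression"`` (FPKM units) or ``"cnv"`` (integer GISTIC
        scores, -2 deep deletion .. +2 amplification).
    genes, cell_lines
        Ordered row / column labels; duplicates are an error.
    values
        Numeric matrix of shape ``(len(genes), len(cell_lines))``.
    """

    feature_name: str
    genes: list[str]
    cell_lines: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.cell_lines = [str(c) for c in self.cell_lines]
        self.values = np.asarray(self.values, dtype=float)
        if self.feature_name not in ("expression", "cnv"):
            raise TableError(
                f"feature_name must be 'expression' or 'cnv', got {self.feature_name!r}"
            )
        if len(set(self.genes)) != len(self.genes):
            raise TableError(f"duplicate gene symbols in {self.feature_name} table")
        if len(set(self.cell_lines)) != len(self.cell_lines):
            raise TableError(f"duplicate cell-line ids in {self.feature_name} table")
        if self.values.shape != (len(self.genes), len(self.cell_lines)):
            raise TableError(
                f"value matrix shape {self.values.shape} does not match "
                f"({len(self.genes)}, {len(self.cell_lines)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise TableError(f"non-finite values in {self.feature_name} table")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cell_lines)

    def value(self, gene: str, cell_line: str) -> float:
        i = self.genes.index(gene)
        j = self.cell_lines.index(cell_line)
        return float(self.values[i, j])

    def subset(self, genes: Sequence[str] | None = None,
               cell_lines: Sequence[str] | None = None) -> "OmicsTable":
        """Reindex to the given gene/cell-line orders (must all be present)."""
        frame = self.to_frame()
        if genes is not None:
            missing = set(genes) - set(self.genes)
            if missing:
                raise TableError(f"genes absent from {self.feature_name} table: {sorted(missing)[:5]}")
            frame = frame.loc[list(genes)]
        if cell_lines is not None:
            missing = set(cell_lines) - set(self.cell_lines)
            if missing:
                raise TableError(f"cell lines absent from {self.feature_name} table: {sorted(missing)[:5]}")
            frame = frame[list(cell_lines)]
        return OmicsTable(self.feature_name, list(frame.index), list(frame.columns),
                          frame.to_numpy())


@dataclass(frozen=True)
class ResponseRecord:
    """One fitted dose-response measurement: drug x cell line -> AUC in [0, 1]."""

    drug: str
    cell_line: str
    auc: float


@dataclass
class PathwayMembership:
    """Many-to-many gene -> signaling-pathway membership.

    ``order`` fixes the pathway ordering used for the pathway tier
    (s = len(order) nodes).
    """

    members: dict[str, set[str]]
    order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.order:
            self.order = sorted(self.members)
        if set(self.order) != set(self.members):
            raise TableError("pathway order does not match membership keys")
        if len(self.order) < 1:
            raise TableError("at least one pathway is required")
        for name, genes in self.members.items():
            if not genes:
                raise TableError(f"pathway {name!r} has no member genes")

    @property
    def n_pathways(self) -> int:
        return len(self.order)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.members.values():
            out |= genes
        return out

    def restricted(self, gene_order: Sequence[str]) -> "PathwayMembership":
        """Membership intersected with ``gene_order``; empty pathways are dropped."""
        universe = set(gene_order)
        members = {p: g & universe for p, g in self.members.items()}
        order = [p for p in self.order if members[p]]
        return PathwayMembership({p: members[p] for p in order}, order)


@dataclass
class Alignment:
    """Consistent gene / cell-line / drug universe across the five tables."""

    gene_order: list[str]
    cell_lines: list[str]
    drugs: list[str]
    responses: list[ResponseRecord]


@dataclass
class AlignedDataset:
    """The assembled training set.

    ``X`` has one row per (drug, cell line) response record; row layout is
    gene-major with ``n_features_per_gene`` consecutive features per gene:
    [expr(g1), cnv(g1), is_target(g1), expr(g2), ...].
    """

    gene_order: list[str]
    X: np.ndarray
    y: np.ndarray
    provenance: list[tuple[str, str]]
    n_features_per_gene: int = N_FEATURES_PER_GENE

    def __post_init__(self) -> None:
        n = len(self.gene_order)
        if self.X.shape != (len(self.y), self.n_features_per_gene * n):
            raise TableError(
                f"X shape {self.X.shape} does not match "
                f"({len(self.y)}, {self.n_features_per_gene}*{n})"
            )
        if len(self.provenance) != len(self.y):
            raise TableError("provenance length does not match sample count")

    @property
    def n_samples(self) -> int:
        return len(self.y)

    @property
    def n_genes(self) -> int:
        return len(self.gene_order)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_omics_table(path: str | Path, feature_name: str) -> OmicsTable:
    """Read a genes-as-rows, cell-lines-as-columns CSV matrix.

    The first column holds gene symbols; the header holds cell-line
    identifiers.  Non-numeric cells, duplicated labels and ragged rows are
    errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise TableError(f"{path}: empty CSV") from exc
    except pd.errors.ParserError as exc:
        raise TableError(f"{path}: malformed CSV ({exc})") from exc
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise TableError(f"{path}: table has no genes or no cell lines")
    values = frame.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = frame.index[np.isnan(values).any(axis=1)][:3].tolist()
        raise TableError(f"{path}: non-numeric or missing cells (e.g. genes {bad})")
    return OmicsTable(feature_name, [str(g) for g in frame.index],
                      [str(c) for c in frame.columns], values)


def write_omics_table(table: OmicsTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index_label="gene")


def read_response_table(path: str | Path) -> list[ResponseRecord]:
    """Read a GDSC2-style fitted dose-response CSV.

    Requires columns DRUG_NAME, CELL_LINE_NAME, AUC; duplicated
    (drug, cell line) pairs are an error.
    """
    frame = pd.read_csv(path)
    required = {"DRUG_NAME", "CELL_LINE_NAME", "AUC"}
    if not required.issubset(frame.columns):
        raise TableError(f"{path}: missing columns {sorted(required - set(frame.columns))}")
    records = [
        ResponseRecord(str(r.DRUG_NAME), str(r.CELL_LINE_NAME), float(r.AUC))
        for r in frame.itertuples(index=False)
    ]
    pairs = [(r.drug, r.cell_line) for r in records]
    if len(set(pairs)) != len(pairs):
        raise TableError(f"{path}: duplicated (drug, cell line) pairs")
    return records


def write_response_table(records: Sequence[ResponseRecord], path: str | Path) -> None:
    pd.DataFrame(
        {"DRUG_NAME": [r.drug for r in records],
         "CELL_LINE_NAME": [r.cell_line for r in records],
         "AUC": [r.auc for r in records]}
    ).to_csv(path, index=False)


def read_drug_gene_pathway(path: str | Path) -> tuple[dict[str, set[str]], PathwayMembership]:
    """Read the three-column (drug, gene, pathway) table.

    Rows with an empty drug field define pure gene-pathway membership; rows
    with a drug additionally declare that gene a target of that drug.
    """
    frame = pd.read_csv(path, keep_default_na=False)
    required = {"drug", "gene", "pathway"}
    if not required.issubset(frame.columns):
        raise TableError(f"{path}: missing columns {sorted(required - set(frame.columns))}")
    targets: dict[str, set[str]] = {}
    members: dict[str, set[str]] = {}
    for row in frame.itertuples(index=False):
        gene = str(row.gene).strip()
        pathway = str(row.pathway).strip()
        drug = str(row.drug).strip()
        if not gene:
            raise TableError(f"{path}: row with empty gene")
        if pathway:
            members.setdefault(pathway, set()).add(gene)
        if drug:
            targets.setdefault(drug, set()).add(gene)
    if not members:
        raise TableError(f"{path}: no gene-pathway membership rows")
    return targets, PathwayMembership(members)


def write_drug_gene_pathway(targets: Mapping[str, set[str]],
                            membership: PathwayMembership,
                            path: str | Path) -> None:
    rows = []
    for pathway in membership.order:
        for gene in sorted(membership.members[pathway]):
            rows.append({"drug": "", "gene": gene, "pathway": pathway})
    for drug in sorted(targets):
        for gene in sorted(targets[drug]):
            rows.append({"drug": drug, "gene": gene, "pathway": ""})
    pd.DataFrame(rows, columns=["drug", "gene", "pathway"]).to_csv(path, index=False)


def write_predictions(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a predictions table with columns drug, cell_line, auc_true, auc_pred, fold."""
    cols = ["drug", "cell_line", "auc_true", "auc_pred", "fold"]
    missing = set(cols) - set(frame.columns)
    if missing:
        raise TableError(f"prediction frame missing columns {sorted(missing)}")
    frame[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Filtering and alignment
# ---------------------------------------------------------------------------

def filter_genes(expr: OmicsTable, max_zero_fraction: float = 1.0 / 3.0) -> list[str]:
    """Genes whose fraction of zero expression values is <= ``max_zero_fraction``.

    Genes with strictly more than the threshold fraction of zeros across all
    cell lines are dropped (a gene with exactly one third zeros is kept).
    """
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise ValueError(f"max_zero_fraction must be in [0, 1], got {max_zero_fraction}")
    zero_frac = (expr.values == 0).mean(axis=1)
    keep = zero_frac <= max_zero_fraction
    return [g for g, k in zip(expr.genes, keep) if k]


def align_datasets(expr: OmicsTable,
                   cnv: OmicsTable,
                   targets: Mapping[str, set[str]],
                   pathways: PathwayMembership,
                   responses: Sequence[ResponseRecord],
                   max_zero_fraction: float = 1.0 / 3.0) -> Alignment:
    """Intersect the five tables into one consistent universe.

    Gene order = (zero-filtered expression genes) ∩ (CNV genes) ∩ (pathway
    member genes), sorted lexicographically.  Cell lines must appear in both
    omics tables.  A drug is retained iff at least one of its target genes
    survives into the gene order; responses are restricted to retained
    (drug, cell line) pairs.
    """
    kept_expr = set(filter_genes(expr, max_zero_fraction))
    gene_order = sorted(kept_expr & set(cnv.genes) & pathways.genes())
    if not gene_order:
        raise TableError("no genes shared by expression, CNV and pathway tables")
    cell_lines = sorted(set(expr.cell_lines) & set(cnv.cell_lines))
    if not cell_lines:
        raise TableError("no cell lines shared by expression and CNV tables")
    universe = set(gene_order)
    drugs = sorted(d for d, tg in targets.items() if tg & universe)
    if not drugs:
        raise TableError("no drug has a target gene inside the aligned gene universe")
    drug_set, cl_set = set(drugs), set(cell_lines)
    kept = [r for r in responses if r.drug in drug_set and r.cell_line in cl_set]
    if not kept:
        raise TableError("no response records survive alignment")
    return Alignment(gene_order, cell_lines, drugs, kept)


def build_sample_vector(drug: str,
                        cell_line: str,
                        expr: OmicsTable,
                        cnv: OmicsTable,
                        targets: Mapping[str, set[str]],
                        gene_order: Sequence[str]) -> np.ndarray:
    """Assemble the length-3n input vector for one (drug, cell line) pair.

    Gene-major layout: for the j-th gene (1-based) the block at positions
    3(j-1)+1 .. 3(j-1)+3 is [expression, copy number, is_target_of_drug].
    """
    if drug not in targets:
        raise KeyError(f"unknown drug {drug!r}")
    if cell_line not in expr.cell_lines or cell_line not in cnv.cell_lines:
        raise KeyError(f"unknown cell line {cell_line!r}")
    e = expr.subset(genes=gene_order).to_frame()[cell_line].to_numpy()
    c = cnv.subset(genes=gene_order).to_frame()[cell_line].to_numpy()
    t = np.array([1.0 if g in targets[drug] else 0.0 for g in gene_order])
    x = np.empty(3 * len(gene_order))
    x[0::3], x[1::3], x[2::3] = e, c, t
    return x


def build_aligned_dataset(expr: OmicsTable,
                          cnv: OmicsTable,
                          targets: Mapping[str, set[str]],
                          pathways: PathwayMembership,
                          responses: Sequence[ResponseRecord],
                          max_zero_fraction: float = 1.0 / 3.0,
                          zscore_expression: bool = False) -> tuple[AlignedDataset, PathwayMembership]:
    """Align all tables and assemble the design matrix in one pass.

    ``zscore_expression`` standardizes each gene's expression across the
    aligned cell lines before vector assembly (off by default: FPKM values
    are passed through raw).
    Returns the dataset together with the pathway membership restricted to
    the aligned gene universe (the basis of the gene -> pathway mask).
    """
    al = align_datasets(expr, cnv, targets, pathways, responses, max_zero_fraction)
    e = expr.subset(genes=al.gene_order, cell_lines=al.cell_lines)
    c = cnv.subset(genes=al.gene_order, cell_lines=al.cell_lines)
    evals = e.values
    if zscore_expression:
        mu = evals.mean(axis=1, keepdims=True)
        sd = evals.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        evals = (evals - mu) / sd
    col = {cl: j for j, cl in enumerate(al.cell_lines)}
    target_flags = {
        d: np.array([1.0 if g in targets[d] else 0.0 for g in al.gene_order])
        for d in al.drugs
    }
    n = len(al.gene_order)
    X = np.empty((len(al.responses), 3 * n))
    y = np.empty(len(al.responses))
    provenance = []
    for i, rec in enumerate(al.responses):
        j = col[rec.cell_line]
        X[i, 0::3] = evals[:, j]
        X[i, 1::3] = c.values[:, j]
        X[i, 2::3] = target_flags[rec.drug]
        y[i] = rec.auc
        provenance.append((rec.drug, rec.cell_line))
    dataset = AlignedDataset(al.gene_order, X, y, provenance)
    return dataset, pathways.restricted(al.gene_order)


def save_dataset_meta(dataset: AlignedDataset, path: str | Path) -> None:
    """Persist orderings/provenance so runs can be reproduced exactly."""
    meta = {
        "gene_order": dataset.gene_order,
        "n_features_per_gene": dataset.n_features_per_gene,
        "provenance": dataset.provenance,
    }
    Path(path).write_text(json.dumps(meta, indent=1))
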
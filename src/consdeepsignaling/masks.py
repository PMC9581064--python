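"""Binary connectivity masks for the two sparsity-constrained network tiers.

Two masks constrain the first two layers of the model:

* the gene-feature -> gene mask ``C_XG`` of shape (K*n, n), wiring each
  gene's K input features exclusively to that gene's node; and
* the gene -> pathway mask ``C_GP`` of shape (n, s), wiring each gene node
  to the signaling pathways it belongs to.

Each mask is element-wise multiplied with a weight matrix of the same
shape, so only biologically allowed connections carry signal.  Masks carry
their row/column entity labels so that an ordering mismatch between a mask
and the data it is applied to is detectable at model-build time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_tables import PathwayMembership

__all__ = [
    "MaskMatrix",
    "build_gene_feature_mask",
    "build_gene_pathway_mask",
    "write_mask_triplets",
    "read_mask_triplets",
]


@dataclass
class MaskMatrix:
    """A labelled binary connectivity matrix.

    Invariants: entries in {0, 1}; every column has at least one nonzero
    (a node with no incoming connection could never carry signal).
    """

    rows: list[str]
    cols: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ValueError(
                f"mask shape {self.values.shape} does not match labels "
                f"({len(self.rows)}, {len(self.cols)})"
            )
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("mask entries must be 0 or 1")
        if (self.values.sum(axis=0) == 0).any():
            empty = [c for c, s in zip(self.cols, self.values.sum(axis=0)) if s == 0]
            raise ValueError(f"mask columns with no connections: {empty[:5]}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nnz(self) -> int:
        return int(self.values.sum())


def build_gene_feature_mask(K: int, n: int,
                            gene_order: Sequence[str] | None = None,
                            feature_names: Sequence[str] | None = None) -> MaskMatrix:
    """The (K*n, n) block-diagonal gene-feature -> gene mask.

    Row i (1-based) connects to column j iff i = K*(j-1)+m for some
    m in 1..K, i.e. each gene's K consecutive features feed that gene's
    node and nothing else: exactly K nonzeros per column, exactly one per
    row.
    """
    if K < 1 or n < 1:
        raise ValueError(f"K and n must be positive, got K={K}, n={n}")
    genes = list(gene_order) if gene_order is not None else [f"g{j+1}" for j in range(n)]
    if len(genes) != n:
        raise ValueError(f"gene_order length {len(genes)} != n={n}")
    feats = list(feature_names) if feature_names is not None else [f"f{m+1}" for m in range(K)]
    if len(feats) != K:
        raise ValueError(f"feature_names length {len(feats)} != K={K}")
    values = np.kron(np.eye(n), np.ones((K, 1)))
    rows = [f"{g}:{f}" for g in genes for f in feats]
    return MaskMatrix(rows, genes, values)


def build_gene_pathway_mask(membership: PathwayMembership,
                            gene_order: Sequence[str]) -> MaskMatrix:
    """The (n, s) gene -> pathway membership mask.

    Entry (j, t) is 1 iff gene j belongs to pathway t; genes may belong to
    several pathways.  A pathway with no member inside ``gene_order`` is an
    error (its node could never activate).
    """
    genes = list(gene_order)
    index = {g: j for j, g in enumerate(genes)}
    values = np.zeros((len(genes), membership.n_pathways))
    for t, pathway in enumerate(membership.order):
        hit = False
        for g in membership.members[pathway]:
            j = index.get(g)
            if j is not None:
                values[j, t] = 1.0
                hit = True
        if not hit:
            raise ValueError(f"pathway {pathway!r} has no member gene in gene_order")
    return MaskMatrix(genes, list(membership.order), values)


def write_mask_triplets(mask: MaskMatrix, path: str | Path) -> None:
    """Export a mask as a sparse (row_label, col_label, 1) CSV for inspection."""
    ii, jj = np.nonzero(mask.values)
    pd.DataFrame(
        {"row_label": [mask.rows[i] for i in ii],
         "col_label": [mask.cols[j] for j in jj],
         "value": np.ones(len(ii), dtype=int)}
    ).to_csv(path, index=False)


def read_mask_triplets(path: str | Path,
                       rows: Sequence[str], cols: Sequence[str]) -> MaskMatrix:
    """Rebuild a mask from a sparse triplet CSV given its full label sets."""
    frame = pd.read_csv(path)
    ri = {r: i for i, r in enumerate(rows)}
    ci = {c: j for j, c in enumerate(cols)}
    values = np.zeros((len(rows), len(cols)))
    for rec in frame.itertuples(index=False):
        values[ri[str(rec.row_label)], ci[str(rec.col_label)]] = 1.0
    return MaskMatrix(list(rows), list(cols), values)
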
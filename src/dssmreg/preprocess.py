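"""Quality control, log-normalization, HVG selection, cell-type subsetting."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from dssmreg.types import CellAnnotation, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    scale_factor: float = 10_000.0
    n_hvg: int = 1_000
    min_cells_per_type: int = 50

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 1 or self.min_cells_per_gene < 1:
            raise ValueError("QC thresholds must be >= 1")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if self.n_hvg < 1 or self.min_cells_per_type < 1:
            raise ValueError("n_hvg and min_cells_per_type must be >= 1")


class EmptyAfterQCError(ValueError):
    pass


def qc_filter(m: ExpressionMatrix, cfg: PreprocessConfig) -> ExpressionMatrix:
    """Drop low-complexity cells, then rarely-detected genes.

    Cells expressing fewer than ``min_genes_per_cell`` genes are removed
    first; genes detected in fewer than ``min_cells_per_gene`` of the
    surviving cells are removed second. Survivor order is preserved.
    """
    if m.is_normalized:
        raise ValueError("qc_filter expects raw counts (is_normalized=False)")
    dense = m.dense()
    genes_per_cell = (dense > 0).sum(axis=0)
    keep_cells = genes_per_cell >= cfg.min_genes_per_cell
    if not keep_cells.any():
        raise EmptyAfterQCError(
            f"no cell expresses >= {cfg.min_genes_per_cell} genes; empty after QC"
        )
    dense = dense[:, keep_cells]
    cells_per_gene = (dense > 0).sum(axis=1)
    keep_genes = cells_per_gene >= cfg.min_cells_per_gene
    if not keep_genes.any():
        raise EmptyAfterQCError("no gene survives QC; empty after QC")
    kept_cells = [c for c, k in zip(m.cell_ids, keep_cells) if k]
    kept_genes = [g for g, k in zip(m.gene_ids, keep_genes) if k]
    logger.info(
        "QC kept %d/%d cells and %d/%d genes",
        len(kept_cells), m.n_cells, len(kept_genes), m.n_genes,
    )
    return ExpressionMatrix(dense[keep_genes, :], kept_genes, kept_cells, False)


def log_normalize(m: ExpressionMatrix, cfg: PreprocessConfig) -> ExpressionMatrix:
    """LogNormalize: x -> ln(1 + x * scale_factor / colsum), per cell."""
    if m.is_normalized:
        raise ValueError("matrix already normalized")
    dense = m.dense()
    colsums = dense.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        raise ValueError(
            f"cell(s) with zero total counts: {[m.cell_ids[j] for j in zero]}"
        )
    out = np.log1p(dense * (cfg.scale_factor / colsums))
    return ExpressionMatrix(out, list(m.gene_ids), list(m.cell_ids), True)


def select_hvg(
    m: ExpressionMatrix,
    n: int,
    tf_universe: set[str] | None = None,
) -> ExpressionMatrix:
    """Keep the n genes with largest variance across cells.

    Ties at the cut are broken by lexicographic gene id. Genes in
    ``tf_universe`` are always retained in addition to the top n, so
    regulon heads are never silently dropped. Input gene order is
    preserved among survivors.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > m.n_genes:
        warnings.warn(
            f"requested {n} HVGs but only {m.n_genes} genes present; keeping all",
            stacklevel=2,
        )
        n = m.n_genes
    dense = m.dense()
    variances = dense.var(axis=1, ddof=1) if m.n_cells > 1 else np.zeros(m.n_genes)
    order = sorted(range(m.n_genes), key=lambda i: (-variances[i], m.gene_ids[i]))
    chosen = {m.gene_ids[i] for i in order[:n]}
    if tf_universe:
        chosen |= set(tf_universe) & set(m.gene_ids)
    keep = [g for g in m.gene_ids if g in chosen]
    return m.subset_genes(keep)


def subset_by_celltype(
    m: ExpressionMatrix,
    ann: CellAnnotation,
    cell_type: str,
    cfg: PreprocessConfig,
) -> ExpressionMatrix:
    """Restrict columns to the cells of one annotated type."""
    if cell_type not in set(ann.labels.values()):
        raise ValueError(f"cell type {cell_type!r} not present in annotation")
    present = set(m.cell_ids)
    cells = [c for c in m.cell_ids if ann.labels.get(c) == cell_type and c in present]
    if len(cells) < cfg.min_cells_per_type:
        raise ValueError(
            f"cell type {cell_type!r} has {len(cells)} cells, below the "
            f"{cfg.min_cells_per_type}-cell floor"
        )
    return m.subset_cells(cells)
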
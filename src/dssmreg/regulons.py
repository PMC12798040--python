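"""Regulon assembly and rank-based activity scoring.

A regulon is a TF plus its retained targets in one cell type. Activity of
a regulon in a cell is the normalized area under the gene set's recovery
curve over the top-ranked genes of that cell (AUCell-style): genes are
ranked by descending expression (ties broken deterministically by gene
id), the curve R(i) counts set members among the top i genes for
i = 1..k with k = ceil(top_fraction * n_genes), and the area is divided
by its maximum attainable value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dssmreg.types import (
    CellAnnotation,
    ExpressionMatrix,
    Regulon,
    RegulonSet,
)

logger = logging.getLogger(__name__)


@dataclass
class AUCellConfig:
    top_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must be in (0, 1]")

    def rank_threshold(self, n_genes: int) -> int:
        return max(1, math.ceil(self.top_fraction * n_genes))


def build_regulons_threshold(t: pd.DataFrame, tau: float = 0.9) -> RegulonSet:
    """Keep TGs with cosine score strictly above tau, per (tf, cell_type).

    The cut is applied to the raw cosine score: a sigmoid-transformed
    probability can never exceed ~0.731, so thresholding the probability
    at 0.9 would always be empty.
    """
    if not -1.0 < tau < 1.0:
        raise ValueError("tau must be in (-1, 1)")
    regulons = []
    for (tf, ctype), grp in t.groupby(["tf", "cell_type"], sort=True):
        kept = grp[grp["score"] > tau]
        if kept.empty:
            continue
        kept = kept.sort_values(["score", "tg"], ascending=[False, True], kind="mergesort")
        regulons.append(
            Regulon(str(tf), str(ctype), list(zip(kept["tg"], kept["score"])))
        )
    return RegulonSet(regulons)


def build_regulons_topk(t: pd.DataFrame, k: int = 200) -> RegulonSet:
    """Keep the k highest-scoring TGs per (tf, cell_type).

    Boundary ties are broken by lexicographic tg id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    regulons = []
    for (tf, ctype), grp in t.groupby(["tf", "cell_type"], sort=True):
        kept = grp.sort_values(
            ["score", "tg"], ascending=[False, True], kind="mergesort"
        ).head(k)
        regulons.append(
            Regulon(str(tf), str(ctype), list(zip(kept["tg"], kept["score"])))
        )
    return RegulonSet(regulons)


def _rank_order(column: np.ndarray, gene_rank: np.ndarray) -> np.ndarray:
    """Indices of genes ordered by descending expression, ties by gene id."""
    return np.lexsort((gene_rank, -column))


def aucell_cell(
    expression_column: np.ndarray,
    gene_ids: list[str],
    gene_set: set[str],
    cfg: AUCellConfig | None = None,
) -> float:
    """AUCell score of one gene set in one cell."""
    cfg = cfg or AUCellConfig()
    if not gene_set:
        raise ValueError("empty gene set")
    column = np.asarray(expression_column, dtype=float)
    n = len(gene_ids)
    if column.shape != (n,):
        raise ValueError("expression column length does not match gene_ids")
    unknown = gene_set - set(gene_ids)
    if unknown:
        raise ValueError(f"gene set members absent from gene universe: {sorted(unknown)}")
    k = cfg.rank_threshold(n)
    gene_rank = np.argsort(np.argsort(np.asarray(gene_ids)))
    order = _rank_order(column, gene_rank)
    member = np.isin(np.asarray(gene_ids)[order], list(gene_set))
    return _auc_from_ranks(np.flatnonzero(member) + 1, len(gene_set), k)


def _auc_from_ranks(member_ranks: np.ndarray, set_size: int, k: int) -> float:
    """Area of the recovery curve over ranks 1..k, max-normalized."""
    raw = int(np.sum(k - member_ranks[member_ranks <= k] + 1))
    c = min(set_size, k)
    max_raw = c * (c + 1) // 2 + (k - c) * c
    return raw / max_raw


@dataclass
class RegulonActivity:
    """Per-cell AUC values per regulon, with per-type means and rankings."""

    auc: pd.DataFrame  # index: "tf::cell_type" regulon keys; columns: cell ids
    mean_by_type: pd.DataFrame  # index: regulon keys; columns: annotation types
    ranking: dict[str, list[str]]  # annotation type -> regulon keys, best first
    excluded: list[str] = field(default_factory=list)
    dropped_genes: int = 0


def regulon_key(r: Regulon) -> str:
    return f"{r.tf_id}::{r.cell_type}"


def prioritize(
    m: ExpressionMatrix,
    regs: RegulonSet,
    ann: CellAnnotation,
    cfg: AUCellConfig | None = None,
) -> RegulonActivity:
    """Score every regulon in every cell and rank by per-type mean AUC.

    Regulon genes absent from the matrix are dropped (count logged);
    regulons left with zero genes are excluded and reported.
    """
    cfg = cfg or AUCellConfig()
    gene_ids = np.asarray(m.gene_ids)
    universe = set(m.gene_ids)
    dense = m.dense()
    n = m.n_genes
    k = cfg.rank_threshold(n)
    gene_rank = np.argsort(np.argsort(gene_ids))

    usable: list[tuple[str, np.ndarray, int]] = []
    excluded: list[str] = []
    dropped_total = 0
    member_masks = []
    for r in regs:
        present = [g for g in r.target_genes() if g in universe]
        dropped_total += len(r.targets) - len(present)
        if not present:
            excluded.append(regulon_key(r))
            continue
        mask = np.isin(gene_ids, present)
        usable.append((regulon_key(r), mask, len(present)))
        member_masks.append(mask)
    if dropped_total:
        logger.info("dropped %d regulon gene(s) absent from the matrix", dropped_total)
    if excluded:
        logger.warning("excluded %d regulon(s) with no genes in the matrix", len(excluded))
    if not usable:
        raise ValueError("no regulon has any gene present in the matrix")

    keys = [key for key, _, _ in usable]
    auc = np.zeros((len(usable), m.n_cells))
    for j in range(m.n_cells):
        order = _rank_order(dense[:, j], gene_rank)
        # rank (1-based) of each gene in this cell
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(1, n + 1)
        for i, (_, mask, size) in enumerate(usable):
            auc[i, j] = _auc_from_ranks(ranks[mask], size, k)

    auc_df = pd.DataFrame(auc, index=keys, columns=m.cell_ids)
    types = ann.cell_types()
    means = {}
    for t in types:
        cells = [c for c in m.cell_ids if ann.labels.get(c) == t]
        means[t] = auc_df[cells].mean(axis=1) if cells else pd.Series(np.nan, index=keys)
    mean_df = pd.DataFrame(means)

    ranking = {}
    for t in types:
        col = mean_df[t]
        ranking[t] = sorted(keys, key=lambda key: (-col[key], key))
    return RegulonActivity(auc_df, mean_df, ranking, excluded, dropped_total)
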
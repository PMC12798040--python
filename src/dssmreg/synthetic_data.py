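"""Self-contained synthetic datasets with planted regulon structure.

The generative model is deliberately the simplest process containing the
two signals the pipeline exploits: cell-type-specific TF->TG
co-variation in expression, and motif support linking a TG to its TF's
motifs. Latent values are converted to counts by Poisson sampling and
thinned with dropout so the QC and normalization stages are exercised
non-trivially.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dssmreg.types import (
    CellAnnotation,
    EdgeList,
    ExpressionMatrix,
    GeneMotifScores,
    MotifAnnotation,
)


@dataclass
class SimulationConfig:
    n_tfs: int = 5
    n_tgs_per_tf: int = 20
    n_decoy_genes: int = 100
    n_cell_types: int = 3
    n_cells_per_type: int = 60
    n_motifs_per_tf: int = 5
    n_decoy_motifs: int = 45
    regulation_strength: float = 3.0
    noise_sd: float = 0.3
    dropout_rate: float = 0.3
    motif_signal: float = 5.0
    seed: int = 0
    count_scale: float = 3.0
    allow_small_types: bool = False

    def __post_init__(self) -> None:
        if min(self.n_tfs, self.n_tgs_per_tf, self.n_cell_types, self.n_cells_per_type) < 1:
            raise ValueError("counts must be >= 1")
        if self.regulation_strength < 0 or self.noise_sd < 0 or self.motif_signal < 0:
            raise ValueError("signal strengths must be >= 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_cells_per_type < 50 and not self.allow_small_types:
            raise ValueError(
                "n_cells_per_type below the 50-cell pipeline floor; "
                "set allow_small_types=True to override"
            )

    @property
    def n_genes(self) -> int:
        return self.n_tfs + self.n_tfs * self.n_tgs_per_tf + self.n_decoy_genes


@dataclass
class SimulatedBundle:
    """Everything the pipeline consumes, with the planted ground truth."""

    expression: ExpressionMatrix  # raw counts
    annotation: CellAnnotation
    edges: dict[str, EdgeList]  # cell type -> planted active edges
    motif_annotation: MotifAnnotation
    motif_scores: GeneMotifScores
    config: SimulationConfig
    tf_active_type: dict[str, str] = field(default_factory=dict)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedBundle:
    """Generate a fully seeded bundle with planted cell-type regulons.

    Each TF is active in exactly one cell type (balanced at random over
    types). In a TF's active type its latent activity per cell is
    log-normal and each of its TGs follows
    ``regulation_strength * activity + N(0, noise_sd)``; elsewhere both
    sit at a low noise floor. Decoy genes are independent noise.
    """
    rng = np.random.default_rng(cfg.seed)

    tfs = [f"TF{i:02d}" for i in range(cfg.n_tfs)]
    tgs = {
        tf: [f"TG{i:02d}_{j:03d}" for j in range(cfg.n_tgs_per_tf)]
        for i, tf in enumerate(tfs)
    }
    decoys = [f"DEC{k:03d}" for k in range(cfg.n_decoy_genes)]
    gene_ids = tfs + [g for tf in tfs for g in tgs[tf]] + decoys

    types = [f"type{t}" for t in range(cfg.n_cell_types)]
    n_cells = cfg.n_cell_types * cfg.n_cells_per_type
    cell_ids = [f"cell{c:04d}" for c in range(n_cells)]
    cell_type_of = {
        cell_ids[t * cfg.n_cells_per_type + j]: types[t]
        for t in range(cfg.n_cell_types)
        for j in range(cfg.n_cells_per_type)
    }

    # balanced random single-type assignment: shuffle TFs, then round-robin
    order = rng.permutation(cfg.n_tfs)
    active_type = {tfs[i]: types[int(k % cfg.n_cell_types)] for k, i in enumerate(order)}

    gene_index = {g: i for i, g in enumerate(gene_ids)}
    latent = np.zeros((len(gene_ids), n_cells))

    # every non-TF gene shares one baseline process so that, with the
    # regulatory signal switched off, TGs and decoys are indistinguishable
    non_tf = [g for tf in tfs for g in tgs[tf]] + decoys
    base_scale = {g: rng.lognormal(0.0, 0.5) for g in non_tf}
    for j, cell in enumerate(cell_ids):
        ctype = cell_type_of[cell]
        for tf in tfs:
            if active_type[tf] == ctype:
                act = rng.lognormal(1.0, 0.4)
            else:
                act = rng.lognormal(-1.5, 0.4)
            latent[gene_index[tf], j] = act
            for tg in tgs[tf]:
                val = base_scale[tg] * rng.lognormal(0.0, 0.6)
                if active_type[tf] == ctype:
                    val += cfg.regulation_strength * act + rng.normal(0.0, cfg.noise_sd)
                latent[gene_index[tg], j] = max(val, 0.0)
        for dec in decoys:
            latent[gene_index[dec], j] = base_scale[dec] * rng.lognormal(0.0, 0.6)

    counts = rng.poisson(latent * cfg.count_scale).astype(float)
    if cfg.dropout_rate > 0:
        counts[rng.random(counts.shape) < cfg.dropout_rate] = 0.0

    expression = ExpressionMatrix(counts, gene_ids, cell_ids, is_normalized=False)
    annotation = CellAnnotation(cell_type_of)
    edges = {
        t: EdgeList(
            [(tf, tg) for tf in tfs if active_type[tf] == t for tg in tgs[tf]]
        )
        for t in types
    }

    motif_ids = [
        f"M{i:02d}_{m}" for i in range(cfg.n_tfs) for m in range(cfg.n_motifs_per_tf)
    ] + [f"MDEC{d:03d}" for d in range(cfg.n_decoy_motifs)]
    motif_annotation = MotifAnnotation(
        {
            tf: [f"M{i:02d}_{m}" for m in range(cfg.n_motifs_per_tf)]
            for i, tf in enumerate(tfs)
        }
    )
    motif_index = {m: i for i, m in enumerate(motif_ids)}
    scores = rng.normal(0.0, 1.0, size=(len(gene_ids), len(motif_ids)))
    for i, tf in enumerate(tfs):
        cols = [motif_index[m] for m in motif_annotation.motifs[tf]]
        for tg in tgs[tf]:
            scores[gene_index[tg], cols] += cfg.motif_signal
    motif_scores = GeneMotifScores(scores, list(gene_ids), motif_ids)

    return SimulatedBundle(
        expression=expression,
        annotation=annotation,
        edges=edges,
        motif_annotation=motif_annotation,
        motif_scores=motif_scores,
        config=cfg,
        tf_active_type=active_type,
    )


def fixture_library() -> dict:
    """Canned micro-fixtures with their independently derived expectations.

    * ``aucell``: 10 genes ranked by a strictly decreasing expression
      column; three gene sets occupying ranks {1,2}, {6,7}, {4,5} with
      recovery-curve areas 1.0, 0.0 and 1/3 at a rank threshold of 5.
    * ``auroc``: four scored pairs with pair-counting AUROC 3/4.
    * ``skipgram``: three TFs, two sharing an identical motif set.
    """
    gene_ids = [f"g{i:02d}" for i in range(1, 11)]
    column = np.arange(10, 0, -1, dtype=float)  # g01 highest ... g10 lowest
    aucell_expr = ExpressionMatrix(
        column[:, None], gene_ids, ["cell1"], is_normalized=True
    )
    aucell = {
        "expression": aucell_expr,
        "column": column,
        "gene_ids": gene_ids,
        "top_fraction": 0.5,
        "sets": {
            "ranks_1_2": {"g01", "g02"},
            "ranks_6_7": {"g06", "g07"},
            "ranks_4_5": {"g04", "g05"},
        },
        "expected": {"ranks_1_2": 1.0, "ranks_6_7": 0.0, "ranks_4_5": 1.0 / 3.0},
    }

    auroc_fixture = {
        "scores": [0.9, 0.8, 0.3, 0.2],
        "labels": [1, 0, 1, 0],
        "expected": 0.75,
        "table": pd.DataFrame(
            {
                "tf": ["A", "A", "A", "A"],
                "tg": ["g1", "g2", "g3", "g4"],
                "cell_type": ["t"] * 4,
                "score": [0.9, 0.8, 0.3, 0.2],
                "prob": [
                    1 / (1 + np.exp(-s)) for s in (0.9, 0.8, 0.3, 0.2)
                ],
            }
        ),
    }

    skipgram = {
        "annotation": MotifAnnotation(
            {"A": ["m1", "m2"], "B": ["m1", "m2"], "C": ["m3", "m4"]}
        ),
        "similar_pair": ("A", "B"),
        "dissimilar_pair": ("A", "C"),
    }

    return {"aucell": aucell, "auroc": auroc_fixture, "skipgram": skipgram}
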
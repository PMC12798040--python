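"""Evaluation metrics and experiment designs.

AUROC is the Mann-Whitney probability that a positive outscores a
negative (ties credited 1/2); AUPRC is the area under the precision-
recall step curve with tied scores processed as one block. The
experiment runner wires the full pipeline (preprocess -> embeddings ->
two-tower training -> held-out scoring) for the baseline, the
embedding-source ablation, and the cell-count downsampling designs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.stats

from dssmreg.dssm_core import (
    DSSMConfig,
    DSSMModel,
    make_training_set,
    predict_pairs,
    train_dssm,
)
from dssmreg.gene_embeddings import (
    AutoencoderConfig,
    FeatureSet,
    build_feature_vectors,
    encode_genes,
    encode_motif_rows,
    train_expression_autoencoder,
    train_motif_autoencoder,
    train_tf_motif_skipgram,
)
from dssmreg.preprocess import (
    PreprocessConfig,
    log_normalize,
    qc_filter,
    select_hvg,
    subset_by_celltype,
)
from dssmreg.regulons import AUCellConfig
from dssmreg.types import CellAnnotation, EdgeList, ExpressionMatrix

logger = logging.getLogger(__name__)

DESIGNS = ("baseline", "ablation", "downsample")
ABLATION_MODES = ("random", "expr_only", "motif_only", "both")


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC; ties counted half. Both classes required."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = scipy.stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Area under the PR step curve; descending sweep, ties as a block."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("AUPRC needs at least one positive")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    area = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        tp += int((y[i:j] == 1).sum())
        fp += (j - i) - int((y[i:j] == 1).sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return float(area)


def paired_t_test(a, b) -> tuple[float, float]:
    """Two-sided paired t-test from its closed form; returns (t, p)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least two pairs")
    sd = d.std(ddof=1)
    if sd == 0.0:
        return (0.0, 1.0) if d.mean() == 0 else (np.inf, 0.0)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * scipy.stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


@dataclass
class EvalReport:
    auroc: float
    auprc: float
    n_pos: int
    n_neg: int
    mode: str
    n_cells: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("report requires n_pos >= 1 and n_neg >= 1")


@dataclass
class PipelineConfig:
    """Every knob of the full pipeline in one place."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    autoencoder: AutoencoderConfig = field(default_factory=AutoencoderConfig)
    dssm: DSSMConfig = field(default_factory=DSSMConfig)
    aucell: AUCellConfig = field(default_factory=AUCellConfig)
    skipgram_epochs: int = 50
    embed_dim: int = 50

    @classmethod
    def for_simulation(cls) -> "PipelineConfig":
        """Thresholds scaled to the small synthetic bundles used in tests."""
        return cls(
            preprocess=PreprocessConfig(
                min_genes_per_cell=10,
                min_cells_per_gene=3,
                n_hvg=1_000,
                min_cells_per_type=50,
            ),
            autoencoder=AutoencoderConfig(epochs=30),
            dssm=DSSMConfig(epochs=200),
        )


def _subseed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0])


@dataclass
class CellTypeResult:
    """Trained model and its inputs for one cell type."""

    cell_type: str
    model: DSSMModel
    features: FeatureSet
    pairs: list
    tf_universe: set[str]
    tg_universe: set[str]
    matrix: ExpressionMatrix  # normalized, subset to this type


def prepare_matrix(bundle, cfg: PipelineConfig) -> ExpressionMatrix:
    """QC, log-normalize and (when applicable) select HVGs."""
    m = qc_filter(bundle.expression, cfg.preprocess)
    m = log_normalize(m, cfg.preprocess)
    tf_universe = set(bundle.motif_annotation.motifs)
    if cfg.preprocess.n_hvg < m.n_genes:
        m = select_hvg(m, cfg.preprocess.n_hvg, tf_universe)
    return m


def _motif_embeddings(bundle, cfg: PipelineConfig, seed: int, mode: str):
    if mode not in ("both", "motif_only"):
        return {}, {}
    sg = train_tf_motif_skipgram(
        bundle.motif_annotation,
        dim=cfg.embed_dim,
        seed=_subseed(seed, 1),
        epochs=cfg.skipgram_epochs,
    )
    mae = train_motif_autoencoder(
        bundle.motif_scores, replace(cfg.autoencoder, seed=_subseed(seed, 2))
    )
    motif_tg = encode_motif_rows(mae, bundle.motif_scores)
    return sg, motif_tg


def fit_celltype_models(
    bundle,
    cfg: PipelineConfig,
    seed: int,
    mode: str = "both",
    cell_types: list[str] | None = None,
) -> dict[str, CellTypeResult]:
    """Run the per-cell-type pipeline; returns one trained model per type.

    Motif embeddings are trained once and shared across cell types;
    expression embeddings are trained per cell type on the subsetted
    matrix.
    """
    norm = prepare_matrix(bundle, cfg)
    sg, motif_tg = _motif_embeddings(bundle, cfg, seed, mode)
    ann = bundle.annotation
    results: dict[str, CellTypeResult] = {}
    types = cell_types or sorted(bundle.edges)
    for idx, ctype in enumerate(types):
        edges = bundle.edges.get(ctype)
        if edges is None or len(edges) == 0:
            logger.info("cell type %s has no ground-truth edges; skipped", ctype)
            continue
        sub = subset_by_celltype(norm, ann, ctype, cfg.preprocess)
        expr_map: dict[str, np.ndarray] = {}
        if mode in ("both", "expr_only"):
            ae = train_expression_autoencoder(
                sub, replace(cfg.autoencoder, seed=_subseed(seed, 10 + idx))
            )
            expr_map = encode_genes(ae, sub)
        features = build_feature_vectors(
            expr_map,
            sg,
            motif_tg,
            mode=mode,
            seed=_subseed(seed, 20 + idx),
            genes=sub.gene_ids,
            dim=cfg.embed_dim,
        )
        usable = set(features.vectors)
        kept_edges = EdgeList(
            [(tf, tg) for tf, tg in edges.edges if tf in usable and tg in usable]
        )
        if len(kept_edges) == 0:
            logger.warning("no usable edges for %s after exclusions; skipped", ctype)
            continue
        tf_universe = set(kept_edges.tfs())
        gene_universe = usable
        dssm_cfg = replace(cfg.dssm, seed=_subseed(seed, 30 + idx))
        pairs = make_training_set(kept_edges, tf_universe, gene_universe, dssm_cfg)
        model = train_dssm(pairs, features, dssm_cfg)
        results[ctype] = CellTypeResult(
            ctype, model, features, pairs, tf_universe,
            gene_universe - tf_universe, sub,
        )
    if not results:
        raise ValueError("no cell type produced a trained model")
    return results


def evaluate_bundle(
    bundle, cfg: PipelineConfig, seed: int, mode: str = "both"
) -> EvalReport:
    """Full pipeline; test-split predictions pooled across cell types."""
    results = fit_celltype_models(bundle, cfg, seed, mode)
    scores, labels = [], []
    n_cells = 0
    for res in results.values():
        p, y = predict_pairs(res.model, res.pairs, res.features, "test")
        scores.append(p)
        labels.append(y)
        n_cells += res.matrix.n_cells
    s = np.concatenate(scores)
    y = np.concatenate(labels)
    return EvalReport(
        auroc=auroc(s, y),
        auprc=auprc(s, y),
        n_pos=int((y == 1).sum()),
        n_neg=int((y == 0).sum()),
        mode=mode,
        n_cells=n_cells,
        seed=seed,
    )


def _downsampled_bundle(bundle, n_cells: int, seed: int):
    """Uniform cell subsample pooled into one pseudo cell type."""
    from dssmreg.synthetic_data import SimulatedBundle

    m = bundle.expression
    rng = np.random.default_rng(seed)
    cols = sorted(rng.choice(m.n_cells, size=n_cells, replace=False))
    cells = [m.cell_ids[j] for j in cols]
    sub = m.subset_cells(cells)
    ann = CellAnnotation({c: "all" for c in cells})
    union = EdgeList(sorted({e for el in bundle.edges.values() for e in el.edges}))
    return SimulatedBundle(
        expression=sub,
        annotation=ann,
        edges={"all": union},
        motif_annotation=bundle.motif_annotation,
        motif_scores=bundle.motif_scores,
        config=bundle.config,
    )


def run_experiment(
    dataset,
    design: str,
    cfg: PipelineConfig,
    seeds: list[int],
    cell_counts: tuple[int, ...] = (50, 100, 500, 1000, 2000, 4000),
) -> list[EvalReport]:
    """Run one experiment design; one EvalReport per condition per seed."""
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}")
    if not seeds:
        raise ValueError("need at least one seed")
    reports: list[EvalReport] = []
    if design == "baseline":
        for seed in seeds:
            reports.append(evaluate_bundle(dataset, cfg, seed, "both"))
    elif design == "ablation":
        for seed in seeds:
            for mode in ABLATION_MODES:
                reports.append(evaluate_bundle(dataset, cfg, seed, mode))
    else:  # downsample
        available = dataset.expression.n_cells
        for count in cell_counts:
            if count < 50:
                warnings.warn(f"skipping cell count {count} below the 50-cell floor", stacklevel=2)
                continue
            if count > available:
                warnings.warn(
                    f"skipping cell count {count} > {available} available cells",
                    stacklevel=2,
                )
                continue
            for seed in seeds:
                sub = _downsampled_bundle(dataset, count, _subseed(seed, 90))
                rep = evaluate_bundle(sub, cfg, seed, "both")
                rep.n_cells = count
                reports.append(rep)
    return reports
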
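"""Per-gene feature vectors.

Each gene gets a 100-dimensional feature vector: a 50-dim expression
embedding from an autoencoder over the (cell-type-specific) expression
matrix, concatenated with a 50-dim motif embedding. TFs take their motif
half from a skip-gram model over (TF, motif) annotation pairs; TGs take
theirs from a second autoencoder over the gene x motif score matrix.
Ablation modes zero-pad the absent half so the downstream model input
width stays fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from dssmreg.nn import MLP, Adam
from dssmreg.types import ExpressionMatrix, GeneMotifScores, MotifAnnotation

logger = logging.getLogger(__name__)

MODES = ("both", "expr_only", "motif_only", "random")


@dataclass
class AutoencoderConfig:
    hidden_width: int = 700
    embed_dim: int = 50
    dropout: float = 0.1
    batch_size: int = 128
    learning_rate: float = 1.0e-5
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class AutoencoderParams:
    """Trained encoder/decoder pair with the per-epoch loss trajectory."""

    encoder: MLP
    decoder: MLP
    input_dim: int
    embed_dim: int
    epoch_losses: list[float] = field(default_factory=list)


def _train_autoencoder(
    data: np.ndarray, cfg: AutoencoderConfig, what: str
) -> AutoencoderParams:
    n_samples, n_features = data.shape
    if n_features < cfg.embed_dim:
        raise ValueError(
            f"{what}: input dimension {n_features} < embedding dimension "
            f"{cfg.embed_dim}; cannot compress below the target dimensionality"
        )
    rng = np.random.default_rng(cfg.seed)
    encoder = MLP([n_features, cfg.hidden_width, cfg.embed_dim], rng)
    decoder = MLP([cfg.embed_dim, cfg.hidden_width, n_features], rng)
    opt = Adam(encoder.parameters() + decoder.parameters(), lr=cfg.learning_rate)

    losses: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n_samples)
        epoch_loss = 0.0
        for start in range(0, n_samples, cfg.batch_size):
            batch = data[order[start : start + cfg.batch_size]]
            z = encoder.forward(batch, train=True, dropout=cfg.dropout, rng=rng)
            y = decoder.forward(z, train=True, dropout=cfg.dropout, rng=rng)
            resid = y - batch
            # mean over coordinates and over the batch
            loss = float(np.mean(resid**2))
            epoch_loss += loss * len(batch)
            d_y = 2.0 * resid / resid.size
            gw_d, gb_d, d_z = decoder.backward(d_y)
            gw_e, gb_e, _ = encoder.backward(d_z)
            opt.step(gw_e + gb_e + gw_d + gb_d)
        losses.append(epoch_loss / n_samples)
    logger.info("%s autoencoder: loss %.6g -> %.6g", what, losses[0], losses[-1])
    return AutoencoderParams(encoder, decoder, n_features, cfg.embed_dim, losses)


def train_expression_autoencoder(
    m: ExpressionMatrix, cfg: AutoencoderConfig
) -> AutoencoderParams:
    """Train the reconstruction autoencoder with gene rows as samples."""
    if not m.is_normalized:
        raise ValueError("expression autoencoder expects a normalized matrix")
    if m.n_cells < cfg.embed_dim:
        raise ValueError(
            f"{m.n_cells} cells < embedding dimension {cfg.embed_dim}"
        )
    return _train_autoencoder(m.dense(), cfg, "expression")


def encode_genes(p: AutoencoderParams, m: ExpressionMatrix) -> dict[str, np.ndarray]:
    """Embed each gene row with the trained encoder (inference mode)."""
    if m.n_cells != p.input_dim:
        raise ValueError(
            f"matrix has {m.n_cells} cells but encoder expects {p.input_dim}"
        )
    z = p.encoder.forward(m.dense(), train=False)
    return {g: z[i].copy() for i, g in enumerate(m.gene_ids)}


def train_motif_autoencoder(
    s: GeneMotifScores, cfg: AutoencoderConfig
) -> AutoencoderParams:
    """Same contract as the expression autoencoder over motif-score rows."""
    if len(s.motif_ids) < cfg.embed_dim:
        raise ValueError(
            f"{len(s.motif_ids)} motifs < embedding dimension {cfg.embed_dim}"
        )
    return _train_autoencoder(np.asarray(s.values, dtype=float), cfg, "motif")


def encode_motif_rows(p: AutoencoderParams, s: GeneMotifScores) -> dict[str, np.ndarray]:
    if len(s.motif_ids) != p.input_dim:
        raise ValueError("motif dimension mismatch with trained encoder")
    z = p.encoder.forward(np.asarray(s.values, dtype=float), train=False)
    return {g: z[i].copy() for i, g in enumerate(s.gene_ids)}


def train_tf_motif_skipgram(
    a: MotifAnnotation,
    dim: int = 50,
    seed: int = 0,
    epochs: int = 50,
    negative: int = 5,
    lr: float = 0.025,
    min_lr: float = 1e-4,
) -> dict[str, np.ndarray]:
    """Skip-gram with negative sampling over (TF, motif) pairs.

    The TF is the center word and its annotated motifs are the context;
    the center-word vector per TF is returned. Training is sequential and
    seeded, hence deterministic.
    """
    tfs = sorted(a.motifs)
    if not tfs:
        raise ValueError("no TFs in motif annotation")
    motifs = a.motif_universe()
    motif_index = {m: i for i, m in enumerate(motifs)}
    pairs = [
        (ti, motif_index[m]) for ti, tf in enumerate(tfs) for m in a.motifs[tf]
    ]
    rng = np.random.default_rng(seed)
    center = (rng.random((len(tfs), dim)) - 0.5) / dim
    context = np.zeros((len(motifs), dim))

    # unigram^0.75 noise distribution over motifs, word2vec-style
    counts = np.zeros(len(motifs))
    for _, mi in pairs:
        counts[mi] += 1
    noise = counts**0.75
    noise /= noise.sum()

    total_steps = epochs * len(pairs)
    step = 0
    for _epoch in range(epochs):
        order = rng.permutation(len(pairs))
        for k in order:
            ti, mi = pairs[k]
            alpha = max(min_lr, lr * (1.0 - step / total_steps))
            step += 1
            negs = rng.choice(len(motifs), size=negative, p=noise)
            v = center[ti]
            grad_v = np.zeros(dim)
            for target, label in [(mi, 1.0)] + [(int(n), 0.0) for n in negs]:
                u = context[target]
                g = (1.0 / (1.0 + np.exp(-v @ u))) - label
                grad_v += g * u
                context[target] = u - alpha * g * v
            center[ti] = v - alpha * grad_v
    return {tf: center[i].copy() for i, tf in enumerate(tfs)}


@dataclass
class GeneFeatureVector:
    """A gene's concatenated expression + motif feature vector."""

    gene_id: str
    expr_vec: np.ndarray
    motif_vec: np.ndarray
    source_flags: tuple[str, str] = ("expr", "motif")

    def __post_init__(self) -> None:
        self.expr_vec = np.asarray(self.expr_vec, dtype=float)
        self.motif_vec = np.asarray(self.motif_vec, dtype=float)
        if not (np.all(np.isfinite(self.expr_vec)) and np.all(np.isfinite(self.motif_vec))):
            raise ValueError(f"non-finite feature entries for {self.gene_id}")

    @property
    def full_vec(self) -> np.ndarray:
        return np.concatenate([self.expr_vec, self.motif_vec])


@dataclass
class FeatureSet:
    """Feature vectors plus a report of genes excluded for missing sources."""

    vectors: dict[str, GeneFeatureVector]
    excluded: dict[str, str] = field(default_factory=dict)
    mode: str = "both"

    def matrix(self, gene_ids: list[str]) -> np.ndarray:
        return np.stack([self.vectors[g].full_vec for g in gene_ids])


def build_feature_vectors(
    expr: dict[str, np.ndarray],
    motif_tf: dict[str, np.ndarray],
    motif_tg: dict[str, np.ndarray],
    mode: str = "both",
    seed: int = 0,
    genes: list[str] | None = None,
    dim: int = 50,
) -> FeatureSet:
    """Assemble per-gene feature vectors for one embedding mode.

    TFs (keys of ``motif_tf``) take the skip-gram motif half; all other
    genes take the motif-autoencoder half. Genes missing a required
    source in mode='both' are excluded and reported, never zero-padded.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if genes is None:
        genes = sorted(set(expr) | set(motif_tf) | set(motif_tg))
    zeros = np.zeros(dim)
    vectors: dict[str, GeneFeatureVector] = {}
    excluded: dict[str, str] = {}

    if mode == "random":
        rng = np.random.default_rng(seed)
        for g in sorted(genes):
            full = rng.random(2 * dim)
            vectors[g] = GeneFeatureVector(g, full[:dim], full[dim:], ("random", "random"))
        return FeatureSet(vectors, excluded, mode)

    for g in sorted(genes):
        e = expr.get(g)
        is_tf = g in motif_tf
        mvec = motif_tf.get(g) if is_tf else motif_tg.get(g)
        if mode in ("both", "expr_only") and e is None:
            excluded[g] = "missing expression embedding"
            continue
        if mode in ("both", "motif_only") and mvec is None:
            excluded[g] = "missing motif embedding"
            continue
        if mode == "both":
            vectors[g] = GeneFeatureVector(g, e, mvec, ("expr", "tf_motif" if is_tf else "tg_motif"))
        elif mode == "expr_only":
            vectors[g] = GeneFeatureVector(g, e, zeros, ("expr", "zero"))
        else:  # motif_only
            vectors[g] = GeneFeatureVector(g, zeros, mvec, ("zero", "tf_motif" if is_tf else "tg_motif"))
    if excluded:
        logger.warning("excluded %d gene(s) lacking a feature source", len(excluded))
    return FeatureSet(vectors, excluded, mode)
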
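"""Two-tower semantic model: negative sampling, training, pair scoring.

Two independent networks with identical architecture (100 -> 300 -> 300
-> 128, ReLU on the first two layers, linear output) embed TF and TG
feature vectors; the link score is the cosine similarity of the two
hidden vectors, squashed through a sigmoid for the binary cross-entropy
loss.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dssmreg.gene_embeddings import FeatureSet
from dssmreg.nn import MLP, Adam
from dssmreg.types import EdgeList

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class DSSMConfig:
    layer_widths: tuple[int, ...] = (300, 300, 128)
    epochs: int = 200
    batch_size: int = 128
    learning_rate: float = 1e-4
    neg_per_pos: float = 1.0
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @property
    def hidden_dim(self) -> int:
        return self.layer_widths[-1]


@dataclass
class LabeledPair:
    tf_id: str
    tg_id: str
    label: int
    split: str  # "train" | "test"


@dataclass
class DSSMModel:
    tf_tower: MLP
    tg_tower: MLP
    config: DSSMConfig
    epoch_losses: list[float] = field(default_factory=list)


def make_training_set(
    pos: EdgeList,
    tf_universe: set[str],
    gene_universe: set[str],
    cfg: DSSMConfig,
) -> list[LabeledPair]:
    """Balanced positives/negatives with a stratified 80:20 split.

    Per TF, ``floor(neg_per_pos * n_pos)`` negatives are drawn without
    replacement from the gene universe minus that TF's positives (and the
    TF itself). Negatives are drawn once, before splitting. The combined
    set is split train/test stratified by label.
    """
    for tf, tg in pos.edges:
        if tf not in tf_universe:
            raise ValueError(f"positive edge TF {tf!r} not in tf_universe")
        if tg not in gene_universe:
            raise ValueError(f"positive edge TG {tg!r} not in gene_universe")
    rng = np.random.default_rng(cfg.seed)
    pairs: list[LabeledPair] = [
        LabeledPair(tf, tg, 1, "train") for tf, tg in pos.edges
    ]
    for tf in pos.tfs():
        positives = pos.targets_of(tf)
        candidates = sorted(gene_universe - positives - {tf})
        n_neg = int(cfg.neg_per_pos * len(positives))
        if n_neg > len(candidates):
            logger.warning(
                "TF %s: requested %d negatives but only %d candidates; "
                "drawing the whole pool", tf, n_neg, len(candidates),
            )
            n_neg = len(candidates)
        drawn = rng.choice(len(candidates), size=n_neg, replace=False)
        pairs.extend(LabeledPair(tf, candidates[i], 0, "train") for i in sorted(drawn))

    for label in (0, 1):
        idx = [i for i, p in enumerate(pairs) if p.label == label]
        perm = rng.permutation(len(idx))
        n_train = int(cfg.train_fraction * len(idx))
        for k in perm[n_train:]:
            pairs[idx[k]].split = "test"
    return pairs


def build_towers(cfg: DSSMConfig, input_dim: int, rng: np.random.Generator) -> tuple[MLP, MLP]:
    widths = [input_dim, *cfg.layer_widths]
    return MLP(widths, rng), MLP(widths, rng)


def tower_forward(t: MLP, v: np.ndarray) -> np.ndarray:
    """Run one tower in inference mode; returns hidden vector(s)."""
    out = t.forward(np.atleast_2d(v), train=False)
    return out[0] if np.asarray(v).ndim == 1 else out


def cosine_score(h_tf: np.ndarray, h_tg: np.ndarray) -> float:
    """s = <a, b> / (|a| |b|), in [-1, 1]. Zero-norm input is an error."""
    a = np.asarray(h_tf, dtype=float)
    b = np.asarray(h_tg, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine undefined for zero-norm vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def edge_probability(s: float) -> float:
    """sigmoid(s) = 1 / (1 + exp(-s))."""
    return float(1.0 / (1.0 + np.exp(-np.asarray(s, dtype=float))))


def bce_loss(p, y) -> float:
    """Binary cross-entropy, mean over samples; p clamped to (0, 1)."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape or p.size == 0:
        raise ValueError("p and y must be non-empty and the same length")
    if np.any((p <= 0.0) | (p >= 1.0)):
        logger.warning("probabilities at {0,1} clamped to [1e-12, 1-1e-12]")
        p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _pair_arrays(
    pairs: list[LabeledPair], vectors: FeatureSet, split: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    selected = [p for p in pairs if p.split == split]
    missing = sorted(
        {p.tf_id for p in selected if p.tf_id not in vectors.vectors}
        | {p.tg_id for p in selected if p.tg_id not in vectors.vectors}
    )
    if missing:
        raise ValueError(f"pairs reference genes without feature vectors: {missing}")
    x_tf = np.stack([vectors.vectors[p.tf_id].full_vec for p in selected])
    x_tg = np.stack([vectors.vectors[p.tg_id].full_vec for p in selected])
    y = np.array([p.label for p in selected], dtype=float)
    return x_tf, x_tg, y


def _cosine_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    na = np.maximum(np.linalg.norm(a, axis=1), _EPS)
    nb = np.maximum(np.linalg.norm(b, axis=1), _EPS)
    s = np.einsum("ij,ij->i", a, b) / (na * nb)
    return s, na, nb


def train_dssm(
    pairs: list[LabeledPair], vectors: FeatureSet, cfg: DSSMConfig
) -> DSSMModel:
    """Train both towers on the train split; test pairs never contribute."""
    x_tf, x_tg, y = _pair_arrays(pairs, vectors, "train")
    if len(y) == 0:
        raise ValueError("no training pairs")
    input_dim = x_tf.shape[1]
    rng = np.random.default_rng(cfg.seed)
    tf_tower, tg_tower = build_towers(cfg, input_dim, rng)
    opt = Adam(tf_tower.parameters() + tg_tower.parameters(), lr=cfg.learning_rate)

    n = len(y)
    losses: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            a = tf_tower.forward(x_tf[sel], train=True)
            b = tg_tower.forward(x_tg[sel], train=True)
            s, na, nb = _cosine_rows(a, b)
            p = 1.0 / (1.0 + np.exp(-s))
            yb = y[sel]
            pc = np.clip(p, _EPS, 1.0 - _EPS)
            loss = float(-np.mean(yb * np.log(pc) + (1.0 - yb) * np.log(1.0 - pc)))
            epoch_loss += loss * len(sel)
            # d(BCE o sigmoid)/ds = (p - y) / batch
            ds = (p - yb) / len(sel)
            inv = 1.0 / (na * nb)
            d_a = ds[:, None] * (b * inv[:, None] - (s / na**2)[:, None] * a)
            d_b = ds[:, None] * (a * inv[:, None] - (s / nb**2)[:, None] * b)
            gw_a, gb_a, _ = tf_tower.backward(d_a)
            gw_b, gb_b, _ = tg_tower.backward(d_b)
            opt.step(gw_a + gb_a + gw_b + gb_b)
        losses.append(epoch_loss / n)
    logger.info("DSSM: train loss %.6g -> %.6g", losses[0], losses[-1])
    return DSSMModel(tf_tower, tg_tower, cfg, losses)


def predict_pairs(
    model: DSSMModel, pairs: list[LabeledPair], vectors: FeatureSet, split: str
) -> tuple[np.ndarray, np.ndarray]:
    """Scores (probabilities) and labels for one split."""
    x_tf, x_tg, y = _pair_arrays(pairs, vectors, split)
    a = model.tf_tower.forward(x_tf, train=False)
    b = model.tg_tower.forward(x_tg, train=False)
    s, _, _ = _cosine_rows(a, b)
    return 1.0 / (1.0 + np.exp(-s)), y


def score_all_pairs(
    model: DSSMModel,
    vectors: FeatureSet,
    tfs: set[str],
    tgs: set[str],
    cell_type: str,
) -> pd.DataFrame:
    """Cosine score and probability for every (tf, tg) pair with vectors.

    Returns a table with columns tf, tg, cell_type, score, prob; genes
    lacking feature vectors are skipped (they appear in the FeatureSet's
    exclusion report).
    """
    tf_list = sorted(t for t in tfs if t in vectors.vectors)
    tg_list = sorted(t for t in tgs if t in vectors.vectors)
    if not tf_list or not tg_list:
        raise ValueError("empty TF or TG set after exclusions")
    a = model.tf_tower.forward(vectors.matrix(tf_list), train=False)
    b = model.tg_tower.forward(vectors.matrix(tg_list), train=False)
    a = a / np.maximum(np.linalg.norm(a, axis=1, keepdims=True), _EPS)
    b = b / np.maximum(np.linalg.norm(b, axis=1, keepdims=True), _EPS)
    s = np.clip(a @ b.T, -1.0, 1.0)
    tf_col = np.repeat(tf_list, len(tg_list))
    tg_col = np.tile(tg_list, len(tf_list))
    flat = s.ravel()
    return pd.DataFrame(
        {
            "tf": tf_col,
            "tg": tg_col,
            "cell_type": cell_type,
            "score": flat,
            "prob": 1.0 / (1.0 + np.exp(-flat)),
        }
    )


def save_model(model: DSSMModel, path: str | Path) -> None:
    """Checkpoint: npz of parameters plus a JSON sidecar of the config."""
    path = Path(path)
    arrays = {}
    for name, tower in (("tf", model.tf_tower), ("tg", model.tg_tower)):
        for i, (w, b) in enumerate(zip(tower.weights, tower.biases)):
            arrays[f"{name}_w{i}"] = w
            arrays[f"{name}_b{i}"] = b
    np.savez(path, **arrays)
    sidecar = path.with_suffix(path.suffix + ".json")
    cfg = model.config
    sidecar.write_text(
        json.dumps(
            {
                "layer_widths": list(cfg.layer_widths),
                "epochs": cfg.epochs,
                "batch_size": cfg.batch_size,
                "learning_rate": cfg.learning_rate,
                "neg_per_pos": cfg.neg_per_pos,
                "train_fraction": cfg.train_fraction,
                "seed": cfg.seed,
                "input_dim": int(model.tf_tower.widths[0]),
            },
            indent=2,
        )
    )


def load_model(path: str | Path) -> DSSMModel:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    cfg = DSSMConfig(
        layer_widths=tuple(meta["layer_widths"]),
        epochs=meta["epochs"],
        batch_size=meta["batch_size"],
        learning_rate=meta["learning_rate"],
        neg_per_pos=meta["neg_per_pos"],
        train_fraction=meta["train_fraction"],
        seed=meta["seed"],
    )
    rng = np.random.default_rng(cfg.seed)
    tf_tower, tg_tower = build_towers(cfg, meta["input_dim"], rng)
    with np.load(path) as data:
        for name, tower in (("tf", tf_tower), ("tg", tg_tower)):
            for i in range(tower.n_layers):
                tower.weights[i] = data[f"{name}_w{i}"]
                tower.biases[i] = data[f"{name}_b{i}"]
    return DSSMModel(tf_tower, tg_tower, cfg)
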
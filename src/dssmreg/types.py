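"""Core domain types with validation.

All containers validate their invariants at construction time; readers in
:mod:`dssmreg.data_io` therefore reject malformed inputs instead of
silently coercing them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """An input violated a domain-type invariant."""


def _find_duplicates(ids) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values with identifier bookkeeping.

    ``values`` may be a dense ndarray or a scipy sparse matrix; the
    contract is value-level equality, not storage layout.
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    is_normalized: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        dups = _find_duplicates(self.gene_ids)
        if dups:
            raise ValidationError(f"duplicate gene_ids: {dups}")
        dups = _find_duplicates(self.cell_ids)
        if dups:
            raise ValidationError(f"duplicate cell_ids: {dups}")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        dense = self.dense()
        if not np.all(np.isfinite(dense)):
            bad = np.argwhere(~np.isfinite(dense))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[bad[0]]}, "
                f"cell {self.cell_ids[bad[1]]}"
            )
        if dense.min(initial=0.0) < 0:
            bad = np.argwhere(dense < 0)[0]
            raise ValidationError(
                f"negative value at gene {self.gene_ids[bad[0]]}, "
                f"cell {self.cell_ids[bad[1]]}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, keep: list[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        rows = [idx[g] for g in keep]
        return ExpressionMatrix(
            self.dense()[rows, :], list(keep), list(self.cell_ids), self.is_normalized
        )

    def subset_cells(self, keep: list[str]) -> "ExpressionMatrix":
        idx = {c: j for j, c in enumerate(self.cell_ids)}
        cols = [idx[c] for c in keep]
        return ExpressionMatrix(
            self.dense()[:, cols], list(self.gene_ids), list(keep), self.is_normalized
        )


@dataclass
class CellAnnotation:
    """Mapping cell_id -> cell-type label."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValidationError("annotation is empty")
        self.labels = {str(k): str(v) for k, v in self.labels.items()}

    def cell_types(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def cells_of_type(self, cell_type: str) -> list[str]:
        return [c for c, t in self.labels.items() if t == cell_type]


@dataclass
class EdgeList:
    """Unique directed (tf, tg) pairs, implicitly labeled positive."""

    edges: list[tuple[str, str]]
    context: str | None = None
    n_duplicates_dropped: int = 0

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        uniq: list[tuple[str, str]] = []
        dropped = 0
        for tf, tg in self.edges:
            pair = (str(tf), str(tg))
            if pair in seen:
                dropped += 1
                continue
            seen.add(pair)
            uniq.append(pair)
        if dropped:
            logger.info("collapsed %d duplicate edges", dropped)
        self_loops = [p for p in uniq if p[0] == p[1]]
        if self_loops:
            logger.warning("edge list contains %d self-loops", len(self_loops))
        self.edges = uniq
        self.n_duplicates_dropped += dropped

    def __len__(self) -> int:
        return len(self.edges)

    def tfs(self) -> list[str]:
        return sorted({tf for tf, _ in self.edges})

    def targets_of(self, tf: str) -> set[str]:
        return {tg for t, tg in self.edges if t == tf}

    def as_set(self) -> set[tuple[str, str]]:
        return set(self.edges)


@dataclass
class MotifAnnotation:
    """Mapping tf_id -> non-empty list of motif_ids."""

    motifs: dict[str, list[str]]

    def __post_init__(self) -> None:
        for tf, ms in self.motifs.items():
            if not ms:
                raise ValidationError(f"TF {tf!r} has an empty motif list")

    def motif_universe(self) -> list[str]:
        return sorted({m for ms in self.motifs.values() for m in ms})


@dataclass
class GeneMotifScores:
    """Genes x motifs score matrix (cisTarget-style)."""

    values: np.ndarray
    gene_ids: list[str]
    motif_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        dups = _find_duplicates(self.gene_ids)
        if dups:
            raise ValidationError(f"duplicate gene_ids: {dups}")
        dups = _find_duplicates(self.motif_ids)
        if dups:
            raise ValidationError(f"duplicate motif_ids: {dups}")
        if self.values.shape != (len(self.gene_ids), len(self.motif_ids)):
            raise ValidationError("score matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite score for gene {self.gene_ids[bad[0]]}, "
                f"motif {self.motif_ids[bad[1]]}"
            )

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class Regulon:
    """A TF with its scored targets in one cell type, sorted by score."""

    tf_id: str
    cell_type: str
    targets: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        tgs = [t for t, _ in self.targets]
        dups = _find_duplicates(tgs)
        if dups:
            raise ValidationError(
                f"regulon {self.tf_id}/{self.cell_type} has duplicate targets: {dups}"
            )
        scores = [s for _, s in self.targets]
        if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
            raise ValidationError(
                f"regulon {self.tf_id}/{self.cell_type} targets not sorted "
                "by descending score"
            )

    def target_genes(self) -> list[str]:
        return [t for t, _ in self.targets]


@dataclass
class RegulonSet:
    """A collection of regulons keyed by (tf_id, cell_type)."""

    regulons: list[Regulon]

    def __post_init__(self) -> None:
        keys = [(r.tf_id, r.cell_type) for r in self.regulons]
        dups = _find_duplicates(keys)  # type: ignore[arg-type]
        if dups:
            raise ValidationError(f"duplicate regulons: {dups}")

    def __len__(self) -> int:
        return len(self.regulons)

    def __iter__(self):
        return iter(self.regulons)

    def get(self, tf_id: str, cell_type: str) -> Regulon | None:
        for r in self.regulons:
            if r.tf_id == tf_id and r.cell_type == cell_type:
                return r
        return None
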
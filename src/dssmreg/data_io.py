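"""Readers and writers for on-disk artifacts.

Conventions
-----------
* Dense expression: CSV/TSV with genes in rows, first column gene id,
  header row of cell ids.
* Sparse expression: MatrixMarket triplet ``<stem>.mtx`` with sidecar
  identifier files ``<stem>.genes.txt`` and ``<stem>.cells.txt`` (one id
  per line, order matching matrix rows/columns).
* Edge lists, motif annotations, regulons and score tables: UTF-8 TSV
  with a single header line.
* Gene-motif scores: CSV/TSV (genes in rows, motifs in columns) or a
  Feather columnar table whose first column is the gene id.

Identifier matching is case-sensitive exact string match throughout.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from dssmreg.types import (
    CellAnnotation,
    EdgeList,
    ExpressionMatrix,
    GeneMotifScores,
    MotifAnnotation,
    RegulonSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

_SEP = {"csv": ",", "tsv": "\t"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    if suffix == ".mtx":
        return "mtx_triplet"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def _read_id_file(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing sidecar identifier file {path}")
    return [line.rstrip("\n") for line in path.read_text().splitlines() if line.strip()]


def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from CSV/TSV or an MTX triplet.

    Order of genes and cells is preserved from the source files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "mtx_triplet":
        stem = path.with_suffix("")
        genes = _read_id_file(Path(str(stem) + ".genes.txt"))
        cells = _read_id_file(Path(str(stem) + ".cells.txt"))
        mat = scipy.io.mmread(path)
        return ExpressionMatrix(sp.csr_matrix(mat), genes, cells)
    if fmt not in _SEP:
        raise ValueError(f"unknown expression format {fmt!r}")
    df = pd.read_csv(path, sep=_SEP[fmt], index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        for gene, row in df.iterrows():
            for cell, val in row.items():
                try:
                    float(val)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"non-numeric entry {val!r} at gene {gene}, cell {cell} "
                        f"in {path.name}"
                    ) from exc
        raise ValidationError(f"non-numeric entry in {path.name}: {exc}") from exc
    return ExpressionMatrix(values, [str(g) for g in df.index], [str(c) for c in df.columns])


def write_expression(
    m: ExpressionMatrix, path: str | Path, format: str | None = None
) -> None:
    """Write an expression matrix; inverse of :func:`read_expression`."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "mtx_triplet":
        stem = path.with_suffix("")
        Path(str(stem) + ".genes.txt").write_text("".join(g + "\n" for g in m.gene_ids))
        Path(str(stem) + ".cells.txt").write_text("".join(c + "\n" for c in m.cell_ids))
        coo = sp.coo_matrix(m.dense())
        scipy.io.mmwrite(path, coo)
        return
    df = pd.DataFrame(m.dense(), index=m.gene_ids, columns=m.cell_ids)
    df.index.name = "gene"
    df.to_csv(path, sep=_SEP[fmt], float_format="%.10g")


def read_annotation(path: str | Path) -> CellAnnotation:
    """Read a two-column (cell_id, cell_type) TSV, header optional."""
    path = Path(path)
    rows = _read_tsv_rows(path, min_cols=2, header_names={"cell", "cell_id"})
    return CellAnnotation({r[0]: r[1] for r in rows})


def write_annotation(ann: CellAnnotation, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cell_id\tcell_type\n")
        for cell, ctype in ann.labels.items():
            fh.write(f"{cell}\t{ctype}\n")


def _read_tsv_rows(
    path: Path, min_cols: int, header_names: set[str]
) -> list[list[str]]:
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].strip().lower() in header_names:
                continue
            if len(parts) < min_cols:
                raise ValidationError(
                    f"{path.name}: line {lineno} has {len(parts)} column(s), "
                    f"expected >= {min_cols}"
                )
            rows.append([p.strip() for p in parts])
    if not rows:
        raise ValidationError(f"{path.name} contains no data rows")
    return rows


def read_edges(path: str | Path) -> EdgeList:
    """Read a TSV of directed (tf, tg) pairs; duplicates are collapsed."""
    rows = _read_tsv_rows(Path(path), min_cols=2, header_names={"tf", "tf_id"})
    return EdgeList([(r[0], r[1]) for r in rows])


def write_edges(edges: EdgeList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tf\ttg\n")
        for tf, tg in edges.edges:
            fh.write(f"{tf}\t{tg}\n")


def read_motif_data(
    annotation_path: str | Path, score_matrix_path: str | Path
) -> tuple[MotifAnnotation, GeneMotifScores]:
    """Read a TF->motif annotation table and a gene x motif score matrix.

    Motifs referenced by the annotation but absent from the score matrix
    are retained in the annotation and logged (tolerant join).
    """
    rows = _read_tsv_rows(Path(annotation_path), min_cols=2, header_names={"tf", "tf_id"})
    motifs: dict[str, list[str]] = {}
    for tf, motif, *_ in rows:
        motifs.setdefault(tf, [])
        if motif not in motifs[tf]:
            motifs[tf].append(motif)
    ann = MotifAnnotation(motifs)

    score_path = Path(score_matrix_path)
    if not score_path.exists():
        raise FileNotFoundError(score_path)
    if score_path.suffix.lower() == ".feather":
        df = pd.read_feather(score_path)
        df = df.set_index(df.columns[0])
    else:
        sep = "," if score_path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(score_path, sep=sep, index_col=0)
    values = df.to_numpy(dtype=float)
    gene_ids = [str(g) for g in df.index]
    motif_ids = [str(m) for m in df.columns]
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"non-finite score for gene {gene_ids[bad[0]]}, motif {motif_ids[bad[1]]}"
        )
    scores = GeneMotifScores(values, gene_ids, motif_ids)

    known = set(motif_ids)
    missing = sorted({m for ms in motifs.values() for m in ms if m not in known})
    if missing:
        logger.warning(
            "%d annotated motif(s) absent from the score matrix: %s",
            len(missing),
            missing,
        )
    return ann, scores


def write_motif_annotation(ann: MotifAnnotation, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tf\tmotif\n")
        for tf in sorted(ann.motifs):
            for motif in ann.motifs[tf]:
                fh.write(f"{tf}\t{motif}\n")


def write_motif_scores(scores: GeneMotifScores, path: str | Path) -> None:
    df = pd.DataFrame(scores.values, index=scores.gene_ids, columns=scores.motif_ids)
    df.index.name = "gene"
    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, float_format="%.10g")


def read_regulons(path: str | Path) -> RegulonSet:
    from dssmreg.types import Regulon

    rows = _read_tsv_rows(Path(path), min_cols=4, header_names={"tf", "tf_id"})
    grouped: dict[tuple[str, str], list[tuple[str, float]]] = {}
    order: list[tuple[str, str]] = []
    for tf, ctype, tg, score, *_ in rows:
        key = (tf, ctype)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append((tg, float(score)))
    return RegulonSet([Regulon(tf, ct, grouped[(tf, ct)]) for tf, ct in order])


def write_regulons(regs: RegulonSet, path: str | Path) -> None:
    """Write regulons as TSV sorted by (tf, cell_type, -score, tg)."""
    rows = []
    for r in regs:
        for tg, score in r.targets:
            rows.append((r.tf_id, r.cell_type, tg, score))
    rows.sort(key=lambda x: (x[0], x[1], -x[3], x[2]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tf\tcell_type\ttg\tscore\n")
        for tf, ct, tg, score in rows:
            fh.write(f"{tf}\t{ct}\t{tg}\t{score:.10g}\n")


def read_score_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "tg": str, "cell_type": str})
    expected = {"tf", "tg", "cell_type", "score", "prob"}
    if not expected.issubset(df.columns):
        raise ValidationError(f"score table missing columns {expected - set(df.columns)}")
    return df


def write_score_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.sort_values(
        by=["tf", "score", "tg"], ascending=[True, False, True], kind="mergesort"
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_outputs(obj, path: str | Path) -> None:
    """Type-dispatched writer with deterministic row/column order."""
    if isinstance(obj, ExpressionMatrix):
        write_expression(obj, path)
    elif isinstance(obj, RegulonSet):
        write_regulons(obj, path)
    elif isinstance(obj, EdgeList):
        write_edges(obj, path)
    elif isinstance(obj, CellAnnotation):
        write_annotation(obj, path)
    elif isinstance(obj, MotifAnnotation):
        write_motif_annotation(obj, path)
    elif isinstance(obj, GeneMotifScores):
        write_motif_scores(obj, path)
    elif isinstance(obj, pd.DataFrame):
        write_score_table(obj, path)
    else:
        raise TypeError(f"no writer for {type(obj).__name__}")
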
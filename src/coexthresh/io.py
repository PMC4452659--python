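"""Reading and writing expression matrices, truth matrices and edge lists.

Files are plain text: tab-separated by default (UTF-8, '.' decimal, no
quoting) with comma-separated input accepted by delimiter sniffing.  An
expression file has genes in rows, the first column holding gene ids and
the header row holding sample ids; ``transpose=True`` accepts
samples-in-rows files.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network import CorrelationMatrix, ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_correlation",
    "write_correlation",
    "write_edge_list",
    "write_adjacency",
]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = None  # let pandas sniff between tab and comma
    try:
        df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
    except Exception as err:  # pragma: no cover - message shaping only
        raise ValueError(f"cannot parse matrix file {path}: {err}") from err
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids in {path}: {dupes}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        for col in non_numeric:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                line = df.index.get_loc(bad.index[0]) + 2  # header + 1-based
                raise ValueError(
                    f"non-numeric cell in {path}, column {col!r}, line {line}"
                )
        df = df.astype(float)
    return df


def read_expression(path: str | Path, transpose: bool = False) -> ExpressionMatrix:
    """Load a genes x samples expression matrix from TSV/CSV."""
    df = _read_table(path)
    if transpose:
        df = df.T
    return ExpressionMatrix(
        df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]
    )


def write_expression(X: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(X.values, index=X.gene_ids, columns=X.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_correlation(path: str | Path) -> CorrelationMatrix:
    """Load a square correlation / ground-truth matrix from TSV/CSV."""
    df = _read_table(path)
    return CorrelationMatrix(df.to_numpy(dtype=float), [str(i) for i in df.index])


def write_correlation(C: CorrelationMatrix, path: str | Path) -> None:
    df = pd.DataFrame(C.values, index=C.gene_ids, columns=C.gene_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Edge list TSV (gene_a, gene_b, abs_pcc), sorted lexicographically."""
    rows = sorted((min(u, v), max(u, v), d.get("weight", 1.0)) for u, v, d in graph.edges(data=True))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tabs_pcc\n")
        for u, v, w in rows:
            fh.write(f"{u}\t{v}\t{w:.10g}\n")


def write_adjacency(graph: nx.Graph, path: str | Path) -> None:
    nodes = list(graph.nodes())
    A = nx.to_numpy_array(graph, nodelist=nodes, weight=None).astype(int)
    df = pd.DataFrame(A, index=nodes, columns=nodes)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n")
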
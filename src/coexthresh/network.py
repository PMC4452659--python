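"""Correlation matrices and hard-threshold coexpression graphs.

An :class:`ExpressionMatrix` holds an m-genes x n-samples real matrix with
row and column identifiers.  :func:`abs_pcc_matrix` turns it into the
symmetric matrix of absolute Pearson correlations, and :func:`infer_graph`
places an (undirected, unweighted) edge wherever |rho| strictly exceeds a
hard threshold.  :func:`er_null_check` verifies empirically that on pure
noise this construction behaves as an Erdos-Renyi graph with edge
probability F(n, p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .null_model import null_exceedance_probability

__all__ = [
    "ExpressionMatrix",
    "CorrelationMatrix",
    "abs_pcc_matrix",
    "infer_graph",
    "er_null_check",
    "ErNullResult",
]


@dataclass
class ExpressionMatrix:
    """Gene expression values with gene (row) and sample (column) labels."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        m, n = self.values.shape
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} columns")
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene ids must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values contain NaN or infinity")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, index: np.ndarray) -> "ExpressionMatrix":
        """Column subset (e.g. a subsampling replicate), preserving labels."""
        index = np.asarray(index)
        return ExpressionMatrix(
            self.values[:, index],
            list(self.gene_ids),
            [self.sample_ids[i] for i in index],
        )


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of absolute correlations with unit diagonal."""

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != m:
            raise ValueError("correlation matrix must be square")
        if not self.gene_ids:
            self.gene_ids = [f"G{i + 1}" for i in range(m)]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} rows")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("absolute correlations must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


def abs_pcc_matrix(X: ExpressionMatrix) -> CorrelationMatrix:
    """Absolute Pearson correlation between every pair of gene rows.

    Raises a ValueError naming the offending gene if any row is constant
    (zero variance makes the PCC undefined); degenerate rows are surfaced
    loudly rather than silently dropped.
    """
    if X.n_samples < 3:
        raise ValueError("at least 3 samples are required to correlate rows")
    sd = X.values.std(axis=1)
    if (sd == 0).any():
        bad = [X.gene_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant expression row(s), PCC undefined: {', '.join(bad)}")
    C = np.abs(np.corrcoef(X.values))
    np.clip(C, 0.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(C, list(X.gene_ids))


def infer_graph(C: CorrelationMatrix, threshold: float) -> nx.Graph:
    """Coexpression graph with an edge iff |rho| is strictly above threshold.

    Nodes follow the input gene order; edges carry the correlation as a
    ``weight`` attribute and are stored sorted lexicographically for
    reproducible output.  ``threshold = 1`` yields the empty graph (ties at
    exactly 1.0 are excluded by strictness).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold!r}")
    G = nx.Graph(threshold=float(threshold))
    G.add_nodes_from(C.gene_ids)
    i_idx, j_idx = np.nonzero(np.triu(C.values, 1) > threshold)
    pairs = sorted(
        (min(C.gene_ids[i], C.gene_ids[j]), max(C.gene_ids[i], C.gene_ids[j]), C.values[i, j])
        for i, j in zip(i_idx, j_idx)
    )
    G.add_weighted_edges_from(pairs)
    return G


@dataclass(frozen=True)
class ErNullResult:
    """Empirical edge density of thresholded pure-noise networks."""

    density: float
    ci_low: float
    ci_high: float
    expected: float
    n: int
    m: int
    threshold: float
    replicates: int

    @property
    def consistent(self) -> bool:
        return self.ci_low <= self.expected <= self.ci_high


def er_null_check(
    n: int,
    m: int,
    p: float,
    reps: int = 200,
    distribution: str = "normal",
    seed: int | None = None,
) -> ErNullResult:
    """Empirically check the Erdos-Renyi behaviour of thresholded noise.

    Generates ``reps`` i.i.d. m x n datasets, thresholds their absolute
    correlation matrices at ``p`` and returns the mean edge density with a
    99% normal-approximation interval over replicates.  Under the null model
    the density should match F(n, p) for both normal and uniform entries.
    """
    if reps < 100:
        raise ValueError("at least 100 replicates are required for a stable interval")
    if distribution not in ("normal", "uniform"):
        raise ValueError(f"distribution must be 'normal' or 'uniform', got {distribution!r}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {p!r}")
    rng = np.random.default_rng(seed)
    M = m * (m - 1) / 2.0
    iu = np.triu_indices(m, 1)
    densities = np.empty(reps)
    for r in range(reps):
        if distribution == "normal":
            data = rng.standard_normal((m, n))
        else:
            data = rng.random((m, n))
        C = np.abs(np.corrcoef(data))
        densities[r] = (C[iu] > p).sum() / M
    mean = float(densities.mean())
    half = 2.5758293035489004 * float(densities.std(ddof=1)) / np.sqrt(reps)
    return ErNullResult(
        density=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        expected=null_exceedance_probability(n, p),
        n=n,
        m=m,
        threshold=p,
        replicates=reps,
    )
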
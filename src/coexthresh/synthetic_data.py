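"""Synthetic expression datasets with known correlation structure.

Three generators cover the validation inputs used throughout the package:

* :func:`generate_block_dataset` -- a 20-gene design with two blocks of 10
  genes each.  Within a block every gene is built from the block's anchor
  gene by ``G_j = r_j * anchor + sqrt(1 - r_j^2) * Z_j`` so the population
  correlation against the anchor hits the target ``r_j`` exactly; targets
  decay linearly (1 - 0.03j in the first block, 0.7 - 0.015j in the second,
  j the global 1-based gene index).  Blocks are independent, so cross-block
  population correlation is zero.
* :func:`generate_two_group_dataset` -- an equicorrelated one-factor design
  per group (default group sizes 11 and 9), emulating two sets of outcome-
  associated genes from a tumour expression study.
* :func:`generate_null_dataset` -- i.i.d. noise (normal or uniform), the
  Erdos-Renyi reference case.

:func:`add_noise` perturbs every gene row with Gaussian noise whose standard
deviation is a fraction ``alpha`` of that row's range.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import CorrelationMatrix, ExpressionMatrix

__all__ = [
    "BlockDesign",
    "generate_block_dataset",
    "add_noise",
    "generate_null_dataset",
    "generate_two_group_dataset",
]


@dataclass(frozen=True)
class BlockDesign:
    """Anchor-decay design of block-correlated genes.

    Each block is described by ``(size, intercept, slope)``: its first gene
    is the anchor and the gene at global 1-based index ``j`` targets
    ``|rho| = intercept + slope * j`` against the anchor.  The defaults are
    the 20-gene two-block design used for validation.
    """

    blocks: tuple[tuple[int, float, float], ...] = ((10, 1.0, -0.03), (10, 0.7, -0.015))
    n_samples: int = 1000
    seed: int = 0

    def targets(self) -> list[float]:
        """Per-gene anchor correlation targets (anchors get 1.0)."""
        out: list[float] = []
        j = 0
        for size, intercept, slope in self.blocks:
            if size < 2:
                raise ValueError("each block needs at least an anchor and one member")
            for within in range(size):
                j += 1
                r = 1.0 if within == 0 else intercept + slope * j
                if not 0.0 <= r <= 1.0:
                    raise ValueError(
                        f"target correlation {r:.4f} for gene {j} is outside [0, 1]"
                    )
                out.append(r)
        return out

    @property
    def n_genes(self) -> int:
        return sum(size for size, _, _ in self.blocks)


def generate_block_dataset(
    design: BlockDesign | None = None, binarize: bool = False
) -> tuple[ExpressionMatrix, CorrelationMatrix]:
    """Block-correlated expression data plus its ground-truth matrix.

    The ground truth is the empirical absolute correlation matrix of the
    generated data with all cross-block entries set to zero; with
    ``binarize=True`` the in-block off-diagonal entries are set to one
    (the convention for counting true/false positive links, whereas the
    real-valued form serves spectral network distances).
    """
    design = design or BlockDesign()
    rng = np.random.default_rng(design.seed)
    targets = design.targets()
    m, n = design.n_genes, design.n_samples

    values = np.empty((m, n))
    membership = np.empty(m, dtype=int)
    row = 0
    for b, (size, _, _) in enumerate(design.blocks):
        anchor = rng.standard_normal(n)
        for within in range(size):
            r = targets[row]
            if within == 0:
                values[row] = anchor
            else:
                values[row] = r * anchor + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
            membership[row] = b
            row += 1

    X = ExpressionMatrix(
        values,
        [f"G{i + 1}" for i in range(m)],
        [f"S{i + 1}" for i in range(n)],
    )
    C = np.abs(np.corrcoef(values))
    same_block = membership[:, None] == membership[None, :]
    C[~same_block] = 0.0
    if binarize:
        C[same_block] = 1.0
    np.fill_diagonal(C, 1.0)
    return X, CorrelationMatrix(C, list(X.gene_ids))


def add_noise(X: ExpressionMatrix, alpha: float, seed: int = 0) -> ExpressionMatrix:
    """Add per-gene Gaussian noise scaled to a fraction of the gene's range.

    Every row ``s`` becomes ``s + eps`` with ``eps ~ N(0, alpha * (max(s) -
    min(s)))`` i.i.d. across samples (the second parameter read as a
    standard deviation).  ``alpha = 0`` returns the input unchanged.
    """
    if alpha < 0:
        raise ValueError(f"noise fraction alpha must be >= 0, got {alpha!r}")
    if alpha == 0:
        return ExpressionMatrix(X.values.copy(), list(X.gene_ids), list(X.sample_ids))
    rng = np.random.default_rng(seed)
    ranges = X.values.max(axis=1) - X.values.min(axis=1)
    noise = rng.standard_normal(X.values.shape) * (alpha * ranges)[:, None]
    return ExpressionMatrix(X.values + noise, list(X.gene_ids), list(X.sample_ids))


def generate_null_dataset(
    m: int, n: int, distribution: str = "normal", seed: int | None = None
) -> ExpressionMatrix:
    """i.i.d. noise dataset: ``m`` independent genes over ``n`` samples."""
    if m < 2 or n < 3:
        raise ValueError("need m >= 2 genes and n >= 3 samples")
    if distribution not in ("normal", "uniform"):
        raise ValueError(f"distribution must be 'normal' or 'uniform', got {distribution!r}")
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((m, n)) if distribution == "normal" else rng.random((m, n))
    return ExpressionMatrix(
        values, [f"G{i + 1}" for i in range(m)], [f"S{i + 1}" for i in range(n)]
    )


def generate_two_group_dataset(
    m_good: int = 11,
    m_poor: int = 9,
    n: int = 161,
    effect: float = 0.8,
    seed: int = 0,
    truth_floor: float = 0.1,
) -> tuple[ExpressionMatrix, CorrelationMatrix]:
    """Two independent equicorrelated gene groups with a latent factor each.

    Every gene loads on its group factor with weight ``effect``:
    ``G_i = effect * factor + sqrt(1 - effect^2) * Z_i``, giving population
    within-group correlation ``effect**2`` and zero across groups.  The
    ground truth is the *population* correlation matrix with every entry
    below ``truth_floor`` zeroed, mirroring how a reference correlation
    structure is cleaned before use as a gold standard; being a population
    object it is deterministic in the design, so the count of true links is
    exactly C(m_good, 2) + C(m_poor, 2) whenever ``effect**2`` clears the
    floor.
    """
    if m_good < 2 or m_poor < 2:
        raise ValueError("each group needs at least 2 genes")
    if not 0.0 <= effect < 1.0:
        raise ValueError(f"effect must lie in [0, 1), got {effect!r}")
    rng = np.random.default_rng(seed)
    loads = np.sqrt(1.0 - effect * effect)
    rows = []
    for size in (m_good, m_poor):
        factor = rng.standard_normal(n)
        rows.append(effect * factor + loads * rng.standard_normal((size, n)))
    values = np.vstack(rows)
    gene_ids = [f"good{i + 1}" for i in range(m_good)] + [f"poor{i + 1}" for i in range(m_poor)]
    X = ExpressionMatrix(values, gene_ids, [f"S{i + 1}" for i in range(n)])
    group = np.repeat([0, 1], [m_good, m_poor])
    C = np.where(group[:, None] == group[None, :], effect * effect, 0.0)
    C[C < truth_floor] = 0.0
    np.fill_diagonal(C, 1.0)
    return X, CorrelationMatrix(C, gene_ids)
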
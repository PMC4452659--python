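"""Scoring inferred networks against a ground truth, and the subsampling
experiment protocol built on it.

Link-level confusion counts follow the all-pairs convention: false positive
and false negative counts are divided by ``m(m-1)/2``, the total number of
possible links, not by the condition-positive/negative counts.  Network
distance uses the Hamming-Ipsen-Mikhailov (HIM) metric, comparing the binary
inferred graph against the real-valued ground-truth weights, while confusion
uses the binarized truth (any positive weight is a true link) -- the dual
convention under which block membership, not exact correlation values, is
the object being recovered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .him import calibration_gamma, him_distance
from .network import CorrelationMatrix, ExpressionMatrix
from .thresholds import secure_threshold

__all__ = [
    "ConfusionSummary",
    "confusion",
    "ExperimentCurves",
    "subsampling_experiment",
    "correlation_vs_samplesize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionSummary:
    """Link-level confusion counts over all m(m-1)/2 unordered pairs."""

    true_positives: int
    true_negatives: int
    false_positives: int
    false_negatives: int

    @property
    def n_links(self) -> int:
        return (
            self.true_positives
            + self.true_negatives
            + self.false_positives
            + self.false_negatives
        )

    @property
    def false_positive_ratio(self) -> float:
        return self.false_positives / self.n_links

    @property
    def false_negative_ratio(self) -> float:
        return self.false_negatives / self.n_links


def _edge_vector(g, reference_nodes=None) -> tuple[np.ndarray, tuple[str, ...]]:
    """Boolean upper-triangle edge indicators plus the node order used."""
    if isinstance(g, nx.Graph):
        nodes = tuple(g.nodes())
        A = nx.to_numpy_array(g, nodelist=list(nodes), weight=None) > 0
    elif isinstance(g, CorrelationMatrix):
        nodes = tuple(g.gene_ids)
        A = g.values > 0
    else:
        A = np.asarray(g) > 0
        nodes = tuple(str(i) for i in range(A.shape[0]))
    iu = np.triu_indices(A.shape[0], 1)
    return A[iu], nodes


def confusion(inferred, truth) -> ConfusionSummary:
    """Compare an inferred network with a (binary) ground-truth network.

    Both arguments may be ``networkx`` graphs, :class:`CorrelationMatrix`
    objects or adjacency arrays; any positive ground-truth weight counts as
    a true link.  The node sets must coincide.
    """
    e_inf, n1 = _edge_vector(inferred)
    e_tru, n2 = _edge_vector(truth)
    if len(n1) != len(n2) or set(n1) != set(n2):
        raise ValueError("inferred and truth networks must share the same node set")
    if n1 != n2:
        raise ValueError("node orders differ; align the inputs before comparing")
    tp = int(np.sum(e_inf & e_tru))
    fp = int(np.sum(e_inf & ~e_tru))
    fn = int(np.sum(~e_inf & e_tru))
    tn = int(np.sum(~e_inf & ~e_tru))
    return ConfusionSummary(tp, tn, fp, fn)


@dataclass
class ExperimentCurves:
    """Per-threshold mean and sd of FPR, FNR and HIM over replicates.

    ``*_at_secure`` fields hold the same statistics evaluated exactly at the
    secure threshold for the experiment's (subsample size, gene count).
    """

    thresholds: np.ndarray
    fpr_mean: np.ndarray
    fpr_sd: np.ndarray
    fnr_mean: np.ndarray
    fnr_sd: np.ndarray
    him_mean: np.ndarray
    him_sd: np.ndarray
    n_subsample: int
    replicates: int
    secure_threshold: float
    fpr_at_secure: tuple[float, float]
    fnr_at_secure: tuple[float, float]
    him_at_secure: tuple[float, float]


def subsampling_experiment(
    X: ExpressionMatrix,
    truth: CorrelationMatrix,
    n_s: int,
    replicates: int = 500,
    threshold_grid: np.ndarray | None = None,
    seed: int = 0,
) -> ExperimentCurves:
    """Replicated subsampling evaluation across a hard-threshold grid.

    Each replicate draws ``n_s`` samples without replacement, computes the
    absolute PCC matrix, thresholds it over the grid (default 0.01j for
    j = 1..100) and scores confusion ratios against the binarized truth and
    HIM distance against the real-valued truth.  Statistics at the secure
    threshold p_bar(n_s, m) are recorded alongside the grid.

    Replicate r uses the seed pair ``(seed, r)``, so runs are reproducible
    and individual replicates can be regenerated in isolation.  Replicates
    that produce a constant gene row after subsampling (PCC undefined) are
    redrawn with a logged warning.
    """
    if n_s > X.n_samples:
        raise ValueError(f"cannot draw {n_s} of {X.n_samples} samples")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if tuple(truth.gene_ids) != tuple(X.gene_ids):
        raise ValueError("truth and expression gene ids must coincide")
    if threshold_grid is None:
        threshold_grid = np.round(np.arange(1, 101) * 0.01, 2)
    grid = np.asarray(threshold_grid, dtype=float)

    m = X.n_genes
    n_links = m * (m - 1) // 2
    iu = np.triu_indices(m, 1)
    truth_w = truth.values.copy()
    np.fill_diagonal(truth_w, 0.0)
    truth_bin = truth_w[iu] > 0
    pbar = secure_threshold(n_s, m).value
    gamma = calibration_gamma(m)
    all_thresholds = np.append(grid, pbar)

    n_thr = all_thresholds.size
    fpr = np.empty((replicates, n_thr))
    fnr = np.empty((replicates, n_thr))
    him = np.empty((replicates, n_thr))

    for r in range(replicates):
        rng = np.random.default_rng([seed, r])
        while True:
            cols = rng.choice(X.n_samples, size=n_s, replace=False)
            sub = X.values[:, cols]
            if (sub.std(axis=1) > 0).all():
                break
            logger.warning(
                "replicate %d drew a constant gene row at n_s=%d; redrawing", r, n_s
            )
        C = np.abs(np.corrcoef(sub))
        np.fill_diagonal(C, 0.0)
        c_vec = C[iu]
        pred = c_vec[None, :] > all_thresholds[:, None]  # n_thr x n_links
        fpr[r] = (pred & ~truth_bin).sum(axis=1) / n_links
        fnr[r] = (~pred & truth_bin).sum(axis=1) / n_links
        for t in range(n_thr):
            A = (C > all_thresholds[t]).astype(float)
            him[r, t] = him_distance(A, truth_w, gamma=gamma)

    def stats(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return a.mean(axis=0), a.std(axis=0, ddof=1) if replicates > 1 else np.zeros(n_thr)

    fpr_m, fpr_s = stats(fpr)
    fnr_m, fnr_s = stats(fnr)
    him_m, him_s = stats(him)
    return ExperimentCurves(
        thresholds=grid,
        fpr_mean=fpr_m[:-1],
        fpr_sd=fpr_s[:-1],
        fnr_mean=fnr_m[:-1],
        fnr_sd=fnr_s[:-1],
        him_mean=him_m[:-1],
        him_sd=him_s[:-1],
        n_subsample=n_s,
        replicates=replicates,
        secure_threshold=pbar,
        fpr_at_secure=(float(fpr_m[-1]), float(fpr_s[-1])),
        fnr_at_secure=(float(fnr_m[-1]), float(fnr_s[-1])),
        him_at_secure=(float(him_m[-1]), float(him_s[-1])),
    )


def correlation_vs_samplesize(
    X: ExpressionMatrix,
    pair: tuple[str, str],
    base_subset: list[str] | list[int],
    replicates: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean |PCC| of one gene pair as samples accrue beyond a fixed base.

    Starting from the fixed ``base_subset`` of samples, the remaining
    samples are appended one at a time in random order and |PCC| is recorded
    at every intermediate size; curves are averaged over ``replicates``
    random orders (the base subset never changes).  Illustrates how a
    spuriously high small-sample correlation decays toward its population
    value as evidence accumulates.

    Returns ``(sizes, mean_abs_rho)`` with sizes from ``len(base_subset)``
    to the full sample count.
    """
    try:
        gi, gj = (X.gene_ids.index(g) for g in pair)
    except ValueError as err:
        raise ValueError(f"gene pair {pair!r} not found in expression matrix") from err
    if len(base_subset) < 3:
        raise ValueError("base subset must contain at least 3 samples")
    if isinstance(base_subset[0], str):
        base_idx = np.array([X.sample_ids.index(s) for s in base_subset])
    else:
        base_idx = np.asarray(base_subset, dtype=int)
    rest = np.setdiff1d(np.arange(X.n_samples), base_idx)

    x_full = X.values[gi]
    y_full = X.values[gj]
    sizes = np.arange(len(base_idx), X.n_samples + 1)
    acc = np.zeros(sizes.size)
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        order = np.concatenate([base_idx, rng.permutation(rest)])
        x, y = x_full[order], y_full[order]
        ks = np.arange(1, x.size + 1)
        sx, sy = np.cumsum(x), np.cumsum(y)
        sxx, syy, sxy = np.cumsum(x * x), np.cumsum(y * y), np.cumsum(x * y)
        cov = sxy - sx * sy / ks
        vx = sxx - sx * sx / ks
        vy = syy - sy * sy / ks
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.abs(cov / np.sqrt(vx * vy))
        acc += rho[len(base_idx) - 1 :]
    return sizes, acc / replicates
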
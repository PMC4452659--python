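"""Hamming-Ipsen-Mikhailov (HIM) distance between networks on shared nodes.

The Hamming part is the mean absolute difference of (possibly weighted)
adjacency entries over all node pairs.  The Ipsen-Mikhailov (IM) part
compares Laplacian spectra: each graph is summarized by the density

    rho(omega) = K * sum_i  gamma / ((omega - omega_i)^2 + gamma^2),

a Lorentzian broadening of the Laplacian mode frequencies
``omega_i = sqrt(lambda_i)`` (one trivial zero eigenvalue dropped), with K
normalizing the density to unit mass on [0, inf).  Then

    IM(G, H) = sqrt( integral_0^inf (rho_G - rho_H)^2 d omega ),

and the broadening ``gamma`` is calibrated per node count so that
IM(empty, complete) = 1.  The combined metric is

    HIM = sqrt(H^2 + IM^2) / sqrt(2),

which is 0 iff the adjacency matrices coincide and 1 between the empty and
the complete graph.

The squared-difference integral is evaluated in closed form: the half-line
integral of a product of two Lorentzians follows from residue calculus,

    I(a, b) = int_0^inf dx / (((x-a)^2 + g^2) ((x-b)^2 + g^2))
            = [pi + atan(a/g) + atan(b/g)] / (g * (d^2 + 4 g^2))
              + log((a^2 + g^2) / (b^2 + g^2)) / (d * (d^2 + 4 g^2)),

with ``d = a - b``; the divided-difference term is computed via ``log1p``
so it stays accurate for nearly coincident eigenvalues.
"""

from __future__ import annotations

from functools import lru_cache

import networkx as nx
import numpy as np
from scipy import optimize

from .network import CorrelationMatrix

__all__ = ["him_distance", "ipsen_mikhailov_distance", "hamming_distance", "calibration_gamma"]


def _pair_integrals(a: np.ndarray, b: np.ndarray, gamma: float) -> np.ndarray:
    """Half-line integral of Lorentzian products, all (a_i, b_j) pairs."""
    a = a[:, None]
    b = b[None, :]
    d = a - b
    base = d * d + 4.0 * gamma * gamma
    term1 = (np.pi + np.arctan(a / gamma) + np.arctan(b / gamma)) / (gamma * base)
    # divided difference of log(x^2 + gamma^2); exact limit 2a/(a^2+g^2) at d=0
    num = d * (a + b) / (b * b + gamma * gamma)
    with np.errstate(divide="ignore", invalid="ignore"):
        dd = np.log1p(num) / d
    dd = np.where(d == 0.0, 2.0 * a / (a * a + gamma * gamma) + 0.0 * b, dd)
    return term1 + dd / base


def _modes(adjacency: np.ndarray) -> np.ndarray:
    """Laplacian mode frequencies sqrt(lambda), one zero mode removed."""
    L = np.diag(adjacency.sum(axis=1)) - adjacency
    lam = np.linalg.eigvalsh(L)
    lam = np.clip(lam, 0.0, None)
    return np.sqrt(lam[1:])  # eigvalsh sorts ascending; drop the trivial zero


def _cross_mass(w1: np.ndarray, w2: np.ndarray, gamma: float) -> float:
    return float(gamma * gamma * _pair_integrals(w1, w2, gamma).sum())


def _im_from_modes(w1: np.ndarray, w2: np.ndarray, gamma: float) -> float:
    k1 = 1.0 / (np.pi / 2.0 + np.arctan(w1 / gamma)).sum()
    k2 = 1.0 / (np.pi / 2.0 + np.arctan(w2 / gamma)).sum()
    sq = (
        k1 * k1 * _cross_mass(w1, w1, gamma)
        - 2.0 * k1 * k2 * _cross_mass(w1, w2, gamma)
        + k2 * k2 * _cross_mass(w2, w2, gamma)
    )
    return float(np.sqrt(max(sq, 0.0)))


@lru_cache(maxsize=None)
def calibration_gamma(m: int) -> float:
    """Lorentzian width making IM(empty, complete) = 1 for ``m`` nodes."""
    if m < 2:
        raise ValueError("need at least 2 nodes")
    w_empty = np.zeros(m - 1)
    w_complete = np.full(m - 1, np.sqrt(m))

    def objective(g: float) -> float:
        return _im_from_modes(w_empty, w_complete, g) - 1.0

    return float(optimize.brentq(objective, 1e-4, 10.0, xtol=1e-13))


def _as_adjacency(g) -> tuple[np.ndarray, tuple[str, ...]]:
    """Adjacency matrix (zero diagonal) plus node labels from graph-like input."""
    if isinstance(g, nx.Graph):
        nodes = tuple(g.nodes())
        A = nx.to_numpy_array(g, nodelist=list(nodes), weight="weight")
    elif isinstance(g, CorrelationMatrix):
        nodes = tuple(g.gene_ids)
        A = g.values.copy()
    else:
        A = np.asarray(g, dtype=float)
        nodes = tuple(str(i) for i in range(A.shape[0]))
    A = np.array(A, dtype=float)
    np.fill_diagonal(A, 0.0)
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if A.min() < 0 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency weights must lie in [0, 1]")
    return A, nodes


def hamming_distance(g1, g2) -> float:
    """Normalized Hamming distance between (weighted) adjacency matrices."""
    A1, n1 = _as_adjacency(g1)
    A2, n2 = _as_adjacency(g2)
    _check_nodes(n1, n2)
    m = A1.shape[0]
    return float(np.abs(A1 - A2).sum() / (m * (m - 1)))


def ipsen_mikhailov_distance(g1, g2, gamma: float | None = None) -> float:
    """Spectral (Ipsen-Mikhailov) distance; gamma defaults to calibrated."""
    A1, n1 = _as_adjacency(g1)
    A2, n2 = _as_adjacency(g2)
    _check_nodes(n1, n2)
    if gamma is None:
        gamma = calibration_gamma(A1.shape[0])
    return _im_from_modes(_modes(A1), _modes(A2), gamma)


def him_distance(g1, g2, gamma: float | None = None) -> float:
    """Combined HIM distance in [0, 1].

    Accepts ``networkx`` graphs, :class:`CorrelationMatrix` objects (their
    unit diagonal is ignored) or plain adjacency arrays with weights in
    [0, 1]; both arguments must share the node set.
    """
    A1, n1 = _as_adjacency(g1)
    A2, n2 = _as_adjacency(g2)
    _check_nodes(n1, n2)
    if np.array_equal(A1, A2):
        return 0.0
    if gamma is None:
        gamma = calibration_gamma(A1.shape[0])
    h = np.abs(A1 - A2).sum() / (A1.shape[0] * (A1.shape[0] - 1))
    im = _im_from_modes(_modes(A1), _modes(A2), gamma)
    return float(np.sqrt((h * h + im * im) / 2.0))


def _check_nodes(n1: tuple[str, ...], n2: tuple[str, ...]) -> None:
    if len(n1) != len(n2) or set(n1) != set(n2):
        raise ValueError("networks must share the same node set")
    if n1 != n2:
        raise ValueError("node orders differ; align the inputs before comparing")
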
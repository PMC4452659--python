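"""Hard thresholds for coexpression networks derived from the PCC null model.

The *secure threshold* ``p_bar(n, m)`` is the smallest cutoff at which a
coexpression network built from pure-noise data with ``n`` samples and ``m``
genes is empty on average: it solves

    F(n, p) * m(m-1)/2 = 1 - eps,   eps -> 0+,

where ``F`` is the null exceedance probability of |PCC| and ``m(m-1)/2`` the
number of candidate links.  A Chebyshev-sharpened variant adds ``k`` standard
deviations of the binomial edge count to the expectation before requiring it
to stay below one.  Bonferroni comparator thresholds invert the Fisher or
Student-t p-value map at the familywise-corrected per-link level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import optimize, special, stats

from .null_model import null_exceedance_probability

__all__ = [
    "ThresholdResult",
    "secure_threshold",
    "chebyshev_threshold",
    "bonferroni_threshold",
]

_XTOL = 1e-12  # bracketed root-finder tolerance on p


@dataclass(frozen=True)
class ThresholdResult:
    """A hard threshold together with its provenance and diagnostics.

    Attributes
    ----------
    value : float
        The threshold on |PCC|, in (0, 1].
    expected_null_edges : float
        ``F(n, value) * m(m-1)/2``, the expected number of edges a pure-noise
        dataset of the same shape would place above the threshold.
    method : str
        One of ``secure``, ``chebyshev``, ``bonferroni_fisher``,
        ``bonferroni_t``.
    unattainable : bool
        Set when the threshold reaches 1 within floating-point tolerance,
        i.e. no correlation below 1 attains the requested level.
    """

    value: float
    expected_null_edges: float
    method: str
    n: int
    m: int
    k: float | None = None
    alpha: float | None = None
    epsilon: float = 0.0
    unattainable: bool = field(default=False)


def _check_nm(n: int, m: int, min_n: int = 3) -> float:
    if n != int(n) or n < min_n:
        raise ValueError(f"sample count n must be an integer >= {min_n}, got {n!r}")
    if m != int(m) or m < 2:
        raise ValueError(f"gene count m must be an integer >= 2, got {m!r}")
    return m * (m - 1) / 2.0


def _check_epsilon(epsilon: float) -> None:
    if not 0.0 <= epsilon < 1.0:
        raise ValueError(f"epsilon must lie in [0, 1), got {epsilon!r}")


def secure_threshold(n: int, m: int, epsilon: float = 0.0) -> ThresholdResult:
    """Smallest p with ``F(n, p) * m(m-1)/2 <= 1 - epsilon``.

    With the default ``epsilon = 0`` (the vanishing-slack convention) this is
    the unique root of ``F(n, p) * M = 1``, found by bracketed root-finding;
    the expected number of false-positive edges in a random network equals
    one there.  Decreasing in ``n`` for fixed ``m``, increasing in ``m`` for
    fixed ``n``.
    """
    M = _check_nm(n, m)
    _check_epsilon(epsilon)
    target = 1.0 - epsilon

    def objective(p: float) -> float:
        return null_exceedance_probability(n, p) * M - target

    value = optimize.brentq(objective, 0.0, 1.0, xtol=_XTOL)
    return ThresholdResult(
        value=float(value),
        expected_null_edges=null_exceedance_probability(n, value) * M,
        method="secure",
        n=n,
        m=m,
        epsilon=epsilon,
    )


def chebyshev_threshold(n: int, m: int, k: float, epsilon: float = 0.0) -> ThresholdResult:
    """Secure threshold sharpened by ``k`` binomial standard deviations.

    Solves ``F*M + k*sqrt(F*(1-F)*M) <= 1 - epsilon``: by Chebyshev's
    inequality the realized edge count of the Erdos-Renyi null then stays
    below one except with probability at most ``1/k^2``.  ``k = 0`` recovers
    the secure threshold; the result is strictly increasing in ``k``.
    """
    M = _check_nm(n, m)
    _check_epsilon(epsilon)
    if k < 0:
        raise ValueError(f"Chebyshev multiplier k must be >= 0, got {k!r}")
    target = 1.0 - epsilon

    def objective(p: float) -> float:
        F = null_exceedance_probability(n, p)
        return F * M + k * math.sqrt(F * (1.0 - F) * M) - target

    value = optimize.brentq(objective, 0.0, 1.0, xtol=_XTOL)
    return ThresholdResult(
        value=float(value),
        expected_null_edges=null_exceedance_probability(n, value) * M,
        method="chebyshev",
        n=n,
        m=m,
        k=k,
        epsilon=epsilon,
    )


def bonferroni_threshold(
    n: int, m: int, alpha: float = 0.05, method: str = "fisher"
) -> ThresholdResult:
    """|PCC| cutoff whose per-link p-value meets the Bonferroni level.

    With ``m(m-1)/2`` candidate links, familywise error rate ``alpha`` gives
    the per-link two-sided level ``p_m = 2*alpha / (m(m-1))``.  The monotone
    p-value map of the chosen test is inverted in closed form:

    - ``fisher``:   rho = tanh(z / sqrt(n-3)),  z the upper p_m/2 normal
      quantile (requires n >= 4);
    - ``student_t``: rho = t / sqrt(t^2 + n - 2),  t the upper p_m/2
      quantile on n - 2 degrees of freedom (requires n >= 3).

    When the resulting cutoff reaches 1 within 1e-12 no attainable
    correlation meets the level and ``unattainable`` is flagged.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    if method == "fisher":
        M = _check_nm(n, m, min_n=4)
    elif method == "student_t":
        M = _check_nm(n, m, min_n=3)
    else:
        raise ValueError(f"method must be 'fisher' or 'student_t', got {method!r}")

    p_link = 2.0 * alpha / (m * (m - 1))
    if method == "fisher":
        z = stats.norm.isf(p_link / 2.0)
        value = math.tanh(z / math.sqrt(n - 3))
        label = "bonferroni_fisher"
    else:
        t = stats.t.isf(p_link / 2.0, n - 2)
        value = t / math.sqrt(t * t + n - 2)
        label = "bonferroni_t"

    return ThresholdResult(
        value=float(value),
        expected_null_edges=null_exceedance_probability(n, min(value, 1.0)) * M,
        method=label,
        n=n,
        m=m,
        alpha=alpha,
        unattainable=value >= 1.0 - 1e-12,
    )
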
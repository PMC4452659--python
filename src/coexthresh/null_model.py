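"""Exact null distribution of the absolute Pearson correlation coefficient.

For two independent normal vectors of length ``n`` the squared sample
correlation rho**2 follows a Beta((n-2)/2 wait, 1/2, (n-2)/2) law, so the
exceedance probability

    F(n, p) = P(|rho| > p)

has the closed form ``I_{1-p^2}((n-2)/2, 1/2)`` in terms of the regularized
incomplete beta function.  The same quantity can be written as a normalized
integral of ``sin^{n-3}`` over ``[0, arccos p]``; that form is kept here as an
independent numerical oracle for the closed form.

The module also provides the two classical p-value maps for an observed
correlation: the Fisher z-transform (normal approximation) and the exact
Student-t test on ``n - 2`` degrees of freedom.  Under normality the t test
is exact, i.e. ``student_pvalue(rho, n) == F(n, |rho|)``.
"""

from __future__ import annotations

import math

from scipy import integrate, special, stats

__all__ = [
    "null_exceedance_probability",
    "null_exceedance_by_quadrature",
    "fisher_pvalue",
    "student_pvalue",
]


def _check_np(n: int, p: float, min_n: int = 3) -> None:
    if n != int(n) or n < min_n:
        raise ValueError(f"sample count n must be an integer >= {min_n}, got {n!r}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"correlation threshold p must lie in [0, 1], got {p!r}")


def _check_rho_n(rho: float, n: int, min_n: int) -> None:
    if abs(rho) > 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {rho!r}")
    if n != int(n) or n < min_n:
        raise ValueError(f"sample count n must be an integer >= {min_n}, got {n!r}")


def null_exceedance_probability(n: int, p: float) -> float:
    """Probability that |PCC| of two independent n-vectors exceeds ``p``.

    Computed in closed form as the regularized incomplete beta function
    ``I_{1-p^2}((n-2)/2, 1/2)``; exact under normal marginals and a good
    approximation whenever skewness is mild.

    Parameters
    ----------
    n : int
        Number of samples, ``n >= 3``.
    p : float
        Correlation magnitude threshold in ``[0, 1]``.
    """
    _check_np(n, p)
    # 1 - p**2 computed as a product to keep accuracy near p = 1
    return float(special.betainc((n - 2) / 2.0, 0.5, (1.0 - p) * (1.0 + p)))


def null_exceedance_by_quadrature(n: int, p: float) -> float:
    """Same contract as :func:`null_exceedance_probability`, via quadrature.

    Integrates ``sin^{n-3}`` over ``[0, arccos p]`` with the prefactor
    ``2 Gamma((n-1)/2) / (sqrt(pi) Gamma((n-2)/2))`` fixed by the
    normalization F(n, 0) = 1.  Log-gamma arithmetic avoids overflow for
    large ``n``.  Kept as an independent oracle for the closed form.
    """
    _check_np(n, p)
    if p >= 1.0:
        return 0.0
    log_norm = (
        math.log(2.0)
        + special.gammaln((n - 1) / 2.0)
        - 0.5 * math.log(math.pi)
        - special.gammaln((n - 2) / 2.0)
    )
    norm = math.exp(log_norm)
    upper = math.acos(p)
    val, _ = integrate.quad(
        lambda t: math.sin(t) ** (n - 3), 0.0, upper, epsabs=1e-14, epsrel=1e-13, limit=200
    )
    return norm * val


def fisher_pvalue(rho: float, n: int) -> float:
    """Two-sided p-value of an observed PCC via the Fisher z-transform.

    ``arctanh(rho)`` is treated as normal with standard deviation
    ``1/sqrt(n-3)`` under the null; requires ``n >= 4``.  At ``|rho| = 1``
    the transform diverges and the p-value underflows to exactly 0, which is
    returned as such (callers needing thresholds invert instead of comparing
    raw p-values).
    """
    _check_rho_n(rho, n, 4)
    if abs(rho) == 1.0:
        return 0.0
    z = abs(math.atanh(rho)) * math.sqrt(n - 3)
    return float(2.0 * stats.norm.sf(z))


def student_pvalue(rho: float, n: int) -> float:
    """Two-sided p-value of an observed PCC via the exact Student-t test.

    ``rho * sqrt((n-2)/(1-rho^2))`` follows a t distribution on ``n - 2``
    degrees of freedom under the null (exact for normal data); requires
    ``n >= 3``.  Identical to ``null_exceedance_probability(n, |rho|)``.
    """
    _check_rho_n(rho, n, 3)
    if abs(rho) == 1.0:
        return 0.0
    t = abs(rho) * math.sqrt((n - 2) / ((1.0 - rho) * (1.0 + rho)))
    return float(2.0 * stats.t.sf(t, n - 2))
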
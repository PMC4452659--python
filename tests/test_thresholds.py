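"""Secure, Chebyshev and Bonferroni thresholds: golden values and inverses."""

import numpy as np
import pytest
from scipy import special

from coexthresh import (
    bonferroni_threshold,
    chebyshev_threshold,
    fisher_pvalue,
    null_exceedance_probability,
    secure_threshold,
    student_pvalue,
)

# Reference grid of the secure threshold: rows n, columns m.
SECURE_GRID_M = [100, 500, 1000, 2000, 10000, 50000, 100000]
SECURE_GRID = {
    8: [0.95629, 0.98520, 0.99070, 0.99415, 0.99800, 0.99932, 0.99957],
    15: [0.81681, 0.89170, 0.91323, 0.93036, 0.95800, 0.97456, 0.97949],
    20: [0.73825, 0.82388, 0.85077, 0.87330, 0.91286, 0.93973, 0.94852],
    30: [0.62814, 0.71776, 0.74817, 0.77485, 0.82534, 0.86367, 0.87729],
    50: [0.50225, 0.58534, 0.61513, 0.64213, 0.69607, 0.74036, 0.75705],
    75: [0.41647, 0.49026, 0.51740, 0.54238, 0.59353, 0.63709, 0.65394],
    100: [0.36343, 0.42999, 0.45477, 0.47774, 0.52537, 0.56662, 0.58279],
}


@pytest.mark.parametrize("n", sorted(SECURE_GRID))
def test_secure_threshold_reference_grid(n):
    """5-decimal reference values over a 7x7 (n, m) grid.

    Published thresholds are rounded up in their last digit (so the printed
    cutoff still guarantees the property), hence agreement is asserted to
    one unit in the fifth decimal rather than round-equality.
    """
    for m, expected in zip(SECURE_GRID_M, SECURE_GRID[n]):
        res = secure_threshold(n, m)
        assert abs(res.value - expected) <= 1e-5
        assert res.expected_null_edges == pytest.approx(1.0, abs=1e-6)


def test_secure_threshold_small_design_values():
    """Thresholds for the 20-gene design at subsample sizes 10/20/50.

    The published 3-decimal companions of these cases (0.799/0.596/0.389)
    carry a slip in the third decimal for the first two: solving
    F(n,p)*190 = 1 -- the same computation that reproduces the 5-decimal
    reference grid exactly -- gives 0.80191 and 0.59894.  The third value
    is reproduced at all three decimals.
    """
    assert secure_threshold(50, 20).value == pytest.approx(0.389, abs=1e-3)
    assert secure_threshold(10, 20).value == pytest.approx(0.799, abs=1e-2)
    assert secure_threshold(20, 20).value == pytest.approx(0.596, abs=1e-2)
    # the exact Eq-3 solutions, frozen at full precision
    assert secure_threshold(10, 20).value == pytest.approx(0.8019137958959, abs=1e-9)
    assert secure_threshold(20, 20).value == pytest.approx(0.5989417873141, abs=1e-9)


# (n, m, published secure threshold, decimals) from array-dataset comparisons
COMPARISON_CELLS = [
    (50, 1000, 0.6152, 4),
    (25, 1000, 0.7956, 4),
    (23, 897, 0.8125, 4),
    (10, 897, 0.9723, 4),
    (10, 675, 0.9681, 4),
    (9, 897, 0.9821, 4),
    (8, 897, 0.98999, 5),
    (7, 897, 0.99558, 5),
    (6, 897, 0.99872, 5),
    (5, 897, 0.99984, 5),
    (4, 401, 0.9999, 4),
    (30, 22277, 0.84570, 5),
    (28, 26199, 0.86492, 5),
    (58, 29211, 0.68841, 5),
    (56, 29211, 0.69741, 5),
    (50, 12453, 0.70261, 5),
    (39, 12235, 0.76591, 5),
    (44, 22383, 0.75203, 5),
    (47, 12453, 0.71857, 5),
    (46, 12453, 0.72411, 5),
    (59, 12453, 0.66011, 5),
    (24, 25859, 0.89684, 5),
]


@pytest.mark.parametrize("n,m,expected,decimals", COMPARISON_CELLS)
def test_secure_threshold_array_datasets(n, m, expected, decimals):
    assert abs(secure_threshold(n, m).value - expected) <= 10.0 ** (-decimals)


def test_secure_threshold_beyond_099():
    """Near-degenerate designs (4 samples) push the cutoff above 0.9999."""
    for n, m in [(4, 897), (4, 675)]:
        assert secure_threshold(n, m).value > 0.9999


def test_secure_threshold_closed_form_inverse():
    """brentq root agrees with the direct incomplete-beta inversion."""
    for n, m in [(8, 100), (15, 500), (50, 20), (100, 100000)]:
        M = m * (m - 1) / 2.0
        direct = np.sqrt(1.0 - special.betaincinv((n - 2) / 2.0, 0.5, 1.0 / M))
        assert secure_threshold(n, m).value == pytest.approx(float(direct), abs=1e-9)


def test_secure_threshold_monotone_in_n_and_m():
    for m in (20, 500):
        vals = [secure_threshold(n, m).value for n in (5, 10, 20, 40, 80)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
    for n in (10, 50):
        vals = [secure_threshold(n, m).value for m in (5, 20, 100, 1000)]
        assert all(a < b for a, b in zip(vals, vals[1:]))


def test_secure_threshold_finite_epsilon():
    """A finite slack demands fewer expected edges, hence a larger cutoff."""
    base = secure_threshold(15, 100)
    eased = secure_threshold(15, 100, epsilon=0.3)
    assert eased.value > base.value
    assert eased.expected_null_edges == pytest.approx(0.7, abs=1e-6)


def test_chebyshev_reduces_to_secure_at_k_zero():
    a = secure_threshold(8, 100).value
    b = chebyshev_threshold(8, 100, k=0.0).value
    assert abs(a - b) <= 1e-10


def test_chebyshev_increasing_in_k():
    vals = [chebyshev_threshold(8, 100, k=k).value for k in (0.0, 0.5, 1.0, 2.0, 5.0)]
    assert all(a < b for a, b in zip(vals, vals[1:]))


def test_chebyshev_grid_scan_oracle():
    """Root-found cutoff matches a brute-force scan of the inequality."""
    n, m, k = 15, 1000, 5.0
    M = m * (m - 1) / 2.0
    p_grid = np.arange(1e-6, 1.0, 1e-6)
    F = special.betainc((n - 2) / 2.0, 0.5, (1.0 - p_grid) * (1.0 + p_grid))
    lhs = F * M + k * np.sqrt(F * (1.0 - F) * M)
    scan = p_grid[np.argmax(lhs <= 1.0)]
    found = chebyshev_threshold(n, m, k=k).value
    assert abs(found - scan) <= 1e-6


TABLE2_M = [5, 10, 25, 50, 100, 1000]
TABLE2 = {
    # n: (secure row, bonferroni-fisher row, bonferroni-t row)
    10: (
        [0.55, 0.71, 0.82, 0.88, 0.92, 0.97],
        [0.79, 0.85, 0.90, 0.92, 0.94, 0.97],
        [0.81, 0.87, 0.92, 0.95, 0.97, 0.99],
    ),
    15: (
        [0.44, 0.58, 0.70, 0.77, 0.82, 0.91],
        [0.67, 0.74, 0.80, 0.83, 0.86, 0.92],
        [0.69, 0.76, 0.83, 0.86, 0.89, 0.95],
    ),
    20: (
        [0.38, 0.51, 0.62, 0.69, 0.74, 0.85],
        [0.60, 0.66, 0.73, 0.76, 0.79, 0.86],
        [0.61, 0.68, 0.75, 0.79, 0.82, 0.90],
    ),
    25: (
        [0.34, 0.46, 0.56, 0.63, 0.68, 0.80],
        [0.54, 0.61, 0.67, 0.71, 0.74, 0.82],
        [0.55, 0.62, 0.69, 0.73, 0.77, 0.85],
    ),
    50: (
        [0.24, 0.32, 0.41, 0.46, 0.50, 0.62],
        [0.39, 0.45, 0.50, 0.54, 0.57, 0.66],
        [0.40, 0.45, 0.51, 0.55, 0.59, 0.68],
    ),
    100: (
        [0.17, 0.23, 0.29, 0.33, 0.36, 0.45],
        [0.28, 0.32, 0.37, 0.40, 0.43, 0.50],
        [0.28, 0.33, 0.37, 0.40, 0.43, 0.51],
    ),
}


@pytest.mark.parametrize("n", sorted(TABLE2))
def test_bonferroni_comparison_grid(n):
    """Secure and Bonferroni thresholds over the comparison grid.

    Published cells round thresholds upward, so values are checked to one
    unit in the second decimal.
    """
    prow, frow, trow = TABLE2[n]
    for j, m in enumerate(TABLE2_M):
        assert abs(secure_threshold(n, m).value - prow[j]) <= 0.01
        bf = bonferroni_threshold(n, m, method="fisher")
        bt = bonferroni_threshold(n, m, method="student_t")
        assert abs(bf.value - frow[j]) <= 0.01
        assert abs(bt.value - trow[j]) <= 0.01
        assert not bf.unattainable and not bt.unattainable


def test_bonferroni_t_dominates_fisher_and_secure():
    """The exact t inversion always exceeds both other thresholds.

    (The Fisher comparator can dip marginally below the secure threshold at
    small n with very many genes, where the normal approximation
    under-covers the extreme tail; the t threshold has no such defect.)
    """
    for n in sorted(TABLE2):
        for m in TABLE2_M:
            s = secure_threshold(n, m).value
            bf = bonferroni_threshold(n, m, method="fisher").value
            bt = bonferroni_threshold(n, m, method="student_t").value
            assert s < bt
            assert bf < bt


def test_bonferroni_round_trip():
    """p-value of the inverted threshold equals the per-link level."""
    for n, m in [(10, 5), (15, 1000), (50, 100)]:
        p_link = 0.1 / (m * (m - 1))
        bf = bonferroni_threshold(n, m, method="fisher").value
        bt = bonferroni_threshold(n, m, method="student_t").value
        assert fisher_pvalue(bf, n) == pytest.approx(p_link, abs=1e-9)
        assert student_pvalue(bt, n) == pytest.approx(p_link, abs=1e-9)
        # the exact t threshold also solves the null-model equation
        assert null_exceedance_probability(n, bt) == pytest.approx(p_link, abs=1e-9)


def test_bonferroni_unattainable_flag():
    """An absurdly small FWER pushes the cutoff to 1 and flags it."""
    res = bonferroni_threshold(4, 10**6, alpha=1e-300, method="fisher")
    assert res.unattainable
    assert res.value >= 1.0 - 1e-12


def test_threshold_domain_errors():
    with pytest.raises(ValueError):
        secure_threshold(2, 100)
    with pytest.raises(ValueError):
        secure_threshold(10, 1)
    with pytest.raises(ValueError):
        chebyshev_threshold(10, 100, k=-1.0)
    with pytest.raises(ValueError):
        bonferroni_threshold(10, 100, alpha=1.5)
    with pytest.raises(ValueError):
        bonferroni_threshold(3, 100, method="fisher")  # Fisher needs n >= 4
    bonferroni_threshold(3, 100, method="student_t")  # t is fine at n = 3
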
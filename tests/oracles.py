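"""Independent brute-force oracles used by the test suite only.

These deliberately avoid the package's code paths: exact-rational
probabilities via ``fractions.Fraction`` and table enumeration via
``itertools.product`` with a margin filter.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def fisher_p_bruteforce(table) -> float:
    """Two-sided Fisher p (point-probability rule) by naive enumeration.

    Every candidate r x c table is generated as a product over cell ranges
    and kept only if its margins match; probabilities are exact Fractions
    P(T) = prod(r_i!) prod(c_j!) / (n! prod(a_ij!)).
    """
    arr = np.asarray(table, dtype=int)
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    arr = arr[rows > 0][:, cols > 0]
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    n = int(arr.sum())
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        return 1.0

    const = Fraction(
        math.prod(math.factorial(int(r)) for r in rows)
        * math.prod(math.factorial(int(c)) for c in cols),
        math.factorial(n),
    )

    def prob(cells) -> Fraction:
        return const / math.prod(math.factorial(int(a)) for a in cells)

    p_obs = prob(arr.ravel())
    nrow, ncol = arr.shape
    row_list = [int(r) for r in rows]
    col_list = [int(c) for c in cols]
    # enumerate the free cells of all rows but the last; the last row is then
    # forced by the column margins
    ranges = [
        range(min(row_list[i], col_list[j]) + 1)
        for i in range(nrow - 1)
        for j in range(ncol)
    ]
    total = Fraction(0)
    tail = Fraction(0)
    for cells in itertools.product(*ranges):
        ok = True
        for i in range(nrow - 1):
            if sum(cells[i * ncol : (i + 1) * ncol]) != row_list[i]:
                ok = False
                break
        if not ok:
            continue
        last = [col_list[j] - sum(cells[i * ncol + j] for i in range(nrow - 1))
                for j in range(ncol)]
        if any(v < 0 for v in last):
            continue
        p = prob((*cells, *last))
        total += p
        if p <= p_obs:
            tail += p
    assert total == 1
    return float(tail)


def hypergeom_p_closed_form(table) -> float:
    """2x2 two-sided Fisher p straight from the hypergeometric pmf.

    pmf(a) = C(r1, a) C(r2, c1 - a) / C(n, c1), summed over the support for
    values with pmf <= pmf(a_obs), all in exact integer arithmetic.
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in support}
    w_obs = weights[a]
    return sum(w for w in weights.values() if w <= w_obs) / math.comb(n, c1)


def ols_normal_equations(y, X):
    """Closed-form OLS coefficients (X'X)^-1 X'y."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def hc1_sandwich_se(y, X):
    """Hand-coded HC1 heteroskedasticity-consistent standard errors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = ols_normal_equations(y, X)
    resid = y - X @ beta
    bread = np.linalg.inv(X.T @ X)
    meat = X.T @ np.diag(resid**2) @ X
    cov = bread @ meat @ bread * n / (n - k)
    return np.sqrt(np.diag(cov))
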
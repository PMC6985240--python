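"""Independent reference implementations used as test oracles.

Everything here is deliberately written from the model definitions, not by
calling package internals: brute-force term sums, nested-loop enumeration,
normal-equations least squares, and closed-form regression.
"""

import itertools
import math

import numpy as np


def coded(level, L):
    """Regression-scale value of a coded level (vehicle at origin)."""
    if level == 0:
        return 0.0
    if L == 1:
        return 1.0
    return -1.0 + 2.0 * (level - 1) / (L - 1)


def quadratic_eval(coefs, levels, L):
    """Term-by-term quadratic evaluation for one coded-level vector."""
    n = len(levels)
    x = [coded(lv, L) for lv in levels]
    val = coefs[0]
    for i in range(n):
        val += coefs[1 + i] * x[i]
        val += coefs[1 + n + i] * x[i] ** 2
    pos = 1 + 2 * n
    for i in range(n):
        for j in range(i + 1, n):
            val += coefs[pos] * x[i] * x[j]
            pos += 1
    return val


def model_matrix(runs, L):
    """Quadratic model matrix assembled column by column from definitions."""
    runs = np.asarray(runs)
    n = runs.shape[1]
    X = np.array([[coded(lv, L) for lv in row] for row in runs])
    cols = [np.ones(len(runs))]
    cols += [X[:, i] for i in range(n)]
    cols += [X[:, i] ** 2 for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            cols.append(X[:, i] * X[:, j])
    return np.column_stack(cols)


def normal_equations_fit(runs, y, L):
    """OLS coefficients via explicit normal equations (pinv for stability)."""
    M = model_matrix(runs, L)
    return np.linalg.pinv(M.T @ M) @ M.T @ np.asarray(y, dtype=float)


def enumerate_nested(n, k, L):
    """All (member tuple, level tuple) pairs by explicit nested loops."""
    out = []
    for members in itertools.combinations(range(n), k):
        for levels in itertools.product(range(1, L + 1), repeat=k):
            out.append((members, levels))
    return out


def combination_count(n, k, L):
    return math.comb(n, k) * L**k


def score_then_sort(coefs, n, k, L):
    """Score every combination by brute-force evaluation; stable sort.

    Returns the list of enumeration indices in rank order.
    """
    scores = []
    for members, levels in enumerate_nested(n, k, L):
        dv = [0] * n
        for m, lv in zip(members, levels):
            dv[m] = lv
        scores.append(quadratic_eval(coefs, dv, L))
    return sorted(range(len(scores)), key=lambda i: (scores[i], i)), scores


def linreg_closed_form(x, y):
    """Slope/intercept from the covariance formulas."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    slope = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
    return slope, ym - slope * xm


def loewe_ci(d, dm, m, fa):
    """CI = sum_i d_i / (Dm_i (fa/(1-fa))^(1/m_i)) spelt out."""
    total = 0.0
    for di, dmi, mi in zip(d, dm, m):
        total += di / (dmi * (fa / (1.0 - fa)) ** (1.0 / mi))
    return total
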
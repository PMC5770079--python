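"""Independent, deliberately naive reference implementations for tests.

These are pure-Python re-derivations from first principles (explicit
sorting for ranks, covariance formula for Spearman, Gaussian elimination
on the normal equations for OLS, textbook pooled-variance t statistic).
They share no code path with the package implementations they check.
"""

from __future__ import annotations

import math


def average_ranks(v: list[float]) -> list[float]:
    """Ranks 1..n with ties given the average of their positions."""
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x: list[float], y: list[float]) -> float:
    """Pearson correlation of average ranks, from the covariance formula."""
    rx, ry = average_ranks(list(x)), average_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in rx) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in ry) / n)
    return cov / (sx * sy)


def solve_normal_equations(design: list[list[float]], y: list[float]) -> list[float]:
    """OLS coefficients via explicit normal equations + Gaussian elimination."""
    n = len(design)
    k = len(design[0])
    ata = [[sum(design[r][i] * design[r][j] for r in range(n)) for j in range(k)]
           for i in range(k)]
    aty = [sum(design[r][i] * y[r] for r in range(n)) for i in range(k)]
    # Gaussian elimination with partial pivoting on the augmented system.
    aug = [row[:] + [aty[i]] for i, row in enumerate(ata)]
    for col in range(k):
        pivot = max(range(col, k), key=lambda r: abs(aug[r][col]))
        if abs(aug[pivot][col]) < 1e-12:
            raise ValueError("singular normal equations")
        aug[col], aug[pivot] = aug[pivot], aug[col]
        for r in range(col + 1, k):
            factor = aug[r][col] / aug[col][col]
            for c in range(col, k + 1):
                aug[r][c] -= factor * aug[col][c]
    coef = [0.0] * k
    for r in range(k - 1, -1, -1):
        s = aug[r][k] - sum(aug[r][c] * coef[c] for c in range(r + 1, k))
        coef[r] = s / aug[r][r]
    return coef


def pooled_t_oracle(a: list[float], b: list[float]) -> tuple[float, int]:
    """Textbook pooled-variance two-sample t statistic and its df."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((v - ma) ** 2 for v in a)
    ssb = sum((v - mb) ** 2 for v in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, df
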
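"""Independent brute-force oracles used to verify the vectorized code paths.

These deliberately use naive Python loops and share no code with the
package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def im_bruteforce(thsp: np.ndarray, gray_levels: int) -> float:
    """Inertia moment by explicit triple loops: rows, time, COM cells."""
    counts = [[0] * gray_levels for _ in range(gray_levels)]
    n_rows, n_cols = thsp.shape
    for r in range(n_rows):
        for t in range(n_cols - 1):
            counts[int(thsp[r, t])][int(thsp[r, t + 1])] += 1
    im = 0.0
    for i in range(gray_levels):
        row_total = sum(counts[i])
        if row_total == 0:
            continue
        for j in range(gray_levels):
            im += counts[i][j] / row_total * (i - j) ** 2
    return im


def glcm_stats_bruteforce(quantized: np.ndarray, levels: int, offset: tuple[int, int]):
    """ASM, ENT, INE, COR of one symmetric normalized GLCM by pair counting.

    ``offset`` is the (row, col) displacement of the second pixel; the
    symmetric matrix counts both (i, j) and (j, i) for every pair.
    """
    counts = [[0] * levels for _ in range(levels)]
    h, w = quantized.shape
    dr, dc = offset
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                i, j = int(quantized[r, c]), int(quantized[r2, c2])
                counts[i][j] += 1
                counts[j][i] += 1
    total = sum(sum(row) for row in counts)
    p = [[counts[i][j] / total for j in range(levels)] for i in range(levels)]
    asm = sum(p[i][j] ** 2 for i in range(levels) for j in range(levels))
    ent = -sum(
        p[i][j] * math.log(p[i][j])
        for i in range(levels)
        for j in range(levels)
        if p[i][j] > 0
    )
    ine = sum(p[i][j] * (i - j) ** 2 for i in range(levels) for j in range(levels))
    pi = [sum(p[i][j] for j in range(levels)) for i in range(levels)]
    pj = [sum(p[i][j] for i in range(levels)) for j in range(levels)]
    mu_i = sum(i * pi[i] for i in range(levels))
    mu_j = sum(j * pj[j] for j in range(levels))
    var_i = sum((i - mu_i) ** 2 * pi[i] for i in range(levels))
    var_j = sum((j - mu_j) ** 2 * pj[j] for j in range(levels))
    if var_i <= 1e-15 or var_j <= 1e-15:
        cor = 0.0
    else:
        cov = sum(
            (i - mu_i) * (j - mu_j) * p[i][j]
            for i in range(levels)
            for j in range(levels)
        )
        cor = cov / math.sqrt(var_i * var_j)
    return asm, ent, ine, cor


def pearson_closed_form(x, y) -> float:
    """Textbook Pearson r from raw sums."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den
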
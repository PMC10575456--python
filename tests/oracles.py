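"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written long-hand (explicit loops, no shared code with
the package) so that agreement with the package is informative.
"""

from __future__ import annotations

import math

import numpy as np

#: The four unit-displacement directions of the default co-occurrence setup,
#: as (row, col) offsets: east, south-east, south, south-west.
UNIT_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))


def glcm_bruteforce(codes: np.ndarray, levels: int,
                    offsets=UNIT_OFFSETS, symmetric: bool = True) -> np.ndarray:
    """Count co-occurring code pairs pair by pair, normalize per offset,
    average over offsets."""
    h, w = codes.shape
    mats = []
    for dy, dx in offsets:
        m = np.zeros((levels, levels))
        for i in range(h):
            for j in range(w):
                i2, j2 = i + dy, j + dx
                if 0 <= i2 < h and 0 <= j2 < w:
                    m[codes[i, j], codes[i2, j2]] += 1.0
        if symmetric:
            m = m + m.T
        mats.append(m / m.sum())
    return np.mean(mats, axis=0)


def texture_bruteforce(p: np.ndarray) -> dict[str, float]:
    """All eight texture statistics via an explicit double loop."""
    n = p.shape[0]
    mean = sum(i * p[i, j] for i in range(n) for j in range(n))
    var = sum(p[i, j] * (i - mean) ** 2 for i in range(n) for j in range(n))
    con = sum(p[i, j] * (i - j) ** 2 for i in range(n) for j in range(n))
    dis = sum(p[i, j] * abs(i - j) for i in range(n) for j in range(n))
    hom = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    ent = -sum(p[i, j] * math.log(p[i, j])
               for i in range(n) for j in range(n) if p[i, j] > 0)
    sm = sum(p[i, j] ** 2 for i in range(n) for j in range(n))
    mu_i = sum(i * p[i, j] for i in range(n) for j in range(n))
    mu_j = sum(j * p[i, j] for i in range(n) for j in range(n))
    sd_i = math.sqrt(sum(p[i, j] * (i - mu_i) ** 2 for i in range(n) for j in range(n)))
    sd_j = math.sqrt(sum(p[i, j] * (j - mu_j) ** 2 for i in range(n) for j in range(n)))
    if sd_i == 0 or sd_j == 0:
        corr = 0.0
    else:
        corr = sum(p[i, j] * (i - mu_i) * (j - mu_j)
                   for i in range(n) for j in range(n)) / (sd_i * sd_j)
    return {"mean": mean, "var": var, "con": con, "dis": dis,
            "hom": hom, "ent": ent, "sm": sm, "corr": corr}


def entropy_weights_bruteforce(norm: np.ndarray):
    """Entropy-weight method in long-hand loops."""
    m, n = norm.shape
    e = []
    for i in range(n):
        col_sum = sum(norm[j, i] for j in range(m))
        acc = 0.0
        for j in range(m):
            pij = norm[j, i] / col_sum
            if pij > 0:
                acc += pij * math.log(pij)
        e.append(-acc / math.log(m))
    d = [1.0 - ei for ei in e]
    total = sum(d)
    w = [di / total for di in d]
    return np.array(e), np.array(w)


def pearson_bruteforce(x, y):
    """Sample Pearson correlation from explicit sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    sxx = sum((x[i] - mx) ** 2 for i in range(n))
    syy = sum((y[i] - my) ** 2 for i in range(n))
    return sxy / math.sqrt(sxx * syy)
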
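"""Independent brute-force reference implementations used only by tests.

Everything here enumerates naively — pixel pairs, runs, label assignments —
and stays deliberately separate from the package's vectorized code paths.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def glcm_bruteforce(pixels: np.ndarray, levels: int, offsets, symmetric: bool) -> np.ndarray:
    """Co-occurrence probabilities by explicit enumeration of pixel pairs."""
    h, w = pixels.shape
    counts = np.zeros((levels, levels))
    for dr, dc in offsets:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    counts[pixels[r, c], pixels[r2, c2]] += 1
                    if symmetric:
                        counts[pixels[r2, c2], pixels[r, c]] += 1
    return counts / counts.sum()


def glcm_features_bruteforce(P: np.ndarray) -> dict[str, float]:
    g = P.shape[0]
    contrast = homogeneity = dissimilarity = asm = 0.0
    for i in range(g):
        for j in range(g):
            contrast += (i - j) ** 2 * P[i, j]
            homogeneity += P[i, j] / (1 + (i - j) ** 2)
            dissimilarity += abs(i - j) * P[i, j]
            asm += P[i, j] ** 2
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mi = sum(i * pi[i] for i in range(g))
    mj = sum(j * pj[j] for j in range(g))
    vi = sum((i - mi) ** 2 * pi[i] for i in range(g))
    vj = sum((j - mj) ** 2 * pj[j] for j in range(g))
    if vi * vj == 0:
        corr = 0.0
    else:
        corr = sum(
            (i - mi) * (j - mj) * P[i, j] for i in range(g) for j in range(g)
        ) / np.sqrt(vi * vj)
    return {
        "contrast": contrast,
        "homogeneity": homogeneity,
        "correlation": corr,
        "dissimilarity": dissimilarity,
        "angular_second_moment": asm,
    }


def runs_bruteforce(pixels: np.ndarray, directions) -> list[tuple[int, int]]:
    """All maximal (level, length) runs along the requested scan directions."""
    runs = []
    for d in directions:
        lines = pixels if d == 0 else pixels.T
        for line in lines:
            k = 0
            while k < len(line):
                j = k
                while j < len(line) and line[j] == line[k]:
                    j += 1
                runs.append((int(line[k]), j - k))
                k = j
    return runs


def rlm_features_bruteforce(runs, n_pixels: int) -> dict[str, float]:
    nr = len(runs)
    sre = sum(1.0 / (l * l) for _, l in runs) / nr
    lre = sum(float(l * l) for _, l in runs) / nr
    levels = {}
    lengths = {}
    for g, l in runs:
        levels[g] = levels.get(g, 0) + 1
        lengths[l] = lengths.get(l, 0) + 1
    gln = sum(v * v for v in levels.values()) / nr
    rln = sum(v * v for v in lengths.values()) / nr
    return {"SRE": sre, "LRE": lre, "GLN": gln, "RLN": rln, "RP": nr / n_pixels}


def mann_whitney_exact_bruteforce(x, y) -> tuple[float, float]:
    """Exact two-sided p by enumerating all group assignments (tie-free)."""
    x, y = list(x), list(y)
    pooled = x + y
    n, m = len(x), len(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    mu = n * m / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(n + m), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in idx]
        u = u_stat(xs, ys)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    assert total == comb(n + m, n)
    return float(u_obs), count / total


def cld_is_valid(letters, P: np.ndarray, alpha: float) -> bool:
    """Letter display validity: a pair shares a letter iff p >= alpha."""
    k = len(letters)
    for i in range(k):
        for j in range(i + 1, k):
            shares = bool(set(letters[i]) & set(letters[j]))
            if (P[i, j] >= alpha) != shares:
                return False
    return True
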
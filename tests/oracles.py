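"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's message-passing machinery: genotype
posteriors come from exhaustive enumeration over all ordered-genotype
configurations, and relationship sums from a naive tabular recursion with
plain Python loops.
"""

from __future__ import annotations

import itertools

import numpy as np

from hybridpeel import Pedigree
from hybridpeel.peeling import KERNEL, hw_prior


def enumerate_posteriors(ped: Pedigree, pen: np.ndarray, seg: np.ndarray,
                         p: float) -> np.ndarray:
    """Exact single-locus posteriors by summing over all 4^n configurations.

    pen and seg are (n, 4); founders use a Hardy-Weinberg prior at allele
    frequency p; children use the segregation-weighted transmission kernel.
    """
    n = ped.n
    prior = hw_prior(np.array(p))
    trans = [np.einsum("s,sabc->abc", seg[i], KERNEL) for i in range(n)]
    post = np.zeros((n, 4))
    for cfg in itertools.product(range(4), repeat=n):
        w = 1.0
        for i in range(n):
            w *= pen[i, cfg[i]]
            s, d = ped.sire[i], ped.dam[i]
            if s == -1 and d == -1:
                w *= prior[cfg[i]]
            else:
                w *= trans[i][cfg[s], cfg[d], cfg[i]]
            if w == 0.0:
                break
        else:
            for i in range(n):
                post[i, cfg[i]] += w
    return post / post.sum(axis=1, keepdims=True)


def tabular_relationship(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the textbook recursion, pure loops."""
    n = ped.n
    A = [[0.0] * n for _ in range(n)]
    for i in range(n):
        s, d = int(ped.sire[i]), int(ped.dam[i])
        for j in range(i):
            val = 0.0
            if s != -1:
                val += 0.5 * A[s][j]
            if d != -1:
                val += 0.5 * A[d][j]
            A[i][j] = A[j][i] = val
        A[i][i] = 1.0 + (0.5 * A[s][d] if (s != -1 and d != -1) else 0.0)
    return np.array(A)


def pearson(x, y) -> float:
    """Plain-arithmetic Pearson correlation (loop form)."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    vx = sum((a - mx) ** 2 for a in x) / n
    vy = sum((b - my) ** 2 for b in y) / n
    return cov / (vx ** 0.5 * vy ** 0.5)
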
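"""Independent brute-force oracles for the turnover statistics.

Deliberately naive scalar-loop implementations, written straight from the
index definitions and kept free of any code shared with the package, so
they can certify the vectorized implementations.
"""

from __future__ import annotations

import numpy as np


def chao_jaccard_oracle(x, y) -> float:
    """Chao abundance-based Jaccard dissimilarity, scalar loops."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = sum(x)
    m = sum(y)
    assert n > 0 and m > 0
    shared = [i for i in range(len(x)) if x[i] > 0 and y[i] > 0]
    if not shared:
        return 1.0

    def one_side(a, na, b, nb):
        f1 = sum(1 for i in shared if b[i] == 1)
        f2 = sum(1 for i in shared if b[i] == 2)
        if f2 == 0:
            f2 = 1
        total = sum(a[i] for i in shared) / na
        corr = ((nb - 1.0) / nb) * (f1 / (2.0 * f2)) * sum(
            a[i] for i in shared if b[i] == 1
        ) / na
        return min(1.0, total + corr)

    U = one_side(x, n, y, m)
    V = one_side(y, m, x, n)
    sim = U * V / (U + V - U * V)
    return 1.0 - sim


def mean_pairwise_oracle(fk, fl, D, species_centered=True):
    """D_kl by explicit double loop over ordered species pairs.

    Returns (value, degenerate_flag).
    """
    fk = np.asarray(fk, float)
    fl = np.asarray(fl, float)
    fk = fk / fk.sum()
    fl = fl / fl.sum()
    num = 0.0
    wsum = 0.0
    S = len(fk)
    for i in range(S):
        for j in range(S):
            if i == j:
                continue
            num += D[i][j] * fk[i] * fl[j]
            wsum += fk[i] * fl[j]
    if species_centered:
        if wsum <= 0:
            return 0.0, True
        return num / wsum, False
    return num, False


def bst_oracle(fk, fl, D, species_centered=True):
    """B_st by composing the brute-force D terms; NaN when D_kl = 0."""
    dkl, _ = mean_pairwise_oracle(fk, fl, D, species_centered)
    dkk, _ = mean_pairwise_oracle(fk, fk, D, species_centered)
    dll, _ = mean_pairwise_oracle(fl, fl, D, species_centered)
    if dkl == 0.0:
        return float("nan")
    return 1.0 - ((dkk + dll) / 2.0) / dkl


def random_instance(rng, max_species=8):
    """A random small pair of communities plus a random metric-free distance
    matrix (symmetric, zero diagonal)."""
    S = int(rng.integers(2, max_species + 1))
    D = rng.uniform(0.1, 5.0, size=(S, S))
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    while True:
        x = rng.poisson(2.0, size=S)
        y = rng.poisson(2.0, size=S)
        if x.sum() > 0 and y.sum() > 0:
            return x, y, D
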
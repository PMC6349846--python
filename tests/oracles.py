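"""Independent oracle implementations used only by the tests.

Everything here is written directly from the classical definitions with
exact rational arithmetic (fractions.Fraction), deliberately sharing no code
with the package: summation-form estimators from a spectrum, brute-force
mean pairwise differences from genotypes, and Tajima's variance constants
derived from scratch.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def sfs_theta_pi(xi) -> float:
    m = len(xi) - 1
    tot = sum(Fraction(int(xi[i]) * i * (m - i)) for i in range(m + 1))
    return float(tot / Fraction(math.comb(m, 2)))


def sfs_theta_w(xi) -> float:
    m = len(xi) - 1
    s = sum(int(x) for x in xi[1:-1])
    a1 = sum(Fraction(1, k) for k in range(1, m))
    return float(Fraction(s) / a1)


def sfs_theta_h(xi) -> float:
    m = len(xi) - 1
    tot = sum(Fraction(int(xi[i]) * i * i) for i in range(1, m))
    return float(tot / Fraction(math.comb(m, 2)))


def sfs_theta_l(xi) -> float:
    m = len(xi) - 1
    tot = sum(Fraction(int(xi[i]) * i) for i in range(1, m))
    return float(tot / Fraction(m - 1))


def sfs_tajimas_d(xi) -> float:
    m = len(xi) - 1
    s = sum(int(x) for x in xi[1:-1])
    if s == 0:
        return math.nan
    a1 = sum(Fraction(1, k) for k in range(1, m))
    a2 = sum(Fraction(1, k * k) for k in range(1, m))
    b1 = Fraction(m + 1, 3 * (m - 1))
    b2 = Fraction(2 * (m * m + m + 3), 9 * m * (m - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(m + 2) / (a1 * m) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    pi = sum(Fraction(int(xi[i]) * i * (m - i)) for i in range(m + 1)) / Fraction(
        math.comb(m, 2)
    )
    w = Fraction(s) / a1
    var = e1 * s + e2 * s * (s - 1)
    return float(pi - w) / math.sqrt(float(var))


def sfs_fay_wu_h(xi) -> float:
    s = sum(int(x) for x in xi[1:-1])
    if s == 0:
        return math.nan
    return sfs_theta_pi(xi) - sfs_theta_h(xi)


def brute_force_pi(dosage: np.ndarray) -> float:
    """Mean pairwise Hamming distance over all chromosome pairs.

    Diploid dosages are expanded into two haplotypes each (dosage 1 ->
    (0, 1)); at any site the number of differing pairs depends only on the
    derived count, so the arbitrary phasing is irrelevant.
    """
    haps = []
    for j in range(dosage.shape[1]):
        col = dosage[:, j]
        h1 = (col >= 1).astype(int)
        h2 = (col == 2).astype(int)
        haps += [h1, h2]
    total = 0
    npairs = 0
    for a, b in itertools.combinations(haps, 2):
        total += int(np.sum(a != b))
        npairs += 1
    return total / npairs


def hudson_fst_site(p1: float, p2: float, m1: int, m2: int) -> tuple[float, float]:
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (m1 - 1) - p2 * (1 - p2) / (m2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den
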
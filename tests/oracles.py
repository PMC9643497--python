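"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle is deliberately naive (exact rational arithmetic, O(n^2)
scans) and shares no code with the implementation it checks.
"""

from fractions import Fraction
from math import factorial

import numpy as np


def hwe_exact_oracle(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact HWE test p by full enumeration in integer arithmetic.

    P(n_het = h | n, n_rare) is proportional to the integer weight
    w(h) = n! * 2^h / (n_hom_rare! h! n_hom_common!); the p-value is the
    exact rational sum of weights no larger than the observed weight over
    the total, evaluated without any floating-point intermediate.
    """
    n = n_hom1 + n_het + n_hom2
    r = 2 * min(n_hom1, n_hom2) + n_het          # rare allele count
    weights = {}
    for h in range(r % 2, min(r, 2 * n - r) + 1, 2):
        hom_rare = (r - h) // 2
        hom_common = n - h - hom_rare
        weights[h] = (factorial(n) * 2 ** h
                      // (factorial(hom_rare) * factorial(h)
                          * factorial(hom_common)))
    obs = weights[n_het]
    num = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(num, sum(weights.values())))


def greedy_clump_oracle(p: np.ndarray, chrom: np.ndarray, pos: np.ndarray,
                        snp_id: np.ndarray, r2: np.ndarray,
                        r2_max: float, window_bp: float,
                        p_index_max: float = 1.0) -> list[int]:
    """Reference greedy clumping on a precomputed full r^2 matrix."""
    order = sorted(range(len(p)), key=lambda i: (p[i], pos[i], snp_id[i]))
    removed = set()
    kept = []
    for i in order:
        if i in removed or p[i] > p_index_max:
            continue
        kept.append(i)
        removed.add(i)
        for j in order:
            if j in removed:
                continue
            if (chrom[j] == chrom[i] and abs(pos[j] - pos[i]) <= window_bp
                    and r2[i, j] > r2_max):
                removed.add(j)
    return sorted(kept, key=lambda i: (chrom[i], pos[i]))


def pearson_r2_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson correlation squared, complete data."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = (n * (x * x).sum() - sx * sx) * (n * (y * y).sum() - sy * sy)
    return float(num * num / den)


def wald_ratio_oracle(y: np.ndarray, x: np.ndarray, z: np.ndarray,
                      C: np.ndarray | None = None) -> float:
    """cov(z~, y~) / cov(z~, x~) after residualizing everything on [1, C]."""
    n = len(y)
    D = np.ones((n, 1)) if C is None else np.column_stack([np.ones(n), C])
    P = D @ np.linalg.pinv(D)
    yr, xr, zr = y - P @ y, x - P @ x, z - P @ z
    return float((zr @ yr) / (zr @ xr))


def interval_count_oracle(chroms, positions, chrom, lo, hi) -> int:
    return sum(1 for c, p in zip(chroms, positions)
               if str(c) == str(chrom) and lo <= p <= hi)
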
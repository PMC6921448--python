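"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths (and, where feasible, the
libraries) used by the package: plain-python Gotoh alignment, factorial
Poisson pmf, exact-fraction hypergeometric and HWE enumerations.
"""

from fractions import Fraction
from math import comb, exp, factorial, lgamma, log

NEG = float("-inf")


def linear_smith_waterman(read, ref, match=1, mismatch=-4, gap_open=6, gap_extend=1):
    """Plain affine-gap local alignment score (Gotoh, python loops)."""
    m, n = len(read), len(ref)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            a, b = read[i - 1].upper(), ref[j - 1].upper()
            s = match if (a == b and a in "ACGT" and b in "ACGT") else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def poisson_pmf(k, mean):
    """Poisson pmf from the factorial formula (log-gamma for large k)."""
    if mean < 0:
        raise ValueError("negative mean")
    if mean == 0:
        return 1.0 if k == 0 else 0.0
    if k <= 170:
        return mean**k * exp(-mean) / factorial(k)
    return exp(k * log(mean) - mean - lgamma(k + 1))


def poisson_log_pmf(k, mean):
    if mean == 0:
        return 0.0 if k == 0 else NEG
    return k * log(mean) - mean - lgamma(k + 1)


def fisher_exact_two_sided(table):
    """Two-sided Fisher exact p of a 2x2 table by exact-fraction
    hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return Fraction(0)
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(0, min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs:
            total += px
    return float(min(total, Fraction(1)))


def hwe_exact_p(n_hom_ref, n_het, n_hom_alt):
    """Exact HWE p-value by exact-fraction enumeration of het counts."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    rare = min(2 * n_hom_alt + n_het, 2 * n_hom_ref + n_het)
    if rare == 0:
        return 1.0
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        n_rare_hom = (rare - h) // 2
        n_common_hom = n - h - n_rare_hom
        if n_common_hom < 0:
            continue
        w = Fraction(
            factorial(n) * 2**h,
            factorial(n_rare_hom) * factorial(h) * factorial(n_common_hom),
        )
        weights[h] = w
    total = sum(weights.values())
    p_obs = weights[n_het]
    p = sum(w for w in weights.values() if w <= p_obs)
    return float(Fraction(p, total))


def normal_sf(z):
    """Upper-tail standard normal probability via erfc."""
    from math import erfc, sqrt

    return 0.5 * erfc(z / sqrt(2.0))
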
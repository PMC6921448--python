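"""Independent oracles used by the acceptance report (plain-python
Gotoh alignment and exact-fraction HWE enumeration)."""

from fractions import Fraction
from math import factorial

NEG = float("-inf")


def linear_smith_waterman(read, ref, match=1, mismatch=-4, gap_open=6, gap_extend=1):
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


def hwe_exact_p(n_hom_ref, n_het, n_hom_alt):
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
        weights[h] = Fraction(
            factorial(n) * 2**h,
            factorial(n_rare_hom) * factorial(h) * factorial(n_common_hom),
        )
    total = sum(weights.values())
    p_obs = weights[n_het]
    return float(Fraction(sum(w for w in weights.values() if w <= p_obs), total))
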
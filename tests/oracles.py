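"""Independent brute-force oracles used to check the package's numerics.

These deliberately avoid the code paths (and libraries) they verify:
exact big-integer binomials for the hypergeometric tail, the step-up
definition for Benjamini-Hochberg, exact rational arithmetic for Pearson r.
"""

from fractions import Fraction
from math import comb, isqrt, sqrt


def hypergeom_tail_exact(N: int, K: int, n: int, x: int) -> Fraction:
    """P(X >= x) by summing C(K,i) C(N-K, n-i) / C(N,n) with big integers."""
    total = comb(N, n)
    acc = 0
    for i in range(x, min(n, K) + 1):
        acc += comb(K, i) * comb(N - K, n - i)
    return Fraction(acc, total)


def bh_stepup(pvals):
    """Benjamini-Hochberg adjusted p-values straight from the definition:
    sort ascending, q_i = p_i * m / i, enforce monotonicity from the largest
    rank down, cap at 1, restore input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        q = pvals[i] * m / rank
        running = min(running, q)
        adj[i] = min(running, 1.0)
    return adj


def pearson_exact(x, y) -> float:
    """Pearson r via exact rational sums (float only at the final sqrt)."""
    n = len(x)
    mx = Fraction(sum(Fraction(v) for v in x), n)
    my = Fraction(sum(Fraction(v) for v in y), n)
    num = sum((Fraction(a) - mx) * (Fraction(b) - my) for a, b in zip(x, y))
    dx = sum((Fraction(a) - mx) ** 2 for a in x)
    dy = sum((Fraction(b) - my) ** 2 for b in y)
    return float(num) / (sqrt(float(dx)) * sqrt(float(dy)))
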
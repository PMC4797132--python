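"""Shared statistical kernels: hypergeometric upper tail and p-value adjustment.

The same over-representation kernel serves two purposes in the package:
testing whether a candidate linker gene touches more seed genes than chance
predicts, and testing whether an annotation term is enriched in a query gene
set.  Both are upper-tail hypergeometric probabilities

    P(X >= x)  with  X ~ Hypergeom(N, K, n)

i.e. drawing ``n`` items from a universe of ``N`` of which ``K`` are marked,
and observing ``x`` or more marked draws.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def hypergeom_tail(N: int, K: int, n: int, x: int) -> float:
    """Upper-tail probability P(X >= x), X ~ Hypergeom(N, K, n).

    Parameters
    ----------
    N : universe size.
    K : number of marked items in the universe.
    n : number of draws.
    x : observed count of marked draws.
    """
    N, K, n, x = int(N), int(K), int(n), int(x)
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if not (0 <= x <= min(n, K)):
        raise ValueError(f"x={x} outside [0, min(n={n}, K={K})]")
    if x == 0:
        return 1.0
    # sf(x-1) = P(X > x-1) = P(X >= x)
    return float(hypergeom.sf(x - 1, N, K, n))


def adjust_pvalues(pvals, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment. ``method``: 'bh', 'bonferroni' or 'none'."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0 or method == "none":
        return p.copy()
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment {method!r}")
    return multipletests(p, method=key)[1]
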
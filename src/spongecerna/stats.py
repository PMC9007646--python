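"""Small shared statistical kernels.

The upper-tail hypergeometric probability is the single kernel behind
both the shared-miRNA sponge test and gene-set over-representation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(population N, successes K, draws n).

    By convention k = 0 gives 1 (the certain event).
    """
    if N <= 0:
        raise ValueError("population size N must be positive")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if k <= 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided t-test p (df = n - 2).

    Returns (nan, nan) when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations for a correlation p-value")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return r, min(p, 1.0)
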
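"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own algorithms: the non-wear oracle
enumerates every candidate window, and the variance-component oracle works
directly from the ANOVA sums of squares with explicit Python loops.
"""

from __future__ import annotations

import numpy as np


def nonwear_oracle(counts, window_min: int = 60, tolerance_min: int = 2) -> np.ndarray:
    """Exhaustive-scan non-wear flags.

    A minute is non-wear iff it lies inside *some* interval [i, j] of length
    >= window_min whose endpoints are zero-count minutes and whose interior
    contains no stretch of more than tolerance_min consecutive non-zero
    minutes.  Every zero start position is scanned forward.
    """
    counts = np.asarray(counts)
    n = len(counts)
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        if counts[i] != 0:
            continue
        consec = 0
        for j in range(i, n):
            if counts[j] == 0:
                consec = 0
                if j - i + 1 >= window_min:
                    flags[i : j + 1] = True
            else:
                consec += 1
                if consec > tolerance_min:
                    break
    return flags


def oneway_anova_oracle(values, groups):
    """Method-of-moments variance components via explicit sums of squares.

    Returns ``(sigma2_between, sigma2_residual)`` using MSW = SSW/(N-k),
    MSB = SSB/(k-1) and the unbalanced effective group size
    n0 = (N - sum(n_i^2)/N)/(k-1); negative between-variance is floored at 0.
    """
    values = list(map(float, values))
    groups = list(groups)
    by_group: dict = {}
    for v, g in zip(values, groups):
        by_group.setdefault(g, []).append(v)
    n = len(values)
    k = len(by_group)
    grand = sum(values) / n
    ssb = 0.0
    ssw = 0.0
    sum_sq_sizes = 0
    for obs in by_group.values():
        m = sum(obs) / len(obs)
        ssb += len(obs) * (m - grand) ** 2
        ssw += sum((v - m) ** 2 for v in obs)
        sum_sq_sizes += len(obs) ** 2
    msw = ssw / (n - k)
    msb = ssb / (k - 1)
    n0 = (n - sum_sq_sizes / n) / (k - 1)
    s2b = max(0.0, (msb - msw) / n0)
    return s2b, msw
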
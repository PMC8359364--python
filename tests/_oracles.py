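"""Independent reference computations used by the test suite.

These deliberately avoid the library code paths they check: the ANOVA
oracle works from the explicit Hotelling-T2 matrix formula, and the
agreement oracle enumerates every ratable pair by brute force.
"""

import numpy as np
from scipy import stats as sps


def hotelling_oracle(y):
    """Wilks' lambda / F / p from the explicit T2 = n dbar' S^-1 dbar form."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    d = np.column_stack([y[:, i] - y[:, i + 1] for i in range(k - 1)])
    dbar = d.mean(axis=0)
    s = np.cov(d.T, ddof=1)
    t2 = n * dbar @ np.linalg.inv(np.atleast_2d(s)) @ dbar
    lam = 1 / (1 + t2 / (n - 1))
    f = t2 * (n - k + 1) / ((n - 1) * (k - 1))
    p = sps.f.sf(f, k - 1, n - k + 1)
    return lam, f, p


def kripp_oracle_ordinal(values):
    """Ordinal Krippendorff's alpha by exhaustive pair enumeration."""
    values = np.asarray(values, dtype=float)
    units = [row[~np.isnan(row)] for row in values]
    units = [u for u in units if len(u) >= 2]
    levels = sorted({v for u in units for v in u})
    n_g = {c: 0.0 for c in levels}
    pairs = []
    for u in units:
        m = len(u)
        for i in range(m):
            n_g[u[i]] += 1.0
            for j in range(m):
                if i != j:
                    pairs.append((u[i], u[j], 1.0 / (m - 1)))
    n_tot = sum(n_g.values())

    def delta2(c, k):
        lo, hi = min(c, k), max(c, k)
        span = sum(n_g[g] for g in levels if lo <= g <= hi)
        return (span - (n_g[c] + n_g[k]) / 2.0) ** 2

    d_o = sum(wt * delta2(c, k) for c, k, wt in pairs)
    d_e = sum(n_g[c] * n_g[k] * delta2(c, k)
              for c in levels for k in levels if c != k) / (n_tot - 1)
    return 1.0 if d_e == 0 else 1.0 - d_o / d_e
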
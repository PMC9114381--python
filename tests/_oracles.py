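"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use only elementary numpy and textbook formulas, never the
code paths they validate.
"""

import numpy as np


def welch_oracle(x, y):
    """Welch two-sample t statistic and Welch-Satterthwaite df, from the
    textbook formulas."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df

def ks_d_oracle(x, y):
    """Two-sample KS D: max |F1 - F2| over the pooled sample points."""
    x, y = np.sort(np.asarray(x, float)), np.sort(np.asarray(y, float))
    pooled = np.concatenate([x, y])
    f1 = np.searchsorted(x, pooled, side="right") / len(x)
    f2 = np.searchsorted(y, pooled, side="right") / len(y)
    return float(np.max(np.abs(f1 - f2)))

def percentile_type7_oracle(values, q):
    """Sort-and-interpolate percentile (linear interpolation between order
    statistics, the type-7 convention)."""
    v = np.sort(np.asarray(values, float))
    h = (len(v) - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))

def connected_components_oracle(xy, cutoff):
    """Brute-force single-linkage components: O(n^2) pairwise distances and
    repeated flood fill."""
    xy = np.asarray(xy, float)
    n = len(xy)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    adj = d <= cutoff
    labels = -np.ones(n, dtype=int)
    comp = 0
    for s in range(n):
        if labels[s] >= 0:
            continue
        stack = [s]
        labels[s] = comp
        while stack:
            i = stack.pop()
            for j in np.nonzero(adj[i])[0]:
                if labels[j] < 0:
                    labels[j] = comp
                    stack.append(j)
        comp += 1
    return labels
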